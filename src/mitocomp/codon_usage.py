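"""Codon usage bias statistics: RSCU, ENC, CBI, G+Cc, G+C3s.

RSCU (relative synonymous codon usage) is a codon's count divided by the
mean count of its synonymous family, so uniform usage gives 1.0 throughout
and family sums equal family sizes.

ENC (effective number of codons) uses Wright's homozygosity estimator
generalized to the split-family scheme: per observed family the
homozygosity is F = (n * sum(p_i^2) - 1) / (n - 1), families are grouped by
size k, and ENC = sum_k N_k / mean(F)_k, capped at the sense-codon count.
Under the split scheme for the invertebrate mitochondrial code this spans
[22, 62].

CBI (codon bias index) rescales preferred-codon usage so that random usage
scores 0 and exclusive use of preferred codons scores 1:
CBI = (N_pref - N_rand) / (N_tot - N_rand) with N_rand = sum over families
of (family total / family size).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .codes import (DEFAULT_CODE, family_of, sense_codons, stop_codons,
                    synonymous_families, translation_table)
from .model import AnnotatedGenome


@dataclass
class CodonUsageTable:
    """Per-codon counts over one gene or gene set, with derived statistics."""

    scope: str
    counts: dict[str, int]
    code: int = DEFAULT_CODE
    n_stop: int = 0
    n_partial: int = 0

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def family_counts(self) -> list[tuple[tuple[str, ...], list[int]]]:
        return [(fam, [self.counts.get(c, 0) for c in fam])
                for fam in synonymous_families(self.code)]


def count_codons(cds_list: Iterable[str], code: int = DEFAULT_CODE,
                 scope: str = "set") -> CodonUsageTable:
    """Count sense codons over in-frame coding sequences.

    Stop codons and trailing partial codons are tallied separately and
    excluded from the sense-codon counts; codons containing N are dropped.
    """
    cds_list = list(cds_list)
    if not cds_list:
        raise ValueError("empty CDS list")
    stops = stop_codons(code)
    counts: Counter = Counter()
    n_stop = n_partial = 0
    for cds in cds_list:
        cds = cds.upper()
        whole = len(cds) - len(cds) % 3
        if whole < len(cds):
            n_partial += 1
        for i in range(0, whole, 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                continue
            if codon in stops:
                n_stop += 1
            else:
                counts[codon] += 1
    return CodonUsageTable(scope, dict(counts), code, n_stop, n_partial)


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """RSCU per sense codon; NaN for codons of unobserved families."""
    out: dict[str, float] = {}
    for fam, cnts in table.family_counts():
        total = sum(cnts)
        if total == 0:
            for c in fam:
                out[c] = math.nan
            continue
        mean = total / len(fam)
        for c, k in zip(fam, cnts):
            out[c] = k / mean
    return out


def enc(table: CodonUsageTable) -> float:
    """Wright's effective number of codons under the split-family scheme.

    Families observed with fewer than 2 codons contribute no F estimate;
    unobserved families of a size class take the class mean F.  Returns NaN
    when no family has 2 or more counted codons.
    """
    by_size: dict[int, list[float]] = {}
    census: Counter = Counter()
    for fam, cnts in table.family_counts():
        k = len(fam)
        if k < 2:
            continue
        census[k] += 1
        n = sum(cnts)
        if n < 2:
            continue
        p2 = sum((c / n) ** 2 for c in cnts)
        f_hat = (n * p2 - 1) / (n - 1)
        if f_hat > 0:  # F<=0 (tiny samples) carries no usable estimate
            by_size.setdefault(k, []).append(f_hat)
    if not by_size:
        return math.nan
    total = 0.0
    for k, n_k in sorted(census.items()):
        fs = by_size.get(k)
        if not fs:
            continue  # whole size class unobserved: dropped from the sum
        f_bar = sum(fs) / len(fs)
        total += n_k / f_bar
    n_sense = len(sense_codons(table.code))
    return min(total, n_sense)


def preferred_codons(table: CodonUsageTable) -> dict[tuple[str, ...], str]:
    """Preferred codon per family: highest count, ties broken alphabetically."""
    out = {}
    for fam, cnts in table.family_counts():
        if len(fam) < 2:
            continue
        # fam is alphabetically sorted, so index() breaks ties alphabetically
        out[fam] = fam[cnts.index(max(cnts))]
    return out


def cbi(table: CodonUsageTable,
        preferred: dict[tuple[str, ...], str] | None = None) -> float:
    """Codon bias index over families of size >= 2; NaN when degenerate."""
    if preferred is None:
        preferred = preferred_codons(table)
    n_tot = n_pref = 0
    n_rand = 0.0
    for fam, cnts in table.family_counts():
        if len(fam) < 2:
            continue
        total = sum(cnts)
        n_tot += total
        n_rand += total / len(fam)
        pref = preferred.get(fam)
        if pref is not None:
            n_pref += table.counts.get(pref, 0)
    if n_tot == 0 or math.isclose(n_tot, n_rand):
        return math.nan
    return (n_pref - n_rand) / (n_tot - n_rand)


def gc_stats(table: CodonUsageTable) -> tuple[float, float]:
    """(G+Cc, G+C3s): GC over all positions of sense codons, and GC at
    third positions of codons in families of size >= 2."""
    gc_all = tot_all = gc3 = tot3 = 0
    fam_map = family_of(table.code)
    for codon, cnt in table.counts.items():
        gc_all += cnt * sum(b in "GC" for b in codon)
        tot_all += cnt * 3
        if len(fam_map[codon]) >= 2:
            gc3 += cnt * (codon[2] in "GC")
            tot3 += cnt
    return (gc_all / tot_all if tot_all else math.nan,
            gc3 / tot3 if tot3 else math.nan)


@dataclass
class StartStopRow:
    genome: str
    gene: str
    start_codon: str
    stop_codon: str
    truncated: bool


@dataclass
class StartStopTable:
    rows: list[StartStopRow]
    start_summary: dict[str, int] = field(init=False)
    stop_summary: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.start_summary = dict(Counter(r.start_codon for r in self.rows))
        self.stop_summary = dict(Counter(r.stop_codon for r in self.rows))


def tabulate_start_stop(genomes: Sequence[AnnotatedGenome]) -> StartStopTable:
    """Start/stop codon per (genome, PCG), with truncated-stop flags."""
    rows = []
    for g in genomes:
        for f in g.by_kind("PCG"):
            cds = g.feature_seq(f)
            if len(cds) < 6:
                raise ValueError(f"{g.identifier}:{f.name} shorter than 6 bases")
            rem = len(cds) % 3
            if rem:
                stop = cds[-rem:]
                truncated = True
            else:
                stop = cds[-3:]
                truncated = stop not in stop_codons(g.genetic_code)
                if truncated:
                    stop = stop[:2] if stop[:2] == "TA" else stop
            rows.append(StartStopRow(g.identifier, f.name, cds[:3], stop,
                                     truncated))
    return StartStopTable(rows)


@dataclass
class CorrelationReport:
    pairs: dict[tuple[str, str], tuple[str, float]]  # (x, y) -> (sign, R^2)


_STAT_FUNCS = ("CBI", "ENC", "GCc", "GC3s")


def genome_bias_stats(table: CodonUsageTable) -> dict[str, float]:
    gcc, gc3s = gc_stats(table)
    return {"CBI": cbi(table), "ENC": enc(table), "GCc": gcc, "GC3s": gc3s}


def bias_correlations(tables: Sequence[CodonUsageTable]) -> CorrelationReport:
    """Least-squares fits between codon-bias statistics across genomes.

    Reports slope sign and R^2 for CBI~ENC, CBI~GCc, CBI~GC3s, ENC~GCc,
    ENC~GC3s.  Requires at least 3 genomes and nonzero variance.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 genomes for correlation analysis")
    stats_by_genome = [genome_bias_stats(t) for t in tables]
    pairs = [("CBI", "ENC"), ("CBI", "GCc"), ("CBI", "GC3s"),
             ("ENC", "GCc"), ("ENC", "GC3s")]
    out = {}
    for x, y in pairs:
        xs = np.array([s[x] for s in stats_by_genome])
        ys = np.array([s[y] for s in stats_by_genome])
        if np.allclose(xs.std(), 0) or np.allclose(ys.std(), 0):
            raise ValueError(f"zero variance in {x} or {y}")
        fit = stats.linregress(xs, ys)
        out[(x, y)] = ("-" if fit.slope < 0 else "+", fit.rvalue ** 2)
    return CorrelationReport(out)


def to_rna(codon: str) -> str:
    """Display helper: DNA codon to the RNA notation used in reports."""
    return codon.replace("T", "U")
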