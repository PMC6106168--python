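"""Ka/Ks estimation by Nei-Gojobori (1986) counting with Jukes-Cantor
correction.

Synonymous (S) and nonsynonymous (N) site fractions per codon come from
enumerating all nine single-base mutants with equal weights; mutations to
stop codons count as nonsynonymous.  Differences between a codon pair are
pathway-averaged: every minimal mutational pathway between the two codons
is enumerated, pathways passing through stop codons are excluded, and the
synonymous/nonsynonymous classification of each step is averaged over the
remaining pathways.  Observed proportions ps = Sd/S and pn = Nd/N are
corrected for multiple hits with d = -(3/4) ln(1 - (4/3) p), defined for
p < 3/4; saturated pairs are flagged, never clamped.

Ka/Ks < 1 indicates purifying selection, > 1 positive selection.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

from .codes import BASES, DEFAULT_CODE, stop_codons, translation_table


class SaturationError(ValueError):
    """Observed proportion >= 3/4: Jukes-Cantor correction undefined."""


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p), p in [0, 0.75)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 0.75; distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def count_sites(codon: str, code: int = DEFAULT_CODE) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one sense codon.

    Enumerates the nine single-base mutants; s = 3 * n_syn/9, n = 3 - s.
    """
    codon = codon.upper()
    tt = translation_table(code)
    stops = stop_codons(code)
    if codon in stops:
        raise ValueError(f"{codon} is a stop codon")
    if codon not in tt:
        raise ValueError(f"{codon} contains ambiguous bases")
    aa = tt[codon]
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in stops and tt[mut] == aa:
                syn += 1
    s = 3.0 * syn / 9.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str,
                      code: int = DEFAULT_CODE) -> tuple[float, float] | None:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    Returns None when every minimal pathway passes through a stop codon.
    """
    tt = translation_table(code)
    stops = stop_codons(code)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_tot = nd_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops and step < len(order) - 1:
                ok = False
                break
            if nxt in stops:  # endpoint should be sense; defensive
                ok = False
                break
            if tt[nxt] == tt[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_tot += sd
            nd_tot += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return sd_tot / n_paths, nd_tot / n_paths


@dataclass
class KaKsResult:
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    codons_used: int
    skipped: int = 0

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S else math.nan

    @property
    def pn(self) -> float:
        return self.Nd / self.N if self.N else math.nan

    @property
    def Ks(self) -> float:
        return jukes_cantor(self.ps)

    @property
    def Ka(self) -> float:
        return jukes_cantor(self.pn)

    @property
    def ratio(self) -> float:
        ks = self.Ks
        if ks == 0:
            return math.nan
        return self.Ka / ks

    @property
    def saturated(self) -> bool:
        return self.ps >= 0.75 or self.pn >= 0.75


def ng86_pair(cds1: str, cds2: str, code: int = DEFAULT_CODE,
              pair: tuple[str, str] = ("seq1", "seq2")) -> KaKsResult:
    """NG86 Ka/Ks for an aligned, gap-free codon pair of sequences.

    Codon pairs containing N, gaps or stop codons are skipped.  Site counts
    S and N are averaged over the two sequences; S + N = 3 * codons_used.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2):
        raise ValueError("sequences must be aligned to equal length")
    if len(cds1) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    stops = stop_codons(code)
    tt = translation_table(code)
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i : i + 3], cds2[i : i + 3]
        if (set(a + b) - set(BASES)) or a in stops or b in stops:
            skipped += 1
            continue
        d = _pair_differences(a, b, code)
        if d is None:
            skipped += 1
            continue
        sa, na = count_sites(a, code)
        sb, nb = count_sites(b, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += d[0]
        Nd += d[1]
        used += 1
    if used == 0:
        raise ValueError("no usable codon pairs")
    return KaKsResult(pair, S, N, Sd, Nd, used, skipped)


@dataclass
class GeneKaKsSummary:
    gene: str
    mean_ka: float
    mean_ks: float
    ratio: float
    n_pairs: int
    n_flagged: int


def gene_kaks_summary(
    alignments: Mapping[str, Mapping[str, str]],
    code: int = DEFAULT_CODE,
    mean_of_ratios: bool = False,
) -> list[GeneKaKsSummary]:
    """Per-gene mean Ka, mean Ks and their ratio over all species pairs.

    `alignments` maps gene -> {species: aligned CDS}.  Saturated pairs are
    excluded from the means and counted in n_flagged.  The default ratio is
    mean(Ka)/mean(Ks); `mean_of_ratios` averages per-pair ratios instead
    (pairs with Ks = 0 excluded).
    """
    out = []
    for gene, seqs in alignments.items():
        species = sorted(seqs)
        if len(species) < 2:
            warnings.warn(f"{gene}: fewer than 2 species, skipped")
            continue
        kas, kss, ratios = [], [], []
        flagged = 0
        for s1, s2 in itertools.combinations(species, 2):
            res = ng86_pair(seqs[s1], seqs[s2], code, (s1, s2))
            if res.saturated:
                flagged += 1
                continue
            kas.append(res.Ka)
            kss.append(res.Ks)
            if res.Ks > 0:
                ratios.append(res.Ka / res.Ks)
        if not kas:
            warnings.warn(f"{gene}: all pairs saturated")
            continue
        mean_ka = sum(kas) / len(kas)
        mean_ks = sum(kss) / len(kss)
        if mean_of_ratios:
            ratio = sum(ratios) / len(ratios) if ratios else math.nan
        else:
            ratio = mean_ka / mean_ks if mean_ks > 0 else math.nan
        out.append(GeneKaKsSummary(gene, mean_ka, mean_ks, ratio,
                                   len(kas), flagged))
    return out
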