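"""Nucleotide composition and strand-skew statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), the classic
strand-asymmetry measures.  N bases are excluded from every numerator and
denominator.  Class reports pool genes by concatenation (count sums), not by
averaging per-gene ratios.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .model import AnnotatedGenome


@dataclass
class SkewReport:
    unit: str
    base_counts: dict[str, int]
    at_content: float = field(init=False)
    at_skew: float = field(init=False)
    gc_skew: float = field(init=False)

    def __post_init__(self) -> None:
        c = self.base_counts
        a, t, g, cc = c.get("A", 0), c.get("T", 0), c.get("G", 0), c.get("C", 0)
        total = a + t + g + cc
        if total == 0:
            raise ValueError(f"{self.unit}: no unambiguous bases")
        self.at_content = (a + t) / total
        self.at_skew = (a - t) / (a + t) if a + t else math.nan
        self.gc_skew = (g - cc) / (g + cc) if g + cc else math.nan

    @property
    def length(self) -> int:
        return sum(self.base_counts.values())


def base_counts(seq: str) -> dict[str, int]:
    c = Counter(seq.upper())
    return {b: c.get(b, 0) for b in "ACGTN"}


def at_content(seq: str) -> float:
    return SkewReport("seq", base_counts(seq)).at_content


def at_skew(seq: str) -> float:
    return SkewReport("seq", base_counts(seq)).at_skew


def gc_skew(seq: str) -> float:
    return SkewReport("seq", base_counts(seq)).gc_skew


def class_composition(genome: AnnotatedGenome) -> list[SkewReport]:
    """Per-gene and pooled composition reports.

    One report per PCG and per rRNA, then pooled PCG / rRNA / tRNA classes
    (on concatenated strand-corrected sequences) and the whole genome.
    Classes without members yield no row.
    """
    reports: list[SkewReport] = []
    pooled: dict[str, Counter] = {"PCG": Counter(), "rRNA": Counter(),
                                  "tRNA": Counter()}
    for f in genome.sorted_features():
        if f.kind not in pooled:
            continue
        counts = base_counts(genome.feature_seq(f))
        pooled[f.kind].update(counts)
        if f.kind in ("PCG", "rRNA"):
            reports.append(SkewReport(f.name, counts))
    for kind in ("PCG", "rRNA", "tRNA"):
        if sum(pooled[kind].values()):
            reports.append(SkewReport(kind,
                                      {b: pooled[kind].get(b, 0) for b in "ACGTN"}))
    reports.append(SkewReport("genome", base_counts(genome.sequence)))
    return reports
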