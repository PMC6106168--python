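"""Core data model: gene features on a circular annotated mitogenome.

Coordinates follow the GenBank convention: 1-based, inclusive.  A feature
may wrap the origin of the circular molecule, expressed as start > end.
All mitogenome analyses in this package read from :class:`AnnotatedGenome`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .codes import DEFAULT_CODE, revcomp

KINDS = ("PCG", "rRNA", "tRNA", "NCR")

PCG_NAMES = (
    "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)
RRNA_NAMES = ("rrnL", "rrnS")

_NAME_PATTERNS = {
    "PCG": re.compile(r"^(cox[1-3]|cytb|nad[1-6]|nad4L|atp[68])$"),
    "rRNA": re.compile(r"^rrn[LS]$"),
    "tRNA": re.compile(r"^trna[A-Z][0-9]*$"),
    "NCR": re.compile(r"^.+$"),
}


def base_symbol(name: str) -> str:
    """Strip the numeric copy suffix of duplicated tRNA isotypes.

    trnaM2 -> trnaM; non-tRNA names are returned unchanged.
    """
    m = re.match(r"^(trna[A-Z])[0-9]+$", name)
    return m.group(1) if m else name


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the circular molecule."""

    name: str
    kind: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; start > end means the feature wraps
    strand: str = "+"
    anticodon: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based; start/end must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not _NAME_PATTERNS[self.kind].match(self.name):
            raise ValueError(f"name {self.name!r} not valid for kind {self.kind}")

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def wraps(self) -> bool:
        return self.start > self.end


@dataclass
class AnnotatedGenome:
    """A circular nucleotide sequence plus its ordered gene features."""

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    genetic_code: int = DEFAULT_CODE

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValueError(
                    f"feature {f.name} coordinates exceed sequence length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def region(self, start: int, end: int) -> str:
        """Sequence of [start, end] (1-based inclusive), wrapping if start > end."""
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def feature_seq(self, feat: GeneFeature) -> str:
        """Strand-corrected sequence of a feature."""
        s = self.region(feat.start, feat.end)
        return revcomp(s) if feat.strand == "-" else s

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in {self.identifier}")

    def by_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def extract_cds(self, name: str) -> str:
        """Strand-corrected coding sequence of a named PCG.

        Length is a multiple of 3 except for truncated-stop genes
        (3n+1 or 3n+2); callers that need the flag use len(seq) % 3.
        """
        feat = self.get(name)
        if feat.kind != "PCG":
            raise ValueError(f"{name} is a {feat.kind}, not a PCG")
        return self.feature_seq(feat)

    def rotated(self, offset: int) -> "AnnotatedGenome":
        """Genome with the origin moved forward by `offset` bases."""
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]

        def shift(pos: int) -> int:
            return (pos - 1 - offset) % n + 1

        feats = [replace(f, start=shift(f.start), end=shift(f.end))
                 for f in self.features]
        return AnnotatedGenome(self.identifier, seq, feats,
                               self.circular, self.genetic_code)
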