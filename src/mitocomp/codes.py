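"""Genetic code tables and synonymous-family machinery.

Translation tables come from NCBI via Biopython. The default throughout the
package is table 5 (invertebrate mitochondrial), under which TGA encodes
tryptophan, AGA/AGG encode serine and ATA encodes methionine, leaving 62
sense codons and only TAA/TAG as stops.

Synonymous families are built with the codonW-style split convention: codons
of one amino acid that differ in their first two positions form separate
families (Leu -> TTR + CTN; Ser under table 5 -> TCN + AGN).  For table 5
this yields 13 two-fold and 9 four-fold families covering all 62 sense
codons, so ENC ranges from 22 (one codon per family) to 62 (uniform usage).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

DEFAULT_CODE = 5


@lru_cache(maxsize=None)
def translation_table(code: int = DEFAULT_CODE) -> dict[str, str]:
    """Map every codon (DNA, upper case) to its amino acid, '*' for stops."""
    table = CodonTable.unambiguous_dna_by_id[code]
    out = dict(table.forward_table)
    for stop in table.stop_codons:
        out[stop] = "*"
    return out


@lru_cache(maxsize=None)
def stop_codons(code: int = DEFAULT_CODE) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[code].stop_codons)


@lru_cache(maxsize=None)
def start_codons(code: int = DEFAULT_CODE) -> tuple[str, ...]:
    """Allowed initiation codons: the metazoan ATN set plus GTG."""
    return ("ATG", "ATA", "ATT", "ATC", "GTG")


@lru_cache(maxsize=None)
def sense_codons(code: int = DEFAULT_CODE) -> tuple[str, ...]:
    stops = stop_codons(code)
    return tuple(c for c in CODONS if c not in stops)


@lru_cache(maxsize=None)
def synonymous_families(code: int = DEFAULT_CODE) -> tuple[tuple[str, ...], ...]:
    """Partition of sense codons into split synonymous families.

    Family key is (amino acid, first two codon bases); members are sorted
    alphabetically.  Families of size 1 exist for some codes (e.g. standard
    code Trp) and are excluded from ENC/CBI/GC3s statistics by the callers.
    """
    tt = translation_table(code)
    groups: dict[tuple[str, str], list[str]] = {}
    for codon in sense_codons(code):
        groups.setdefault((tt[codon], codon[:2]), []).append(codon)
    return tuple(tuple(sorted(v)) for _, v in sorted(groups.items()))


@lru_cache(maxsize=None)
def family_of(code: int = DEFAULT_CODE) -> dict[str, tuple[str, ...]]:
    """Codon -> its synonymous family tuple."""
    out: dict[str, tuple[str, ...]] = {}
    for fam in synonymous_families(code):
        for codon in fam:
            out[codon] = fam
    return out


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, code: int = DEFAULT_CODE) -> str:
    """Translate codon by codon; trailing partial codon is ignored.

    Codons containing N translate to 'X'; internal stops appear as '*'.
    Raises ValueError on non-ACGTN characters.
    """
    cds = cds.upper()
    bad = set(cds) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in CDS: {sorted(bad)}")
    tt = translation_table(code)
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aa.append(tt.get(codon, "X"))
    return "".join(aa)
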