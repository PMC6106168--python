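"""Readers and writers for annotated mitogenomes.

Two dialects are supported: GenBank flat files (via Biopython) and a plain
FASTA + tab-separated feature table with columns
``name kind start end strand anticodon``.  Gene symbols are normalized to
the canonical lower-case forms (cox1..cox3, cytb, nad1..nad6, nad4L, atp6,
atp8, rrnL, rrnS, trnaX) through a bundled synonym table; duplicated tRNA
isotypes receive numeric suffixes in encounter order.
"""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO

from .model import AnnotatedGenome, GeneFeature, PCG_NAMES, RRNA_NAMES

TABLE_COLUMNS = ("name", "kind", "start", "end", "strand", "anticodon")

# Canonical symbol per common GenBank gene/product spelling (upper-cased key).
_SYNONYMS = {
    "COX1": "cox1", "COI": "cox1", "CO1": "cox1", "COXI": "cox1",
    "CYTOCHROME C OXIDASE SUBUNIT 1": "cox1",
    "CYTOCHROME C OXIDASE SUBUNIT I": "cox1",
    "COX2": "cox2", "COII": "cox2", "CO2": "cox2", "COXII": "cox2",
    "CYTOCHROME C OXIDASE SUBUNIT 2": "cox2",
    "CYTOCHROME C OXIDASE SUBUNIT II": "cox2",
    "COX3": "cox3", "COIII": "cox3", "CO3": "cox3", "COXIII": "cox3",
    "CYTOCHROME C OXIDASE SUBUNIT 3": "cox3",
    "CYTOCHROME C OXIDASE SUBUNIT III": "cox3",
    "CYTB": "cytb", "COB": "cytb", "CYB": "cytb", "CYTOCHROME B": "cytb",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATP SYNTHASE F0 SUBUNIT 6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATP SYNTHASE F0 SUBUNIT 8": "atp8",
    "ND1": "nad1", "NAD1": "nad1", "NADH DEHYDROGENASE SUBUNIT 1": "nad1",
    "ND2": "nad2", "NAD2": "nad2", "NADH DEHYDROGENASE SUBUNIT 2": "nad2",
    "ND3": "nad3", "NAD3": "nad3", "NADH DEHYDROGENASE SUBUNIT 3": "nad3",
    "ND4": "nad4", "NAD4": "nad4", "NADH DEHYDROGENASE SUBUNIT 4": "nad4",
    "ND4L": "nad4L", "NAD4L": "nad4L",
    "NADH DEHYDROGENASE SUBUNIT 4L": "nad4L",
    "ND5": "nad5", "NAD5": "nad5", "NADH DEHYDROGENASE SUBUNIT 5": "nad5",
    "ND6": "nad6", "NAD6": "nad6", "NADH DEHYDROGENASE SUBUNIT 6": "nad6",
    "RRNL": "rrnL", "16S": "rrnL", "16S RIBOSOMAL RNA": "rrnL",
    "L-RRNA": "rrnL", "LARGE SUBUNIT RIBOSOMAL RNA": "rrnL", "LSU": "rrnL",
    "RRNS": "rrnS", "12S": "rrnS", "12S RIBOSOMAL RNA": "rrnS",
    "S-RRNA": "rrnS", "SMALL SUBUNIT RIBOSOMAL RNA": "rrnS", "SSU": "rrnS",
}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def normalize_symbol(raw: str, kind: str) -> str | None:
    """Map a gene/product qualifier to a canonical symbol, or None."""
    key = raw.strip().upper()
    if kind in ("PCG", "rRNA"):
        if key in _SYNONYMS:
            return _SYNONYMS[key]
        low = raw.strip()
        if low in PCG_NAMES or low in RRNA_NAMES:
            return low
        return None
    # tRNA: accept trnX / trnaX / tRNA-Xxx forms
    m = re.match(r"^TRNA?[-_ ]?([A-Z])[0-9]*$", key)
    if m:
        return "trna" + m.group(1)
    m = re.match(r"^TRNA[-_ ]?([A-Z]{3})", key)
    if m and m.group(1) in _AA3_TO_1:
        return "trna" + _AA3_TO_1[m.group(1)]
    return None


def _suffix_duplicates(feats: list[GeneFeature]) -> list[GeneFeature]:
    """Give duplicated tRNA isotypes numeric suffixes in encounter order."""
    from dataclasses import replace

    counts: dict[str, int] = {}
    for f in feats:
        counts[f.name] = counts.get(f.name, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for f in feats:
        if f.kind == "tRNA" and counts[f.name] > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            out.append(replace(f, name=f"{f.name}{seen[f.name]}"))
        else:
            out.append(f)
    return out


def read_genbank(path: str | Path, code: int | None = None) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    CDS/rRNA/tRNA features are mapped to canonical symbols; features whose
    qualifiers cannot be mapped are kept as NCR with a note.  Raises
    ValueError on records without features or with out-of-range coordinates.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    n = len(seq)
    feats: list[GeneFeature] = []
    for sf in record.features:
        kind = {"CDS": "PCG", "rRNA": "rRNA", "tRNA": "tRNA"}.get(sf.type)
        if kind is None:
            continue
        start = int(sf.location.start) + 1
        end = int(sf.location.end)
        if start > n or end > n or start < 1:
            raise ValueError(
                f"feature at {start}..{end} exceeds sequence length {n}"
            )
        strand = "-" if sf.location.strand == -1 else "+"
        raw_names = sf.qualifiers.get("gene", []) + sf.qualifiers.get("product", [])
        name = None
        for raw in raw_names:
            name = normalize_symbol(raw, kind)
            if name:
                break
        anticodon = None
        if kind == "tRNA":
            ac = sf.qualifiers.get("anticodon", [None])[0]
            if ac:
                m = re.search(r"[ACGTUacgtu]{3}(?=\)|$)", ac)
                if m:
                    anticodon = m.group(0).upper().replace("U", "T")
        if name is None:
            feats.append(GeneFeature(
                name=f"unmapped{len(feats)}", kind="NCR",
                start=start, end=end, strand=strand,
                notes=f"unmapped qualifiers: {raw_names}"))
        else:
            feats.append(GeneFeature(name=name, kind=kind, start=start,
                                     end=end, strand=strand,
                                     anticodon=anticodon))
    if not feats:
        raise ValueError(f"no CDS/rRNA/tRNA features in {path}")
    feats = _suffix_duplicates(feats)
    code = code if code is not None else 5
    topo = record.annotations.get("topology", "circular")
    return AnnotatedGenome(record.id or record.name, seq, feats,
                           circular=(topo != "linear"), genetic_code=code)


def read_feature_table(fasta: str | Path, table: str | Path,
                       code: int = 5) -> AnnotatedGenome:
    """Read a genome from one-sequence FASTA plus a TSV feature table."""
    record = SeqIO.read(str(fasta), "fasta")
    seq = str(record.seq).upper()
    feats: list[GeneFeature] = []
    names_seen: set[str] = set()
    with open(table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[: len(TABLE_COLUMNS)]) != TABLE_COLUMNS:
            raise ValueError(
                f"feature table header must be {TABLE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name, kind, start, end, strand = parts[:5]
            anticodon = parts[5] if len(parts) > 5 and parts[5] else None
            if strand not in "+-":
                raise ValueError(
                    f"line {lineno}: strand must be '+' or '-', got {strand!r}")
            if name in names_seen:
                raise ValueError(f"line {lineno}: duplicate feature name {name}")
            names_seen.add(name)
            feats.append(GeneFeature(name=name, kind=kind,
                                     start=int(start), end=int(end),
                                     strand=strand, anticodon=anticodon))
    return AnnotatedGenome(record.id, seq, feats, genetic_code=code)


def write_feature_table(genome: AnnotatedGenome, fasta: str | Path,
                        table: str | Path) -> None:
    """Inverse of :func:`read_feature_table` (round-trips exactly)."""
    with open(fasta, "w") as fh:
        fh.write(f">{genome.identifier}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    with open(table, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for f in genome.features:
            fh.write("\t".join([f.name, f.kind, str(f.start), str(f.end),
                                f.strand, f.anticodon or ""]) + "\n")
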