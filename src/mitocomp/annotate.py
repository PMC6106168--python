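"""Gene-boundary re-annotation for draft mitogenome annotations.

Mitogenome gene boundaries from BLAST-based draft annotation are often off
by a few codons.  The rules applied here are the standard curation
conventions for compact animal mitogenomes:

* the start of each protein-coding gene is moved to the first in-frame
  allowed start codon (ATN or GTG) that does not overlap the upstream gene;
* the stop is the first in-frame full stop codon that does not overlap the
  downstream gene; when no full stop fits, a truncated terminator ("TA" or
  "T") abutting the downstream gene is recorded — such stops are completed
  by polyadenylation of the transcript;
* rRNA boundaries, which cannot be called precisely from sequence alone,
  are extended to abut the flanking genes.

The adjustment is idempotent and returns a change log for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .codes import start_codons, stop_codons
from .model import AnnotatedGenome, GeneFeature

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class BoundaryChange:
    gene: str
    field: str          # "start" | "end"
    old: int
    new: int
    note: str = ""


class AnnotationError(ValueError):
    pass


def _signed_mod(x: int, n: int) -> int:
    """Circular distance folded into (-n/2, n/2]: overlaps come out negative."""
    return (x + n // 2) % n - n // 2


def _codon(seq: str, anchor0: int, offset: int, strand: str) -> str:
    """Codon at transcriptional offset from a 0-based anchor position."""
    n = len(seq)
    if strand == "+":
        return "".join(seq[(anchor0 + offset + i) % n] for i in range(3))
    return "".join(_COMP[seq[(anchor0 - offset - i) % n]] for i in range(3))


def adjust_gene_boundaries(
    genome: AnnotatedGenome,
) -> tuple[AnnotatedGenome, list[BoundaryChange]]:
    """Apply start/stop and rRNA boundary rules; returns (genome, change log)."""
    n = len(genome.sequence)
    seq = genome.sequence
    starts_ok = set(start_codons(genome.genetic_code))
    stops = stop_codons(genome.genetic_code)
    feats = genome.sorted_features()
    changes: list[BoundaryChange] = []

    def near0(f: GeneFeature, side: str) -> int:
        """0-based genomic position of a feature boundary."""
        return (f.start - 1) if side == "start" else (f.end - 1)

    for idx, f in enumerate(feats):
        if f.kind != "PCG":
            continue
        prev_f = feats[idx - 1]
        next_f = feats[(idx + 1) % len(feats)]
        if f.strand == "+":
            up, down = prev_f, next_f
            anchor0 = f.start - 1
            up_end0 = near0(up, "end")
            down_start0 = near0(down, "start")
            gap_up = _signed_mod(anchor0 - up_end0 - 1, n)
            L = f.length(n)
            gap_down = _signed_mod(down_start0 - (anchor0 + L) % n, n)
        else:
            up, down = next_f, prev_f
            anchor0 = f.end - 1
            up_end0 = near0(up, "start")
            down_start0 = near0(down, "end")
            gap_up = _signed_mod(up_end0 - anchor0 - 1, n)
            L = f.length(n)
            gap_down = _signed_mod((anchor0 - L) % n - down_start0, n)

        # --- start: first in-frame allowed codon clear of the upstream gene;
        # upstream extension is only valid while the frame stays open
        k_min = -3 * (gap_up // 3)
        k = -3
        while k >= k_min:
            if _codon(seq, anchor0, k, f.strand) in stops:
                k_min = k + 3
                break
            k -= 3
        k_max = L - 6
        new_start_off = None
        k = k_min
        while k <= k_max:
            if _codon(seq, anchor0, k, f.strand) in starts_ok:
                new_start_off = k
                break
            k += 3
        if new_start_off is None:
            raise AnnotationError(
                f"{f.name}: no valid in-frame start codon before the stop")

        # --- stop: first in-frame full stop clear of the downstream gene
        limit = L + gap_down          # transcriptional offset of downstream gene
        j = new_start_off + 3
        end_off = None
        truncated = ""
        while j + 2 <= limit - 1:
            if _codon(seq, anchor0, j, f.strand) in stops:
                end_off = j + 2
                break
            j += 3
        if end_off is None:
            leftover = limit - j
            tail = _codon(seq, anchor0, j, f.strand)[: max(leftover, 0)]
            if leftover == 2 and tail == "TA":
                end_off, truncated = j + 1, "TA"
            elif leftover == 1 and tail == "T":
                end_off, truncated = j, "T"
            else:
                raise AnnotationError(
                    f"{f.name}: no in-frame stop codon fits before {down.name}")

        if f.strand == "+":
            new_start = (anchor0 + new_start_off) % n + 1
            new_end = (anchor0 + end_off) % n + 1
        else:
            new_end = (anchor0 - new_start_off) % n + 1
            new_start = (anchor0 - end_off) % n + 1
        note = f"truncated stop {truncated}" if truncated else ""
        nf = f
        if new_start != f.start:
            changes.append(BoundaryChange(f.name, "start", f.start, new_start, note))
            nf = replace(nf, start=new_start)
        if new_end != f.end:
            changes.append(BoundaryChange(f.name, "end", f.end, new_end, note))
            nf = replace(nf, end=new_end)
        if truncated and "truncated" not in nf.notes:
            nf = replace(nf, notes=(nf.notes + " " if nf.notes else "")
                         + f"truncated stop {truncated}")
        feats[idx] = nf

    # --- rRNAs extend to abut flanking genes
    for idx, f in enumerate(feats):
        if f.kind != "rRNA":
            continue
        prev_f = feats[idx - 1]
        next_f = feats[(idx + 1) % len(feats)]
        new_start = prev_f.end % n + 1
        new_end = (next_f.start - 2) % n + 1
        nf = f
        if new_start != f.start:
            changes.append(BoundaryChange(f.name, "start", f.start, new_start,
                                          f"abut {prev_f.name}"))
            nf = replace(nf, start=new_start)
        if new_end != f.end:
            changes.append(BoundaryChange(f.name, "end", f.end, new_end,
                                          f"abut {next_f.name}"))
            nf = replace(nf, end=new_end)
        feats[idx] = nf

    adjusted = AnnotatedGenome(genome.identifier, genome.sequence, feats,
                               genome.circular, genome.genetic_code)
    return adjusted, changes
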