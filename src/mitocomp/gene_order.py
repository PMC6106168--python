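"""Circular gene-order comparison: shared blocks and tRNA translocations.

Gene orders are circular lists of signed gene symbols.  A shared block is a
maximal run of genes that is contiguous, in the same order and with the
same relative strands, in both genomes; blocks of fewer than 2 genes are
not reported.  A run that matches in reversed order with flipped strands is
an inversion candidate and is reported separately.

By default symbols private to one genome are dropped before block finding
(`drop_missing=True`); with `drop_missing=False` private symbols break
blocks instead.  Duplicated tRNA isotype copies compare by base symbol, so
a second trnaM is an insertion rather than a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnnotatedGenome, base_symbol


@dataclass
class GeneOrder:
    genome_id: str
    symbols: list[str]               # circular order
    strands: list[str] = field(default_factory=list)
    filter: str = ""

    def __post_init__(self) -> None:
        if not self.strands:
            self.strands = ["+"] * len(self.symbols)
        if len(self.symbols) != len(self.strands):
            raise ValueError("symbols and strands must have equal length")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene symbols must be unique within an order")

    def __len__(self) -> int:
        return len(self.symbols)

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.symbols)
        return GeneOrder(self.genome_id,
                         self.symbols[k:] + self.symbols[:k],
                         self.strands[k:] + self.strands[:k], self.filter)

    def canonical(self) -> "GeneOrder":
        """Rotation starting at cox1 when present, else alphabetical minimum."""
        anchor = "cox1" if "cox1" in self.symbols else min(self.symbols)
        return self.rotated(self.symbols.index(anchor))


@dataclass
class SharedBlock:
    symbols: tuple[str, ...]
    positions: tuple[int, int]  # start index in each canonical order
    inverted: bool = False


def extract_order(genome: AnnotatedGenome,
                  exclude_kinds: set[str] = frozenset()) -> GeneOrder:
    """Gene order by circular start coordinate, canonical rotation at cox1."""
    feats = [f for f in genome.sorted_features() if f.kind not in exclude_kinds]
    if not feats:
        raise ValueError("no features left after filtering")
    order = GeneOrder(genome.identifier,
                      [f.name for f in feats],
                      [f.strand for f in feats],
                      filter="-".join(sorted(exclude_kinds)))
    return order.canonical()


def _restrict(order: GeneOrder, keep: set[str]) -> GeneOrder:
    idx = [i for i, s in enumerate(order.symbols) if s in keep]
    return GeneOrder(order.genome_id,
                     [order.symbols[i] for i in idx],
                     [order.strands[i] for i in idx], order.filter)


def _adjacencies(order: GeneOrder) -> set[tuple[str, str, str, str]]:
    """Directed circular adjacencies with strands, in writing orientation.

    Orientation is kept genome-wide: a segment conserved only in the
    reverse-complement reading shows up through the inverted check, not as
    a forward block.
    """
    n = len(order)
    out = set()
    for i in range(n):
        j = (i + 1) % n
        out.add((order.symbols[i], order.strands[i],
                 order.symbols[j], order.strands[j]))
    return out


def shared_blocks(o1: GeneOrder, o2: GeneOrder,
                  drop_missing: bool = True) -> list[SharedBlock]:
    """Maximal shared circular gene blocks (length >= 2) of two genomes.

    Forward blocks partition o1's order (restricted to shared symbols when
    `drop_missing`); runs conserved only in inverted orientation are
    returned with ``inverted=True``.  Output is sorted by length
    (descending) then by symbols for determinism.
    """
    shared = set(o1.symbols) & set(o2.symbols)
    if not shared:
        raise ValueError("orders have no symbols in common")
    a = _restrict(o1, shared) if drop_missing else o1
    b = _restrict(o2, shared) if drop_missing else o2
    adj_b = _adjacencies(b)
    flip = {"+": "-", "-": "+"}
    n = len(a)
    pos_b = {s: i for i, s in enumerate(b.symbols)}

    def conserved(i: int, inverted: bool) -> bool:
        j = (i + 1) % n
        x, sx = a.symbols[i], a.strands[i]
        y, sy = a.symbols[j], a.strands[j]
        if x not in pos_b or y not in pos_b:
            return False
        if not inverted:
            return (x, sx, y, sy) in adj_b
        return (y, flip[sy], x, flip[sx]) in adj_b

    def chains(inverted: bool) -> list[SharedBlock]:
        good = [conserved(i, inverted) for i in range(n)]
        if n >= 2 and all(good):
            syms = tuple(a.symbols)
            return [SharedBlock(syms, (0, pos_b.get(syms[0], -1)), inverted)]
        blocks = []
        i = 0
        # start scanning just after a break so chains never split spuriously
        starts = [i for i in range(n) if not good[i - 1]]
        for s in starts:
            if not good[s]:
                continue
            run = [s]
            k = s
            while good[k]:
                k = (k + 1) % n
                run.append(k)
                if k == s:
                    break
            syms = tuple(a.symbols[i % n] for i in run)
            blocks.append(SharedBlock(syms, (s, pos_b.get(syms[0], -1)),
                                      inverted))
        return blocks

    forward = chains(False)
    taken = {s for blk in forward for s in blk.symbols}
    inverted = [blk for blk in chains(True)
                if not set(blk.symbols) & taken]
    out = forward + inverted
    out.sort(key=lambda blk: (-len(blk.symbols), blk.symbols))
    return out


@dataclass
class TranslocationReport:
    genome_id: str
    translocated: list[str]
    inserted: list[str]
    lost: list[str]


def detect_translocations(orders: list[GeneOrder],
                          reference: str) -> list[TranslocationReport]:
    """Per genome: translocated symbols (both neighbors differ from the
    reference, among shared symbols) plus inserted/lost symbols.

    tRNA copy suffixes are stripped before comparison, so trnaM2 in a genome
    whose reference has one trnaM counts as an insertion.
    """
    ref = next((o for o in orders if o.genome_id == reference), None)
    if ref is None:
        raise KeyError(f"reference {reference!r} not among orders")

    def bases(order: GeneOrder) -> list[str]:
        # unsuffixed copy keeps the base name; extra copies stay distinct
        groups: dict[str, list[str]] = {}
        for s in order.symbols:
            groups.setdefault(base_symbol(s), []).append(s)
        mapping: dict[str, str] = {}
        for b, members in groups.items():
            ordered = sorted(members, key=lambda s: (s != b, s))
            for rank, s in enumerate(ordered):
                mapping[s] = b if rank == 0 else f"{b}#{rank + 1}"
        return [mapping[s] for s in order.symbols]

    ref_syms = bases(ref)
    ref_set = set(ref_syms)

    def neighbors(symbols: list[str], keep: set[str]) -> dict[str, set[str]]:
        core = [s for s in symbols if s in keep]
        n = len(core)
        return {core[i]: {core[i - 1], core[(i + 1) % n]} for i in range(n)}

    reports = []
    for order in orders:
        if order.genome_id == reference:
            continue
        syms = bases(order)
        sym_set = set(syms)
        shared = sym_set & ref_set
        nb = neighbors(syms, shared)
        nb_ref = neighbors(ref_syms, shared)
        translocated = sorted(s for s in shared
                              if nb[s].isdisjoint(nb_ref[s]))
        inserted = sorted(s.replace("#", "") for s in sym_set - ref_set)
        lost = sorted(s.replace("#", "") for s in ref_set - sym_set)
        reports.append(TranslocationReport(order.genome_id, translocated,
                                           inserted, lost))
    return reports
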