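"""Synthetic mitogenomes and sequence pairs with known ground truth.

The generators emulate the properties of compact bivalve mitogenomes: a
circular molecule with 13 protein-coding genes, 2 rRNAs and 22 tRNAs, all
on one strand, AT-rich with controllable strand skews and codon bias, with
ATG starts and TAG stops.  They do not emulate indel processes, rate
heterogeneity along trees, or control-region repeat structure.

Every generator is deterministic for a fixed seed; the PRNG is NumPy's
PCG64 (the `numpy.random.default_rng` generator), which is stable across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import (DEFAULT_CODE, revcomp, sense_codons, stop_codons,
                    synonymous_families, translation_table)
from .model import AnnotatedGenome, GeneFeature
from .gene_order import GeneOrder

# typical vesicomyid-scale gene lengths (bp, multiples of 3 for PCGs)
PCG_LENGTHS = {
    "cox1": 1806, "cox2": 1101, "cox3": 861, "cytb": 1140,
    "nad1": 900, "nad2": 960, "nad3": 351, "nad4": 1302, "nad4L": 282,
    "nad5": 1650, "nad6": 480, "atp6": 702, "atp8": 162,
}
RRNA_LENGTHS = {"rrnL": 1237, "rrnS": 888}

# a single-strand gene order consistent with the conserved blocks of
# venerid/vesicomyid mitogenomes (rrnL between cytb and atp8, rrnS flanked
# by trnaT/trnaM, trnaG downstream of nad4L, trnaF after cox3)
DEFAULT_ORDER = [
    "cox1", "trnaP", "cox2", "trnaI", "cytb", "rrnL", "atp8", "trnaD",
    "nad4", "trnaH", "atp6", "nad3", "trnaA", "nad1", "trnaN", "trnaR",
    "trnaW", "nad5", "trnaE", "nad6", "nad4L", "trnaG", "nad2", "trnaV",
    "trnaL1", "trnaL2", "trnaS1", "trnaS2", "trnaC", "trnaQ", "trnaK",
    "trnaY", "trnaT", "rrnS", "trnaM", "cox3", "trnaF",
]

# one anticodon per tRNA isotype (revcomp of a codon for that amino acid
# under the invertebrate mitochondrial code)
_ISOTYPE_CODON = {
    "trnaA": "GCA", "trnaR": "CGA", "trnaN": "AAT", "trnaD": "GAT",
    "trnaC": "TGT", "trnaQ": "CAA", "trnaE": "GAA", "trnaG": "GGA",
    "trnaH": "CAC", "trnaI": "ATT", "trnaK": "AAA",
    "trnaM": "ATG", "trnaF": "TTT", "trnaP": "CCA", "trnaT": "ACA",
    "trnaW": "TGA", "trnaY": "TAT", "trnaV": "GTA",
    "trnaL1": "CTA", "trnaL2": "TTA", "trnaS1": "AGA", "trnaS2": "TCA",
}


def isotype_anticodon(name: str) -> str:
    codon = _ISOTYPE_CODON.get(name) or _ISOTYPE_CODON[name.rstrip("0123456789")]
    return revcomp(codon)


def canonical_trna(anticodon: str = "CAT", d_arm: bool = True) -> str:
    """A cloverleaf fixture satisfying every scanner constraint.

    GC-rich stems lock the intended parse: 7-bp acceptor, 4-bp D-stem with
    8-nt loop, 5-bp anticodon stem with 7-nt loop (anticodon central, U33
    conserved), variable loop, 5-bp T-stem with TTC-prefixed 7-nt loop.
    With the D-arm the fixture is 71 nt and forms 21 base pairs; without it
    (the DHU-armless serine architecture) the variable loop is lengthened
    to keep the molecule above the scanner's minimum length, giving 60 nt
    and 17 pairs.
    """
    acc5 = "GCGGCGG"
    d5, dloop = "GGCC", "TTTTAAAA"
    ac5 = "GCGCG"
    ac_loop = "CT" + anticodon.upper() + "AG"
    t5, tloop = "GGGCC", "TTCGAAT"
    if d_arm:
        middle = d5 + dloop + revcomp(d5) + "A"
        var = "ACTA"
    else:
        middle = ""
        var = "ACTATTGACT"
    return (acc5 + "TA" + middle
            + ac5 + ac_loop + revcomp(ac5)
            + var
            + t5 + tloop + revcomp(t5)
            + revcomp(acc5))


@dataclass
class SyntheticConfig:
    seed: int = 0
    genome_length: int = 15650
    at_target: float = 0.65
    at_skew_target: float = -0.15
    gc_skew_target: float = 0.30
    gene_census: dict[str, int] = field(
        default_factory=lambda: {"PCG": 13, "rRNA": 2, "tRNA": 22})
    codon_bias: float = 1.0       # weight multiplier for preferred codons
    order_template: list[str] = field(default_factory=lambda: list(DEFAULT_ORDER))
    code: int = DEFAULT_CODE

    def base_probs(self) -> dict[str, float]:
        at, gc = self.at_target, 1.0 - self.at_target
        return {
            "A": at * (1 + self.at_skew_target) / 2,
            "T": at * (1 - self.at_skew_target) / 2,
            "G": gc * (1 + self.gc_skew_target) / 2,
            "C": gc * (1 - self.gc_skew_target) / 2,
        }


def _codon_weights(cfg: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    """Sense-codon sampling distribution from base probabilities and bias."""
    probs = cfg.base_probs()
    codons = list(sense_codons(cfg.code))
    w = np.array([probs[c[0]] * probs[c[1]] * probs[c[2]] for c in codons])
    if cfg.codon_bias != 1.0:
        idx = {c: i for i, c in enumerate(codons)}
        for fam in synonymous_families(cfg.code):
            if len(fam) < 2:
                continue
            weights = [w[idx[c]] for c in fam]
            preferred = fam[int(np.argmax(weights))]
            w[idx[preferred]] *= cfg.codon_bias
    return codons, w / w.sum()


def _random_bases(rng: np.random.Generator, n: int,
                  probs: dict[str, float]) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=n, p=p / p.sum()))


def _random_cds(rng: np.random.Generator, length: int,
                cfg: SyntheticConfig) -> str:
    if length % 3:
        raise ValueError("PCG length must be a multiple of 3")
    codons, w = _codon_weights(cfg)
    n_inner = length // 3 - 2
    inner = rng.choice(np.array(codons), size=n_inner, p=w)
    return "ATG" + "".join(inner) + "TAG"


def generate_genome(cfg: SyntheticConfig) -> AnnotatedGenome:
    """Deterministic synthetic mitogenome with the requested census.

    Realized AT content lands within 0.02 of `at_target`; all genes are on
    the + strand, PCGs start with ATG and stop with TAG, tRNAs are
    cloverleaf fixtures, and gaps pad the molecule to `genome_length`.
    Raises ValueError when the census cannot fit.
    """
    rng = np.random.default_rng(cfg.seed)
    census = dict(cfg.gene_census)
    order = [s for s in cfg.order_template]
    by_kind = {"PCG": [s for s in order if s in PCG_LENGTHS],
               "rRNA": [s for s in order if s in RRNA_LENGTHS],
               "tRNA": [s for s in order if s.startswith("trna")]}
    for kind in ("PCG", "rRNA", "tRNA"):
        want = census.get(kind, 0)
        if want > len(by_kind[kind]):
            raise ValueError(
                f"census asks for {want} {kind} but template has "
                f"{len(by_kind[kind])}")
        drop = set(by_kind[kind][want:])
        order = [s for s in order if s not in drop]

    # fixed-sequence parts first (PCGs, tRNA fixtures); their composition is
    # constrained, so the free parts compensate to land on at_target
    spacers = [int(rng.integers(1, 3)) for _ in order]
    gene_seqs: dict[str, str | None] = {}
    for sym in order:
        if sym in PCG_LENGTHS:
            gene_seqs[sym] = _random_cds(rng, PCG_LENGTHS[sym], cfg)
        elif sym in RRNA_LENGTHS:
            gene_seqs[sym] = None
        else:
            gene_seqs[sym] = canonical_trna(isotype_anticodon(sym))
    fixed = "".join(s for s in gene_seqs.values() if s)
    fixed_at = fixed.count("A") + fixed.count("T")
    rrna_total = sum(RRNA_LENGTHS[s] for s in order if s in RRNA_LENGTHS)
    total = len(fixed) + rrna_total + sum(spacers)
    if total > cfg.genome_length:
        raise ValueError(
            f"census needs {total} bp, exceeding genome_length "
            f"{cfg.genome_length}")
    free_len = cfg.genome_length - len(fixed)
    at_free = (cfg.at_target * cfg.genome_length - fixed_at) / free_len
    probs = SyntheticConfig(
        at_target=float(np.clip(at_free, 0.05, 0.95)),
        at_skew_target=cfg.at_skew_target,
        gc_skew_target=cfg.gc_skew_target).base_probs()

    pieces: list[str] = []
    feats: list[GeneFeature] = []
    pos = 1
    for sym, spacer in zip(order, spacers):
        pieces.append(_random_bases(rng, spacer, probs))
        pos += spacer
        if sym in RRNA_LENGTHS:
            seq = _random_bases(rng, RRNA_LENGTHS[sym], probs)
            kind, anticodon = "rRNA", None
        elif sym in PCG_LENGTHS:
            seq = gene_seqs[sym]
            kind, anticodon = "PCG", None
        else:
            anticodon = isotype_anticodon(sym)
            seq = gene_seqs[sym]
            kind = "tRNA"
        pieces.append(seq)
        feats.append(GeneFeature(name=sym, kind=kind, start=pos,
                                 end=pos + len(seq) - 1, strand="+",
                                 anticodon=anticodon))
        pos += len(seq)
    pieces.append(_random_bases(rng, cfg.genome_length - (pos - 1), probs))
    return AnnotatedGenome(f"synthetic-{cfg.seed}", "".join(pieces), feats,
                           circular=True, genetic_code=cfg.code)


def mutate_cds_pair(cds: str, n_syn: int, n_nonsyn: int,
                    seed: int = 0,
                    code: int = DEFAULT_CODE) -> tuple[str, str]:
    """(original, mutant) differing by exactly n_syn synonymous and
    n_nonsyn nonsynonymous single-base codon changes; no codon hit twice.

    Changes never create stop codons; the result is verified by
    translation.  Raises ValueError when not enough eligible codons exist.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    tt = translation_table(code)
    stops = stop_codons(code)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]

    def options(codon: str, synonymous: bool) -> list[str]:
        if codon in stops or "N" in codon:
            return []
        out = []
        for p in range(3):
            for b in "ACGT":
                if b == codon[p]:
                    continue
                mut = codon[:p] + b + codon[p + 1 :]
                if mut in stops:
                    continue
                if (tt[mut] == tt[codon]) == synonymous:
                    out.append(mut)
        return out

    # interior codons only (leave start and stop untouched)
    idx_all = list(range(1, len(codons) - 1))
    rng.shuffle(idx_all)
    mutant = list(codons)
    used: set[int] = set()
    for want_syn, n_want in ((True, n_syn), (False, n_nonsyn)):
        done = 0
        for i in idx_all:
            if done == n_want:
                break
            if i in used:
                continue
            opts = options(codons[i], want_syn)
            if not opts:
                continue
            mutant[i] = opts[int(rng.integers(len(opts)))]
            used.add(i)
            done += 1
        if done < n_want:
            kind = "synonymous" if want_syn else "nonsynonymous"
            raise ValueError(f"only {done} of {n_want} {kind} changes possible")
    out = "".join(mutant)
    from .codes import translate
    if n_nonsyn == 0 and translate(out, code) != translate(cds, code):
        raise AssertionError("synonymous-only mutant changed the protein")
    return cds, out


def plant_proto_trna(flank_len: int, seed: int = 0,
                     anticodon: str = "CAT") -> tuple[str, tuple[int, str]]:
    """Intergenic region hiding a tRNA one insertion away from detection.

    Returns (region, (position, base)): the region is the canonical fixture
    tRNA with one acceptor-stem base deleted, embedded in AT-rich random
    flanks; inserting `base` after `position` bases restores the tRNA.  The
    generator verifies that the unmodified region does not already contain
    an equivalent hit.
    """
    from .trna import DEFAULT_CONFIG, TRNAHit, _same_hit, scan_trnas

    rng = np.random.default_rng(seed)
    trna = canonical_trna(anticodon)
    probs = SyntheticConfig().base_probs()
    for _ in range(50):
        del_idx = int(rng.integers(0, 7))  # delete within the 5' acceptor stem
        left = _random_bases(rng, flank_len, probs)
        right = _random_bases(rng, flank_len, probs)
        damaged = trna[:del_idx] + trna[del_idx + 1 :]
        region = left + damaged + right
        restored_hit = TRNAHit(start=flank_len + 1,
                               end=flank_len + len(trna),
                               anticodon=anticodon, amino_acid="")
        if not any(_same_hit(h, restored_hit) for h in scan_trnas(region)):
            return region, (flank_len + del_idx, trna[del_idx])
    raise RuntimeError("could not plant an undetectable proto-tRNA")


def permute_order(template: GeneOrder,
                  moves: list[tuple[str, str]],
                  seed: int = 0) -> GeneOrder:
    """Apply translocations (symbol, insert_after_symbol) to a gene order."""
    symbols = list(template.symbols)
    strands = {s: st for s, st in zip(template.symbols, template.strands)}
    moved: set[str] = set()
    for sym, after in moves:
        if sym not in symbols:
            raise ValueError(f"unknown symbol {sym!r}")
        if after not in symbols or after == sym:
            raise ValueError(f"invalid insertion target {after!r}")
        if sym in moved:
            raise ValueError(f"conflicting moves for {sym!r}")
        moved.add(sym)
        symbols.remove(sym)
        symbols.insert(symbols.index(after) + 1, sym)
    return GeneOrder(template.genome_id + "-perm", symbols,
                     [strands[s] for s in symbols], template.filter)
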