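"""Orchestration of the full comparative report over a set of genomes.

Stages: annotate -> composition -> codon bias -> Ka/Ks -> gene order ->
tRNA analyses.  Stages are independent: a failing stage is logged and the
others still run; the bundle's `failures` list records what went wrong.
Inputs are local files; accession fetching (via NCBI E-utilities) happens
only when explicitly requested, so everything runs offline by default.
"""

from __future__ import annotations

import configparser
import itertools
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_usage, composition, gene_order, kaks
from .annotate import adjust_gene_boundaries
from .io import read_feature_table, read_genbank
from .model import AnnotatedGenome

log = logging.getLogger("mitocomp")


@dataclass
class PipelineConfig:
    inputs: list[str]
    code: int = 5
    clade_sets: dict[str, list[str]] = field(default_factory=dict)
    output_dir: str = "mitocomp-out"
    exclude_kinds_for_order: tuple[str, ...] = ("tRNA", "NCR")
    reference: str | None = None
    adjust_boundaries: bool = True

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("pipeline needs at least one input")
        for name, members in self.clade_sets.items():
            missing = set(members) - {Path(p).stem for p in self.inputs}
            if missing:
                raise ValueError(f"clade set {name!r} references unknown "
                                 f"inputs {sorted(missing)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read the flat INI-style pipeline config.

    Sections: [inputs] (one `path.N = file` per line or a single `paths`
    comma list), [options] (code, output_dir, reference), [clades]
    (name = comma-separated genome ids).
    """
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    inputs = []
    if cp.has_section("inputs"):
        for _, v in cp.items("inputs"):
            inputs.extend(s.strip() for s in v.split(",") if s.strip())
    options = dict(cp.items("options")) if cp.has_section("options") else {}
    clades = {}
    if cp.has_section("clades"):
        for name, v in cp.items("clades"):
            clades[name] = [s.strip() for s in v.split(",") if s.strip()]
    return PipelineConfig(
        inputs=inputs,
        code=int(options.get("code", 5)),
        clade_sets=clades,
        output_dir=options.get("output_dir", "mitocomp-out"),
        reference=options.get("reference"),
    )


def _load_genome(path: str, code: int) -> AnnotatedGenome:
    p = Path(path)
    if p.suffix in (".gb", ".gbk", ".genbank"):
        return read_genbank(p, code)
    if p.suffix in (".fa", ".fasta", ".fna"):
        table = p.with_suffix(".tsv")
        return read_feature_table(p, table, code)
    raise ValueError(f"unrecognized input format: {path}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the report bundle (also written as TSVs)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"failures": []}

    genomes: list[AnnotatedGenome] = []
    for path in cfg.inputs:
        try:
            g = _load_genome(path, cfg.code)
            if cfg.adjust_boundaries:
                g, changes = adjust_gene_boundaries(g)
                bundle.setdefault("boundary_changes", {})[g.identifier] = [
                    (c.gene, c.field, c.old, c.new, c.note) for c in changes]
            genomes.append(g)
        except Exception as exc:  # fault isolation per input
            log.error("failed to load %s: %s", path, exc)
            bundle["failures"].append(("load", path, str(exc)))
    if not genomes:
        raise ValueError("no readable inputs")

    def stage(name, fn):
        try:
            bundle[name] = fn()
        except Exception as exc:
            log.error("stage %s failed: %s\n%s", name, exc,
                      traceback.format_exc())
            bundle["failures"].append((name, "", str(exc)))

    def comp_stage():
        rows = []
        for g in genomes:
            for r in composition.class_composition(g):
                c = r.base_counts
                rows.append([g.identifier, r.unit, r.length,
                             c["A"], c["C"], c["G"], c["T"],
                             r.at_content, r.at_skew, r.gc_skew])
        df = pd.DataFrame(rows, columns=["genome", "unit", "length",
                                         "A", "C", "G", "T",
                                         "at_content", "at_skew", "gc_skew"])
        df.to_csv(outdir / "composition.tsv", sep="\t", index=False,
                  float_format="%.6g")
        return df

    def codon_stage():
        rows = []
        tables = []
        for g in genomes:
            cds_list = [g.extract_cds(f.name) for f in g.by_kind("PCG")]
            table = codon_usage.count_codons(cds_list, g.genetic_code,
                                             scope=g.identifier)
            tables.append(table)
            stats = codon_usage.genome_bias_stats(table)
            rows.append([g.identifier, table.n_codons, stats["ENC"],
                         stats["CBI"], stats["GCc"], stats["GC3s"]])
        df = pd.DataFrame(rows, columns=["genome", "n_codons", "ENC", "CBI",
                                         "GCc", "GC3s"])
        df.to_csv(outdir / "codon_bias.tsv", sep="\t", index=False,
                  float_format="%.6g")
        if len(tables) >= 3:
            corr = codon_usage.bias_correlations(tables)
            cdf = pd.DataFrame(
                [[x, y, sign, r2] for (x, y), (sign, r2) in corr.pairs.items()],
                columns=["x", "y", "slope_sign", "r_squared"])
            cdf.to_csv(outdir / "bias_correlations.tsv", sep="\t",
                       index=False, float_format="%.6g")
        ss = codon_usage.tabulate_start_stop(genomes)
        sdf = pd.DataFrame([[r.genome, r.gene, r.start_codon, r.stop_codon,
                             r.truncated] for r in ss.rows],
                           columns=["genome", "gene", "start", "stop",
                                    "truncated"])
        sdf.to_csv(outdir / "start_stop.tsv", sep="\t", index=False)
        return df

    def kaks_stage():
        # per-gene alignments across genomes; genes must be length-matched
        # (a codon-aware aligner is out of scope here — equal-length CDSs
        # are compared directly, others are skipped with a warning)
        alignments: dict[str, dict[str, str]] = {}
        for gene in sorted({f.name for g in genomes for f in g.by_kind("PCG")}):
            seqs = {}
            for g in genomes:
                try:
                    seqs[g.identifier] = g.extract_cds(gene)
                except KeyError:
                    continue
            lens = {len(s) for s in seqs.values()}
            if len(seqs) >= 2 and len(lens) == 1 and not (lens.pop() % 3):
                alignments[gene] = seqs
        summaries = kaks.gene_kaks_summary(alignments, cfg.code)
        df = pd.DataFrame([[s.gene, s.mean_ka, s.mean_ks, s.ratio,
                            s.n_pairs, s.n_flagged] for s in summaries],
                          columns=["gene", "mean_ka", "mean_ks", "ratio",
                                   "n_pairs", "n_flagged"])
        df.to_csv(outdir / "kaks.tsv", sep="\t", index=False,
                  float_format="%.6g")
        return df

    def order_stage():
        orders = [gene_order.extract_order(g, set(cfg.exclude_kinds_for_order))
                  for g in genomes]
        rows = []
        for o1, o2 in itertools.combinations(orders, 2):
            for i, blk in enumerate(gene_order.shared_blocks(o1, o2)):
                rows.append([f"{o1.genome_id}|{o2.genome_id}", i,
                             "-".join(blk.symbols), len(blk.symbols),
                             blk.inverted])
        df = pd.DataFrame(rows, columns=["genome_pair", "block_index",
                                         "symbols", "length", "inverted"])
        df.to_csv(outdir / "gene_order_blocks.tsv", sep="\t", index=False)
        ref = cfg.reference or genomes[0].identifier
        trna_orders = [gene_order.extract_order(g, {"NCR"}) for g in genomes]
        reports = gene_order.detect_translocations(trna_orders, ref)
        tdf = pd.DataFrame([[r.genome_id, ",".join(r.translocated),
                             ",".join(r.inserted), ",".join(r.lost)]
                            for r in reports],
                           columns=["genome", "translocated", "inserted",
                                    "lost"])
        tdf.to_csv(outdir / "translocations.tsv", sep="\t", index=False)
        return df

    stage("composition", comp_stage)
    stage("codon_bias", codon_stage)
    stage("kaks", kaks_stage)
    stage("gene_order", order_stage)

    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"genomes analyzed: {len(genomes)}\n")
        for g in genomes:
            fh.write(f"  {g.identifier}: {len(g)} bp, "
                     f"{len(g.features)} features\n")
        for name in ("composition", "codon_bias", "kaks", "gene_order"):
            df = bundle.get(name)
            status = f"{len(df)} rows" if df is not None else "FAILED"
            fh.write(f"stage {name}: {status}\n")
        for failure in bundle["failures"]:
            fh.write(f"failure: {failure}\n")
    return bundle
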