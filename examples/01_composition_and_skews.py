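"""Nucleotide composition and strand skews of a mitogenome.

Builds a synthetic AT-rich mitogenome (13 PCGs + 2 rRNAs + 22 tRNAs on one
strand), then reports AT content, AT-skew = (A-T)/(A+T) and GC-skew =
(G-C)/(G+C) per gene class and for the whole molecule.  Negative AT-skew
with positive GC-skew is the compositional signature of these clam
mitogenomes.
"""

from mitocomp import class_composition
from mitocomp.synthetic import SyntheticConfig, generate_genome

genome = generate_genome(SyntheticConfig(seed=7, at_target=0.65))
print(f"genome {genome.identifier}: {len(genome)} bp, "
      f"{len(genome.features)} genes\n")
print(f"{'unit':10s} {'len':>6s} {'AT%':>6s} {'AT-skew':>8s} {'GC-skew':>8s}")
for report in class_composition(genome):
    if report.unit in ("PCG", "rRNA", "tRNA", "genome"):
        print(f"{report.unit:10s} {report.length:6d} "
              f"{100 * report.at_content:6.1f} "
              f"{report.at_skew:8.3f} {report.gc_skew:8.3f}")
print("\nAT% is the fraction of A+T bases; skews measure which strand "
      "carries the excess A (or G).")
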