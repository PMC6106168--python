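# Methods

This note documents the models, conventions and numerical choices behind
mitocomp, and what the synthetic-data tests do and do not demonstrate
about real data.

## Genetic code and synonymous families

All translation, site counting and degeneracy use NCBI translation table 5
(invertebrate mitochondrial) by default: TGA = Trp, AGA/AGG = Ser,
ATA = Met, and only TAA/TAG terminate, leaving 62 sense codons.
Synonymous families follow the codonW-style *split* convention: codons of
one amino acid differing in their first two positions form separate
families (Leu → TTR + CTN, Ser → TCN + AGN). Under table 5 this yields
13 two-fold and 9 four-fold families (13·2 + 9·4 = 62) and makes every
family purely third-position degenerate, which keeps ENC size classes and
G+C3s well defined. Other code tables are accepted; families of size 1
(e.g. Trp in the standard code) are excluded from ENC, CBI and G+C3s.

Allowed initiation codons are the metazoan ATN set {ATG, ATA, ATT, ATC}
plus GTG.

## Boundary re-annotation

Coordinates are 1-based inclusive, GenBank style; a feature with
start > end wraps the circular origin. For each protein-coding gene the
start is moved to the first in-frame allowed start codon that does not
overlap the upstream feature. Upstream extension beyond the draft start
is permitted only while the reading frame stays open — without this guard
an AT-rich intergenic gap containing a chance ATN would absorb the gene
start and an in-frame stop in the gap would then truncate the gene to a
fragment. The stop becomes the first in-frame full terminator that does
not overlap the downstream feature; when none fits, a truncated `TA` or
`T` abutting the downstream gene is recorded (these terminators are
completed by transcript polyadenylation). rRNA boundaries, not precisely
determinable from sequence alone, extend to abut both flanking features.
The procedure is idempotent and returns a change log so curation is
auditable. Both strands are supported via transcription-direction
coordinate mapping, although all genomes in the intended application are
single-strand.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C). N bases are excluded from
every numerator and denominator; an all-N unit is an error and a zero
denominator yields NaN, never a silent 0. Class statistics (pooled PCG,
rRNA, tRNA) are computed on concatenated strand-corrected sequences —
i.e. count sums — not by averaging per-gene ratios, so pooled counts are
exactly additive over members.

## Codon-usage statistics

RSCU(c) = count(c) / mean count over c's family; family sums therefore
equal family sizes whenever the family is observed, and unobserved
families yield NaN.

ENC uses Wright's homozygosity estimator generalized to the split scheme:
for each family with n ≥ 2 counted codons,
F̂ = (n·Σp² − 1)/(n − 1); families are grouped by size k, and
ENC = Σ_k N_k / mean(F̂)_k, capped at the sense-codon count (62).
Families with F̂ ≤ 0 — possible only at very small n — carry no usable
estimate and are treated as unobserved; unobserved families take their
size-class mean, and a wholly unobserved size class is dropped with a
warning. Because of the small-sample correction, ENC is only
asymptotically invariant under duplication of the codon sample; the
property suite asserts approximate invariance at realistic sample sizes.

CBI = (N_pref − N_rand)/(N_tot − N_rand) over families of size ≥ 2, with
N_rand = Σ families (family total / family size). The preferred codon per
family defaults to the most counted codon of the analyzed table itself
(ties broken alphabetically); an explicit preferred-codon map can be
passed to freeze a reference set. G+Cc is the G+C fraction over all three
positions of sense codons; G+C3s restricts to third positions of codons
in families of size ≥ 2.

Cross-genome correlations (CBI~ENC, CBI~G+Cc, CBI~G+C3s, ENC~G+Cc,
ENC~G+C3s) are ordinary least-squares fits reporting slope sign and R²;
at least 3 genomes are required and zero variance is an error. Genome
statistics are computed over concatenated PCGs per genome.

## Ka/Ks (NG86 with Jukes–Cantor correction)

Synonymous site fractions come from enumerating all nine single-base
mutants of each codon with equal weights (mutations to stops count as
nonsynonymous); s + n = 3 exactly, and S, N for a sequence pair are
averaged over the two sequences. Differences are pathway-averaged: all
minimal mutational pathways between a codon pair are enumerated, pathways
passing through stop codons are excluded, and the per-step
synonymous/nonsynonymous classification is averaged over the remaining
pathways, so Sd + Nd equals the nucleotide difference count whenever at
least one pathway is stop-free; codon pairs with no stop-free pathway (or
containing N or a stop) are skipped and counted. The Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)·p) is applied to ps = Sd/S and
pn = Nd/N; p ≥ 0.75 raises a saturation error rather than being clamped.

Gene-level summaries average Ka and Ks over all unordered species pairs;
the default ratio is mean(Ka)/mean(Ks) (matching per-gene "average Ka and
Ks then ratio" reporting), with mean-of-ratios available as an option.
Saturated pairs are excluded from means and reported. No
transition/transversion weighting is applied (that would be modified NG,
a different estimator), and codon-aware alignment is an input, not a
responsibility — equal-length in-frame sequences are compared directly.

## Gene order

Orders are circular lists of signed gene symbols, canonically rotated to
start at cox1. A shared block is a maximal run of genes contiguous, in
the same order and relative strands, in both genomes (length ≥ 2);
forward blocks partition each order, and a run conserved only in
reverse-complement reading (inverted order, flipped strands) is reported
separately as an inversion candidate. Orientation is kept genome-wide, so
a within-genome segment inversion is classified as an inversion, not a
forward match. By default symbols private to one genome are dropped
before block finding (`drop_missing=True`); the alternative treats them
as block breakers. This drop-missing convention is the package's choice
for cross-family comparisons where individual genes (e.g. atp8) are
missing from one genome; it is documented as a convention, not a claim
about any published block-finding method. Duplicated tRNA isotypes
compare by base symbol — the unsuffixed copy is canonical and extra
copies count as insertions. Translocation detection flags shared symbols
whose both flanking neighbors (among shared symbols) differ from the
reference, which pinpoints a moved gene without flagging its former
neighbors.

## tRNA scanner

The scanner is a transparent structural heuristic in the spirit of
ARWEN's constraints, not a covariance model; its purpose is to make
claims about structural detectability testable and reproducible.
Geometry: acceptor stem 7 bp; spacer 1–3 nt; optional D-arm (stem 3–4 bp,
loop 4–12 nt, then 0–1 nt spacer); anticodon stem 5 bp closing an exactly
7-nt loop whose central triplet is the anticodon; variable loop 3–23 nt;
T-arm (stem 4–5 bp, loop 3–9 nt) abutting the 3' acceptor strand; total
length 60–75 nt. G·U wobble counts as a pair. The score is the total
number of base pairs formed (maximum 21 with all arms; 17 without the
D-arm), and overlapping hits are resolved by score, then leftmost start.
The D-arm may be absent only when the decoded isotype (anticodon
reverse-complemented and translated) is serine, matching the DHU-armless
serine tRNAs of bivalve mitogenomes, unless `allow_armless` widens this.

Specificity calibration: pair-geometry constraints alone are not
selective — 10 kb of random 65 % AT sequence contains maximal-score
(21-pair) parses, so no score threshold can separate signal from noise by
itself. The default configuration therefore demands complete stem pairing
(mismatch tolerances are config fields for permissive scans) plus two
conserved sequence elements: U33, the nucleotide immediately 5' of the
anticodon, and the TTC prefix of the T-loop (the TΨC motif). With
min_score = 17 — the exact score of a perfect armless hit — this
combination yields zero hits on the 10 kb AT-rich random calibration
sequence at seed 1 while detecting the canonical and armless-serine
fixtures. Real mitochondrial tRNAs often degenerate away from these
motifs; permissive settings trade specificity for sensitivity and are a
config choice, so absence of a hit at defaults is not evidence of absence
in real data.

The insertion scan tries every (position, base) single-base insertion —
position p means "after base p", p = 0 prepends — rescans, and reports
hits with no counterpart in the unmodified region (same span within 2 nt
and same anticodon), in deterministic (p, base) order.

Pairwise percent identity uses Biopython's global aligner (match +1,
mismatch −1, linear gap −2; configurable), with identity = matches /
alignment columns × 100.

## Synthetic data

All generators draw from NumPy's PCG64 (`numpy.random.default_rng`) and
are byte-identical for a fixed seed across platforms. Defaults emulate
the study conditions for vesicomyid-scale mitogenomes: 15,650 bp target
length, 0.65 AT content, AT-skew −0.15 and GC-skew +0.30 (AT-rich,
negatively AT-skewed, positively GC-skewed, as these genomes are),
13 PCGs + 2 rRNAs + 22 tRNAs on one strand in an order consistent with
the conserved venerid/vesicomyid blocks (rrnL between cytb and atp8, rrnS
flanked by trnaT/trnaM, trnaG downstream of nad4L, trnaF after cox3),
gene lengths at typical vesicomyid values (cox1 1806 bp, rrnL 1237 bp,
rrnS 888 bp, …), ATG starts and TAG stops, and no in-frame internal stops
(codon-level sampling from sense codons only). PCG codons are sampled
from base-composition-derived weights with an optional preferred-codon
multiplier (`codon_bias`) that controls ENC/CBI; tRNA genes are the
canonical GC-stem cloverleaf fixture with per-isotype anticodons. Because
the fixture tRNAs are GC-rich and PCG composition is codon-constrained,
the free regions (rRNAs, spacers, padding) are drawn from a compensated
base distribution so realized genome AT lands within 0.02 of target —
a side effect is that synthetic rRNA regions are more AT-rich than real
rRNAs.

What the generator does *not* emulate: indel processes, substitution-rate
heterogeneity along trees, control-region tandem repeats, realistic tRNA
sequence diversity (fixtures share stems), or strand-specific mutational
pressure beyond the stationary skew targets. Passing parameter-recovery
tests therefore demonstrates correctness of the estimators on their own
model assumptions, not detector sensitivity on real, motif-degenerate
tRNAs or alignment robustness on indel-rich genes.

`mutate_cds_pair` plants exactly n_syn synonymous and n_nonsyn
nonsynonymous single-base codon changes (no codon touched twice, never
creating stops, start/stop codons untouched) and verifies the result by
translation. `plant_proto_trna` deletes one 5' acceptor-stem base from
the fixture, embeds it in AT-rich flanks, verifies the damaged region has
no equivalent detection, and returns the reverting insertion as ground
truth.

## Pipeline

The pipeline stages (annotate → composition → codon bias → Ka/Ks → gene
order) are fault-isolated: a corrupt input or failing stage is logged and
recorded in the bundle's failure list while other stages complete; the
exit status reflects failures. Outputs are deterministic TSVs plus a
plain-text summary whose numbers are taken from the stage tables, never
recomputed. Accessions are not fetched: inputs are local files, so tests
and the acceptance script never require a network.

## Problem sizes

The verification suite uses 10,000 random codon pairs for NG86 oracle
agreement, a 300-codon CDS with 8 planted synonymous changes for Ka/Ks
recovery, 1,000 random sequences for skew antisymmetry, 500 random
circular permutations of ≤ 10 symbols for the block-finder oracle, and
100 planted proto-tRNA regions (10 nt flanks) for the insertion-revert
property — sizes chosen so each property is exercised across its input
space while the whole suite completes in well under a minute of compute
per check.
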