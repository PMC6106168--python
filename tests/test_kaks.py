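"""NG86 site/difference counting, Jukes-Cantor correction, gene summaries.

Oracles here re-derive everything from the genetic code table directly:
site fractions by independent 9-mutant enumeration, and pathway averages
by a brute-force enumeration written separately from the implementation.
"""

import itertools
import math

import numpy as np
import pytest

from mitocomp import count_sites, gene_kaks_summary, jukes_cantor, ng86_pair
from mitocomp.codes import BASES, sense_codons, stop_codons, translation_table
from mitocomp.kaks import SaturationError, _pair_differences
from mitocomp.synthetic import SyntheticConfig, generate_genome, mutate_cds_pair


def oracle_sites(codon: str) -> float:
    """Synonymous site fraction by direct enumeration (independent oracle)."""
    tt = translation_table(5)
    stops = stop_codons(5)
    syn = sum(
        1
        for pos in range(3)
        for b in BASES
        if b != codon[pos]
        and (m := codon[:pos] + b + codon[pos + 1:]) not in stops
        and tt[m] == tt[codon]
    )
    return syn / 3.0


def oracle_pathways(c1: str, c2: str):
    """Pathway-averaged (Sd, Nd) by brute force over step orders."""
    tt = translation_table(5)
    stops = stop_codons(5)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd = c1, 0, 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                valid = False
                break
            sd += tt[nxt] == tt[cur]
            nd += tt[nxt] != tt[cur]
            cur = nxt
        if valid:
            results.append((sd, nd))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


@pytest.mark.parametrize("codon,s", [("TTT", 1 / 3), ("GGG", 1.0)])
def test_count_sites_worked_examples(codon, s):
    got_s, got_n = count_sites(codon)
    assert got_s == pytest.approx(s)
    assert got_s + got_n == pytest.approx(3.0)


def test_count_sites_rejects_stop_and_ambiguous():
    with pytest.raises(ValueError):
        count_sites("TAA")
    with pytest.raises(ValueError):
        count_sites("ANT")


def test_count_sites_matches_oracle_for_all_sense_codons():
    for codon in sense_codons(5):
        s, n = count_sites(codon)
        assert s == pytest.approx(oracle_sites(codon))
        assert s + n == pytest.approx(3.0)


def test_pathway_averaging_matches_brute_force():
    rng = np.random.default_rng(11)
    codons = list(sense_codons(5))
    for _ in range(300):
        c1, c2 = rng.choice(codons, size=2)
        got = _pair_differences(c1, c2)
        want = oracle_pathways(c1, c2)
        if want is None:
            assert got is None
        else:
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])
            ndiff = sum(a != b for a, b in zip(c1, c2))
            assert got[0] + got[1] == pytest.approx(ndiff)


def test_two_step_pathway_case():
    # TTT -> GTA: both 2-step pathways, averaged
    got = _pair_differences("TTT", "GTA")
    want = oracle_pathways("TTT", "GTA")
    assert got == pytest.approx(want)


def test_ng86_pair_worked_example():
    r = ng86_pair("TTTGGGCCCAAA", "TTCGGGCCCAAA")
    assert r.S == pytest.approx(8 / 3)
    assert r.S + r.N == pytest.approx(3 * r.codons_used)
    assert (r.Sd, r.Nd) == (1.0, 0.0)
    assert r.Ks == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (3 / 8)))
    assert r.Ka == 0.0


def test_ng86_pair_symmetric():
    rng = np.random.default_rng(5)
    codons = list(sense_codons(5))
    a = "".join(rng.choice(codons, size=30))
    b = "".join(rng.choice(codons, size=30))
    r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
    for field in ("S", "N", "Sd", "Nd", "codons_used"):
        assert getattr(r1, field) == pytest.approx(getattr(r2, field))


def test_identical_sequences_give_zero_rates_undefined_ratio():
    r = ng86_pair("ATGAAATTT", "ATGAAATTT")
    assert r.Ka == 0.0 and r.Ks == 0.0
    assert math.isnan(r.ratio)


def test_saturation_flagged_not_clamped():
    with pytest.raises(SaturationError):
        jukes_cantor(0.8)


def test_jc_correction_monotone_increasing():
    ps = np.linspace(0, 0.74, 100)
    ds = [jukes_cantor(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))
    assert jukes_cantor(0.0) == 0.0


def test_parameter_recovery_synonymous_only_pair():
    genome = generate_genome(SyntheticConfig(seed=13))
    cds = genome.extract_cds("nad5")[:900]  # 300 codons
    orig, mut = mutate_cds_pair(cds, n_syn=8, n_nonsyn=0, seed=13)
    r = ng86_pair(orig, mut)
    assert r.Ka == 0.0
    assert (r.Sd, r.Nd) == (8.0, 0.0)
    analytic = jukes_cantor(8.0 / r.S)
    assert r.Ks == pytest.approx(analytic, rel=0.10)


def test_gene_summary_identical_species_all_zero(genome):
    cds = genome.extract_cds("cox1")
    summaries = gene_kaks_summary({"cox1": {"a": cds, "b": cds, "c": cds}})
    (s,) = summaries
    assert s.mean_ka == 0.0 and s.mean_ks == 0.0 and s.n_pairs == 3


def test_gene_summary_synonymous_clade_has_zero_ka(genome):
    cds = genome.extract_cds("nad1")
    seqs = {"ref": cds}
    for i, seed in enumerate((21, 22, 23)):
        seqs[f"sp{i}"] = mutate_cds_pair(cds, n_syn=6, n_nonsyn=0,
                                         seed=seed)[1]
    summaries = gene_kaks_summary({"nad1": seqs})
    (s,) = summaries
    assert s.mean_ka == 0.0
    assert s.mean_ks > 0.0
    assert s.ratio == 0.0
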