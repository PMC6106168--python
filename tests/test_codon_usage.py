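"""Codon-usage bias statistics: RSCU, ENC, CBI, GC stats, correlations."""

import math
from collections import Counter

import numpy as np
import pytest

from mitocomp import (bias_correlations, cbi, count_codons, enc, gc_stats,
                      rscu, sense_codons, synonymous_families,
                      tabulate_start_stop)
from mitocomp.codon_usage import CodonUsageTable, genome_bias_stats


def make_table(counts: dict[str, int]) -> CodonUsageTable:
    return CodonUsageTable("test", counts)


def test_family_census_for_invertebrate_mito_code():
    sizes = Counter(len(f) for f in synonymous_families(5))
    assert sizes == {2: 13, 4: 9}
    assert len(sense_codons(5)) == 62
    assert sum(k * v for k, v in sizes.items()) == 62


def test_count_codons_separates_stops_and_partials():
    t = count_codons(["ATGTAA"])
    assert t.counts == {"ATG": 1}
    assert t.n_stop == 1
    t = count_codons(["ATGATG", "ATG"])
    assert t.counts["ATG"] == 3
    t = count_codons(["ATGAA"])  # trailing partial codon
    assert t.counts == {"ATG": 1}
    assert t.n_partial == 1
    with pytest.raises(ValueError):
        count_codons([])


def test_count_codons_additive_over_concatenation(genome):
    cds_list = [genome.extract_cds(f.name) for f in genome.by_kind("PCG")]
    whole = count_codons(cds_list)
    parts = [count_codons([c]) for c in cds_list]
    summed = Counter()
    for p in parts:
        summed.update(p.counts)
    assert whole.counts == dict(summed)
    assert whole.n_codons == sum(p.n_codons for p in parts)


def test_rscu_closed_forms():
    fam = synonymous_families(5)
    four_fold = next(f for f in fam if len(f) == 4)
    # equal use -> all 1.0
    vals = rscu(make_table({c: 5 for c in four_fold}))
    assert all(vals[c] == pytest.approx(1.0) for c in four_fold)
    # single codon used -> 4.0 and zeros
    vals = rscu(make_table({four_fold[0]: 9}))
    assert vals[four_fold[0]] == pytest.approx(4.0)
    assert all(vals[c] == 0.0 for c in four_fold[1:])
    # counts (2,1,1,0) -> (2,1,1,0)
    counts = dict(zip(four_fold, (2, 1, 1, 0)))
    vals = rscu(make_table(counts))
    assert [vals[c] for c in four_fold] == pytest.approx([2.0, 1.0, 1.0, 0.0])


def test_rscu_family_sums_equal_family_size(genome):
    cds_list = [genome.extract_cds(f.name) for f in genome.by_kind("PCG")]
    t = count_codons(cds_list)
    vals = rscu(t)
    for fam in synonymous_families(5):
        total = sum(t.counts.get(c, 0) for c in fam)
        if total:
            assert sum(vals[c] for c in fam) == pytest.approx(len(fam))


def test_enc_uniform_usage_hits_sense_codon_count():
    t = make_table({c: 100 for c in sense_codons(5)})
    assert enc(t) == pytest.approx(62.0)


def test_enc_single_codon_per_family_is_family_count():
    counts = {fam[0]: 50 for fam in synonymous_families(5)}
    assert enc(make_table(counts)) == pytest.approx(22.0)


def test_enc_undefined_when_no_family_observed_twice():
    assert math.isnan(enc(make_table({})))
    assert math.isnan(enc(make_table({"ATG": 1})))


def test_enc_approximately_scale_invariant(genome):
    cds_list = [genome.extract_cds(f.name) for f in genome.by_kind("PCG")]
    t = count_codons(cds_list)
    doubled = make_table({c: 2 * n for c, n in t.counts.items()})
    assert enc(doubled) == pytest.approx(enc(t), rel=0.01)


def test_cbi_closed_forms():
    fams = synonymous_families(5)
    # only preferred codons used -> 1.0
    assert cbi(make_table({f[0]: 10 for f in fams})) == pytest.approx(1.0)
    # uniform usage -> 0.0
    assert cbi(make_table({c: 7 for c in sense_codons(5)})) == pytest.approx(0.0)
    # zero preferred used, all two-fold families -> -1.0, preferred fixed
    two_fold = [f for f in fams if len(f) == 2]
    table = make_table({f[1]: 5 for f in two_fold})
    preferred = {f: f[0] for f in two_fold}
    assert cbi(table, preferred) == pytest.approx(-1.0)


def test_cbi_decreases_when_preferred_count_moves_away():
    fams = [f for f in synonymous_families(5) if len(f) == 4]
    base = {c: 1 for f in fams for c in f}
    for f in fams:
        base[f[0]] = 10
    t1 = make_table(base)
    preferred = {f: f[0] for f in fams}
    moved = dict(base)
    moved[fams[0][0]] -= 3
    moved[fams[0][1]] += 3
    assert cbi(make_table(moved), preferred) < cbi(t1, preferred)


def test_gc_stats_brute_force_recount(genome):
    cds_list = [genome.extract_cds(f.name) for f in genome.by_kind("PCG")]
    t = count_codons(cds_list)
    gcc, gc3s = gc_stats(t)
    # independent recount straight from the codon stream
    from mitocomp.codes import family_of, stop_codons
    stops = stop_codons(5)
    fam = family_of(5)
    gc_all = tot_all = gc3 = tot3 = 0
    for cds in cds_list:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon in stops or "N" in codon:
                continue
            gc_all += sum(b in "GC" for b in codon)
            tot_all += 3
            if len(fam[codon]) >= 2:
                gc3 += codon[2] in "GC"
                tot3 += 1
    assert gcc == pytest.approx(gc_all / tot_all)
    assert gc3s == pytest.approx(gc3 / tot3)


def test_gc_stats_all_gc_codons():
    assert gc_stats(make_table({"GGC": 4, "GCG": 2}))[0] == pytest.approx(1.0)


def test_tabulate_start_stop_synthetic_defaults(genome):
    table = tabulate_start_stop([genome])
    assert table.start_summary == {"ATG": 13}
    assert table.stop_summary == {"TAG": 13}
    assert not any(r.truncated for r in table.rows)


def test_tabulate_start_stop_truncated_flag(genome):
    from dataclasses import replace
    from mitocomp.model import AnnotatedGenome
    cox3 = genome.get("cox3")
    feats = [replace(f, end=f.end - 1) if f.name == "cox3" else f
             for f in genome.features]
    g = AnnotatedGenome("t", genome.sequence, feats)
    row = next(r for r in tabulate_start_stop([g]).rows if r.gene == "cox3")
    assert row.truncated and row.stop_codon == "TA"


def test_bias_correlations_colinear_points():
    tables = []
    for seed, bias in [(1, 1.0), (2, 3.0), (3, 9.0), (4, 27.0)]:
        rng = np.random.default_rng(seed)
        counts = {}
        for fam in synonymous_families(5):
            for i, c in enumerate(fam):
                counts[c] = int(100 * bias) if i == 0 else 100
        tables.append(make_table(counts))
    report = bias_correlations(tables)
    # CBI and ENC move in opposite directions as bias strengthens
    sign, r2 = report.pairs[("CBI", "ENC")]
    assert sign == "-"
    assert 0.9 <= r2 <= 1.0


def test_bias_correlations_requires_three_genomes():
    with pytest.raises(ValueError):
        bias_correlations([make_table({"ATG": 1})] * 2)


def test_genome_bias_stats_move_with_generator_bias(genome_trio):
    stats = []
    for g in genome_trio:
        cds = [g.extract_cds(f.name) for f in g.by_kind("PCG")]
        stats.append(genome_bias_stats(count_codons(cds)))
    cbis = [s["CBI"] for s in stats]
    encs = [s["ENC"] for s in stats]
    assert cbis == sorted(cbis), "CBI should rise with generator codon bias"
    assert encs == sorted(encs, reverse=True), "ENC should fall with bias"
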