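import math
from itertools import permutations

import numpy as np
import pytest

import congevol as cv
from congevol.codonmodel import codon_space, uniform_freqs, _TransitionCache
from congevol.kaks import jukes_cantor, pairwise_loglik
from congevol.codonmodel import compress_alignment

CODE = cv.standard_code()
SENSE = CODE.sense_codons


def oracle_sites(codon):
    """Independent single-mutant enumeration of NG86 site fractions."""
    s = n = 0.0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if CODE.is_stop(mutant) or CODE.aa(mutant) != CODE.aa(codon):
                n += 1 / 3
            else:
                s += 1 / 3
    return s, n


def oracle_differences(a, b):
    """Independent path enumeration of NG86 difference counts."""
    positions = [k for k in range(3) if a[k] != b[k]]
    syn, non, paths = 0.0, 0.0, 0
    for order in permutations(positions):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if CODE.is_stop(nxt):
                ok = False
                break
            if CODE.aa(cur) == CODE.aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            syn, non, paths = syn + sd, non + nd, paths + 1
    if paths == 0:
        return 0.0, float(len(positions))
    return syn / paths, non / paths


def test_site_count_examples():
    assert cv.count_sites_ng86("TTT") == pytest.approx((1 / 3, 8 / 3))
    assert cv.count_sites_ng86("ATG") == pytest.approx((0.0, 3.0))
    s, n = cv.count_sites_ng86("GGG")
    assert s + n == pytest.approx(3.0)
    assert s == pytest.approx(*[oracle_sites("GGG")[0]])


def test_site_counts_match_enumeration_for_all_sense_codons():
    for codon in SENSE:
        s, n = cv.count_sites_ng86(codon)
        so, no = oracle_sites(codon)
        assert s == pytest.approx(so)
        assert n == pytest.approx(no)
        assert s + n == pytest.approx(3.0)


def test_stop_codon_site_count_rejected():
    with pytest.raises(ValueError, match="stop"):
        cv.count_sites_ng86("TAA")


def test_difference_count_examples():
    assert cv.count_differences_ng86("AAA", "AAA") == (0.0, 0.0)
    assert cv.count_differences_ng86("TTT", "TTC") == (1.0, 0.0)
    assert cv.count_differences_ng86("TTT", "GTA") == oracle_differences("TTT", "GTA")


def test_difference_counts_match_enumeration_all_pairs():
    """Exhaustive oracle over all 61x61 sense-codon pairs."""
    for a in SENSE:
        for b in SENSE:
            got = cv.count_differences_ng86(a, b)
            want = oracle_differences(a, b)
            assert got == pytest.approx(want), (a, b)


def test_difference_count_symmetric(rng):
    for _ in range(50):
        a, b = rng.choice(SENSE, size=2)
        assert cv.count_differences_ng86(a, b) == pytest.approx(
            cv.count_differences_ng86(b, a)
        )


def _pair_alignment(row_a, row_b):
    return cv.CodonAlignment(ids=("a", "b"), rows=(row_a, row_b))


def test_identical_pair_has_zero_rates():
    row = "ATGAAA" * 50
    est = cv.kaks_ng86(_pair_alignment(row, row))
    assert est.a_subs == est.s_subs == 0
    assert est.ka == est.ks == 0
    assert not est.valid and math.isnan(est.omega)


def test_two_synonymous_changes_hand_oracle():
    """Two synonymous substitutions across two codons saturate the JC
    correction (p_S = 2 / 1.33 sites > 3/4) and are flagged as such."""
    est = cv.kaks_ng86(_pair_alignment("TTTGGG", "TTCGGA"))
    assert est.s_subs == pytest.approx(2.0)
    assert est.a_subs == pytest.approx(0.0)
    assert est.ka == pytest.approx(0.0)
    s_sites = (sum(cv.count_sites_ng86(c)[0] for c in ("TTT", "GGG"))
               + sum(cv.count_sites_ng86(c)[0] for c in ("TTC", "GGA"))) / 2
    assert est.s_sites == pytest.approx(s_sites)
    assert est.ps == pytest.approx(2.0 / s_sites)
    assert est.ps > 0.75 and math.isnan(est.ks) and not est.valid
    # a longer, mostly-identical pair stays in the JC-defined regime
    row_a = "TTTGGG" + "ATGAAA" * 20
    row_b = "TTCGGA" + "ATGAAA" * 20
    est2 = cv.kaks_ng86(_pair_alignment(row_a, row_b))
    assert est2.ks == pytest.approx(jukes_cantor(est2.ps))


def test_kaks_invariant_to_row_order():
    row_a = "TTTGGGATGAAA" + "ATGAAA" * 10
    row_b = "TTCGGAATGCAA" + "ATGAAA" * 10
    aln = _pair_alignment(row_a, row_b)
    flipped = cv.CodonAlignment(ids=("b", "a"), rows=(row_b, row_a))
    e1, e2 = cv.kaks_ng86(aln), cv.kaks_ng86(flipped)
    assert e1.ka == pytest.approx(e2.ka)
    assert e1.ks == pytest.approx(e2.ks)
    assert e1.omega == pytest.approx(e2.omega)


def test_ng86_totals_equal_pathway_hamming():
    """Sum of per-codon (sd+nd) equals the pathway-averaged distance."""
    rng = np.random.default_rng(3)
    codons_a = rng.choice(SENSE, size=40)
    codons_b = rng.choice(SENSE, size=40)
    aln = _pair_alignment("".join(codons_a), "".join(codons_b))
    est = cv.kaks_ng86(aln)
    total = sum(
        sum(cv.count_differences_ng86(a, b))
        for a, b in zip(codons_a, codons_b)
    )
    assert est.s_subs + est.a_subs == pytest.approx(total)


def test_jc_saturation_flags_invalid():
    est = cv.kaks_ng86(_pair_alignment("TTT" * 4, "CTG" * 4))
    assert not est.valid


def test_ml_likelihood_matches_direct_double_sum():
    """2-taxon likelihood equals the naive 61x61 sum at fixed parameters."""
    tree = cv.parse_newick("(A:0.05,B:0.05);")
    config = cv.SimConfig(tree=tree, site_classes=[(1.0, 0.5)],
                          n_genes=1, codons_per_gene=100, seed=5)
    aln, _ = cv.simulate_alignment(config)
    space = codon_space()
    patterns = compress_alignment(aln, space)
    freqs = uniform_freqs(space)
    cache = _TransitionCache(freqs, space)
    t, kappa, omega = 0.13, 2.4, 0.6
    got = pairwise_loglik(patterns, t, kappa, omega, freqs, cache)
    p = cache.probability(kappa, omega, t)
    want = 0.0
    for col in range(patterns.states.shape[1]):
        i, j = patterns.states[:, col]
        want += patterns.weights[col] * math.log(freqs[i] * p[i, j])
    assert got == pytest.approx(want, abs=1e-9)


def test_ml_identical_sequences_hit_zero_divergence():
    row = "ATGAAACCCGGG" * 25
    est = cv.kaks_ml_pairwise(_pair_alignment(row, row))
    assert est.ka == pytest.approx(0.0, abs=1e-4)
    assert est.ks == pytest.approx(0.0, abs=1e-4)


def test_ng86_unbiased_at_kappa_one():
    """With no ts/tv bias, and sites counted over the sense-codon space the
    neutral process actually explores (stop mutants excluded), the counting
    estimator recovers omega = 1 without systematic bias."""
    tree = cv.parse_newick("(A:0.1,B:0.1);")
    omegas = []
    for seed in range(100, 105):
        config = cv.SimConfig(tree=tree, kappa=1.0, site_classes=[(1.0, 1.0)],
                              n_genes=1, codons_per_gene=10000, seed=seed)
        aln, _ = cv.simulate_alignment(config)
        omegas.append(cv.kaks_ng86(aln, stops_as_nonsyn=False).omega)
    assert abs(np.mean(omegas) - 1.0) < 0.03


def test_ml_and_ng86_ks_agree_at_low_divergence():
    tree = cv.parse_newick("(A:0.04,B:0.04);")
    config = cv.SimConfig(tree=tree, kappa=2.0, site_classes=[(1.0, 0.3)],
                          n_genes=1, codons_per_gene=4000, seed=8)
    aln, _ = cv.simulate_alignment(config)
    ng = cv.kaks_ng86(aln)
    ml = cv.kaks_ml_pairwise(aln)
    assert abs(ml.ks - ng.ks) / ml.ks < 0.15
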