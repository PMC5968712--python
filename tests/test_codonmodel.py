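import numpy as np
import pytest

import congevol as cv
from congevol.codonmodel import (
    _TransitionCache,
    codon_space,
    compress_alignment,
    ka_ks_from_branch,
    substitution_flux,
    tree_loglik,
    uniform_freqs,
)

SPACE = codon_space()
FREQS = uniform_freqs(SPACE)


def test_rate_matrix_omega_zero_kills_nonsynonymous():
    q = cv.rate_matrix(2.0, 0.0, FREQS)
    assert np.all(q[SPACE.nonsynonymous] == 0)
    assert np.any(q[SPACE.synonymous] > 0)


def test_rate_matrix_detailed_balance():
    rng = np.random.default_rng(1)
    freqs = rng.dirichlet(np.ones(61))
    q = cv.rate_matrix(3.0, 0.7, freqs)
    flux = freqs[:, None] * q
    assert np.allclose(flux, flux.T, atol=1e-14)


def test_transition_probabilities_are_stochastic():
    cache = _TransitionCache(FREQS, SPACE)
    assert np.allclose(cache.probability(2.0, 0.5, 0.0), np.eye(61), atol=1e-12)
    for t in (0.01, 0.1, 1.0):
        p = cache.probability(2.0, 0.5, t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all()


def test_transition_matches_scipy_expm():
    from scipy.linalg import expm

    q = cv.rate_matrix(2.0, 0.5, FREQS)
    cache = _TransitionCache(FREQS, SPACE)
    for t in (0.05, 0.4):
        assert np.allclose(cache.probability(2.0, 0.5, t), expm(q * t),
                           atol=1e-10)


def _patterns_from_states(states):
    return cv.compress_alignment(
        cv.CodonAlignment(
            ids=tuple(f"t{i}" for i in range(len(states))),
            rows=tuple(SPACE.codons[s] for s in states),
        )
    )


def test_pruning_equals_exhaustive_enumeration_three_taxa():
    """One site on an unrooted trifurcation: sum over the 61 internal
    states explicitly and compare with the pruning recursion."""
    tree = cv.parse_newick("(t0:0.1,t1:0.25,t2:0.07);")
    cache = _TransitionCache(FREQS, SPACE)
    kappa, omega = 2.0, 0.4
    states = [5, 17, 40]
    patterns = _patterns_from_states(states)
    lengths = {"t0": 0.1, "t1": 0.25, "t2": 0.07}
    got = tree_loglik(
        patterns, tree, FREQS,
        lambda n: cache.probability(kappa, omega, lengths[n.name]),
        SPACE,
    )
    ps = {name: cache.probability(kappa, omega, t)
          for name, t in lengths.items()}
    total = sum(
        FREQS[x] * ps["t0"][x, states[0]] * ps["t1"][x, states[1]]
        * ps["t2"][x, states[2]]
        for x in range(61)
    )
    assert got == pytest.approx(np.log(total), abs=1e-10)


def test_pruning_equals_exhaustive_enumeration_four_taxa():
    """Two internal nodes: brute-force the 61^2 ancestral combinations."""
    tree = cv.parse_newick("((t0:0.1,t1:0.2):0.05,t2:0.15,t3:0.3);")
    cache = _TransitionCache(FREQS, SPACE)
    kappa, omega = 1.7, 0.9
    states = [3, 30, 12, 55]
    patterns = _patterns_from_states(states)
    lengths = {"t0": 0.1, "t1": 0.2, "t2": 0.15, "t3": 0.3, None: 0.05}

    def branch_p(node):
        return cache.probability(kappa, omega, lengths[node.name])

    got = tree_loglik(patterns, tree, FREQS, branch_p, SPACE)
    p_int = cache.probability(kappa, omega, 0.05)
    p_tip = {n: cache.probability(kappa, omega, lengths[n])
             for n in ("t0", "t1", "t2", "t3")}
    total = 0.0
    for root in range(61):
        inner = sum(
            p_int[root, y] * p_tip["t0"][y, states[0]]
            * p_tip["t1"][y, states[1]]
            for y in range(61)
        )
        total += (FREQS[root] * inner * p_tip["t2"][root, states[2]]
                  * p_tip["t3"][root, states[3]])
    assert got == pytest.approx(np.log(total), abs=1e-10)


def test_duplicated_sites_double_loglik():
    tree = cv.parse_newick("(A:0.1,B:0.2,C:0.1);")
    cfg = cv.SimConfig(tree=tree, n_genes=1, codons_per_gene=30, seed=5)
    aln, _ = cv.simulate_alignment(cfg)
    doubled = cv.CodonAlignment(ids=aln.ids,
                                rows=tuple(r + r for r in aln.rows))
    cache = _TransitionCache(FREQS, SPACE)

    def bp(node):
        return cache.probability(2.0, 0.3, node.length)

    l1 = tree_loglik(compress_alignment(aln), tree, FREQS, bp, SPACE)
    l2 = tree_loglik(compress_alignment(doubled), tree, FREQS, bp, SPACE)
    assert l2 == pytest.approx(2 * l1, abs=1e-8)


def test_zero_length_branch_does_not_change_loglik():
    tree_a = cv.parse_newick("(A:0.1,B:0.2,C:0.1);")
    tree_b = cv.parse_newick("((A:0.1,B:0.2):0.0,C:0.1);")
    cfg = cv.SimConfig(tree=tree_a, n_genes=1, codons_per_gene=40, seed=6)
    aln, _ = cv.simulate_alignment(cfg)
    cache = _TransitionCache(FREQS, SPACE)

    def bp(node):
        return cache.probability(2.0, 0.3, node.length)

    patterns = compress_alignment(aln)
    assert tree_loglik(patterns, tree_a, FREQS, bp, SPACE) == pytest.approx(
        tree_loglik(patterns, tree_b, FREQS, bp, SPACE), abs=1e-9
    )


def test_branch_kaks_decomposition_recovers_omega():
    for omega in (0.1, 1.0, 3.0):
        ka, ks = ka_ks_from_branch(0.2, omega, 2.0, FREQS, SPACE)
        assert ka / ks == pytest.approx(omega)
    # at omega=1 flux fractions match site fractions: Ka = Ks = t/3
    ka, ks = ka_ks_from_branch(0.3, 1.0, 2.0, FREQS, SPACE)
    assert ka == pytest.approx(0.1)
    assert ks == pytest.approx(0.1)


def test_m0_identical_alignment_hits_lower_bound():
    row = "ATGAAACCCGGGTTTCTG" * 10
    aln = cv.CodonAlignment(ids=("A", "B", "C"), rows=(row, row, row))
    tree = cv.parse_newick("(A:0.1,B:0.1,C:0.1);")
    fit = cv.fit_m0(aln, tree)
    assert all(t <= 1e-5 for t in fit.branch_lengths.values())
    n_codons = len(row) // 3
    assert fit.lnl == pytest.approx(n_codons * np.log(1 / 61), rel=1e-6)


def test_free_ratio_recovers_branch_omegas():
    """Three-branch free-ratio fit recovers heterogeneous omegas."""
    tree = cv.parse_newick("(A:0.15,B:0.15,C:0.15);")
    true_omega = {"A": 0.1, "B": 0.5, "C": 1.5}
    ok = 0
    n_rep = 6
    for rep in range(n_rep):
        cfg = cv.SimConfig(tree=tree, kappa=2.0, site_classes=[(1.0, 0.3)],
                           branch_omega={k: v for k, v in true_omega.items()},
                           n_genes=1, codons_per_gene=1500, seed=400 + rep)
        aln, _ = cv.simulate_alignment(cfg)
        fit = cv.fit_free_ratio(aln, tree)
        good = all(
            abs(fit.branches[b].omega - w) / w < 0.3
            for b, w in true_omega.items()
        )
        ok += good
        for b in true_omega:
            bk = fit.branches[b]
            if bk.ks > 1e-8:
                assert bk.ka / bk.ks == pytest.approx(bk.omega, rel=1e-6)
    assert ok >= n_rep - 2


def test_lineage_median_values():
    def fr(omega, ka=0.01, ks=0.05):
        return cv.FreeRatioFit(
            kappa=2.0, lnl=0.0, converged=True,
            branches={"X": cv.BranchKaKs(branch="X", t=0.1, omega=omega,
                                         ka=ka, ks=ks)},
        )

    assert cv.lineage_median([fr(0.1)], "X")["median_omega"] == 0.1
    fits = [fr(0.05), fr(0.10), fr(0.20)]
    assert cv.lineage_median(fits, "X")["median_omega"] == pytest.approx(0.10)
    with pytest.raises(ValueError):
        cv.lineage_median([], "X")


def test_branch_site_statistic_invariant_to_background_relabeling(quartet_tree):
    cfg = cv.SimConfig(tree=quartet_tree, kappa=2.0,
                       site_classes=[(0.6, 0.2), (0.4, 1.0)],
                       n_genes=1, codons_per_gene=150, seed=31)
    aln, _ = cv.simulate_alignment(cfg)
    lrt1, _, _ = cv.fit_branch_site(aln, quartet_tree, foreground="FG")
    # relabel background tips C <-> D (swap their sequences and names)
    ids = list(aln.ids)
    rows = dict(zip(ids, aln.rows))
    rows["C"], rows["D"] = rows["D"], rows["C"]
    aln2 = cv.CodonAlignment(ids=tuple(ids), rows=tuple(rows[i] for i in ids))
    tree2 = cv.parse_newick("((FG:0.2,B:0.2):0.1,D:0.2,C:0.2);")
    lrt2, _, _ = cv.fit_branch_site(aln2, tree2, foreground="FG")
    # identical up to the optimizer's convergence tolerance
    assert lrt1.statistic == pytest.approx(lrt2.statistic, abs=0.01)
    assert lrt1.statistic >= 0


def test_branch_site_requires_single_foreground(quartet_tree):
    cfg = cv.SimConfig(tree=quartet_tree, n_genes=1, codons_per_gene=60,
                       seed=1)
    aln, _ = cv.simulate_alignment(cfg)
    with pytest.raises(ValueError, match="foreground"):
        cv.fit_branch_site(aln, quartet_tree, foreground="nope")


def test_psg_scan_zero_cutoff_is_empty(quartet_tree):
    cfg = cv.SimConfig(tree=quartet_tree, n_genes=2, codons_per_gene=60,
                       seed=8)
    alns, _ = cv.simulate_gene_set(cfg)
    results, psgs = cv.psg_scan(alns, quartet_tree, "FG", fdr_cutoff=0.0)
    assert psgs == []
    assert all(r.q is not None for r in results)
    # genes shorter than the comparable-codon floor are excluded
    _, psgs2 = cv.psg_scan(alns, quartet_tree, "FG", min_codons=10**6)
    assert psgs2 == []
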