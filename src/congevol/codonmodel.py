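"""Codon substitution models on trees.

Implements the Goldman–Yang-style codon model: a 61-state continuous-time
Markov chain whose instantaneous rate between codons differing at one
nucleotide is proportional to the target codon frequency, multiplied by the
transition/transversion ratio kappa for transitions and by omega (= Ka/Ks)
for nonsynonymous changes.  On top of the likelihood engine (Felsenstein
pruning over the 61 sense codons) sit:

* a single-ratio (M0) fit used for branch lengths and kappa,
* the free-ratio model (an independent omega per branch) with lineage
  medians,
* branch-site model A and its likelihood-ratio test for positive selection
  on a designated foreground branch, with BH-FDR over a gene set.

All optimizations use bounded L-BFGS-B with deterministic multistart grids,
so fits are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .genetics import GeneticCode, is_transition, standard_code
from .trees import Tree

N_SENSE = 61  # standard code; other codes may differ


class _CodonSpace:
    """Pair structure of the sense-codon state space for one genetic code."""

    def __init__(self, code: GeneticCode):
        self.code = code
        self.codons = code.sense_codons
        self.n = len(self.codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        n = self.n
        self.single_diff = np.zeros((n, n), dtype=bool)
        self.transition = np.zeros((n, n), dtype=bool)
        self.synonymous = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                self.single_diff[i, j] = True
                self.transition[i, j] = is_transition(ci[k], cj[k])
                self.synonymous[i, j] = code.aa(ci) == code.aa(cj)
        self.nonsynonymous = self.single_diff & ~self.synonymous


@lru_cache(maxsize=4)
def codon_space(table_id: int = 1) -> _CodonSpace:
    return _CodonSpace(standard_code(table_id))


def uniform_freqs(space: _CodonSpace | None = None) -> np.ndarray:
    space = space or codon_space()
    return np.full(space.n, 1.0 / space.n)


def f3x4_freqs(
    position_nt_freqs: np.ndarray, space: _CodonSpace | None = None
) -> np.ndarray:
    """Codon frequencies from 3x4 positional nucleotide frequencies.

    ``position_nt_freqs[p]`` gives frequencies of T, C, A, G at codon
    position p.  Stop codons are zeroed and the vector renormalized.
    """
    space = space or codon_space()
    nt_index = {n: i for i, n in enumerate("TCAG")}
    freqs = np.array(
        [
            np.prod(
                [position_nt_freqs[p][nt_index[c[p]]] for p in range(3)]
            )
            for c in space.codons
        ]
    )
    total = freqs.sum()
    if total <= 0:
        raise ValueError("degenerate positional frequencies")
    return freqs / total


def alignment_f3x4(aln: CodonAlignment) -> np.ndarray:
    """F3x4 frequencies estimated from an alignment's ungapped codons."""
    counts = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate("TCAG")}
    for row in aln.rows:
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            if "-" in codon or "N" in codon:
                continue
            for p in range(3):
                counts[p, nt_index[codon[p]]] += 1
    counts += 0.5  # avoid zero frequencies on short alignments
    return f3x4_freqs(counts / counts.sum(axis=1, keepdims=True))


def rate_matrix(
    kappa: float,
    omega: float,
    freqs: np.ndarray,
    space: _CodonSpace | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """GY94 generator: q_ij = pi_j * kappa^[ts] * omega^[nonsyn].

    Rows sum to zero.  With ``normalize`` the matrix is scaled to one
    expected substitution per codon per unit time at stationarity.
    """
    space = space or codon_space()
    q = np.where(space.single_diff, np.tile(freqs, (space.n, 1)), 0.0)
    q = q * np.where(space.transition, kappa, 1.0)
    q = q * np.where(space.nonsynonymous, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        scale = -(freqs * np.diag(q)).sum()
        if scale > 0:
            q = q / scale
    return q


def substitution_flux(
    kappa: float, freqs: np.ndarray, space: _CodonSpace | None = None
) -> tuple[float, float]:
    """Stationary nonsynonymous and synonymous flux at omega = 1.

    Returns (A, S): the expected rates of nonsynonymous and synonymous
    change per codon per unit (unnormalized) time; the omega-weighted total
    flux is ``omega * A + S``.
    """
    space = space or codon_space()
    base = np.where(space.single_diff, np.tile(freqs, (space.n, 1)), 0.0)
    base = base * np.where(space.transition, kappa, 1.0)
    a = float((freqs[:, None] * np.where(space.nonsynonymous, base, 0.0)).sum())
    s = float((freqs[:, None] * np.where(space.synonymous, base, 0.0)).sum())
    return a, s


def ka_ks_from_branch(
    t: float, omega: float, kappa: float, freqs: np.ndarray,
    space: _CodonSpace | None = None,
) -> tuple[float, float]:
    """Decompose a branch length into Ka and Ks per site.

    With flux fractions rhoN = omega*A/(omega*A+S) and mutational site
    fractions fN = A/(A+S), Ka = t*rhoN/(3*fN) and Ks = t*rhoS/(3*fS);
    the ratio recovers omega exactly.
    """
    a, s = substitution_flux(kappa, freqs, space)
    total = omega * a + s
    fn, fs = a / (a + s), s / (a + s)
    ka = t * (omega * a / total) / (3.0 * fn)
    ks = t * (s / total) / (3.0 * fs)
    return ka, ks


class _TransitionCache:
    """Eigendecomposition-backed P(t) with caching on (kappa, omega).

    The GY94 chain is reversible, so diag(pi)^1/2 Q diag(pi)^-1/2 is
    symmetric and a single eigh per (kappa, omega) serves every branch
    length; within an optimizer run the cache makes finite-difference
    gradients cheap.
    """

    def __init__(self, freqs: np.ndarray, space: _CodonSpace, scale: float | None = None):
        self.freqs = freqs
        self.space = space
        self.scale = scale  # external time-unit scale; None = per-matrix
        self._decomp: dict[tuple[float, float], tuple] = {}
        self.sqrt_pi = np.sqrt(freqs)

    def _get_decomp(self, kappa: float, omega: float):
        key = (kappa, omega)
        decomp = self._decomp.get(key)
        if decomp is None:
            q = rate_matrix(
                kappa, omega, self.freqs, self.space,
                normalize=self.scale is None,
            )
            if self.scale is not None:
                q = q / self.scale
            sym = (self.sqrt_pi[:, None] * q) / self.sqrt_pi[None, :]
            w, v = np.linalg.eigh((sym + sym.T) / 2.0)
            left = self.sqrt_pi[:, None] * v  # maps P = D^-1/2 V e^wt V' D^1/2
            self._decomp[key] = (w, v / self.sqrt_pi[:, None], left)
            decomp = self._decomp[key]
        return decomp

    def probability(self, kappa: float, omega: float, t: float) -> np.ndarray:
        w, right, left = self._get_decomp(kappa, omega)
        p = (right * np.exp(w * t)) @ left.T
        np.clip(p, 1e-300, None, out=p)
        return p

    def clear(self) -> None:
        self._decomp.clear()


@dataclass
class SitePatterns:
    """Codon alignment compressed to unique site patterns with weights."""

    ids: tuple[str, ...]
    states: np.ndarray  # (ntips, npatterns) codon indices
    weights: np.ndarray  # (npatterns,)

    @property
    def n_codons(self) -> int:
        return int(self.weights.sum())


def compress_alignment(
    aln: CodonAlignment, space: _CodonSpace | None = None
) -> SitePatterns:
    """Clean an alignment (complete deletion) and compress to patterns."""
    space = space or codon_space()
    clean = aln.clean(space.code)
    if clean.n_codons == 0:
        raise ValueError("no comparable codons after cleaning")
    mat = np.array(
        [[space.index[c] for c in clean.codon_row(sid)] for sid in clean.ids]
    )
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return SitePatterns(
        ids=clean.ids, states=patterns, weights=counts.astype(float)
    )


def _indexed_tree(tree: Tree, tip_ids: tuple[str, ...]):
    """Postorder node list with parent links and tip state-row indices."""
    order = list(tree.postorder())
    missing = set(tree.tip_names()) - set(tip_ids)
    if missing:
        raise ValueError(f"tip(s) {sorted(missing)} missing from alignment")
    return order


def tree_loglik(
    patterns: SitePatterns,
    tree: Tree,
    freqs: np.ndarray,
    branch_p,  # callable node -> (61, 61) transition matrix
    space: _CodonSpace | None = None,
) -> float:
    """Felsenstein pruning over sense-codon states.

    ``branch_p`` supplies the transition matrix for the branch above each
    non-root node; site-class mixtures call this once per class.
    """
    space = space or codon_space()
    order = _indexed_tree(tree, patterns.ids)
    tip_row = {sid: r for r, sid in enumerate(patterns.ids)}
    npat = patterns.states.shape[1]
    messages: dict[int, np.ndarray] = {}
    for node in order:
        if node.is_leaf:
            p = branch_p(node)
            cond = p[:, patterns.states[tip_row[node.name]]].T  # (npat, 61)
        else:
            cond = np.ones((npat, space.n))
            for child in node.children:
                cond = cond * messages.pop(id(child))
            if node is tree.root:
                site_l = cond @ freqs
                return float(patterns.weights @ np.log(site_l))
            p = branch_p(node)
            cond = cond @ p.T
        messages[id(node)] = cond
    raise RuntimeError("tree has no root")  # pragma: no cover


def mixture_loglik(
    patterns: SitePatterns,
    tree: Tree,
    freqs: np.ndarray,
    class_weights: np.ndarray,
    branch_p_for_class,  # callable (class index, node) -> P
    space: _CodonSpace | None = None,
) -> float:
    """Log-likelihood of a site-class mixture: L_site = sum_c p_c L_c."""
    space = space or codon_space()
    order = _indexed_tree(tree, patterns.ids)
    tip_row = {sid: r for r, sid in enumerate(patterns.ids)}
    npat = patterns.states.shape[1]
    site_mix = np.zeros(npat)
    for c, wc in enumerate(class_weights):
        if wc == 0:
            continue
        messages: dict[int, np.ndarray] = {}
        for node in order:
            if node.is_leaf:
                p = branch_p_for_class(c, node)
                cond = p[:, patterns.states[tip_row[node.name]]].T
            else:
                cond = np.ones((npat, space.n))
                for child in node.children:
                    cond = cond * messages.pop(id(child))
                if node is tree.root:
                    site_mix += wc * (cond @ freqs)
                    break
                p = branch_p_for_class(c, node)
                cond = cond @ p.T
            messages[id(node)] = cond
    return float(patterns.weights @ np.log(np.clip(site_mix, 1e-300, None)))


# ---------------------------------------------------------------------------
# Model fits


@dataclass
class M0Fit:
    """Single-ratio fit: shared omega, shared kappa, per-branch lengths."""

    kappa: float
    omega: float
    branch_lengths: dict[str, float]
    lnl: float
    converged: bool
    tree: Tree = field(repr=False)


def _label_internals(tree: Tree) -> None:
    i = 0
    for node in tree.preorder():
        if node.name is None and node is not tree.root:
            node.name = f"_b{i}"
            i += 1


def fit_m0(
    aln: CodonAlignment,
    tree: Tree,
    freqs: np.ndarray | None = None,
    space: _CodonSpace | None = None,
    kappa_bounds=(0.1, 20.0),
    omega_bounds=(1e-4, 20.0),
    t_bounds=(1e-6, 50.0),
) -> M0Fit:
    """Estimate kappa, a single omega, and all branch lengths by ML."""
    space = space or codon_space()
    if freqs is None:
        freqs = uniform_freqs(space)
    patterns = compress_alignment(aln, space)
    work = tree.copy()
    _label_internals(work)
    branches = [n for n in work.postorder() if n is not work.root]
    nb = len(branches)
    cache = _TransitionCache(freqs, space)

    # crude initial scale from the mean pairwise codon mismatch fraction
    mismatch = np.mean(
        patterns.weights
        @ (patterns.states != patterns.states[0]).T[:, 1:].astype(float)
        / patterns.n_codons
    ) if patterns.states.shape[0] > 1 else 0.05
    t0 = max(0.01, min(1.0, float(mismatch)))

    def negloglik(x):
        kappa, omega = x[0], x[1]
        ts = x[2:]
        pmap = {
            id(b): cache.probability(kappa, omega, ts[k])
            for k, b in enumerate(branches)
        }
        return -tree_loglik(
            patterns, work, freqs, lambda n: pmap[id(n)], space
        )

    x0 = np.concatenate([[2.0, 0.3], np.full(nb, t0)])
    bounds = [kappa_bounds, omega_bounds] + [t_bounds] * nb
    best = None
    for omega_start in (0.3, 1.5):
        cache.clear()
        x0[1] = omega_start
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    lengths = {
        b.name: float(t) for b, t in zip(branches, best.x[2:])
    }
    return M0Fit(
        kappa=float(best.x[0]),
        omega=float(best.x[1]),
        branch_lengths=lengths,
        lnl=-float(best.fun),
        converged=bool(best.success),
        tree=work,
    )


@dataclass
class BranchKaKs:
    branch: str
    t: float
    omega: float
    ka: float
    ks: float


@dataclass
class FreeRatioFit:
    kappa: float
    branches: dict[str, BranchKaKs]
    lnl: float
    converged: bool


def fit_free_ratio(
    aln: CodonAlignment,
    tree: Tree,
    freqs: np.ndarray | None = None,
    space: _CodonSpace | None = None,
    omega_bounds=(1e-4, 99.0),
    t_bounds=(1e-6, 50.0),
) -> FreeRatioFit:
    """ML fit with an independent omega per branch (free-ratio model)."""
    space = space or codon_space()
    if freqs is None:
        freqs = uniform_freqs(space)
    patterns = compress_alignment(aln, space)
    work = tree.copy()
    _label_internals(work)
    branches = [n for n in work.postorder() if n is not work.root]
    nb = len(branches)
    cache = _TransitionCache(freqs, space)

    m0 = fit_m0(aln, tree, freqs, space)
    t_init = [
        max(t_bounds[0], m0.branch_lengths.get(b.name, 0.05))
        for b in branches
    ]

    def negloglik(x):
        kappa = x[0]
        ts = x[1 : 1 + nb]
        omegas = x[1 + nb :]
        pmap = {
            id(b): cache.probability(kappa, omegas[k], ts[k])
            for k, b in enumerate(branches)
        }
        return -tree_loglik(
            patterns, work, freqs, lambda n: pmap[id(n)], space
        )

    x0 = np.concatenate(
        [[m0.kappa], t_init, np.full(nb, max(1e-3, m0.omega))]
    )
    bounds = [(0.1, 20.0)] + [t_bounds] * nb + [omega_bounds] * nb
    res = minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-10},
    )
    kappa = float(res.x[0])
    out: dict[str, BranchKaKs] = {}
    for k, b in enumerate(branches):
        t = float(res.x[1 + k])
        omega = float(res.x[1 + nb + k])
        ka, ks = ka_ks_from_branch(t, omega, kappa, freqs, space)
        out[b.name] = BranchKaKs(branch=b.name, t=t, omega=omega, ka=ka, ks=ks)
    return FreeRatioFit(
        kappa=kappa, branches=out, lnl=-float(res.fun),
        converged=bool(res.success),
    )


def lineage_median(
    fits: list[FreeRatioFit], branch: str
) -> dict[str, float]:
    """Median omega (and Ka, Ks) across genes for one named branch.

    Genes whose fitted branch omega sits at the upper bound or whose Ks is
    ~0 (omega unidentifiable) are excluded, mirroring the usual treatment
    of undefined ratios.
    """
    omegas, kas, kss = [], [], []
    for fit in fits:
        bk = fit.branches.get(branch)
        if bk is None:
            continue
        if bk.ks <= 1e-8 or bk.omega >= 98.0:
            continue
        omegas.append(bk.omega)
        kas.append(bk.ka)
        kss.append(bk.ks)
    if not omegas:
        raise ValueError(f"no valid omega estimates for branch {branch!r}")
    return {
        "median_omega": float(np.median(omegas)),
        "median_ka": float(np.median(kas)),
        "median_ks": float(np.median(kss)),
        "n_genes": len(omegas),
    }


# ---------------------------------------------------------------------------
# Branch-site model A


@dataclass
class SiteClassSpec:
    """Branch-site model A site classes.

    Classes 0 and 1 have omega0 (purifying) and omega1 = 1 everywhere;
    classes 2a/2b switch to omega2 >= 1 on the foreground branch, with
    proportions tied to the p0:p1 odds.
    """

    p0: float
    p1: float
    omega0: float
    omega2: float

    @property
    def proportions(self) -> np.ndarray:
        f = 1.0 - self.p0 - self.p1
        r = self.p0 / (self.p0 + self.p1)
        return np.array(
            [self.p0, self.p1, f * r, f * (1.0 - r)]
        )

    def background_omegas(self) -> np.ndarray:
        return np.array([self.omega0, 1.0, self.omega0, 1.0])

    def foreground_omegas(self) -> np.ndarray:
        return np.array([self.omega0, 1.0, self.omega2, self.omega2])


@dataclass
class BranchSiteFit:
    spec: SiteClassSpec
    lnl: float
    converged: bool


@dataclass
class LRTResult:
    gene: str
    lnl_null: float
    lnl_alt: float
    statistic: float
    df: int
    p: float
    q: float | None = None
    converged: bool = True


def _branch_site_negloglik(
    x, fixed_omega2, patterns, work, branches, fg_ids, freqs, space, cache_holder
):
    f, r, omega0, t_fg = x[0], x[1], x[2], x[3]
    omega2 = fixed_omega2 if fixed_omega2 is not None else x[4]
    p0 = (1.0 - f) * r
    p1 = (1.0 - f) * (1.0 - r)
    spec = SiteClassSpec(p0=p0, p1=p1, omega0=omega0, omega2=omega2)
    weights = spec.proportions
    bg = spec.background_omegas()
    fg = spec.foreground_omegas()
    # Common time scale: background mixture flux at stationarity.  Folding
    # the scale into the branch times (P = expm(Q_raw * t / scale)) lets the
    # unnormalized eigendecompositions be cached across optimizer steps.
    a, s = cache_holder["flux"]
    scale = float(np.dot(weights, bg * a + s))
    cache = cache_holder["cache"]
    if len(cache._decomp) > 256:
        cache.clear()
    pmat: dict[tuple[int, int], np.ndarray] = {}

    def branch_p_for_class(c, node):
        on_fg = id(node) in fg_ids
        omega = fg[c] if on_fg else bg[c]
        t = t_fg if on_fg else cache_holder["t"][id(node)]
        key = (round(omega, 12), id(node))
        if key not in pmat:
            pmat[key] = cache.probability(
                cache_holder["kappa"], omega, t / scale
            )
        return pmat[key]

    return -mixture_loglik(
        patterns, work, freqs, weights, branch_p_for_class, space
    )


def fit_branch_site(
    aln: CodonAlignment,
    tree: Tree,
    foreground: str | None = None,
    freqs: np.ndarray | None = None,
    space: _CodonSpace | None = None,
    gene: str = "gene",
) -> tuple[LRTResult, BranchSiteFit, BranchSiteFit]:
    """Branch-site positive-selection LRT for one gene.

    Branch lengths and kappa are first estimated under the single-ratio
    model; background branch lengths and kappa are then held fixed while
    the foreground branch length is re-estimated jointly with the
    site-class parameters (the single-ratio fit systematically shrinks the
    foreground length when selection is present).  The null fixes
    omega2 = 1 and the alternative
    frees omega2 >= 1, initialized at the null optimum with a deterministic
    omega2 multistart.  The statistic 2*(lnL_alt - lnL_null), clamped at 0,
    is referred to chi-square with 1 df (conservative versus the 50:50
    boundary mixture).
    """
    space = space or codon_space()
    if freqs is None:
        freqs = uniform_freqs(space)
    work = tree.copy()
    _label_internals(work)
    if foreground is not None:
        for node in work.preorder():
            node.foreground = node.name == foreground
    fg_nodes = [n for n in work.preorder() if n.foreground]
    if len(fg_nodes) != 1:
        raise ValueError("exactly one foreground branch must be marked")
    fg_ids = {id(n) for n in fg_nodes}

    m0 = fit_m0(aln, work, freqs, space)
    patterns = compress_alignment(aln, space)
    # m0 was fitted on a labeled copy of `work`; address branches by label
    t_by_id = {}
    for node in work.preorder():
        if node is not work.root:
            t_by_id[id(node)] = m0.branch_lengths[node.name]

    holder = {
        "kappa": m0.kappa,
        "t": t_by_id,
        "flux": substitution_flux(m0.kappa, freqs, space),
        "cache": _TransitionCache(freqs, space, scale=1.0),
    }
    args_common = (patterns, work, [n for n in work.postorder() if n is not work.root],
                   fg_ids, freqs, space, holder)
    t_fg0 = max(1e-6, t_by_id[next(iter(fg_ids))])
    bounds_null = [
        (1e-6, 0.999), (1e-6, 1 - 1e-6), (1e-4, 1.0), (1e-6, 50.0)
    ]
    x0 = np.array([0.1, 0.7, min(1.0, max(1e-3, m0.omega)), t_fg0])
    res_null = minimize(
        _branch_site_negloglik, x0, args=(1.0, *args_common),
        method="L-BFGS-B", bounds=bounds_null,
        options={"maxiter": 500, "ftol": 1e-10},
    )
    bounds_alt = bounds_null + [(1.0, 999.0)]
    best_alt = None
    for omega2_start in (1.5, 5.0):
        x0a = np.concatenate([res_null.x, [omega2_start]])
        res = minimize(
            _branch_site_negloglik, x0a, args=(None, *args_common),
            method="L-BFGS-B", bounds=bounds_alt,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if best_alt is None or res.fun < best_alt.fun:
            best_alt = res

    lnl_null = -float(res_null.fun)
    lnl_alt = max(-float(best_alt.fun), lnl_null)  # alt nests the null
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p = float(chi2.sf(stat, df=1))

    def to_spec(x, omega2=None):
        f, r, omega0 = x[0], x[1], x[2]
        w2 = omega2 if omega2 is not None else x[4]
        return SiteClassSpec(
            p0=(1 - f) * r, p1=(1 - f) * (1 - r), omega0=omega0, omega2=w2
        )

    null_fit = BranchSiteFit(
        spec=to_spec(res_null.x, omega2=1.0),
        lnl=lnl_null, converged=bool(res_null.success),
    )
    alt_fit = BranchSiteFit(
        spec=to_spec(best_alt.x),
        lnl=lnl_alt, converged=bool(best_alt.success),
    )
    lrt = LRTResult(
        gene=gene, lnl_null=lnl_null, lnl_alt=lnl_alt,
        statistic=stat, df=1, p=p,
        converged=bool(res_null.success and best_alt.success),
    )
    return lrt, null_fit, alt_fit


def psg_scan(
    alignments: dict[str, CodonAlignment],
    tree: Tree,
    foreground: str,
    fdr_cutoff: float = 0.05,
    min_codons: int = 50,
    freqs: np.ndarray | None = None,
) -> tuple[list[LRTResult], list[str]]:
    """Branch-site LRT over a gene set with BH-FDR; PSGs have q < cutoff.

    Genes with fewer than ``min_codons`` comparable codons, or whose fits
    fail to converge, are excluded from the FDR family.
    """
    from statsmodels.stats.multitest import multipletests

    results: list[LRTResult] = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        try:
            patterns = compress_alignment(aln)
        except ValueError:
            continue
        if patterns.n_codons < min_codons:
            continue
        lrt, _, _ = fit_branch_site(
            aln, tree, foreground=foreground, freqs=freqs, gene=gene
        )
        if lrt.converged:
            results.append(lrt)
    if results:
        pvals = np.array([r.p for r in results])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    psgs = [r.gene for r in results if r.q is not None and r.q < fdr_cutoff]
    return results, psgs
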