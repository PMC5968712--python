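"""No-replicate differential expression with a fixed NB dispersion.

With one RNA-seq library per species there is no way to estimate
biological variance, so the dispersion of the negative-binomial model is
an explicit a-priori parameter (default 0.2, a deliberately conservative
choice for between-individual variation).  The test is the classic
two-sample conditional exact test: counts are scaled to the geometric mean
of the two library sizes, and conditional on the rescaled total the
two-sided p-value sums the probabilities of all splits no more likely than
the observed one.  Because the null conditional distribution is symmetric,
this equals the doubled smaller tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .categories import bh_fdr
from .io import CountMatrix


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, per sample."""
    return matrix.counts / matrix.library_sizes * 1e6


def filter_min_cpm(matrix: CountMatrix, threshold: float = 10.0) -> CountMatrix:
    """Keep genes with CPM >= threshold in *every* sample."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (cpm(matrix) >= threshold).all(axis=1)
    return CountMatrix(
        counts=matrix.counts.loc[keep],
        library_sizes=matrix.library_sizes,
    )


def _equalize(count_a, count_b, libsize_a, libsize_b):
    """Scale both counts to the geometric-mean library size, rounding
    half-to-even."""
    common = float(np.sqrt(libsize_a * libsize_b))
    a = np.asarray(
        np.round(np.asarray(count_a, dtype=float) * common / libsize_a)
    )
    b = np.asarray(
        np.round(np.asarray(count_b, dtype=float) * common / libsize_b)
    )
    return a.astype(int), b.astype(int)


def _conditional_logpmf(n: int, mean: float, dispersion: float) -> np.ndarray:
    """Log pmf of the split k | k + (n-k) = n under equal NB means."""
    k = np.arange(n + 1)
    if dispersion == 0:
        lp = stats.poisson.logpmf(k, mean)
    else:
        size = 1.0 / dispersion
        p = size / (size + mean)
        lp = stats.nbinom.logpmf(k, size, p)
    logf = lp + lp[::-1]
    return logf - logsumexp(logf)


def nb_exact_test(
    count_a: int,
    count_b: int,
    libsize_a: float,
    libsize_b: float,
    dispersion: float = 0.2,
) -> float:
    """Two-sided exact test for one gene; returns the p-value."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a, b = _equalize([count_a], [count_b], libsize_a, libsize_b)
    a, b = int(a[0]), int(b[0])
    n = a + b
    if n == 0:
        return 1.0
    logf = _conditional_logpmf(n, n / 2.0, dispersion)
    keep = logf <= logf[a] + 1e-12
    return float(min(1.0, np.exp(logsumexp(logf[keep]))))


@dataclass
class DGEResult:
    """Per-gene differential-expression calls for one two-sample comparison."""

    sample_a: str
    sample_b: str
    table: pd.DataFrame  # index gene; cpm_a, cpm_b, log2fc, p, q, direction
    fdr_cutoff: float

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "down"])


def exact_test_comparison(
    matrix: CountMatrix,
    sample_a: str,
    sample_b: str,
    dispersion: float = 0.2,
    fdr_cutoff: float = 0.01,
) -> DGEResult:
    """Exact test of sample_a vs sample_b for every gene in the matrix.

    log2 fold changes are of a over b (positive = higher in a), computed
    from library-size-equalized counts with a half-count offset.  Direction
    is assigned only below the FDR cutoff.
    """
    counts_a = matrix.counts[sample_a].to_numpy()
    counts_b = matrix.counts[sample_b].to_numpy()
    lib_a = float(matrix.library_sizes[sample_a])
    lib_b = float(matrix.library_sizes[sample_b])
    a_eq, b_eq = _equalize(counts_a, counts_b, lib_a, lib_b)
    cpms = cpm(matrix)
    pvals = np.empty(len(a_eq))
    for i, (a, b) in enumerate(zip(a_eq, b_eq)):
        n = int(a + b)
        if n == 0:
            pvals[i] = 1.0
            continue
        logf = _conditional_logpmf(n, n / 2.0, dispersion)
        keep = logf <= logf[int(a)] + 1e-12
        pvals[i] = min(1.0, np.exp(logsumexp(logf[keep])))
    qvals = bh_fdr(pvals)
    log2fc = np.log2((a_eq + 0.5) / (b_eq + 0.5))
    direction = np.where(
        qvals < fdr_cutoff,
        np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "ns")),
        "ns",
    )
    table = pd.DataFrame(
        {
            "cpm_a": cpms[sample_a],
            "cpm_b": cpms[sample_b],
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "direction": direction,
        },
        index=matrix.counts.index,
    )
    return DGEResult(
        sample_a=sample_a, sample_b=sample_b, table=table,
        fdr_cutoff=fdr_cutoff,
    )


def intersect_calls(
    result_1: DGEResult, result_2: DGEResult
) -> tuple[set[str], set[str]]:
    """Genes called in the same direction in both comparisons.

    Mirrors the shared up-/down-regulated sets used when one focal species
    is compared against two congeners.
    """
    shared_up = result_1.up & result_2.up
    shared_down = result_1.down & result_2.down
    return shared_up, shared_down


def median_ratio_scaling(matrix: CountMatrix) -> CountMatrix:
    """Optional median-of-ratios library-size adjustment (off by default).

    Rescales library sizes by each sample's median count ratio to the
    across-sample geometric-mean reference gene, using genes expressed
    everywhere.
    """
    counts = matrix.counts
    expressed = counts[(counts > 0).all(axis=1)]
    if expressed.empty:
        return matrix
    log_geo = np.log(expressed).mean(axis=1)
    factors = {}
    for sample in counts.columns:
        ratios = np.log(expressed[sample]) - log_geo
        factors[sample] = float(np.exp(np.median(ratios)))
    libs = matrix.library_sizes * pd.Series(factors)
    return CountMatrix(counts=matrix.counts, library_sizes=libs)
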