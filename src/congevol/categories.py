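"""Accelerated-evolution tests by functional category.

Given per-ortholog Ka/Ks estimates for two species pairs (e.g. the
invasive-vs-native pair and the native-vs-native pair) and a gene ->
GO-category annotation, each category is scored with:

* pooled-count Fisher test — a 2x2 table of total nonsynonymous (A) and
  synonymous (S) substitution counts in either pair; a significant result
  means the A:S balance, i.e. the average protein evolutionary rate,
  differs between the pairs;
* two-tailed binomial sign test on the number of genes with the higher
  omega in one pair versus the other (ties dropped);
* Wilcoxon signed-rank test on the paired per-gene omega values;
* mean Ka, Ks, omega per pair, a top-decile flag on mean omega, and
  BH-FDR within each test family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable
from .kaks import KaKsEstimate


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_acceleration_test(
    a1: int, s1: int, a2: int, s2: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the pooled A/S 2x2 table.

    Returns (odds ratio, p).  The odds ratio (A1*S2)/(S1*A2) is inf/0 on
    zero margins; an all-zero table yields p = 1 by convention.
    """
    table = np.array([[a1, s1], [a2, s2]])
    if (table < 0).any():
        raise ValueError("negative counts in contingency table")
    if table.sum() == 0:
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def binomial_sign_test(n_higher_1: int, n_higher_2: int) -> float:
    """Exact two-tailed binomial test under p = 1/2, ties pre-excluded."""
    if n_higher_1 < 0 or n_higher_2 < 0:
        raise ValueError("counts must be non-negative")
    n = n_higher_1 + n_higher_2
    if n == 0:
        return 1.0
    return float(
        stats.binomtest(n_higher_1, n, p=0.5, alternative="two-sided").pvalue
    )


def wilcoxon_paired_test(
    omega_1, omega_2
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired omega values.

    Pairs with an undefined omega on either side and zero differences are
    dropped; exact null enumeration for n <= 25, normal approximation with
    continuity correction above.
    """
    x = np.asarray(list(omega_1), dtype=float)
    y = np.asarray(list(omega_2), dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    nz = x != y
    x, y = x[nz], y[nz]
    if x.size == 0:
        return float("nan"), 1.0
    method = "exact" if x.size <= 25 else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CategoryAccelResult:
    category: str
    n_genes: int
    a1: int
    s1: int
    a2: int
    s2: int
    mean_ka_1: float
    mean_ks_1: float
    mean_omega_1: float
    mean_ka_2: float
    mean_ks_2: float
    mean_omega_2: float
    pooled_omega_1: float = float("nan")
    pooled_omega_2: float = float("nan")
    fisher_odds: float = float("nan")
    fisher_p: float = float("nan")
    fisher_q: float = float("nan")
    n_higher_1: int = 0
    n_higher_2: int = 0
    n_ties: int = 0
    binomial_p: float = float("nan")
    binomial_q: float = float("nan")
    wilcoxon_stat: float = float("nan")
    wilcoxon_p: float = float("nan")
    wilcoxon_q: float = float("nan")
    top_decile: bool = False


def _mean_valid(values: list[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def aggregate_by_category(
    estimates_1: dict[str, KaKsEstimate],
    estimates_2: dict[str, KaKsEstimate],
    annotation: AnnotationTable,
    min_genes: int = 5,
) -> list[CategoryAccelResult]:
    """Per-category aggregation of two species-pair estimate sets.

    Estimates are keyed by a shared ortholog id.  Pooled A/S counts sum the
    per-gene substitution counts (rounded half-away-from-zero to integers
    for the exact test); per-pair averages use genes with valid estimates.
    Categories with fewer than ``min_genes`` genes present in both pairs
    are dropped.
    """
    if not annotation.gene_to_categories:
        raise ValueError("empty annotation table")
    shared = sorted(set(estimates_1) & set(estimates_2))
    by_cat: dict[str, list[str]] = {}
    for gene in shared:
        for cat in annotation.gene_to_categories.get(gene, ()):
            by_cat.setdefault(cat, []).append(gene)
    results = []
    for cat in sorted(by_cat):
        genes = by_cat[cat]
        if len(genes) < min_genes:
            continue
        e1 = [estimates_1[g] for g in genes]
        e2 = [estimates_2[g] for g in genes]
        a1 = sum(_round_half_away(e.a_subs) for e in e1)
        s1 = sum(_round_half_away(e.s_subs) for e in e1)
        a2 = sum(_round_half_away(e.a_subs) for e in e2)
        s2 = sum(_round_half_away(e.s_subs) for e in e2)
        omega1 = [e.omega for e in e1]
        omega2 = [e.omega for e in e2]
        n_higher_1 = n_higher_2 = n_ties = 0
        for w1, w2 in zip(omega1, omega2):
            if math.isnan(w1) or math.isnan(w2):
                continue
            if w1 > w2:
                n_higher_1 += 1
            elif w2 > w1:
                n_higher_2 += 1
            else:
                n_ties += 1
        odds, fisher_p = fisher_acceleration_test(a1, s1, a2, s2)
        binom_p = binomial_sign_test(n_higher_1, n_higher_2)
        wstat, wp = wilcoxon_paired_test(omega1, omega2)

        def pooled(ka_list, ks_list):
            ka, ks = sum(ka_list), sum(ks_list)
            return ka / ks if ks > 0 else float("nan")

        results.append(
            CategoryAccelResult(
                category=cat,
                n_genes=len(genes),
                a1=a1, s1=s1, a2=a2, s2=s2,
                mean_ka_1=_mean_valid([e.ka for e in e1]),
                mean_ks_1=_mean_valid([e.ks for e in e1]),
                mean_omega_1=_mean_valid(omega1),
                mean_ka_2=_mean_valid([e.ka for e in e2]),
                mean_ks_2=_mean_valid([e.ks for e in e2]),
                mean_omega_2=_mean_valid(omega2),
                pooled_omega_1=pooled(
                    [e.ka for e in e1], [e.ks for e in e1]
                ),
                pooled_omega_2=pooled(
                    [e.ka for e in e2], [e.ks for e in e2]
                ),
                fisher_odds=odds,
                fisher_p=fisher_p,
                n_higher_1=n_higher_1,
                n_higher_2=n_higher_2,
                n_ties=n_ties,
                binomial_p=binom_p,
                wilcoxon_stat=wstat,
                wilcoxon_p=wp,
            )
        )
    # FDR within each test family separately
    if results:
        for attr_p, attr_q in (
            ("fisher_p", "fisher_q"),
            ("binomial_p", "binomial_q"),
            ("wilcoxon_p", "wilcoxon_q"),
        ):
            q = bh_fdr([getattr(r, attr_p) for r in results])
            for r, qv in zip(results, q):
                setattr(r, attr_q, float(qv))
    rank_top_decile(results)
    return results


def rank_top_decile(results: list[CategoryAccelResult]) -> set[str]:
    """Flag the top ceil(10%) categories by pair-1 mean omega.

    NaN means sort last; ties break by category id for determinism.
    """
    if not results:
        return set()
    m = len(results)
    k = math.ceil(0.1 * m)
    ranked = sorted(
        results,
        key=lambda r: (
            -(r.mean_omega_1 if not math.isnan(r.mean_omega_1) else -np.inf),
            r.category,
        ),
    )
    flagged = {r.category for r in ranked[:k]}
    for r in results:
        r.top_decile = r.category in flagged
    return flagged


def results_table(results: list[CategoryAccelResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
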