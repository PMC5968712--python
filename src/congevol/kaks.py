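"""Pairwise Ka/Ks estimation.

Two estimators over a cleaned two-sequence codon alignment:

* NG86 — the Nei–Gojobori counting method: fractional synonymous and
  nonsynonymous sites from single-base mutant enumeration, substitution
  counts averaged over all orderings of the single-step mutational paths
  between differing codons (paths through stop codons excluded), and the
  Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).
* ML — joint maximization of the two-sequence GY94 likelihood over
  divergence t, kappa and omega, with Ka and Ks read off the fitted flux.

NG86 is the deterministic reference estimator (exhaustively oracle-
testable); ML is the fidelity option mirroring codeml's pairwise mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .codonmodel import (
    _TransitionCache,
    codon_space,
    compress_alignment,
    ka_ks_from_branch,
    substitution_flux,
    uniform_freqs,
)
from .genetics import GeneticCode, standard_code

logger = logging.getLogger(__name__)

NUCS = "TCAG"


def count_sites_ng86(
    codon: str,
    code: GeneticCode | None = None,
    stops_as_nonsyn: bool = True,
) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous sites of one sense codon.

    Each of the 9 single-base mutants contributes 1/3 of a site to the
    synonymous total if it preserves the amino acid.  Mutants that create a
    stop codon count as nonsynonymous under the original Nei–Gojobori
    convention (so s + n = 3); with ``stops_as_nonsyn=False`` they are
    excluded and s + n <= 3.
    """
    if code is None:
        code = standard_code()
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if set(codon) - set("ACGT"):
        raise ValueError(f"ambiguous codon {codon!r}")
    s = n = 0.0
    aa = code.aa(codon)
    for pos in range(3):
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if code.is_stop(mutant):
                if stops_as_nonsyn:
                    n += 1.0 / 3.0
                continue
            if code.aa(mutant) == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


def count_differences_ng86(
    codon_a: str,
    codon_b: str,
    code: GeneticCode | None = None,
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between codons.

    For Hamming distance k the k! orderings of the single-base steps are
    enumerated; orderings passing through a stop codon are dropped and each
    surviving path's steps are classified by whether they change the amino
    acid.  If every path hits a stop, all k steps count as nonsynonymous
    (with a warning).
    """
    if code is None:
        code = standard_code()
    for c in (codon_a, codon_b):
        if code.is_stop(c):
            raise ValueError(f"stop codon {c!r} in difference counting")
        if set(c) - set("ACGT"):
            raise ValueError(f"ambiguous codon {c!r}")
    diff_positions = [k for k in range(3) if codon_a[k] != codon_b[k]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0
    path_syn: list[int] = []
    path_nonsyn: list[int] = []
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.aa(current) == code.aa(nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            path_syn.append(syn)
            path_nonsyn.append(nonsyn)
    if not path_syn:
        logger.warning(
            "all mutational paths %s -> %s pass through stops; "
            "counting %d steps as nonsynonymous", codon_a, codon_b, k,
        )
        return 0.0, float(k)
    return (
        sum(path_syn) / len(path_syn),
        sum(path_nonsyn) / len(path_nonsyn),
    )


@lru_cache(maxsize=4)
def _difference_table(table_id: int = 1) -> np.ndarray:
    """(61, 61, 2) pathway-averaged (sd, nd) for every sense-codon pair."""
    space = codon_space(table_id)
    table = np.zeros((space.n, space.n, 2))
    for i, ci in enumerate(space.codons):
        for j, cj in enumerate(space.codons):
            if i < j:
                sd, nd = count_differences_ng86(ci, cj, space.code)
                table[i, j] = table[j, i] = (sd, nd)
    return table


@lru_cache(maxsize=4)
def _site_table(table_id: int = 1, stops_as_nonsyn: bool = True) -> np.ndarray:
    space = codon_space(table_id)
    return np.array(
        [
            count_sites_ng86(c, space.code, stops_as_nonsyn)
            for c in space.codons
        ]
    )


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; returns nan when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion below 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # avoid -0.0


@dataclass
class KaKsEstimate:
    """Substitution sites, counts, and corrected rates for one pair."""

    pair: str
    s_sites: float
    n_sites: float
    s_subs: float  # pooled synonymous count, the "S" of category tests
    a_subs: float  # pooled nonsynonymous count, the "A" of category tests
    ps: float
    pn: float
    ks: float
    ka: float
    omega: float
    method: str
    n_codons: int
    valid: bool
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "pair": self.pair,
            "method": self.method,
            "n_codons": self.n_codons,
            "S_sites": self.s_sites,
            "N_sites": self.n_sites,
            "S_subs": self.s_subs,
            "A_subs": self.a_subs,
            "Ks": self.ks,
            "Ka": self.ka,
            "omega": self.omega,
            "valid": self.valid,
            "note": self.note,
        }


def kaks_ng86(
    aln: CodonAlignment,
    pair_id: str | None = None,
    table_id: int = 1,
    stops_as_nonsyn: bool = True,
) -> KaKsEstimate:
    """NG86 Ka/Ks for a two-sequence codon alignment.

    Sites are averaged over the two sequences; omega is flagged undefined
    when Ks = 0 or either Jukes–Cantor correction saturates.
    """
    if len(aln.ids) != 2:
        raise ValueError("NG86 estimation needs exactly two sequences")
    space = codon_space(table_id)
    patterns = compress_alignment(aln, space)
    if patterns.n_codons < 1:
        raise ValueError("no comparable codons")
    pair_id = pair_id or f"{aln.ids[0]}|{aln.ids[1]}"
    sites = _site_table(table_id, stops_as_nonsyn)
    diffs = _difference_table(table_id)
    sa, sb = patterns.states
    w = patterns.weights
    s_sites = float(((sites[sa, 0] + sites[sb, 0]) / 2.0) @ w)
    n_sites = float(((sites[sa, 1] + sites[sb, 1]) / 2.0) @ w)
    s_subs = float(diffs[sa, sb, 0] @ w)
    a_subs = float(diffs[sa, sb, 1] @ w)
    ps = s_subs / s_sites if s_sites > 0 else 0.0
    pn = a_subs / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    note = ""
    valid = True
    if math.isnan(ks) or math.isnan(ka):
        valid = False
        note = "JC correction saturated"
        omega = float("nan")
    elif ks == 0.0:
        valid = False
        note = "Ks = 0; omega undefined"
        omega = float("nan")
    else:
        omega = ka / ks
    return KaKsEstimate(
        pair=pair_id, s_sites=s_sites, n_sites=n_sites,
        s_subs=s_subs, a_subs=a_subs, ps=ps, pn=pn,
        ks=ks, ka=ka,
        omega=omega, method="NG86", n_codons=patterns.n_codons,
        valid=valid, note=note,
    )


def pairwise_loglik(
    patterns, t: float, kappa: float, omega: float, freqs: np.ndarray,
    cache: _TransitionCache,
) -> float:
    """Two-sequence GY94 log-likelihood: sum_site log(pi_i * P_ij(t))."""
    p = cache.probability(kappa, omega, t)
    sa, sb = patterns.states
    site_l = freqs[sa] * p[sa, sb]
    return float(patterns.weights @ np.log(np.clip(site_l, 1e-300, None)))


def kaks_ml_pairwise(
    aln: CodonAlignment,
    pair_id: str | None = None,
    freq_mode: str = "uniform",
    table_id: int = 1,
) -> KaKsEstimate:
    """Pairwise ML Ka/Ks under GY94 with a deterministic t multistart."""
    if len(aln.ids) != 2:
        raise ValueError("pairwise ML needs exactly two sequences")
    space = codon_space(table_id)
    patterns = compress_alignment(aln, space)
    pair_id = pair_id or f"{aln.ids[0]}|{aln.ids[1]}"
    if freq_mode == "uniform":
        freqs = uniform_freqs(space)
    elif freq_mode == "f3x4":
        from .codonmodel import alignment_f3x4

        freqs = alignment_f3x4(aln)
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    cache = _TransitionCache(freqs, space)

    def negloglik(x):
        return -pairwise_loglik(
            patterns, x[0], x[1], x[2], freqs, cache
        )

    bounds = [(1e-6, 20.0), (0.1, 20.0), (1e-4, 99.0)]
    best = None
    for t0 in (0.01, 0.1, 0.5):
        cache.clear()
        res = minimize(
            negloglik, np.array([t0, 2.0, 0.4]),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    t_hat, kappa_hat, omega_hat = (float(v) for v in best.x)
    ka, ks = ka_ks_from_branch(t_hat, omega_hat, kappa_hat, freqs, space)
    a, s = substitution_flux(kappa_hat, freqs, space)
    fn, fs = a / (a + s), s / (a + s)
    n_sites = 3.0 * patterns.n_codons * fn
    s_sites = 3.0 * patterns.n_codons * fs
    valid = bool(best.success) and t_hat > 1e-5
    note = "" if best.success else "optimizer did not converge"
    if t_hat <= 1e-5:
        note = "t at lower bound; omega unidentifiable"
        omega_hat = float("nan")
        valid = False
    return KaKsEstimate(
        pair=pair_id, s_sites=s_sites, n_sites=n_sites,
        s_subs=ks * s_sites, a_subs=ka * n_sites,
        ps=ks, pn=ka, ks=ks, ka=ka, omega=omega_hat,
        method="ML", n_codons=patterns.n_codons, valid=valid, note=note,
    )
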