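"""Synthetic data generation for the whole pipeline.

Three generators, all seeded and deterministic:

* codon alignments evolved on a tree under the GY94 model with discrete
  site classes and per-branch omega overrides, by exact stochastic
  simulation (Gillespie jumps per codon per branch) so that the *realized*
  numbers of synonymous/nonsynonymous substitutions are available as truth;
* families of gene alignments with an annotation table in which chosen
  categories carry an accelerated (omega-multiplied) foreground branch;
* negative-binomial count matrices with planted differentially expressed
  genes, emulating a two-sample no-replicate RNA-seq comparison.

Branch lengths are in expected substitutions per codon under that branch's
site-class-average omega, matching the time unit of the model fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codonmodel import (
    _CodonSpace,
    codon_space,
    f3x4_freqs,
    rate_matrix,
    substitution_flux,
    uniform_freqs,
)
from .io import AnnotationTable, CountMatrix
from .trees import Tree


@dataclass
class SimConfig:
    """Parameters of the codon-alignment simulator.

    site_classes is a list of (proportion, omega) pairs; proportions must
    sum to 1.  branch_omega maps a branch (node) name to either a scalar
    omega override for all site classes, or a per-class omega sequence —
    the latter is how branch-site selection regimes are expressed.
    """

    tree: Tree
    kappa: float = 2.0
    codon_freqs: np.ndarray | str = "uniform"
    site_classes: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 0.2)]
    )
    branch_omega: dict[str, float | list[float]] = field(default_factory=dict)
    n_genes: int = 1
    codons_per_gene: int = 300
    seed: int = 0
    table_id: int = 1

    def __post_init__(self) -> None:
        props = np.array([p for p, _ in self.site_classes])
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError(f"site-class proportions sum to {props.sum()}")
        if ((props < 0) | (props > 1)).any():
            raise ValueError("site-class proportions must lie in [0, 1]")
        if any(w < 0 for _, w in self.site_classes):
            raise ValueError("omegas must be >= 0")
        if self.codons_per_gene <= 0 or self.n_genes <= 0:
            raise ValueError("n_genes and codons_per_gene must be positive")
        if not self.tree.tip_names():
            raise ValueError("empty tree")

    def resolve_freqs(self, space: _CodonSpace) -> np.ndarray:
        if isinstance(self.codon_freqs, str):
            if self.codon_freqs == "uniform":
                return uniform_freqs(space)
            raise ValueError(f"unknown frequency spec {self.codon_freqs!r}")
        freqs = np.asarray(self.codon_freqs, dtype=float)
        if freqs.ndim == 2:  # 3x4 positional nucleotide frequencies
            return f3x4_freqs(freqs, space)
        if freqs.shape != (space.n,):
            raise ValueError(f"expected {space.n} codon frequencies")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")
        return freqs


@dataclass
class BranchTruth:
    """Realized substitution counts on one branch of one gene."""

    branch: str
    omega_by_class: list[float]
    syn_subs: int
    nonsyn_subs: int


@dataclass
class PlantedTruth:
    """What the simulator actually did, for downstream recovery tests."""

    site_class_of_codon: dict[str, np.ndarray] = field(default_factory=dict)
    branch_truth: dict[str, list[BranchTruth]] = field(default_factory=dict)
    accelerated_categories: dict[str, float] = field(default_factory=dict)
    gene_category: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    dispersion: float | None = None


def _class_omegas(
    config: SimConfig, branch_name: str | None
) -> list[float]:
    base = [w for _, w in config.site_classes]
    override = config.branch_omega.get(branch_name) if branch_name else None
    if override is None:
        return base
    if np.isscalar(override):
        return [float(override)] * len(base)
    if len(override) != len(base):
        raise ValueError("per-class omega override length mismatch")
    return [float(w) for w in override]


def _evolve_branch(
    states: np.ndarray,
    t: float,
    q: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gillespie evolution of codon states for time t under generator q.

    Returns (new_states, from_states, to_states) where the last two list
    every realized jump (for truth bookkeeping).  Vectorized over codons:
    each pass samples one exponential waiting time per still-active codon.
    """
    n = q.shape[0]
    rate_out = -np.diag(q)
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_cdf = np.cumsum(jump / rate_out[:, None], axis=1)
    states = states.copy()
    remaining = np.full(states.shape, float(t))
    active = rate_out[states] > 0
    froms, tos = [], []
    while active.any():
        idx = np.nonzero(active)[0]
        waits = rng.exponential(1.0 / rate_out[states[idx]])
        done = waits >= remaining[idx]
        jump_idx = idx[~done]
        remaining[idx] -= waits
        active[idx[done]] = False
        if jump_idx.size:
            u = rng.random(jump_idx.size)
            new = np.array(
                [
                    np.searchsorted(jump_cdf[states[k]], u[m])
                    for m, k in enumerate(jump_idx)
                ]
            )
            new = np.minimum(new, n - 1)
            froms.append(states[jump_idx].copy())
            tos.append(new)
            states[jump_idx] = new
            active[jump_idx] = rate_out[new] > 0
    f = np.concatenate(froms) if froms else np.empty(0, dtype=int)
    to = np.concatenate(tos) if tos else np.empty(0, dtype=int)
    return states, f, to


def simulate_alignment(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CodonAlignment, PlantedTruth]:
    """Simulate one gene's codon alignment on the configured tree."""
    space = codon_space(config.table_id)
    freqs = config.resolve_freqs(space)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ncod = config.codons_per_gene
    props = np.array([p for p, _ in config.site_classes])
    classes = rng.choice(len(props), size=ncod, p=props)
    root_states = rng.choice(space.n, size=ncod, p=freqs)

    truth = PlantedTruth()
    truth.site_class_of_codon["gene"] = classes

    # per-(branch, class) generators, scaled so the branch length is the
    # expected substitutions per codon under the branch's class mixture
    tip_states: dict[str, np.ndarray] = {}
    branch_records: list[BranchTruth] = []

    def recurse(node, states):
        for child in node.children:
            omegas = _class_omegas(config, child.name)
            a, s = substitution_flux(config.kappa, freqs, space)
            mix_rate = float(np.dot(props, [w * a + s for w in omegas]))
            child_states = states.copy()
            syn = nonsyn = 0
            for c, omega in enumerate(omegas):
                mask = classes == c
                if not mask.any():
                    continue
                q = rate_matrix(
                    config.kappa, omega, freqs, space, normalize=False
                )
                q = q / mix_rate
                t = child.length if child.length is not None else 0.0
                new, f, to = _evolve_branch(states[mask], t, q, rng)
                child_states[mask] = new
                if f.size:
                    syn += int(space.synonymous[f, to].sum())
                    nonsyn += int(space.nonsynonymous[f, to].sum())
            branch_records.append(
                BranchTruth(
                    branch=child.name or "",
                    omega_by_class=omegas,
                    syn_subs=syn,
                    nonsyn_subs=nonsyn,
                )
            )
            if child.is_leaf:
                tip_states[child.name] = child_states
            else:
                recurse(child, child_states)

    recurse(config.tree.root, root_states)
    truth.branch_truth["gene"] = branch_records

    ids = tuple(config.tree.tip_names())
    rows = tuple(
        "".join(space.codons[s] for s in tip_states[tip]) for tip in ids
    )
    return CodonAlignment(ids=ids, rows=rows), truth


def simulate_gene_set(
    config: SimConfig,
) -> tuple[dict[str, CodonAlignment], PlantedTruth]:
    """Simulate ``config.n_genes`` independent genes with split RNG streams.

    Per-gene streams are spawned from the global seed, so results for gene
    *i* do not depend on how many genes precede it.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_genes)
    alignments: dict[str, CodonAlignment] = {}
    truth = PlantedTruth()
    for i, ss in enumerate(streams):
        gene = f"g{i + 1:04d}"
        aln, gt = simulate_alignment(config, np.random.default_rng(ss))
        alignments[gene] = aln
        truth.site_class_of_codon[gene] = gt.site_class_of_codon["gene"]
        truth.branch_truth[gene] = gt.branch_truth["gene"]
    return alignments, truth


def simulate_family_set(
    config: SimConfig,
    categories: list[str],
    accelerated: dict[str, float],
    foreground: str,
) -> tuple[dict[str, CodonAlignment], AnnotationTable, PlantedTruth]:
    """Gene families with planted accelerated categories.

    Genes are assigned to categories round-robin; genes in ``accelerated``
    categories have their omega on the ``foreground`` branch multiplied by
    the stated factor (a multiplier of 1 plants nothing).
    """
    for cat, mult in accelerated.items():
        if mult < 0:
            raise ValueError(f"negative acceleration multiplier for {cat}")
        if cat not in categories:
            raise ValueError(f"accelerated category {cat!r} not in categories")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_genes)
    alignments: dict[str, CodonAlignment] = {}
    annot: dict[str, set[str]] = {}
    truth = PlantedTruth()
    truth.accelerated_categories = {
        c: m for c, m in accelerated.items() if m != 1.0
    }
    for i, ss in enumerate(streams):
        gene = f"g{i + 1:04d}"
        cat = categories[i % len(categories)]
        annot[gene] = {cat}
        truth.gene_category[gene] = cat
        gene_config = config
        mult = accelerated.get(cat, 1.0)
        if mult != 1.0:
            base = _class_omegas(config, foreground)
            overrides = dict(config.branch_omega)
            overrides[foreground] = [w * mult for w in base]
            gene_config = SimConfig(
                tree=config.tree,
                kappa=config.kappa,
                codon_freqs=config.codon_freqs,
                site_classes=config.site_classes,
                branch_omega=overrides,
                n_genes=1,
                codons_per_gene=config.codons_per_gene,
                seed=config.seed,
                table_id=config.table_id,
            )
        aln, gt = simulate_alignment(gene_config, np.random.default_rng(ss))
        alignments[gene] = aln
        truth.branch_truth[gene] = gt.branch_truth["gene"]
    return alignments, AnnotationTable(gene_to_categories=annot), truth


@dataclass
class NBCountConfig:
    """Negative-binomial count simulator for a two-sample comparison.

    Baseline per-gene means are log-normal; counts for sample j are
    NB(mean * libsize_j / 1e6, dispersion).  DE genes multiply the second
    sample's mean by 2**log2_fold_change (sign alternating, so both
    directions are planted).
    """

    n_genes: int = 1000
    log_mean: float = 5.0
    log_sd: float = 1.0
    dispersion: float = 0.2
    library_sizes: tuple[float, ...] = (1e6, 1e6)
    de_fraction: float = 0.0
    log2_fold_change: float = 2.0
    seed: int = 0
    sample_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(l <= 0 for l in self.library_sizes):
            raise ValueError("library sizes must be positive")


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    """NB(mean, phi) with var = mean + phi*mean^2; phi = 0 is Poisson."""
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    config: NBCountConfig,
) -> tuple[CountMatrix, PlantedTruth]:
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i + 1:05d}" for i in range(n)]
    samples = config.sample_names or tuple(
        f"s{j + 1}" for j in range(len(config.library_sizes))
    )
    base_mean = rng.lognormal(config.log_mean, config.log_sd, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    truth = PlantedTruth(dispersion=config.dispersion)
    fold = 2.0 ** config.log2_fold_change
    if fold != 1.0:
        for k, i in enumerate(de_idx):
            lfc = config.log2_fold_change if k % 2 == 0 else -config.log2_fold_change
            truth.de_genes[genes[i]] = lfc

    cols = {}
    for j, (name, lib) in enumerate(zip(samples, config.library_sizes)):
        mean = base_mean * (lib / 1e6)
        if j == 1 and truth.de_genes:
            shift = np.ones(n)
            for k, i in enumerate(de_idx):
                shift[i] = fold if k % 2 == 0 else 1.0 / fold
            mean = mean * shift
        cols[name] = _nb_draw(rng, mean, config.dispersion)
    counts = pd.DataFrame(cols, index=genes)
    matrix = CountMatrix(
        counts=counts,
        library_sizes=pd.Series(
            dict(zip(samples, config.library_sizes))
        ),
    )
    return matrix, truth
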