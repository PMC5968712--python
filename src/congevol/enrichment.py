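"""Fisher-exact category enrichment with BH-FDR.

Two uses, mirroring how functional categories are compared in congener
studies:

* over-representation of categories within a focal gene set (differentially
  expressed genes, positively selected genes) against a population of
  annotated genes;
* comparison of category gene contents between two species' annotation
  tables (which species over-represents each category).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .categories import bh_fdr
from .io import AnnotationTable


@dataclass
class EnrichmentResult:
    category: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    odds: float
    p: float
    q: float = float("nan")
    enriched: bool = False
    direction: str = ""  # which side over-represents (species comparison)


def fisher_enrichment(
    study: set[str],
    annotation: AnnotationTable,
    population: set[str] | None = None,
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-category over-representation of a study set.

    The population defaults to all annotated genes; the study set must be a
    subset of it.  A category is flagged enriched when q < cutoff and the
    odds ratio exceeds 1.
    """
    if not study:
        raise ValueError("empty study set")
    if population is None:
        population = set(annotation.gene_to_categories)
    if not study <= population:
        raise ValueError("study set is not a subset of the population")
    results: list[EnrichmentResult] = []
    n_pop = len(population)
    n_study = len(study)
    for cat in sorted(annotation.categories()):
        in_cat = annotation.genes_in(cat) & population
        k_pop = len(in_cat)
        k_study = len(in_cat & study)
        table = [
            [k_study, n_study - k_study],
            [k_pop - k_study, n_pop - n_study - (k_pop - k_study)],
        ]
        # one-sided (over-representation), the convention of GO enrichment
        odds, p = stats.fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(
                category=cat,
                study_count=k_study,
                study_size=n_study,
                population_count=k_pop,
                population_size=n_pop,
                odds=float(odds),
                p=float(p),
            )
        )
    q = bh_fdr([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
        r.enriched = bool(qv < fdr_cutoff and r.odds > 1)
    return results


def compare_species_categories(
    annot_a: AnnotationTable,
    annot_b: AnnotationTable,
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-category species-content comparison.

    For each category the 2x2 table is (species A, species B) x (genes in
    category, genes not in category), with gene totals as margins.  The
    direction records which species over-represents the category.
    """
    sizes_a = annot_a.category_sizes()
    sizes_b = annot_b.category_sizes()
    n_a, n_b = len(annot_a), len(annot_b)
    results: list[EnrichmentResult] = []
    for cat in sorted(set(sizes_a) | set(sizes_b)):
        k_a = sizes_a.get(cat, 0)
        k_b = sizes_b.get(cat, 0)
        table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        frac_a = k_a / n_a if n_a else 0.0
        frac_b = k_b / n_b if n_b else 0.0
        results.append(
            EnrichmentResult(
                category=cat,
                study_count=k_a,
                study_size=n_a,
                population_count=k_b,
                population_size=n_b,
                odds=float(odds),
                p=float(p),
                direction="a" if frac_a > frac_b else (
                    "b" if frac_b > frac_a else ""
                ),
            )
        )
    q = bh_fdr([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
        r.enriched = bool(qv < fdr_cutoff)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.replace({np.nan: np.nan})
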