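"""Detecting functional categories with accelerated protein evolution.

Simulates 100 genes in 10 GO-like categories on a three-species tree, with
one category's genes evolving 3x faster on the focal (e.g. invasive)
lineage.  The per-category battery then compares the focal-vs-relative
species pair against the relative-vs-relative pair: pooled substitution
counts feed a Fisher exact test, gene-level omega comparisons feed a sign
test and a Wilcoxon test, and categories are ranked by mean omega.
"""

import congevol as cv

tree = cv.parse_newick("((invasive:0.05,native1:0.05):0.02,native2:0.08);")
config = cv.SimConfig(
    tree=tree, kappa=2.0, site_classes=[(1.0, 0.2)],
    n_genes=100, codons_per_gene=500, seed=3,
)
categories = [f"GO:{i:04d}" for i in range(10)]
alignments, annotation, truth = cv.simulate_family_set(
    config, categories, accelerated={"GO:0004": 3.0}, foreground="invasive"
)

pair1, pair2 = {}, {}
for gene, aln in alignments.items():
    pair1[gene] = cv.kaks_ng86(aln.subset(["invasive", "native1"]), pair_id=gene)
    pair2[gene] = cv.kaks_ng86(aln.subset(["native1", "native2"]), pair_id=gene)

results = cv.aggregate_by_category(pair1, pair2, annotation, min_genes=5)
print(f"{len(results)} categories tested "
      f"(planted acceleration: {truth.accelerated_categories})\n")
print(f"{'category':>9} {'n':>3} {'mean w1':>8} {'mean w2':>8} "
      f"{'fisher q':>9} {'binom p':>8} {'top10%':>6}")
for r in sorted(results, key=lambda r: r.fisher_q):
    print(f"{r.category:>9} {r.n_genes:>3} {r.mean_omega_1:>8.3f} "
          f"{r.mean_omega_2:>8.3f} {r.fisher_q:>9.2g} "
          f"{r.binomial_p:>8.2g} {str(r.top_decile):>6}")

print("\nThe planted category should head the table: its pooled "
      "nonsynonymous/synonymous balance shifts in the focal pair (small "
      "Fisher q) and its mean omega puts it in the top decile.")
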