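"""Pairwise Ka/Ks between simulated congeners.

Simulates 40 genes on a three-species tree shaped like a recently diverged
congener trio (two close relatives plus a more distant one), then estimates
Ka, Ks and omega = Ka/Ks for each ortholog pair with the NG86 counting
method and prints the per-pair medians.  Omega well below 1 indicates the
purifying selection typical of conserved coding genes.
"""

import numpy as np

import congevol as cv

tree = cv.parse_newick("((invasive:0.03,native1:0.03):0.01,native2:0.05);")
config = cv.SimConfig(
    tree=tree, kappa=2.0, site_classes=[(1.0, 0.2)],
    n_genes=40, codons_per_gene=400, seed=1,
)
alignments, _ = cv.simulate_gene_set(config)

for pair in (("invasive", "native1"), ("native1", "native2")):
    ka, ks, omega = [], [], []
    for gene, aln in alignments.items():
        est = cv.kaks_ng86(aln.subset(list(pair)), pair_id=gene)
        if est.valid:
            ka.append(est.ka)
            ks.append(est.ks)
            omega.append(est.omega)
    print(f"{pair[0]} vs {pair[1]} ({len(omega)} pairs with defined omega):")
    print(f"  median Ka = {np.median(ka):.4f}  median Ks = {np.median(ks):.4f}"
          f"  median Ka/Ks = {np.median(omega):.3f}")

print("\nThe close pair shows smaller Ka and Ks (less divergence); both "
      "pairs have Ka/Ks << 1, i.e. most amino-acid changes are removed by "
      "purifying selection.")
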