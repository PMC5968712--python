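"""Branch-site scan for positively selected genes on a focal lineage.

Simulates 12 genes on a four-taxon tree: ten evolve under purifying
selection everywhere, two carry a site class with omega = 8 at 15% of
sites on the focal branch only.  The branch-site likelihood-ratio test is run per gene with
the focal branch as foreground, and genes with BH-FDR q < 0.05 are called
positively selected (PSGs).
"""

import congevol as cv

tree = cv.parse_newick("((focal:0.2,sister:0.2):0.1,out1:0.2,out2:0.2);")
null_classes = [(0.6, 0.2), (0.4, 1.0)]
sel_classes = [(0.51, 0.2), (0.34, 1.0), (0.09, 0.2), (0.06, 1.0)]

alignments = {}
selected_truth = set()
for i in range(12):
    under_selection = i < 2
    config = cv.SimConfig(
        tree=tree, kappa=2.0,
        site_classes=sel_classes if under_selection else null_classes,
        branch_omega={"focal": [0.2, 1.0, 8.0, 8.0]} if under_selection else {},
        n_genes=1, codons_per_gene=800, seed=40 + i,
    )
    aln, _ = cv.simulate_alignment(config)
    gene = f"gene{i:02d}"
    alignments[gene] = aln
    if under_selection:
        selected_truth.add(gene)

results, psgs = cv.psg_scan(alignments, tree, foreground="focal",
                            fdr_cutoff=0.05)
print(f"{'gene':>7} {'2dlnL':>7} {'p':>9} {'q':>9} {'selected?':>9}")
for r in results:
    mark = "PSG" if r.gene in psgs else ""
    truth = "yes" if r.gene in selected_truth else ""
    print(f"{r.gene:>7} {r.statistic:>7.2f} {r.p:>9.2g} {r.q:>9.2g} "
          f"{truth:>9} {mark}")
print(f"\nPSGs after FDR: {psgs}")
print("Genes simulated with the selected site class should carry large "
      "LRT statistics; the FDR step keeps false calls among the null "
      "genes rare.")
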