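# congevol

Comparative molecular evolution and expression analysis for congeneric
species — the workflow used when an invasive plant is contrasted with close
non-invasive relatives from transcriptome-derived gene sets, built as an
importable Python library with a thin command-line layer.

## What it does, and for whom

Given coding sequences and proteomes for two or more closely related
species, a species tree, gene-to-category annotations (GO terms or
pathways), and per-species read counts, `congevol` answers the questions a
comparative study asks:

* **Which genes are orthologs?** Reciprocal best hits (RBH) from BLAST
  tabular files or from the built-in global protein aligner; RBH cliques
  give single-copy groups across k species; protein-guided back-translation
  produces codon alignments.
* **How fast are proteins evolving?** Pairwise Ka (nonsynonymous
  substitutions per nonsynonymous site) and Ks (synonymous per synonymous
  site), by Nei–Gojobori (1986) counting with Jukes–Cantor correction, or by
  maximum likelihood under the Goldman–Yang (GY94) codon model
  q<sub>ij</sub> ∝ π<sub>j</sub>·κ^[ts]·ω^[nonsyn]. ω = Ka/Ks < 1 means
  purifying selection; ω > 1, positive selection.
* **Which functional categories evolve faster between the focal pair than
  between relatives?** Per-category pooled A/S contingency tables (Fisher
  exact test), a binomial sign test on per-gene ω comparisons, a Wilcoxon
  signed-rank test on paired ω values, top-decile ranking by mean ω, and
  BH-FDR — each test sensitive to a different signature of acceleration.
* **Which genes show lineage-specific positive selection?** Free-ratio fits
  (an independent ω per branch, with lineage medians) and the branch-site
  model A scan: a likelihood-ratio test of ω₂ > 1 at a fraction of sites on
  a marked foreground branch, 2Δℓ ~ χ²₁, with FDR control over the gene set.
* **Which genes are differentially expressed when there are no
  replicates?** CPM filtering and the conditional negative-binomial exact
  test with an explicit a-priori dispersion (default 0.2), FDR-controlled
  up/down calls, and shared-direction intersections across comparisons.
* **Which categories are enriched** in a resulting gene set, and how do two
  species' annotation contents differ — one-sided and two-sided Fisher
  tests with BH-FDR.

Everything is driven either by user data in standard formats (FASTA,
newick, TSV, BLAST outfmt 6) or by the built-in simulator, which evolves
codon alignments on a tree by exact stochastic simulation under the same
GY94 model (with site classes and per-branch ω overrides), plants
accelerated categories and DE genes, and records the realized truth — so
every stage of the pipeline is testable offline.

## Worked example

`examples/04_positive_selection_scan.py` simulates twelve 800-codon genes on
a four-taxon tree — ten under purifying selection everywhere, two with a
site class at ω = 8 on the focal branch — and scans them:

```
   gene   2dlnL         p         q selected?
 gene00   25.59   4.2e-07   2.5e-06       yes PSG
 gene01   26.67   2.4e-07   2.5e-06       yes PSG
 gene02    0.00         1         1
 gene03    1.52      0.22      0.77
 ...
PSGs after FDR: ['gene00', 'gene01']
```

The two genes simulated with foreground selection carry large
likelihood-ratio statistics and survive FDR correction; the null genes do
not. The other examples walk through pairwise Ka/Ks
(`01_pairwise_kaks.py`), RBH orthology and codon alignment (`02`), the
category-acceleration battery (`03`), no-replicate differential expression
(`05`), and enrichment (`06`); each prints its numbers with a line on what
they mean.

A command-line interface mirrors the library for shell pipelines:

```bash
congevol simulate --tree sp.nwk --n-genes 50 --categories 10 \
    --accelerate CAT003:3.0 --foreground Mmicrantha --seed 7 --out sim/
congevol kaks --aln-dir sim/ --pair Mmicrantha:Mcordata --out k1.tsv
congevol kaks --aln-dir sim/ --pair Mcordata:Mcordifolia --out k2.tsv
congevol accel --kaks k1.tsv k2.tsv --annot sim/annotation.tsv --out accel.tsv
congevol dge --counts counts.tsv --pairs A:B A:C --dispersion 0.2 --out dge.tsv
```

Identical seeds produce byte-identical output files.

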