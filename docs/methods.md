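# Methods

`congevol` implements the comparative molecular-evolution and expression
workflow used when an invasive species is contrasted with close non-invasive
relatives from transcriptome-derived gene sets: ortholog pairing, codon-level
Ka/Ks estimation, tests for functional categories with accelerated protein
evolution, lineage-level free-ratio and branch-site positive-selection scans,
and differential expression without biological replicates. This note records
the models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Orthology and codon alignments

Orthologs between two species are reciprocal best hits (RBH): gene *x* in
species A pairs with *y* in B iff *y* is the unique top-scoring match of *x*
and vice versa. Scores come from a BLAST tabular file when available, or from
the internal global protein aligner (Needleman–Wunsch with affine gaps,
BLOSUM62, gap open 10, gap extend 0.5 — BLASTP-like scoring without the
external binary). Ties for best hit exclude the gene entirely: with no
stated tie rule in common practice, strict uniqueness is the conservative
choice, and ties are logged. Single-copy groups across *k* species are RBH
cliques — one gene per species with every cross pair reciprocal-best.

Codon alignments are protein-guided: proteins are aligned, then each residue
column is expanded to the source codon (`---` for a residue gap). A CDS that
does not translate exactly to its protein row is an error, not a warning.
Before any substitution counting or likelihood work, columns containing a
gap, an ambiguous codon, or a stop in any row are removed (complete
deletion). All coordinates are 0-based half-open; codon *i* occupies
nucleotides `3i..3i+3`.

## Pairwise Ka/Ks

Two estimators share one result type.

**NG86 (reference).** Fractional synonymous/nonsynonymous sites per codon are
counted by enumerating the nine single-base mutants; substitutions between
codon pairs are averaged over all orderings of the single-step mutational
paths, excluding paths through stop codons. Proportions are corrected for
multiple hits with the Jukes–Cantor transform d = −(3/4)·ln(1 − 4p/3).
Conventions, each the original Nei–Gojobori choice unless noted:

* mutations *to* stop codons count as nonsynonymous sites (so s + n = 3 per
  codon); `stops_as_nonsyn=False` excludes them instead. The default keeps
  the textbook definition; the exclusion variant matches the mutational
  opportunity of a process that never visits stops and is the convention
  under which the estimator is unbiased when transitions and transversions
  are equally likely.
* if every path between two codons passes through a stop, all steps count as
  nonsynonymous and a warning is emitted.
* Ks = 0 or a saturated correction (p ≥ 3/4) flags omega as undefined; such
  genes are excluded from per-gene ratio averaging but their counts still
  enter pooled tests.

NG86 is deliberately the reference method because every number it produces
can be checked by exhaustive enumeration. Its known limitation is retained,
not patched: with transition/transversion bias (kappa > 1) it undercounts
synonymous opportunity and underestimates omega by roughly 15% at kappa = 2.
The ML estimator is the remedy when that bias matters.

**Pairwise ML.** The two-sequence likelihood under the GY94 codon model
(below) is maximized over divergence t, kappa, and omega with bounded
L-BFGS-B from a deterministic multistart grid (t ∈ {0.01, 0.1, 0.5}).
Ka and Ks are read off the fitted rate matrix by splitting t into
nonsynonymous and synonymous flux per site; A and S counts are the
real-valued products Ka·N-sites and Ks·S-sites.

## The codon model and likelihood engine

The GY94-type model is a 61-state reversible Markov chain: q_ij = π_j ·
kappa^[transition] · omega^[nonsynonymous] for single-nucleotide changes,
zero otherwise, normalized to one expected substitution per codon per time
unit. Codon frequencies π are uniform (the default in tests) or F3x4
(positional nucleotide frequencies with stop codons zeroed and the vector
renormalized) — the choice is a parameter, since transcriptome data rarely
justify richer frequency models. Transition probabilities use the symmetric
eigendecomposition of the reversible generator: one `eigh` per (kappa,
omega) serves every branch length, which makes finite-difference gradients
cheap. Likelihoods are computed by Felsenstein pruning over site patterns
(alignments are compressed to unique codon columns with weights); site-class
models are mixtures Σ_c p_c L_c per site.

**Free-ratio model.** Kappa shared, an independent (t_b, omega_b) per
branch. Branch lengths are initialized from a single-ratio (M0) fit. Per
branch, Ka_b = t_b·ρN_b/(3 f_N) and Ks_b = t_b·ρS_b/(3 f_S), where ρ are
the fitted matrix's nonsynonymous/synonymous rate fractions and f the
site fractions at omega = 1; this decomposition reproduces Ka_b/Ks_b =
omega_b identically. Lineage-level summaries use the median across genes
(robust to the heavy right tail of per-gene ratios); genes whose branch
omega is unidentifiable (Ks ≈ 0, or omega at its upper bound) are dropped.

**Branch-site model A.** Four site classes: (0) omega0 ≤ 1 everywhere,
(1) omega1 = 1 everywhere, (2a/2b) omega0-or-1 on background but omega2 ≥ 1
on the single marked foreground branch, with class-2 proportions tied to the
p0:p1 odds. The null fixes omega2 = 1; the likelihood-ratio statistic
2·(lnL_alt − lnL_null), clamped at zero, is referred to chi-square with one
degree of freedom — conservative relative to the 50:50 boundary mixture.
Fitting is two-stage: kappa and branch lengths come from the M0 fit and are
held fixed, *except* the foreground branch length, which is re-estimated
jointly with the site-class parameters in both null and alternative models
(the M0 fit shrinks the foreground length when selection is present, and
fixing it costs real power). The alternative starts from the null optimum
with a deterministic omega2 multistart {1.5, 5}. A scan over a gene set
applies BH-FDR to the per-gene p-values; PSGs are genes with q below the
cutoff (default 0.05). Genes with fewer than 50 comparable codons are
excluded from the scan — their LRTs are degenerate.

The mixture's time unit is defined by the background class mixture (one
expected substitution per codon under the background regime), so branch
lengths keep a single interpretation across null and alternative fits.

## Category-level acceleration tests

Per-gene estimates for two species pairs (focal-vs-relative and
relative-vs-relative), keyed by a shared ortholog id, are aggregated by
annotation category. Three tests are reported per category:

* **Pooled Fisher**: a 2×2 table of total nonsynonymous (A) and synonymous
  (S) substitution counts per pair; counts are rounded half-away-from-zero
  to integers (exact tests need integers; NG86 path averages and ML expected
  counts are real-valued). Sensitive to rate shifts carried by few genes.
* **Binomial sign test**: counts of genes with the higher omega in each pair,
  ties excluded, exact two-tailed p under p = 1/2. Sensitive only to broad
  shifts across many genes.
* **Wilcoxon signed-rank** on paired per-gene omegas (zero differences and
  undefined omegas dropped; exact null for n ≤ 25, normal approximation with
  continuity correction above).

The three tests answer different questions, which is why a category can have
a tiny Fisher p and a null sign-test p: a handful of fast genes moves pooled
counts but not the gene-count balance. "Average Ka/Ks" is reported both as
the mean of per-gene ratios (default — this is the reading under which
category averages can exceed 1 when a few genes have extreme ratios) and as
the ratio of pooled rates. Categories with fewer than `min_genes` (default
5) genes are dropped. The top decile by mean omega is flagged with a ceiling
rule (⌈0.1·m⌉ categories; ties break by category id). BH-FDR is applied
within each test family separately. Annotations are used as given — GO
ancestor propagation, if wanted, is a pre-processing step.

## Differential expression without replicates

With one library per species, biological variance cannot be estimated, so
the negative-binomial dispersion φ is an explicit a-priori parameter
(default 0.2 — a deliberately conservative value for between-individual
variation; var = μ + φμ², i.e. a biological CV of √0.2 ≈ 0.45). Genes with
CPM below 10 in *any* sample are removed first. The test is the classic
conditional exact test: counts are rescaled to the geometric mean of the two
library sizes (rounding half-to-even), and given the rescaled total the
two-sided p sums the probabilities of all splits no more likely than the
observed one; by the symmetry of the null conditional distribution this is
the doubled smaller tail. At φ = 0 the test reduces exactly to the
conditional binomial (Poisson) test. The implementation agrees with edgeR's
`exactTest` at fixed common dispersion to ~10 significant digits across
count configurations.

A structural consequence worth stating plainly: at φ = 0.2 the dispersion is
an information floor. A perfectly observed 4-fold split has p ≈ 0.04 no
matter how large the counts, so at stringent FDR only near on/off
differences are callable. That is the honest resolution of a no-replicate
design, not a defect of the test. Direction calls (up/down) are made only
below the FDR cutoff (default 0.01); genes significant in the same direction
in two comparisons form the shared up-/down-regulated sets. Optional
median-of-ratios library rescaling is available but off by default.

## Enrichment

Category over-representation within a gene set uses the one-sided
(greater) Fisher exact test against the annotated-gene population, with
BH-FDR; enriched means q < 0.05 and odds > 1. Species content comparison
uses the two-sided test on (species × in/out category) tables with gene
totals as margins, recording which species over-represents each category.

## The simulator

The synthetic-data module is first-class code, not a fixture. Codon
alignments evolve on a tree by exact stochastic simulation — Gillespie jumps
per codon per branch under the same GY94 generator the fits assume — so the
*realized* synonymous/nonsynonymous substitution counts per branch are
recorded as truth, which is what makes counting-method oracles possible.
Branch lengths are expected substitutions per codon under the branch's
site-class-average omega, matching the time unit of the fits. Site classes
are drawn per codon; per-branch omega overrides (scalar, or per-class for
branch-site regimes) implement lineage acceleration and foreground
selection. Stop codons cannot be produced. A single seed drives everything;
per-gene streams are split from it, so gene order does not affect results.

Family sets plant accelerated categories by multiplying the foreground
branch omega for genes in chosen categories. Count matrices are negative
binomial with log-normal baseline means (log-mean 5, log-sd 1 ≈ median 150
counts), library-size scaling, and planted DE genes whose second-sample
mean shifts by the fold change with alternating sign.

What the simulator does *not* emulate: indels and alignment error, assembly
artifacts, within-species polymorphism, expression-level coverage bias, GO
term overlap/hierarchy, and paralogy. Passing tests therefore demonstrate
correctness of the estimators and calibration of the tests under the stated
models, not robustness to the full messiness of transcriptome data.

## Test and calibration sizes

Deterministic oracles run exhaustively (all 61 codons, all 61×61 codon
pairs, brute-force likelihoods on ≤4-tip trees). Stochastic checks use
sizes chosen to keep the suite fast while leaving clear margins: pairwise
recovery at 20 replicates × 5,000 codons; branch-site null calibration at
100 genes × 300 codons and power at 50 replicates × 600 codons on a
four-taxon tree with 0.2-substitutions/codon branches (the regime of
published branch-site power analyses); category recovery at 50 replicates of
200 genes × 500 codons in 20 categories; DGE calibration at 10,000 genes.
The acceptance script reruns the same computations at reduced replicate
counts and reports the measured numbers.

## Known limitations

* NG86 retains its transition/transversion bias by design; use ML when
  kappa is far from 1.
* Branch-site fits hold background branch lengths at their M0 estimates;
  this is the standard two-stage approximation and can cost a little power
  relative to full joint optimization.
* Multi-species codon alignments for k > 2 are built pairwise against a
  reference species and merged, an approximation to a true multiple
  alignment.
* The chi-square(1) reference for the LRT is conservative near the boundary;
  calibration tests verify the type-I rate stays at or below nominal.
* No Bayes empirical Bayes identification of selected sites — the scan says
  *which genes*, not which sites.
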