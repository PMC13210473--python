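# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer from the code.

## Preprocessing of intensity layers

Protein and PTM-site matrices are raw, log-normal-distributed intensities
with missing cells. The chain is:

1. **Filtering.** A feature is kept iff it has ≥ 2 observed values across
   all samples *and* at least one condition group is observed at ≥ 50%
   (inclusive at exactly 50%). Both clauses are evaluated on the raw
   missingness mask; filtering is idempotent.
2. **Imputation.** Missing cells in a group observed at ≥ 50% get that
   feature's group mean; all remaining missing cells get half the global
   minimum observed intensity, a standard stand-in for below-detection
   values. All statistics come from observed values only, computed before
   any fill, so imputed values never feed later imputations.
3. **Normalization and transform.** Each sample column is scaled
   multiplicatively (pre-log) so its median equals the global median of the
   column medians; then log2; then every cell is shifted by
   `10 + |min(log2 matrix)|`. The multiplicative pre-log reading of
   "median normalization" is the common convention for intensity data; a
   subtractive post-log version would differ only by the same column
   constants after the log. The shift applies `|min|` literally even when
   the minimum is positive (giving `2·min + 10` in that corner), keeping
   the transform a fixed formula rather than a conditional.

RNA enters as TPM and is not normalized here (upstream TPM is already
library-size scaled); all RNA log work uses `log2(TPM + 1)` so that one
pseudocount convention holds across contrasts and PTR.

## Differential testing

Per-feature tests are Welch two-sample *t*-tests on log2-scale values.
This is a deliberate, documented stand-in for count-based RNA models
(negative-binomial machinery is out of scope; the analysis of interest is
downstream of DE calling) and for vendor DIA statistics. Degenerate
features with zero variance in both groups get *p* = 1 when the means
coincide and *p* → 0 otherwise — the limit of the Welch statistic as
replicate scatter vanishes, needed so that noise-free data behave sanely.

Benjamini–Hochberg adjustment is the classic step-up with monotonicity
enforcement, order-preserving. Significance policies are per layer:
RNA |log2FC| > 1.5 with adjusted *p* < 0.01; protein and PTM layers
|log2FC| > 1.2 with raw *p* < 0.05. RNA uses the adjusted *p* and protein
the raw *p* deliberately — the two layers' conventions differ in the
design this mirrors — and both cutoffs are plain parameters
(`ThresholdPolicy`) for users who want symmetric rules.

## Temporal clustering

Features are reduced to condition-mean trajectories (CK, DT, DTR), z-scored
per feature with the population SD (the Mfuzz convention); flat profiles
are excluded. Fuzzy c-means uses the Bezdek alternating updates with
Euclidean distance, fuzzifier m = 1.25 (a standard choice for short, highly
standardized profiles; larger m washes memberships out at dimension 3),
c = 5 clusters, tolerance 1e-6 on centroid movement. Initialization is
k-means++ seeding with 5 restarts, keeping the lowest objective
`sum(u^m d^2)`; with random-membership initialization the 5-archetype
benchmark converged to merged-cluster local optima in a substantial
fraction of seeds, and seeded restarts removed that failure mode. Runs are
deterministic given a seed. Cluster labels are arbitrary, so clusters are
matched to named archetype shapes (up-recover, up-persist, down-recover,
down-persist, late-up) by nearest standardized centroid when identity
matters; recovery tests allow label permutation.

Cluster-pair overlap between an RNA cluster and a protein cluster counts
shared genes (protein ids resolved through the id map) and reports the
count as a percentage of each cluster, rounded to two decimals.

## PTR, MAD, stratification

`PTR = log2(protein abundance) − log2(TPM + 1)` per gene and condition,
where "protein abundance" is the preprocessed (already log2-scale)
intensity used directly — re-logging a logged value would be dimensionally
wrong. PTR is computed on condition means, not per replicate. Dispersion
uses the unscaled MAD, `median(|x_i − median(x)|)`, with no 1.4826
consistency factor: the quantity is a descriptive spread, not a robust SD
estimate. High-PTR genes exceed `median + 2·MAD`; low-PTR genes are the
lowest quartile, `floor(0.25·n)` genes with ties broken by gene id for
reproducibility. Cross-condition comparison is a Kruskal–Wallis rank test
with tie correction (all-identical input returns H = 0, p = 1 rather than
an undefined statistic).

## Discordance classification

For each gene–protein pair and contrast, with ΔRNA and ΔProtein the layer
log2 fold changes and layer significance defined by the threshold policies:

1. either layer unquantified → `NA`;
2. strictly opposite signs and ≥ 1 layer significant → `inconsistent`;
3. |ΔProtein| ≥ 2|ΔRNA| and protein significant → `translation_dominant`;
4. |ΔRNA| ≥ 2|ΔProtein| and RNA significant → `transcription_dominant`;
5. otherwise `stable`.

Opposite-signed pairs are evaluated before dominance so that the headline
discordance class is never absorbed by a magnitude rule; a zero delta has
no sign and cannot make a pair inconsistent. The share of inconsistent
pairs is reported under two denominators (all quantified pairs, and only
the three changed categories) because the appropriate denominator depends
on the question asked.

## Residual regression and PTM correlation

Per contrast, `ΔProtein = β0 + β1·ΔRNA + ε` is fit by OLS with intercept
over *all* quantified pairs (not only significant ones); residuals then
measure protein change unexplained by RNA change. Site-level analysis
pairs every PTM site's ΔPTM with its gene's residual — residuals are
duplicated across a gene's sites, unweighted. Protein-level analysis first
collapses each protein's sites of one modification type to their median
(`dPTM_pro`). Both use Spearman correlation with average-rank ties; the
two-sided p-value uses the *t* approximation for n > 10 and the exact
permutation distribution (all n! pairings) for n ≤ 10, where the
approximation is unreliable. Reports with n < 3 carry an undefined ρ.

## Physiology utilities

Group means of gas-exchange metrics (net photosynthesis Pn,
μmol CO₂ m⁻² s⁻¹; stomatal conductance Gs, mol m⁻² s⁻¹; leaf water
potential, MPa) reduce to `percent_of_control` (one decimal) and
`percent_reduction` (nearest integer); the two sum to 100 before rounding.
The rounding conventions match how such recovery figures are customarily
quoted.

## Synthetic data generator

The generator emulates a 3-condition × 3-replicate design with ~70% of
genes detected at the protein level, ~40% of detected proteins carrying
phospho sites and ~40% acetyl sites, and a site-multiplicity distribution
(46% single-site, 21% two-site, tail to six) matching typical plant
phosphoproteome surveys.

Per gene and contrast a target category is drawn (defaults 43%
transcription-dominant, 13% translation-dominant, 32% inconsistent, 12%
stable, the quantified-pair composition of a drought time-course), and
(ΔRNA, ΔProtein) are drawn to realize it: stable genes follow the global
linear coupling `ΔProtein = β0 + β1·ΔRNA` (defaults 0, 0.4) with small
ΔRNA; dominant and inconsistent genes use structured draws that keep every
delta at least ~0.27 log2 units away from the nearest decision boundary
(fold-change cuts, the 2× ratio, the zero crossing). That margin exists
because per-sample median normalization of the protein matrix introduces a
small global shift on measured ΔProtein — the column medians react to the
asymmetry of regulation and to median sampling noise of the base-intensity
distribution (SD 1.2 → shift SD ≈ 0.07 at ~700 proteins) — and noise-free
category recovery must be exact despite it. PTM effects add
`γ_phos·dPTM_pro + γ_acet·dPTM_pro` to carrier genes' ΔProtein, where
`dPTM_pro` is the median of the protein's true site deltas (drawn i.i.d.
N(0, 1) per site and contrast) — the same aggregation the analysis uses, so
protein-level recovery is exact by construction. Ground-truth categories
are recomputed from the *final* deltas, so they stay consistent with the
classification rules whatever the PTM terms do.

RNA trajectories are built on the log2(TPM + 1) scale (baseline U(8, 13))
and exponentiated to TPM; protein and site intensities are log-normal
(log2 baselines N(17, 1.2) and N(15, 1.5)) with replicate noise on the log
scale (defaults σ 0.15/0.2/0.25 for RNA/protein/PTM). Missingness applies
to intensity layers only: MCAR at rate 0.02 plus an MNAR logistic dropout
in log2 intensity (midpoint 13, slope 1; slope 0 disables the mechanism
entirely rather than meaning a flat 50%). Each layer has its own RNG
stream spawned from the master seed, so changing PTM parameters never
perturbs the RNA or protein draws.

What the generator does **not** emulate: detection bias toward
high-abundance proteins (detection is a uniform subsample; an expression-
coupled version was considered and left out as the simplest mechanism
suffices for layer-attrition behavior), condition-dependent detection,
count noise in RNA (TPM is treated as a continuous abundance), correlated
site effects within a protein beyond the shared protein effect, batch
structure, and interference between modification types. Passing tests
therefore demonstrate correctness of the analysis machinery under a clean
generative model, not robustness to those real-data complications.

## Verification strategy and problem sizes

Every nontrivial primitive is checked against an independent oracle: MAD
against a sort-based double-median, Spearman against rank-then-Pearson and
scipy (and, at small n, scipy's exact pairing permutation test), BH against
statsmodels, the filter rules against exhaustive enumeration of all 2⁹
presence masks on a 3×3-group design, set overlaps against brute-force
membership enumeration. End-to-end checks run the full pipeline on
generated data: noise-free runs must reproduce truth categories
gene-for-gene; an injected unit phospho effect (γ_phos = 1, σ_prot = 0.2,
~2100 phospho sites from 3400 genes) must give a positive site-level ρ
within 0.1 of the same correlation computed directly on the truth table;
slope recovery uses 20 replicate datasets of 1000 all-stable genes with
β1 = 1.2 and replicate noise 0.1; clustering recovery uses 2000 archetype
profiles at noise 0.1; null calibration runs 1000 effect-free simulations
(80 genes each, multiplicity-distributed sites) and expects 4–6% rejection
at α = 0.05. These sizes keep the whole suite under a minute while leaving
the statistical margins comfortable.

Known quantitative caveat: with measurement noise on, the pipeline's
site-level ρ sits systematically ~0.05–0.1 *below* the truth-table ρ
(regression dilution: noisy ΔPTM and residual estimates attenuate rank
correlation), so the gap to the truth-table computation hovers near its
0.1 allowance depending on seed; the effect direction is always preserved.

## Limitations

* The Welch-on-log2 stand-in ignores RNA count overdispersion structure;
  with 3 replicates its power differs from negative-binomial tests, so
  absolute DEG counts on real data will differ from count-model pipelines.
* Median normalization assumes most features are unchanged; under heavy
  asymmetric regulation it biases fold changes by a small global constant
  (quantified above). A spike-in or quantile scheme would be needed for
  strongly asymmetric designs.
* Residual–ΔPTM correlation is associational; no causal ordering between
  PTM change and protein-abundance change is implied or recoverable here.
* The exact permutation p-value is O(n!) and intended only for the n ≤ 10
  fallback where it is fast enough (worst case a few seconds at n = 10).
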