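# Methods

This note documents the models implemented in `ucquant`, the choices made
where the methodology was genuinely open, and what the synthetic-data tests
do and do not establish about real cohorts.

## Data model and conventions

All bulk analyses operate on gene × sample matrices of log2-scale
expression (normalized microarray or log-transformed RNA-seq). A config
flag (`log2_input: false`) applies log2(x+1) on load for linear-scale
input. Rows with any missing value are dropped at load (not imputed) and
counted; duplicate gene rows (multi-probe genes) are collapsed by mean.
Sample annotations carry `group` (case/control), and optionally `stage`
and `cohort`. Every module draws randomness from a named substream of the
single run seed, so any stage reproduces in isolation, and all written
tables carry a config-hash/seed comment header.

## Differential expression

Per-gene Welch two-sample *t* on log2 values. Direction calls use the
classical raw-*P* < 0.05 together with |log2FC| > 1 (both strict); a
Benjamini–Hochberg FDR column is always reported alongside. A Welch test
stands in for a moderated *t*: at the sample sizes this pipeline targets
(tens per group) the moderation of gene-wise variances changes calls only
marginally, and the stage stays self-contained. Genes constant in both
groups have an undefined *t* and are called `ns` with a warning.

## Global divergence

RMSD(x, y) = √(mean((log2 x − log2 y)²)) over shared genes — a Euclidean
distance scaled by 1/√n, hence comparable across panels of different
sizes. It is a pseudometric (symmetry, identity, triangle inequality are
property-tested). The pairwise summary bins all unordered sample pairs
into case↔control, within-case and within-control distributions.

## Co-expression modules

Unsigned WGCNA-style pipeline on the `top_n_variable` (default 5000) genes
by SD: adjacency |r|^β with β = 14 by default (a scale-free-fit R² sweep
is available as a diagnostic but β is always taken from config, never
auto-selected), unsigned TOM, average-linkage clustering of 1−TOM.
Because the full dynamic tree cut algorithm is out of scope, the dendrogram
is cut at a static height (default 0.995 on the 1−TOM scale); clusters
below `min_module_size` (default 50) stay unassigned. At β = 14 noise
gene pairs have TOM ≈ 0 (distance ≈ 1, above the cut) while genuinely
co-expressed blocks sit well below it, so the static cut cleanly isolates
planted blocks in testing; on real data the cut height is the parameter to
tune first. Module eigengenes are first principal components of
standardized module expression, unit variance, sign-oriented to correlate
positively with the module's mean profile (the sign is otherwise
arbitrary). Modules whose eigengenes correlate above 1 − `merge_cut_height`
(default 0.25) are merged iteratively, largest label kept. Outlier samples
(mean inter-sample correlation more than 3 SD below the cohort mean) are
excluded before network construction and logged. Gene significance is
|cor(gene, trait)| and module membership |cor(gene, eigengene)|. The
signature pool is the intersection of the most trait-correlated module
with the DEG calls, directions inherited from the sign of log2FC.

## Learner benchmark and RF-RFE

All learners are scored on one materialized repeated-stratified-K-fold
plan, so metric differences cannot come from resampling. Metrics per
fold: recall, precision, F1, accuracy at the 0.5 probability cut; C-index
as the ROC AUC of ranked probabilities (the binary-outcome equivalence;
a constant ranking scores 0.5 by convention); RMSR = √(mean((p − y)²)) on
predicted probabilities vs 0/1 labels (the residual is not otherwise
defined for classification). A learner failing a fold is recorded and
flagged; failing all folds is an error.

RF-RFE: inside each CV fold a 250-tree forest ranks genes by mean decrease
in Gini; forests refit on the top-k for each candidate size give the
held-out error curve; the optimum is the argmin with ties broken to the
smallest size (parsimony). The reported panel is the top `panel_size`
(default 12) genes by Gini importance of a forest on the full training
set — deliberately decoupled from the CV optimum, which is reported as a
diagnostic: the two answer different questions (how many genes are needed
vs which fixed-size panel to carry forward). Mean decrease in accuracy is
computed by permutation importance on the full fit.

## Feature score and the diagnostic network

Encoding: per gene, the cohort median of its expression; an up-regulated
gene strictly above its median encodes 1 (else 0), a down-regulated gene
strictly above encodes 0 (else 1). Ties at the median count as "not
above" (the strict-`>` rule); the encoding therefore depends only on
within-gene ranks and is invariant under any strictly increasing per-gene
transform — this is what lets one fixed network transfer across
platforms. The per-gene (not per-sample) median reading is implemented;
external cohorts are always encoded against **their own** medians, since
absolute medians are incomparable across platforms.

The classifier is a fully connected [panel → 10 → 6 → 1] network with
logistic activations everywhere, trained by full-batch gradient descent on
mean cross-entropy (default 2000 epochs, learning rate 0.5, weights
initialized N(0, 0.5²) from the seed). The loss curve is recorded and
must stay non-increasing within tolerance; training is deterministic given
the seed and the model serializes to JSON (architecture, weights, medians,
panel) with bit-stable re-scoring. Confusion metrics use the 0.5
threshold; AUC is rank-based with a percentile-bootstrap CI (default 200
resamples). Single-class cohorts report NA for the undefined rate with a
warning.

## UCRScore

Bray–Curtis needs non-negative input; log2 matrices containing negative
values are shifted by their global minimum (logged) rather than
exponentiated, which preserves the geometry of differences while keeping
BC within [0, 1]. Pairs with zero combined abundance are defined as
dissimilarity 0 with a warning. PCoA is classical scaling: Gower-centered
−½ J D² J, eigendecomposition, coordinates scaled by √λ for positive
eigenvalues; negative-eigenvalue mass is reported, not silently dropped.

The score is PCoA1 + PCoA2 (`sum_axes`, the default), with each axis's
sign oriented to correlate positively with summed panel up-gene
expression, so "High" is reproducibly the disease-like stratum; a
`weighted` variant multiplies the axis sum by total panel expression for
users who prefer the literal multiplicative formula. Samples split at the
median score (ties broken by rank so strata differ by at most one).

ANOSIM uses the rank contrast R = (mean between − mean within) / (M/2);
PERMANOVA uses Anderson's partition of squared dissimilarities into
within/between-group sums. Both compute permutation *P*-values as
(1 + #{stat_perm ≥ stat_obs}) / (n_perm + 1) with label permutations
vectorized over the condensed pair index, which keeps 500-replicate
calibration runs inside seconds. PERMANOVA is implemented as one-factor
on group; a second crossed factor was not added because no second factor
is defined for the designs the pipeline targets.

Gene-set activity is the rank-recovery AUC: genes ranked descending per
column (stable tie-break by input gene order), recovery curve of set genes
among the top k for k up to ⌈top_fraction × n_genes⌉ (default window 5%),
area normalized by the maximum achievable area, so 1.0 requires all set
genes to outrank everything else inside the window. Per-cell panel
scoring is offered both as mean panel expression and as this AUC; both
orderings agree strongly on the synthetic fixtures and the choice is left
to the caller.

## Regulatory network

Dimension filters (all strict): TFs |logFC| > 0.5, hallmark and cell
components |t| > 2, pathway and reaction components |t| > 5, each at
FDR < 0.01. Component activities are per-sample gene-set activity scores
(above) or direct TF expression; dysregulation statistics are Welch *t*
with BH-FDR across each dimension. Correlation per (panel gene,
component) pair: Shapiro–Wilk at α = 0.05 on both vectors chooses Pearson
(both normal) or Spearman; edges require |r| ≥ 0.5 and raw *P* < 0.001.
The magnitude threshold is implemented as ≥ (the "prominent correlation"
reading); a literal `<` variant sits behind a flag. Raw *P* matches the
filter definition; a BH-adjusted mode is available and logged. Constant
vectors are skipped with warnings; the edge contract is asserted on
output.

## XSum drug reversion

Profiles are truncated to the `extreme_n` highest and lowest values
(default 500 — a conventional choice; the method is insensitive to it as
long as planted effects exceed the extreme threshold), everything else
treated as 0, ties at a cut resolved first-in-gene-order. The score is
sum_up − sum_down: although the formula is often printed as a plain sum,
only the difference form makes strongly negative scores mean reversal
(up-genes repressed *and* down-genes induced), which is the interpretation
the ranking relies on; the literal `+` variant is available behind a flag.
Significance is one-sided toward reversal from size-matched random
gene-label signatures, p = (1 + #{null ≤ obs}) / (n_perm + 1); drugs are
ranked ascending by score so rank 1 is the strongest reverser.

## DNB criticality

CI = SD_in · PCC_in / (PCC_out + ε) with ε = 1e−6 guarding the quotient;
the quotient form is the canonical combination of the three criticality
criteria (variance inflation, internal correlation rise, external
correlation collapse). SD uses ddof = 1; correlation terms exclude
constant genes with a warning. Candidate modules come from average-linkage
clustering of 1 − |r| within each stage, cut at distance 0.7 and filtered
to `min_size` (default 10); when no cluster survives (pure noise), a
fixed-count cut supplies candidates so null calibration still produces a
CI landscape. Every candidate is evaluated at every stage; the DNB is the
global CI argmax and its argmax stage the predicted critical point. The
per-stage DNB score is the mean CI of the top decile of candidates (an
interpretation — the aggregate is not otherwise pinned down), and the MCI
of a user-supplied panel is its CI trajectory across stages. Stages are
independent cross-sections; stages with fewer than 3 samples are skipped.

## Synthetic cohorts: what they emulate and what they do not

The generator produces log2-scale Gaussian cohorts (baseline means
log-normal, per-gene noise SD 0.5) because the emulated data are
normalized arrays, already continuous. Defaults: 40 cases / 40 controls,
30 up + 30 down planted genes at mean log2FC 2 — the effect size of
top disease markers in inflamed-vs-healthy mucosa comparisons, giving the
feature selector and classifier a realistic but not trivial target.
Co-expression blocks share a latent factor with loading √ρ; batch effects
are additive per cohort (SD 0.2 by default — small, since batch
correction proper is out of scope). The stage series plants a 20-gene
group at the middle ("Inactive") stage with SD × 3, internal correlation
0.8 and external correlation shrunk to 0.05; the drug library plants one
perfect reverser and one mimic at strength 3 over unit noise; the cell
matrix is dropout-thinned log-normal with a boosted panel in 30% of cells.
Truth records (planted genes, stages, drugs, cells) are first-class
outputs, so tests never re-derive ground truth.

These fixtures have independent Gaussian noise, no probe-level artifacts,
no library-size or dropout structure beyond Bernoulli thinning, and
planted effects that are homogeneous within the case group. Passing tests
therefore establish correctness and calibration of the *methods* — type-I
error of the permutation tests, recovery of planted structure at stated
effect sizes, exactness of the worked-example arithmetic — not performance
on real cohorts, where batch structure, outliers and heterogeneous effect
sizes will dominate.

Test and example problem sizes (hundreds of genes, tens of samples, 20-seed
replicate sweeps) are deliberate scale-downs of the config defaults
(5000-gene module detection, 10×100 CV); the statistical structure, not
the volume, is what the assertions exercise, and the full-scale settings
remain available in `RunConfig`.

## Known limitations

- The static dendrogram cut is cruder than dynamic tree cutting; very
  unequal module densities on real data will need `cut_height` tuning.
- PLS enters the learner roster through a regression-on-labels wrapper
  with clipped probabilities; its RMSR is not comparable to genuinely
  probabilistic learners.
- PERMANOVA is one-factor; crossed/nested designs are out of scope.
- The diagnostic network has no regularization or early stopping; with
  ~12 binary inputs and 80 training samples overfitting is mild, but the
  epochs/learning-rate defaults are not tuned for larger panels.
- Bray–Curtis on min-shifted log2 data is a pragmatic convention; results
  are not invariant to the shift, and callers wanting abundance semantics
  should pass linear-scale data.
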