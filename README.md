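# ucquant

A quantification toolkit for ulcerative-colitis (UC) transcriptomics —
and, more generally, for any two-group disease-vs-control expression study
that wants to go from a raw gene-by-sample matrix to (1) a compact
diagnostic gene signature, (2) a trained diagnostic classifier, (3) an
unsupervised per-sample disease score with biological interpretability,
(4) a regulatory landscape around the signature, (5) drug-repurposing
candidates that reverse the signature, and (6) an early-warning analysis of
the disease's critical transition stage.

It is written for computational biologists who work in Python on bulk
microarray/RNA-seq cohorts (log2 scale) and single-cell matrices. Every
stage is exercisable end-to-end on synthetic cohorts generated by the
package itself, with planted ground truth, so the statistical behaviour of
the whole pipeline is testable without any data download.

## What it computes

**Signature discovery.** Per-gene Welch tests call DEGs at raw *P* < 0.05
and |log2FC| > 1. A lightweight weighted co-expression network
(adjacency *a<sub>ij</sub>* = |cor(*g<sub>i</sub>*, *g<sub>j</sub>*)|<sup>β</sup>, β = 14,
smoothed into the topological overlap matrix
TOM<sub>ij</sub> = (Σ<sub>u</sub> *a<sub>iu</sub>a<sub>uj</sub>* + *a<sub>ij</sub>*) / (min(*k<sub>i</sub>*, *k<sub>j</sub>*) + 1 − *a<sub>ij</sub>*))
clusters genes into modules; the module most correlated with disease,
intersected with the DEG calls, is the dysregulated signature pool.
Global expression divergence between two profiles is
RMSD = √(Σ<sub>i</sub> (log2 x<sub>i</sub> − log2 y<sub>i</sub>)² / n).

**Panel selection.** Eight classical learners (neural net, random forest,
boosted GLM, elastic net, bagged CART, GLM, PLS, CART) are benchmarked
under repeated stratified cross-validation on one shared fold plan
(recall, precision, F1, accuracy, C-index, RMSR). The final panel comes
from random-forest recursive feature elimination: forests of 250 trees
rank genes by mean decrease in Gini, refits on top-*k* subsets trace the
CV error curve, and the top 12 genes by full-train importance form the
directional panel.

**Diagnostic model.** Panel expression is binarized into a *feature
score* against each gene's cohort median — up-regulated gene above its
median → 1 (else 0), down-regulated gene above its median → 0 (else 1) —
and a feed-forward logistic network with hidden layers of 10 and 6 units
is trained by backpropagation on cross-entropy. External cohorts are
encoded against their own medians and reported with the full confusion
suite (sensitivity, specificity, accuracy, Cohen's κ, precision, recall,
F1, bootstrap-CI AUC).

**UCRScore.** Bray–Curtis dissimilarities BC(a, b) = Σ|a−b| / Σ(a+b) over
panel expression are embedded by principal coordinates analysis (Gower
double-centering); the per-sample score is PCoA1 + PCoA2 with axis signs
oriented so high = disease-like, and samples split High/Low at the median.
ANOSIM and PERMANOVA (with vectorized label permutation) test the group
structure. The same module provides AUCell-style rank-recovery AUC
scoring of gene sets for bulk samples and single cells.

**Regulatory landscape.** Transcription factors (|logFC| > 0.5), hallmark
and cell components (|t| > 2), pathway and reaction components (|t| > 5),
all at FDR < 0.01, are correlated against panel genes — Pearson when both
vectors pass Shapiro–Wilk normality, Spearman otherwise — and edges with
|r| ≥ 0.5 and *P* < 0.001 form the network.

**Drug reversion.** Drug profiles truncated to their extreme values are
scored by XSum = sum<sub>up</sub> − sum<sub>down</sub> over the disease
signature; strongly negative scores mark reversal candidates, with
significance from size-matched random-signature randomization and drugs
ranked ascending by score.

**Critical transition.** For gene modules across ordered disease stages,
the composite index CI = SD<sub>in</sub> · PCC<sub>in</sub> / PCC<sub>out</sub>
quantifies dynamic-network-biomarker criticality; the stage where CI peaks
is the predicted pre-disease tipping point, and a fixed panel's CI
trajectory is its module criticality index (MCI).

## Worked example

`examples/04_disease_score.py` simulates one 40-case/40-control cohort with
60 planted marker genes, scores it, and prints:

```
ANOSIM R = 1.000 (p = 0.001); PERMANOVA pseudo-F = 459.6 (p = 0.001)
PCoA1/PCoA2 explain 85.6% / 0.6% of positive inertia
group    case  control
stratum
High       40        0
Low         0       40
94 cells flagged panel-active at AUC threshold 0.15 (planted: 90)
```

Read: the Bray–Curtis geometry of panel expression separates cases from
controls perfectly (ANOSIM R = 1 means every between-group dissimilarity
exceeds every within-group one), the first coordinate carries almost all
the structure, and the median split of the score recovers the case/control
partition exactly. On the single-cell matrix, thresholding the panel's
rank-AUC flags 94 cells of which the 90 planted active cells are the core.

The other examples cover signature discovery (`01`), learner benchmarking
and RF-RFE (`02`), the diagnostic network and external validation (`03`),
the regulatory network and drug-reversion ranking (`05`), and the
three-stage DNB analysis (`06`); each prints the quantities it computes
and a one-line interpretation.

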