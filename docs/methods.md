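# Methods

This note records the model assumptions, parameter choices, and numerical
decisions behind `mcicps`, and what the synthetic validation does and does
not establish about real cohort data.

## Pipeline model and assumptions

The pipeline assumes three aligned feature blocks per patient — additive
genotype codes (0/1/2 minor-allele counts), continuous expression values,
and ROI volumes in mL with a per-patient intracranial volume (ICV) — and a
binary three-year conversion outcome (S-MCI = 0, P-MCI = 1).  Molecular
subtype structure is assumed to live in the genotype and expression layers
only; those two layers drive subtyping, while all three layers contribute
conversion-predictive features.  Every fitted statistic (QC decisions,
imputation means, ICV slopes, z-scoring parameters, selection counts,
kernel bandwidths, classifier posteriors) is computed from training data
and applied unchanged to test data; cross-validation re-fits the entire
pipeline, including subtyping, inside each training fold and assigns
test-fold patients by label propagation.

### Genotype QC

Filters are applied in order missing rate → MAF → HWE with strict
inequalities (drop iff missing rate > 0.05, MAF < 0.05, HWE p < 10⁻³),
each computed on non-missing calls.  The HWE test is the 1-df χ² of
observed genotype counts against expectation at the observed allele
frequency, without continuity correction — chosen for transparency over an
exact test; at the 10⁻³ threshold and the cohort sizes involved the
difference is immaterial.  Missing calls surviving QC are mean-imputed per
feature on training data; reference-panel genotype imputation is outside
this package's scope.

### ICV adjustment

`ROI_adj,i = ROI_raw,i − θ_i (ICV − ICV_mean)` removes only the slope
component about the training-mean ICV; the intercept is retained so ROIs
keep their natural volume scale.  On the training set this makes each
adjusted ROI numerically orthogonal to ICV (OLS residual orthogonality).
Adjustment precedes z-scoring — the regression is meaningful on raw
volumes, not on standardized ones.

### SNF and spectral subtyping

Affinities use the scaled exponential kernel
`W(i,j) = exp(−d²(i,j) / (μ ε_ij))` with
`ε_ij = (m_i + m_j + d_ij)/3`, where `m_i` is sample i's mean distance to
its K nearest neighbors.  Defaults K = 20 (capped at N/3), μ = 0.5,
T = 20 fusion iterations — the commonly recommended ranges for this
kernel; per-iteration change norms are kept as a convergence diagnostic
and decrease after a short burn-in.  Euclidean distance is used for all
layers by default; a χ² distance is available for genotype codes.  The
fused network is cut by the RatioCut relaxation (unnormalized Laplacian,
C = 2 eigenvectors, k-means with 20 restarts at a fixed seed).  C is fixed
at 2 by default; the assignment carries the low end of the Laplacian
spectrum so an eigengap can be inspected, but it is not used to pick C.

Label propagation builds a joint fused network over train + new samples
from the subtyping layers and iterates `F ← α P F + (1 − α) Y` with
training rows clamped to their one-hot labels (α = 0.99, tolerance 1e-6,
max 1000 iterations); the joint-graph clamped iteration is our choice
among the propagation variants in the literature.

### Stability Lasso with EDPP screening

The penalty range "0.05 < λ < 0.5" is read as *fractions of λ_max* (the
convention of safe-screening toolkits), discretized to 10 evenly spaced
fractions; each inner run draws one fraction uniformly from that grid
(one draw per run, rather than sweeping the grid within a run).  Each
inner run keeps all minority-class samples plus an equal-size random
majority draw, re-standardizes the subdesign, centers the 0/1 response,
and solves the Lasso by cyclic coordinate descent with covariance updates
(numba-compiled) to a KKT residual ≤ 1e-8 (1e-10 where tests require
exactness).  EDPP screening from the zero solution at λ_max discards
features provably zero at the drawn λ; the screened and unscreened
solutions agree coefficientwise — this dual-route equality is the module's
central test, with scikit-learn's coordinate descent as an additional
independent oracle.  Counts accumulate over all outer × inner runs
(default 50 × 1000; the outer layer re-seeds the undersampler), and
"selected" means a nonzero coefficient, with no magnitude threshold.
Ranking ties break by higher mean |coefficient| across runs, then
lexicographic feature id.  The search for the optimal per-modality feature
count (n = 1…100, classifier AUC under five-fold CV with rankings refit
inside folds) is provided as `choose_n_features`; the training pipeline
itself uses a fixed per-modality n (default 20) so that its cost is
predictable — the search is expensive and is left as an explicit,
user-invoked step.

### VBpMKL classifier

Multinomial probit with auxiliary variables: `y_n = W k_n + ε`,
`t_n = argmax_c y_nc`, Gaussian prior on each class row of W with
precision φ = 1, and a factorized posterior Q(W)Q(Y).  The Q(W) update has
a shared covariance `(φI + KKᵀ)⁻¹` that does not depend on E[Y]; its
Cholesky factor is computed once per kernel configuration, so VB
iterations cost O(N²C).  Truncated-Gaussian moments and the posterior
predictive both reduce to 1-D standard-normal integrals, evaluated by
64-node Gauss–Hermite quadrature; in the binary case the predictive
collapses to `Φ((w₁−w₂)k/√2)`, which the quadrature matches to well below
1e-6.  A jitter of 1e-8 stabilizes the kernel system; predictive rows are
renormalized to sum to one; argmax ties resolve to the lower class index.

**Convergence.**  The iteration stops when either the largest change in
E[Y] or the largest change in the training class probabilities falls below
1e-5 (max 5000 iterations).  The dual criterion matters: on separable
data the auxiliary means grow without bound (the probit analogue of
divergent logistic weights) while the predicted probabilities saturate, so
a criterion on E[Y] alone would never fire there even though the fit is
complete.  On overlapping data — the realistic regime — E[Y] itself
converges and the two criteria agree.

**Kernel weights β.**  Default is the mean composite kernel, β_m = 1/M
fixed.  An optional relevance update (`update_beta=True`) sets β to the
softmax of each kernel's Gaussian log marginal likelihood of the current
E[Y] (`E[Y]_c ∼ N(0, K_m K_mᵀ/φ + I)`) — the posterior over kernels under
a flat prior.  The evidence form was chosen deliberately: reweighting by
raw residual fit lets a near-identity noise kernel "memorize" the labels,
whereas the marginal likelihood charges it an Occam penalty, which is what
makes the informative-modality ranking reliable.

### Evaluation

AUC uses the Mann–Whitney rank statistic with midrank tie correction
(equal to trapezoidal ROC integration; asserted against scikit-learn).
Sensitivity is TP/(TP+FN) on the P-MCI class, the decision threshold
τ = 0.5 with ties called P-MCI.  Gini importance fits a 500-tree random
forest (Gini criterion, √p features per split) over 10 seeds and averages
the mean decrease in impurity; the model behind the importance is our
interpretation, as any impurity-based importance requires a tree ensemble.

## Synthetic cohort generator

The generator is the package's ground-truth instrument.  Defaults: 150
training and 100 test patients; 100 SNPs / 100 genes / 60 ROIs; two
equiprobable subtypes expressed as an allele-frequency shift of ±0.15 on
40 SNPs and a ±1 SD mean shift on 30 genes; conversion rates 0.45
(subtype 1) and 0.33 (subtype 2), echoing a worse-prognosis subtype and an
overall rate near 40%, typical of three-year MCI follow-up; 10
conversion-informative features per subtype per modality, disjoint between
subtypes within each modality and disjoint from the subtype-informative
sets; converter shifts of 1 SD (for SNPs implemented as the
allele-frequency change that moves the genotype mean by one genotype SD);
ICV ∼ N(1500, 120²) mL with per-ROI confounding slopes drawn from
U(0.002, 0.02) mL/mL; 2% missing genotype calls.  Conversion signal is
injected additively after the label draw so per-feature effect sizes are
exactly known.  One root seed drives hierarchical substreams per stage.

What the generator does *not* emulate: linkage disequilibrium and
population structure, probe-level microarray noise, spatial correlation
among ROI volumes, label noise in the three-year outcome, and batch
effects.  Passing tests therefore establish that the implementation
recovers planted structure under idealized conditions — near-ceiling AUCs
on the synthetic cohort say nothing about achievable accuracy on real
cohorts, where effect sizes are far smaller and correlated.  The relative
comparison (subtype-aware vs pooled) is the meaningful synthetic readout,
not the absolute AUC level.

## Problem sizes in tests and the acceptance script

The repeated-selection depth used in the end-to-end checks is 50 inner ×
20 outer runs (1000 per modality), a scaled-down version of the 1000 × 50
default that leaves the selection ranking stable on the synthetic effect
sizes while keeping the full 20-seed paired comparison fast.  The
acceptance script runs one seeded draw of the full study (150/100) plus
20 screening instances and 200 quadrature points.

## Known limitations

* Subtype labels across CV folds are not canonically matched; per-subtype
  breakdowns within a fold are consistent, but subtype "1" in one fold may
  correspond to subtype "2" in another.
* The λ-fraction reading of the penalty range is a convention choice; a
  cohort with a very different λ_max scale would shift which absolute
  penalties are visited.
* Mean imputation understates genotype uncertainty relative to
  reference-panel imputation.
* `choose_n_features` is quadratic in (folds × grid) classifier fits and
  is intended for offline use, not inside the default training path.
* With `update_beta=True` the evidence softmax tends toward sparse β; this
  is the desired behavior for relevance ranking but differs from the
  fixed mean-kernel combination used for the headline pipeline.
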