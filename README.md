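# mcicps — subtype-aware prediction of MCI-to-AD conversion

Not every patient with mild cognitive impairment (MCI) develops Alzheimer's
disease (AD): roughly one in ten converts per year, and the underlying
biology is heterogeneous.  `mcicps` implements a subtyping-based prediction
strategy for the three-year MCI→AD conversion question: patients are first
clustered into molecular subtypes from blood-derived omics, and a separate
classifier is then trained for each subtype, on the premise that
conversion-relevant features differ between subtypes and a pooled model
dilutes them.

The package is aimed at researchers working with multi-modal cohort data —
genotype (SNP) matrices, peripheral-blood gene expression, and structural
MRI region-of-interest (ROI) volumes — who want a reproducible,
leakage-free implementation of the full pipeline plus a synthetic cohort
generator with planted ground truth for validating every stage.

## The method

1. **Preprocessing.** SNPs are filtered by missing rate > 0.05, minor
   allele frequency < 0.05, and Hardy–Weinberg equilibrium p < 10⁻³
   (1-df χ² test); remaining missing calls are mean-imputed on training
   data.  ROI volumes are adjusted for head size by removing the ICV slope,
   `ROI_adj,i = ROI_raw,i − θ_i (ICV − ICV_mean)`, with θ_i the OLS slope of
   ROI i on ICV over the training samples; all features are then z-scored
   with training parameters.
2. **Subtyping.** Per-modality patient similarity networks (scaled
   exponential kernel) on the SNP and expression layers are merged by
   similarity network fusion (SNF) — an iterative cross-diffusion in which
   each network's K-nearest-neighbor kernel passes messages through the
   average of the others.  The fused network is cut into C = 2 subtypes by
   the RatioCut spectral relaxation (eigenvectors of the unnormalized
   Laplacian, then k-means).  New patients are subtyped by clamped label
   propagation, `F ← α P F + (1 − α) Y`, on a joint fused graph.
3. **Feature selection.** Per modality and per subtype, the Lasso
   `min ½‖Ax − y‖² + λ‖x‖₁` is solved on repeated class-balanced
   undersamples with λ drawn as a fraction (0.05–0.5) of λ_max per run,
   using EDPP safe screening (features provably zero at the target λ are
   discarded before solving, with no change to the solution).  Selection
   counts accumulate over 1000 inner × 50 outer runs and the top-n features
   per modality feed the classifier.
4. **Classification.** A variational-Bayes probabilistic multiple-kernel
   classifier (VBpMKL): Gaussian base kernels per modality combined as the
   mean composite kernel `K = Σ_m β_m K_m` (M = 3), a multinomial-probit
   likelihood `t_n = argmax_c (W k_n + ε)_c` with auxiliary variables, and
   a factorized variational posterior.  The posterior predictive
   `P(t = i | W, k) = E_{u∼N(0,1)} ∏_{j≠i} Φ(u + (w_i − w_j)k)`
   is evaluated by Gauss–Hermite quadrature.
5. **Evaluation.** Rank-formulation (Mann–Whitney) AUC with tie
   correction, accuracy / sensitivity / specificity at a 0.5 threshold
   (P-MCI positive), repeated stratified five-fold cross-validation with
   subtyping and selection re-fit inside every training fold, and random-
   forest mean-decrease-in-Gini feature importance.

## Worked example

```python
from mcicps import (PipelineConfig, SyntheticConfig, evaluate,
                    predict_mci_cps, train_mci_cps, train_raw_classifier)
from mcicps.synthetic import generate_train_test

train, test = generate_train_test(SyntheticConfig(seed=0))
cfg = PipelineConfig(inner_reps=50, outer_reps=20, seed=0)
cps = train_mci_cps(train, cfg)           # subtype-aware model
raw = train_raw_classifier(train, cfg)    # same pipeline, no subtyping
assignment, p_cps = predict_mci_cps(cps, test)
_, p_raw = predict_mci_cps(raw, test)
print(evaluate(p_cps[:, 1], test.labels).as_dict())
```

Running `python examples/04_train_predict_evaluate.py` prints:

```
model              AUC    Acc%     Sn%     Sp%
subtype-aware   0.9996   98.00   95.12  100.00
pooled (raw)    0.9843   91.00   85.37   94.92
AUC gain from subtyping: +0.0153
```

The synthetic cohort plants conversion signal in *disjoint* feature sets
per subtype, so the subtype-matched classifiers see cleaner signal than
the pooled model — the AUC gain is the synthetic analogue of the benefit
of subtyping.  The other scripts under `examples/` walk through cohort
simulation, SNF subtyping and propagation, stability selection, and Gini
importance, each printing what it computes.

A thin CLI mirrors the library:
`mcicps simulate | qc | adjust-icv | subtype | select | train | predict |
evaluate | cv | importance` (see `mcicps --help`).

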