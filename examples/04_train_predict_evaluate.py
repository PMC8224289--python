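"""Train the subtype-aware predictor and the pooled baseline, then compare.

The subtype-aware model (one multiple-kernel classifier per molecular
subtype, routed by label propagation) is compared against the same
pipeline without subtyping on a held-out synthetic test set.
"""

from mcicps import (PipelineConfig, SyntheticConfig, evaluate,
                    predict_mci_cps, train_mci_cps, train_raw_classifier)
from mcicps.synthetic import generate_train_test

train, test = generate_train_test(SyntheticConfig(seed=0))
cfg = PipelineConfig(inner_reps=50, outer_reps=20, seed=0)

cps = train_mci_cps(train, cfg)
raw = train_raw_classifier(train, cfg)
assignment, p_cps = predict_mci_cps(cps, test)
_, p_raw = predict_mci_cps(raw, test)

rep_cps = evaluate(p_cps[:, 1], test.labels, tau=cfg.threshold,
                   subtypes=assignment.labels)
rep_raw = evaluate(p_raw[:, 1], test.labels, tau=cfg.threshold)

print(f"{'model':14s} {'AUC':>7s} {'Acc%':>7s} {'Sn%':>7s} {'Sp%':>7s}")
for name, rep in (("subtype-aware", rep_cps), ("pooled (raw)", rep_raw)):
    print(f"{name:14s} {rep.auc:7.4f} {100 * rep.accuracy:7.2f} "
          f"{100 * rep.sensitivity:7.2f} {100 * rep.specificity:7.2f}")
for s, entry in rep_cps.per_subtype.items():
    auc = entry.get("auc")
    print(f"  subtype {s}: n={entry['n']}"
          + (f", AUC={auc:.4f}" if auc is not None else ""))
print("\nAUC gain from subtyping:",
      f"{rep_cps.auc - rep_raw.auc:+.4f}")
# Conversion signal is planted in disjoint feature sets per subtype, so the
# subtype-matched classifiers see cleaner signal than the pooled model --
# the AUC gain above is the synthetic analogue of that benefit.
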