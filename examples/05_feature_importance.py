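"""Rank each bundle's selected features by mean decrease in Gini impurity.

A random forest is fit on the features each subtype's classifier selected;
mean decrease in Gini, averaged over trees and forest seeds, measures each
feature's (and each data source's) contribution to separating stable from
progressive MCI.
"""

import numpy as np

from mcicps import PipelineConfig, SyntheticConfig, gini_importance, train_mci_cps
from mcicps.pipeline import MODALITIES, _bundle_blocks, _new_processed_snp
from mcicps.synthetic import generate_train_test

train, _ = generate_train_test(SyntheticConfig(seed=0))
cfg = PipelineConfig(inner_reps=50, outer_reps=10, seed=0)
model = train_mci_cps(train, cfg)
snp_imp = _new_processed_snp(model, train)

for s, bundle in model.bundles.items():
    idx = np.flatnonzero(model.train_subtypes.labels == s)
    std = _bundle_blocks(train, snp_imp, bundle.icv_adjuster,
                         bundle.standardizers, idx)
    blocks = {t: std[t].select_features(bundle.selected[t]).values
              for t in MODALITIES}
    rep = gini_importance(blocks, bundle.selected, train.labels[idx],
                          n_trees=300, repeats=5, seed=0)
    print(f"subtype {s} ({len(idx)} patients): top features")
    print(rep.table.head(8).to_string(index=False))
    print("per-source mean importance:",
          {k: round(v, 4) for k, v in sorted(rep.per_source.items())})
    print()
# Features planted as conversion-informative for each subtype dominate that
# subtype's ranking; the per-source averages show which modality carries
# the most predictive signal for each subtype.
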