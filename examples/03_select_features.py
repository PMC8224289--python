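"""Rank conversion-informative features by undersampled stability Lasso.

Each run draws a class-balanced undersample and a penalty fraction in
(0.05, 0.5) of lambda_max, solves the EDPP-screened Lasso, and marks the
nonzero coefficients; counts accumulate over all runs.
"""

import numpy as np

from mcicps import SyntheticConfig, rank_features, run_stability_selection
from mcicps.preprocess import apply_standardizer, fit_standardizer
from mcicps.synthetic import generate_cohort

cohort = generate_cohort(SyntheticConfig(seed=0), n_samples=150)
sub = np.flatnonzero(cohort.subtype_truth == 1)  # select within one subtype
expr = cohort.modalities["expr"].take_samples(sub)
expr = apply_standardizer(fit_standardizer(expr), expr)
labels = cohort.labels[sub]

profile = run_stability_selection(expr, labels, inner=100, outer=10, seed=0)
ranking = rank_features(profile)
planted = set(cohort.truth["conv_informative"][1]["expr"])

print(f"{profile.total_runs} balanced-undersample Lasso runs on "
      f"{len(sub)} subtype-1 patients ({labels.sum()} converters)")
print("rank  feature      count  planted?")
for r, (fid, cnt) in enumerate(zip(ranking.ordered_ids[:15],
                                   ranking.counts[:15]), 1):
    print(f"{r:4d}  {fid:10s}  {cnt:5d}  {'yes' if fid in planted else ''}")
hits = len(planted & set(ranking.top(10)))
print(f"\n{hits}/10 of the top-10 features are planted conversion features")
# High counts concentrate on the genes whose expression was shifted in
# converters of this subtype; pure-noise genes are selected far less often.
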