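"""Train the movement clock and compute delta-age on held-out data.

Features are the hourly maximum intensity and hourly variance over a week
(7 days x 24 hours x 2 = 336 per person).  The random forest predicts
chronological age; peer-median normalization corrects the usual
regression-to-the-mean compression, and delta_age = normalized prediction
minus chronological age is the age-acceleration statistic.
"""

import pandas as pd

from accelage import age_model, qc_features, synthcohort

cohort = synthcohort.generate(synthcohort.SynthConfig(n_participants=600, seed=2))
features = qc_features.feature_matrix(cohort.weeks())
ages = pd.Series(cohort.ages, index=cohort.seqn, dtype=float)

train_ids, test_ids = age_model.split_train_test(features, ages, seed=2)
clock = age_model.train_rf(features.loc[train_ids], ages.loc[train_ids],
                           seed=2, n_trees=300)

pred = age_model.predict_age(clock, features.loc[test_ids])
r_raw, rmse_raw = age_model.evaluate(pred, ages)
norm = age_model.normalize_predictions(pred, ages)
r_norm, rmse_norm = age_model.evaluate(norm, ages)
delta = age_model.delta_age(norm, ages)

print(f"held-out raw prediction:        r = {r_raw:.3f}, RMSE = {rmse_raw:.2f} y")
print(f"after peer-median rescaling:    r = {r_norm:.3f}, RMSE = {rmse_norm:.2f} y")
print(f"delta-age spread (SD):          {delta.std():.2f} y")
print("positive delta_age = movement looks older than peers (accelerated aging)")

imp = age_model.importance(clock, features.loc[test_ids], ages, n_repeats=3, seed=2)
print("\nstrongest predictors (%IncMSE):")
print(imp.sort_values(ascending=False).head(5).round(1).to_string())
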