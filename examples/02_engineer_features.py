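"""Compute the 69 historical features for one participant.

Every 5-minute glucose reading with at least 24 h of prior data gets one
row; each feature only uses data from 5 minutes to 24 hours before the
reading, so the table is safe to use for forecasting.
"""

from persglu import CohortConfig, FEATURE_NAMES, assemble_features, generate_participant

config = CohortConfig(n_participants=2, days_min=3, days_max=3, seed=7,
                      wear_gap_fraction=0.0)
record = generate_participant(config, 1)
table = assemble_features(record)

print(f"{len(table)} feature rows (3 days minus the first 24 h of history)")
print(f"{len(FEATURE_NAMES)} features per row")
row = table.iloc[100]
print(f"example row at t={row['epoch_start']:.0f} "
      f"(glucose target {row['glucose_target']:.1f} mg/dL):")
for name in ["hr_mean", "acc_mean", "eda_peaks_total_2h", "rmssd",
             "activity_bout", "wake_time", "sugar_24h", "minutes_from_midnight"]:
    print(f"  {name:>22}: {row[name]:.2f}")
# Interpretation: e.g. sugar_24h is the grams of sugar logged in the 24 h
# before this reading; wake_time is the previous day's estimated wake
# (minutes from midnight) from actigraphy + heart rate.
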