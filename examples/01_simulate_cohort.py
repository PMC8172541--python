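"""Generate a small synthetic cohort and look at what was planted.

Each participant gets wrist-wearable streams (heart rate 1 Hz, EDA and
skin temperature 4 Hz, accelerometry 32 Hz), inter-beat intervals, a
5-minute CGM trace with meal-driven rises and activity dips, and a food
log. The planted truth tables list exactly which meals, activity bouts
and EDA stress bursts went in, so downstream detections can be checked.
"""

from persglu import CohortConfig, generate_participant, planted_truth

config = CohortConfig(n_participants=2, days_min=3, days_max=3, seed=7,
                      wear_gap_fraction=0.3)
record = generate_participant(config, 1)
truth = planted_truth(config)

print(f"participant {record.participant_id}: sex={record.sex}, "
      f"HbA1c={record.hba1c:.2f}%")
print(f"glucose points: {len(record.glucose)} "
      f"(70% of the 3-day 5-min grid; 30% wear gaps)")
print(f"glucose range: {record.glucose.glucose_mg_dl.min():.0f}-"
      f"{record.glucose.glucose_mg_dl.max():.0f} mg/dL")
for kind, stream in record.streams.items():
    print(f"  {kind.value}: {len(stream)} samples at {stream.rate_hz:g} Hz")
mine = truth["meals"].query("participant_id == 1")
print(f"planted meals: {len(mine)} over 3 days "
      f"(mean {mine['sugar_g'].mean():.0f} g sugar each)")
print(f"planted activity bouts: {len(truth['bouts'].query('participant_id == 1'))}")
# Interpretation: the generator plants the causal structure (meals raise
# glucose, activity dips it) that the models downstream must recover.
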