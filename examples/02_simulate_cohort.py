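"""Simulate a synthetic donor cohort and write it as CSV.

The generator emulates blood-bank practice: donations at least 14 days
apart, integer log2 titer measurements with Gaussian error, boosters at the
first 3-5 donations of a new donor and titer-triggered boosters afterwards
(at most once per year).
"""

import numpy as np

from antird import CohortConfig, dataset_summary, expected_boosters, simulate_cohort, write_dataset

config = CohortConfig(n_donors=200, seed=42)
sample = simulate_cohort(config)

summary = dataset_summary(sample.records)
titers = np.concatenate([r.measured_titers for r in sample.records])
boosters = np.mean([r.n_boosters for r in sample.records])
print(f"simulated {summary['n_donors']} donors: {summary['n_titers']} titer "
      f"measurements, {summary['n_boosters']} booster events")
print(f"median measured titer: log2 {np.median(titers):.0f} "
      f"(fraction >= 14: {np.mean(titers >= 14):.1%})")
print(f"boosters per donor: {boosters:.2f} observed vs "
      f"{expected_boosters(config):.2f} predicted from the policy")

write_dataset(sample.records, "cohort_extended.csv", dialect="extended", seed=config.seed)
write_dataset(sample.records, "cohort_s1.csv", dialect="s1", seed=config.seed)
print("wrote cohort_extended.csv (day-resolved) and cohort_s1.csv (anonymised, no days)")
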