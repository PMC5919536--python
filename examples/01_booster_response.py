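"""A single booster's effect on a donor's anti-RhD titer.

Evaluates the core response curve for the calibrated default population:
how fast the titer rises after a booster, where it peaks, and how the gain
shrinks as the titer at boostering grows.
"""

import numpy as np

from antird import (
    booster_envelope,
    booster_gain,
    booster_saturation,
    default_population,
    percent_change,
    response_peak_day,
)

pop = default_population()
donor = pop.mean_donor

print(f"calibrated population: B={pop.max_effect:.2f} log2, H={pop.timing_rate:.3f}/day,")
print(f"  mean decline {pop.annual_mean_decline:+.2f} log2/yr, "
      f"mean saturation speed {pop.mean_saturation:.3f}/log2\n")

print("envelope (fraction of the eventual gain reached t days after boostering):")
for t in (7, 14, 26, 50, 100):
    print(f"  day {t:3d}: {booster_envelope(t, pop.timing_rate):.3f}")

print("\nasymptotic gain of one booster by titer at boostering:")
for t0 in (0, 3, 9, 11, 13):
    gain = 2 * pop.max_effect * booster_saturation(t0, donor.saturation_speed)
    print(f"  starting log2 titer {t0:2d}: +{gain:.2f} log2  ({percent_change(gain):+.0f}% absolute)")

peak = response_peak_day(pop, donor, 11.0)
g26 = booster_gain(11.0, peak, pop, donor)
print(f"\nboostered at the median titer (log2 11), the mean donor peaks "
      f"{peak:.0f} days later, +{g26:.2f} log2 above the starting titer")
print("(the decline then takes over: the envelope is saturated but the titer drifts down)")
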