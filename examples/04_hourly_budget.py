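"""Hourly activity budget with baseline-relative normalization.

Simulates five days of daytime behaviour (1 Hz states, lights 6:30-18:30)
with walking-propensity peaks at hours 7-9 and 13-15, aggregates mean
state per hour of day, and normalizes by the pig's own all-time mean.
Values above 1.0 mark hours more active than this animal's norm; the two
highest hours should fall inside the configured peak windows.
"""

from pentrack.activity import ActivityRecord
from pentrack.aggregation import baseline_relative, hourly_mean, overall_mean
from pentrack.synthetic import behavior_state_machine

import numpy as np

profile = {h: 0.1 for h in range(6, 19)}
profile.update({7: 0.9, 8: 0.9, 13: 0.9, 14: 0.9})

rng = np.random.default_rng(1)
records: list[ActivityRecord] = []
for day in range(5):
    start = 6.5 * 3600 + day * 86_400
    states = behavior_state_machine(profile, 12 * 3600, rng, start_s=start)
    records += [
        ActivityRecord(start + i, len(records) + i, int(s), False, None, None)
        for i, s in enumerate(states)
    ]

hourly = baseline_relative(hourly_mean(records, "P1"), overall_mean(records))
print(f"overall mean state: {overall_mean(records):.3f}")
print("hour  mean_state  relative")
for h in hourly:
    bar = "#" * int(20 * h.relative_activity)
    print(f"{h.hour_of_day:4d}  {h.mean_state:10.3f}  {h.relative_activity:8.3f}  {bar}")
top2 = sorted(hourly, key=lambda h: h.relative_activity, reverse=True)[:2]
print("two most active hours:", [h.hour_of_day for h in top2])
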