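"""Annual threshold deterioration: TBC vs TLDc domain groups.

Simulates a two-group cross-sectional cohort in which TBC-domain carriers
deteriorate faster at every frequency, estimates each group's ATD (pooled
OLS slope of threshold on age, dB/year) and tests the per-frequency group
difference with a seeded label-permutation test.
"""

import numpy as np

from audioprofile import AudiogramRecord, atd_table

rng = np.random.default_rng(11)
FREQS = (250, 500, 1000, 2000, 4000, 8000)
records = []
for group, rate, prefix in (("TBC", 0.75, "T"), ("TLDc", 0.30, "L")):
    for i in range(35):
        age = float(rng.uniform(18, 60))
        thresholds = {
            f: float(np.clip(15 + rate * (age - 18) + rng.normal(0, 4), -10, 120))
            for f in FREQS
        }
        records.append(AudiogramRecord(f"{prefix}{i}", age, "binaural", thresholds, group))

table = atd_table(records, permutations=10_000, seed=1)
print(table.to_frame().round(4).to_string())
# Rows: each group's ATD in dB/year per frequency; the p-value row is the
# two-sided permutation p for the TBC - TLDc slope difference. With rates
# 0.75 vs 0.30 dB/year the difference is significant at every frequency.
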