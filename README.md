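# audioprofile

Audiometric progression analysis for cross-sectional cohorts with
progressive sensorineural hearing loss — built around the genotype–phenotype
question in TBC1D24-related autosomal dominant non-syndromic hearing loss
(DFNA65), where carriers are stratified by whether their mutation falls in
the protein's TBC or TLDc domain.

Given one audiogram per subject at a known age, the package answers three
questions an audiological geneticist asks of such a cohort:

1. **When does hearing loss start?** Fit candidate threshold-vs-age models
   to the four-frequency pure-tone average (PTA, mean of 500/1000/2000/4000
   Hz) — power `y = a·x^b`, linear, logarithmic, quadratic — select the best
   by R² on the threshold scale, and invert the winning curve at 25 dB HL to
   obtain the **onset age**.
2. **How fast does it progress per band?** Fit power curves to the low
   (250/500 Hz), mid (1000/2000 Hz) and high (4000/8000 Hz) band means and
   invert at 25 and 60 dB HL; the difference of crossing ages is the
   **hearing progression time** (HPT), the years needed to deteriorate from
   25 to 60 dB.
3. **Do the mutation-domain groups differ?** Estimate each group's **annual
   threshold deterioration** (ATD) per frequency as the pooled OLS slope of
   threshold on age (dB/year) and test TBC-vs-TLDc differences with a
   seeded, two-sided label-permutation test.

A seeded synthetic-cohort generator reproduces the statistical structure the
analysis assumes (power-law progression, group-specific rates, additive
Gaussian noise in dB, audiometer clipping), so every stage is testable
end-to-end without patient data.

## Worked example

Reconstruct each band's progression curve from its published crossing ages
and compute the HPT by curve inversion (`examples/01_published_hpt.py`):

```python
from audioprofile import (TBC1D24_BAND_ANCHORS, hearing_progression_time,
                          two_point_power_model)

for band, (age_25, age_60) in TBC1D24_BAND_ANCHORS.items():
    model = two_point_power_model((age_25, 25.0), (age_60, 60.0))
    print(band, round(hearing_progression_time(model), 2))
```

```
low   y = 1.1161 * x^0.9535   25 dB @ 26.07 y, 60 dB @ 65.3 y  ->  HPT = 39.23 years
mid   y = 0.2534 * x^1.4705   25 dB @ 22.7 y, 60 dB @ 41.17 y  ->  HPT = 18.47 years
high  y = 0.7259 * x^1.2159   25 dB @ 18.37 y, 60 dB @ 37.74 y  ->  HPT = 19.37 years
```

Low-frequency hearing takes ~39 years to fall from 25 to 60 dB HL; mid and
high frequencies take only ~18–19 years — the hallmark of faster mid/high
frequency deterioration in this phenotype.

The other examples cover model fitting/selection and onset estimation on a
noisy synthetic cohort (`02`), the ATD permutation comparison (`03`), and
the full CSV-in, report-out pipeline (`04`). The same pipeline is scriptable
from a shell:

```sh
audioprofile simulate --out cohort.csv --n 80 --noise-sd 3 --seed 23
audioprofile run --input cohort.csv --out report/ --seed 23
```

Input CSVs are tidy tables with columns
`subject_id, age_years, ear, freq_hz, threshold_db, group[, source]`,
one row per subject/ear/frequency.

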