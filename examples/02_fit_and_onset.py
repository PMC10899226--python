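"""Model fitting, selection, and onset age on a synthetic noisy cohort.

Simulates 60 subjects whose pure-tone-average (PTA) curve crosses 25 dB at
19.23 years, fits all four candidate threshold-vs-age families, selects the
best by R^2 (with parsimony tie-breaking), and inverts the winner for the
onset age.
"""

from audioprofile import (
    PTA_FREQUENCIES,
    compute_pta,
    fit_all,
    generate_cohort,
    onset_age,
    select_best,
    tbc1d24_profile_spec,
)

spec = tbc1d24_profile_spec(noise_sd=3.0, seed=7, pta_anchor_ages=(19.23, 50.0))
cohort = generate_cohort(spec)
ages = [r.age for r in cohort]
ptas = [compute_pta(r) for r in cohort]

fits = fit_all(ages, ptas)
best = select_best(fits)
print(f"PTA = mean threshold over {list(PTA_FREQUENCIES)} Hz, n = {len(cohort)} subjects\n")
for fit in sorted(fits, key=lambda m: -m.r_squared):
    marker = "  <- selected" if fit is best else ""
    print(f"{fit.family:<12} R^2 = {fit.r_squared:.4f}{marker}")

print(f"\nonset age (curve crosses 25 dB HL): {onset_age(best):.2f} years")
# With 3 dB measurement noise the estimate lands close to the generating
# 19.23-year onset; rerun with noise_sd=0.0 to recover it almost exactly.
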