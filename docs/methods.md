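# Methods

## Data model

An observation is one subject's air-conduction audiogram at one age: a map
from test frequency (125–8000 Hz, the standard octave set) to threshold in
dB HL, restricted to [−10, 120] — the dynamic range of a clinical
audiometer. Cohorts are cross-sectional: one audiogram per subject, so all
age trends are between-subject. Left/right pairs are averaged per frequency
into a binaural record before analysis ("bilaterally symmetric" audiograms
justify the average); a dataset supplying a ready-made binaural record for a
subject takes precedence over that subject's per-ear rows, which are dropped
with a warning to avoid double counting. Scalar responses derived per
record:

* **PTA** — arithmetic mean over 500/1000/2000/4000 Hz. All four
  frequencies are required (hard error): the PTA is the regression response
  and must mean the same thing for every subject.
* **Band means** — low (250, 500), mid (1000, 2000), high (4000, 8000) Hz.
  One missing member is tolerated (single-member fallback with a warning):
  band fits can still use partially observed audiograms.
* **Severity** — WHO-1997 grades (normal ≤ 25, mild 26–40, moderate 41–60,
  severe 61–80, profound ≥ 81 dB HL), supplied as a configurable table.

## Progression model

Thresholds are modelled as deterministic functions of age `x` (years > 0)
plus homoskedastic Gaussian error in dB. Four candidate mean functions:

| family      | form                    | parameters |
|-------------|-------------------------|------------|
| power       | `a·x^b`, a > 0          | 2          |
| linear      | `c0 + c1·x`             | 2          |
| logarithmic | `c0 + c1·ln x`          | 2          |
| quadratic   | `c0 + c1·x + c2·x²`     | 3          |

The "polynomial" candidate is fixed at degree 2 — the smallest polynomial
distinct from the linear family. All fits minimise squared error **on the
threshold scale**, and R² = 1 − SS_res/SS_tot is computed on that same
scale, so the four families compete under one loss. The power family is fit
by Levenberg–Marquardt-style nonlinear least squares (trust-region
reflective under the a > 0 bound), initialised from OLS on the log–log
transform; observations with threshold ≤ 0 are excluded from the
initialisation only, never from the fit. Convergence tolerances: parameter
tolerance 1e-10, max 10 000 function evaluations; non-convergence raises an
error carrying the initialisation rather than returning a best effort.
Observations are sorted into a canonical order before fitting so results are
bit-identical under input permutation.

**Selection.** The best model is the one with maximal R²; fits whose R² lie
within `R2_TIE_TOL = 0.005` of the best — half a unit in the second decimal,
the precision at which R² is conventionally reported — are treated as tied,
and ties resolve to fewer parameters, then to the fixed order power,
logarithmic, linear, quadratic. Without this parsimony margin the quadratic
family would win on pure noise: one extra parameter buys an R² improvement
of order (1 − R²)/n, far below any reportable difference. The margin is a
documented, configurable argument of `select_best`.

**Inversion.** A crossing age is the smallest age in (0, 120] years at which
the fitted curve attains a level *going upward* (positive derivative at the
crossing). Power, linear and logarithmic curves invert in closed form;
quadratics via the root formula with the upward-slope filter. Crossings
outside the observed age range are returned flagged `extrapolated` rather
than refused — published progression curves are themselves extrapolated
beyond the oldest patients. Derived statistics:

* **onset age** = crossing age at 25 dB HL of the best PTA model;
* **HPT** = crossing(60 dB) − crossing(25 dB) per band, positive for
  increasing curves, computed from the same inversion code path so the
  identity HPT = Δcrossing holds exactly.

Band fits use the power family by fiat (the established audioprofile shape
for this phenotype); full selection per band is available via the
`band_families` argument. 25 and 60 dB are configuration defaults, not
constants, so sensitivity analyses are possible while the defaults
reproduce the standard definitions.

**Censoring at the scale limits.** A summary threshold at or beyond the
audiometric range limits (≥ 120 or ≤ −10 dB HL) is a saturated
"no response"-style reading, not a measurement. Such values are excluded
from all threshold-vs-age regressions (PTA fit, band fits, ATD slopes) with
a logged count. Without this the fastest-progressing bands would be
flattened by a ceiling artifact: in synthetic cohorts the mid/high band
curves reach 120 dB within the simulated age span, and retaining the
clipped values biases fitted HPTs by several percent.

## Annual threshold deterioration and group comparison

With single-visit data the only available rate estimator is cross-sectional:
ATD at a frequency is the pooled OLS slope of threshold on age across a
group's subjects, in dB/year. The TBC-vs-TLDc contrast at each frequency is
the raw slope difference, tested by label permutation: subjects are the
exchangeable unit, group labels are reshuffled B times (default 10 000,
minimum 1000 before a warning), and the two-sided p-value is
`(b + 1)/(B + 1)` with `b` the count of permuted |differences| at least as
large as observed — the add-one correction keeps p strictly positive. The
permutation kernel is vectorised (all B shuffles evaluated as one array
operation) and seeded; the pooled sample is canonically sorted and the
permuted split sized by the smaller group, which by complement symmetry
samples the same null and makes p-values exactly invariant under swapping
the two groups. Each frequency of the ATD table receives an independent
child seed spawned from the table seed, so the table is reproducible as a
whole. No multiple-testing correction is applied to the per-frequency
p-values; a supplementary Bonferroni column is emitted alongside.

One property of this statistic worth knowing: its permutation null widens
with any between-group *mean* offset, not only slope differences, because
permuted subsets mix the two threshold distributions. Cohorts whose groups
start from similar baseline hearing and diverge with age (the realistic
geometry for progressive loss, and the one the calibration suite simulates)
give the test its full sensitivity; artificial cohorts with a large constant
offset between groups dilute it.

## Synthetic cohorts

`CohortSpec` describes a generating process: `n_subjects` ages drawn
uniformly over an age range, a group label drawn from stated proportions,
and per-frequency, per-group power-law mean curves with additive Gaussian
noise (s.d. in dB), clipped to the audiometer range. Everything is driven
by one `numpy` generator seed; identical specs reproduce identical cohorts,
and the clipped fraction is reported. Uniform ages stress the fit across
the whole range rather than imitating any particular cohort's demography.
The noise model is homoskedastic in dB; group effects enter only through
the curve parameters (no subject random effects), matching what the pooled
cross-sectional estimators can identify.

`tbc1d24_profile_spec()` anchors each band's curve at the published
crossing-age pairs — low (26.07, 65.30), mid (22.70, 41.17), high
(18.37, 37.74) years at (25, 60) dB — assigning the band curve to both
member frequencies, with defaults n = 60, ages uniform (10, 75) and
noise_sd = 3 dB (typical audiometric test–retest spread; pass 0 for
noiseless ground-truth checks). An optional `pta_anchor_ages` variant pins
the PTA curve instead (all four PTA frequencies share one curve), which
fixes the cohort's onset age by construction.

What the generator does **not** emulate: audiogram digitisation error, 5-dB
step quantisation, test–retest asymmetry between ears, conductive overlays,
heteroskedastic noise, or realistic age pyramids. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every property of literature-harvested audiograms.

## Problem sizes and determinism

Defaults keep every routine interactive: cohorts of 60–100 subjects,
10 000 permutations per comparison, and 20-replicate recovery studies run
in seconds; the type-I calibration study (500 replicates × 2000
permutations) completes in well under a minute thanks to the vectorised
kernel. All randomness flows from explicit integer seeds; JSON reports
contain no timestamps and regenerate byte-identically from the same inputs
and seed. Reported years are rounded to two decimals only at the rendering
layer, never internally.

## Known limitations

* Cross-sectional slopes conflate cohort effects with within-subject
  progression; longitudinal modelling is out of scope.
* No confidence intervals on onset age or HPT (point estimates only, by
  design); bootstrap wrappers would be a natural extension.
* The censoring rule treats exactly-at-limit values as missing rather than
  modelling them (no Tobit-style likelihood).
* No inter-ear asymmetry filter is applied when averaging ears; strongly
  asymmetric losses should be screened upstream.
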