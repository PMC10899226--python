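"""Threshold-vs-age progression models: fitting, selection and inversion.

Four candidate families describe how hearing thresholds (dB HL) grow with
age ``x`` (years):

* power:        y = a * x**b          (a > 0)
* linear:       y = c0 + c1*x
* logarithmic:  y = c0 + c1*ln(x)
* quadratic:    y = c0 + c1*x + c2*x**2

All families are fit by least squares on the original threshold scale and
compared by R^2 = 1 - SS_res/SS_tot on that same scale, so the comparison is
apples-to-apples (a log-log power fit would optimise a different loss). The
power family is fit by nonlinear least squares initialised from an ordinary
least-squares fit on the log-log transform.

Inverting a fitted curve gives *crossing ages*: the onset age is where the
curve reaches 25 dB HL, and the hearing progression time (HPT) is the number
of years the curve takes to climb from 25 to 60 dB HL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .audiograms import AudiogramRecord, FrequencyBand, DEFAULT_BANDS, band_mean, compute_pta
from .exceptions import (
    DegenerateDataError,
    FitFailureError,
    IncompleteAudiogramError,
    InsufficientDataError,
    NoCrossingError,
)

logger = logging.getLogger("audioprofile")

#: Maximum age (years) considered when searching for curve crossings.
MAX_AGE = 120.0

MODEL_FAMILIES = ("power", "linear", "logarithmic", "quadratic")

_PARAM_COUNT = {"power": 2, "linear": 2, "logarithmic": 2, "quadratic": 3}

#: Tie-break preference order for model selection.
_FAMILY_ORDER = ("power", "logarithmic", "linear", "quadratic")


def _predict(family: str, params: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if family == "power":
        a, b = params
        return a * np.power(x, b)
    if family == "linear":
        c0, c1 = params
        return c0 + c1 * x
    if family == "logarithmic":
        c0, c1 = params
        return c0 + c1 * np.log(x)
    if family == "quadratic":
        c0, c1, c2 = params
        return c0 + c1 * x + c2 * x * x
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class FittedModel:
    """A fitted (or constructed) threshold-vs-age curve.

    ``r_squared`` is ``None`` for curves constructed analytically (e.g. the
    two-point power model), where a goodness-of-fit is not applicable.
    """

    family: str
    params: tuple[float, ...]
    r_squared: float | None
    n: int
    age_range: tuple[float, float]

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if len(self.params) != _PARAM_COUNT[self.family]:
            raise ValueError(
                f"{self.family} model takes {_PARAM_COUNT[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        if self.r_squared is not None and self.r_squared > 1 + 1e-12:
            raise ValueError(f"r_squared must be <= 1, got {self.r_squared}")
        if not self.age_range[0] > 0:
            raise ValueError("age_range must start at a positive age")

    @property
    def parameter_count(self) -> int:
        return _PARAM_COUNT[self.family]

    def predict(self, ages) -> np.ndarray | float:
        """Predicted threshold (dB HL) at the given age(s) in years."""
        out = _predict(self.family, np.asarray(self.params, dtype=float), ages)
        return float(out) if np.isscalar(ages) else out

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": [float(p) for p in self.params],
            "r_squared": None if self.r_squared is None else float(self.r_squared),
            "n": self.n,
            "age_range": [float(self.age_range[0]), float(self.age_range[1])],
        }


def fit_model(ages, thresholds, family: str) -> FittedModel:
    """Least-squares fit of one model family to (age, threshold) data.

    R^2 is always computed on the original threshold scale, whatever the
    family's internal transform.

    Raises
    ------
    InsufficientDataError
        Fewer than ``parameter_count + 1`` observations.
    DegenerateDataError
        Thresholds have zero variance.
    FitFailureError
        The nonlinear solver (power family) did not converge; the exception
        carries the log-log initialization used.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(thresholds, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and thresholds must be equal-length 1-D vectors")
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    k = _PARAM_COUNT[family]
    if x.size < k + 1:
        raise InsufficientDataError(
            f"{family} fit needs at least {k + 1} observations, got {x.size}"
        )
    if np.any(x <= 0):
        raise ValueError("all ages must be positive")
    # canonical observation order makes fits bit-identical under permutation
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("thresholds have zero variance; nothing to fit")

    if family == "linear":
        design = np.column_stack([np.ones_like(x), x])
        params, *_ = np.linalg.lstsq(design, y, rcond=None)
    elif family == "logarithmic":
        design = np.column_stack([np.ones_like(x), np.log(x)])
        params, *_ = np.linalg.lstsq(design, y, rcond=None)
    elif family == "quadratic":
        design = np.column_stack([np.ones_like(x), x, x * x])
        params, *_ = np.linalg.lstsq(design, y, rcond=None)
    else:  # power
        params = _fit_power(x, y)

    yhat = _predict(family, np.asarray(params, dtype=float), x)
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return FittedModel(
        family=family,
        params=tuple(float(p) for p in params),
        r_squared=r2,
        n=int(x.size),
        age_range=(float(x.min()), float(x.max())),
    )


def _fit_power(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # Initialise from OLS on the log-log transform; non-positive thresholds
    # are excluded from the initialisation only, never from the fit itself.
    pos = y > 0
    if pos.sum() >= 2:
        lx, ly = np.log(x[pos]), np.log(y[pos])
        design = np.column_stack([np.ones_like(lx), lx])
        (loga, b0), *_ = np.linalg.lstsq(design, ly, rcond=None)
        p0 = (math.exp(loga), b0)
    else:
        p0 = (1.0, 1.0)

    def f(xv, a, b):
        return a * np.power(xv, b)

    try:
        popt, _, infodict, mesg, ier = optimize.curve_fit(
            f, x, y, p0=p0,
            bounds=([1e-12, -np.inf], [np.inf, np.inf]),
            xtol=1e-10, ftol=1e-12, gtol=1e-12,
            maxfev=10_000, full_output=True,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"power fit did not converge: {exc}", init=p0) from exc
    if ier not in (1, 2, 3, 4):  # pragma: no cover - curve_fit raises first
        raise FitFailureError(f"power fit did not converge: {mesg}", init=p0)
    return popt


def fit_all(ages, thresholds, families=MODEL_FAMILIES) -> list[FittedModel]:
    """Fit every requested family to the same data, logging (not raising) on
    per-family failures, and return the successful fits."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_model(ages, thresholds, fam))
        except FitFailureError as exc:
            logger.warning("%s fit failed: %s", fam, exc)
    return fits


#: Two fits whose R^2 differ by less than this are considered tied and the
#: more parsimonious family preferred. Half a unit in the second decimal —
#: the precision at which R^2 is conventionally reported — so an extra
#: parameter must buy a reportable improvement to justify itself.
R2_TIE_TOL = 0.005


def select_best(fits: list[FittedModel], tie_tol: float = R2_TIE_TOL) -> FittedModel:
    """The fit with maximal R^2, with parsimony tie-breaking.

    Fits within ``tie_tol`` of the best R^2 are treated as tied; among tied
    fits the one with fewer parameters wins, then the fixed family order
    power, logarithmic, linear, quadratic.
    """
    if not fits:
        raise InsufficientDataError("no fitted models to select from")
    r2 = lambda m: m.r_squared if m.r_squared is not None else -np.inf
    best_r2 = max(r2(m) for m in fits)
    tied = [m for m in fits if r2(m) >= best_r2 - tie_tol] or list(fits)
    return min(tied, key=lambda m: (m.parameter_count, _FAMILY_ORDER.index(m.family)))


def crossing_age(model: FittedModel, level: float) -> tuple[float, bool]:
    """Smallest positive age at which the curve crosses ``level`` going upward.

    Returns ``(age_years, extrapolated)`` where ``extrapolated`` is True when
    the crossing lies outside the model's observed age range. The search is
    confined to (0, 120] years.

    Raises :class:`NoCrossingError` when the curve never attains the level
    upward within that range.
    """
    if not (-10.0 < level < 120.0):
        raise ValueError(f"level {level} dB HL outside (-10, 120)")
    fam, p = model.family, model.params

    if fam == "power":
        a, b = p
        # an upward crossing requires an increasing curve (a > 0, b > 0)
        if b <= 0 or level <= 0 or a <= 0:
            raise NoCrossingError(f"power curve y={a}*x^{b} never crosses {level} dB upward")
        xc = (level / a) ** (1.0 / b)
        if not (0 < xc <= MAX_AGE):
            raise NoCrossingError(
                f"power curve crosses {level} dB at {xc:.2f} y, outside (0, {MAX_AGE:g}]"
            )
    elif fam == "linear":
        c0, c1 = p
        if c1 <= 0:
            raise NoCrossingError(f"linear curve with slope {c1} has no upward crossing")
        xc = (level - c0) / c1
        if not (0 < xc <= MAX_AGE):
            raise NoCrossingError(f"linear curve crosses {level} dB at {xc:.2f} y, outside range")
    elif fam == "logarithmic":
        c0, c1 = p
        if c1 <= 0:
            raise NoCrossingError(f"logarithmic curve with slope {c1} has no upward crossing")
        xc = math.exp((level - c0) / c1)
        if not (0 < xc <= MAX_AGE):
            raise NoCrossingError(
                f"logarithmic curve crosses {level} dB at {xc:.2f} y, outside range"
            )
    elif fam == "quadratic":
        c0, c1, c2 = p
        roots = np.roots([c2, c1, c0 - level]) if c2 != 0 else (
            np.array([(level - c0) / c1]) if c1 != 0 else np.array([])
        )
        candidates = []
        for r in roots:
            if abs(r.imag) > 1e-9:
                continue
            xr = float(r.real)
            if 0 < xr <= MAX_AGE and (c1 + 2 * c2 * xr) > 0:  # upward slope at crossing
                candidates.append(xr)
        if not candidates:
            raise NoCrossingError(f"quadratic curve has no upward crossing of {level} dB in (0, {MAX_AGE:g}]")
        xc = min(candidates)
    else:  # pragma: no cover
        raise ValueError(f"unknown model family {fam!r}")

    lo, hi = model.age_range
    return float(xc), not (lo <= xc <= hi)


def onset_age(model: FittedModel, level: float = 25.0) -> float:
    """Age (years) at which the fitted PTA curve crosses the onset level (25 dB HL)."""
    return crossing_age(model, level)[0]


def hearing_progression_time(
    model: FittedModel, lower: float = 25.0, upper: float = 60.0
) -> float:
    """Years for the fitted threshold to climb from ``lower`` to ``upper`` dB HL.

    Positive for increasing curves; computed as the difference of the two
    crossing ages.
    """
    return crossing_age(model, upper)[0] - crossing_age(model, lower)[0]


def two_point_power_model(
    p1: tuple[float, float], p2: tuple[float, float]
) -> FittedModel:
    """The unique power curve ``y = a*x^b`` through two (age, threshold) points.

    Useful for reconstructing a curve from published crossing ages:
    ``b = ln(y2/y1)/ln(x2/x1)``, ``a = y1/x1^b``. Goodness-of-fit is not
    applicable (``r_squared`` is None).
    """
    (x1, y1), (x2, y2) = p1, p2
    if min(x1, x2, y1, y2) <= 0:
        raise ValueError("two-point power model needs positive ages and thresholds")
    if x1 == x2:
        raise DegenerateDataError("the two anchor points must have distinct ages")
    if y1 == y2:
        raise DegenerateDataError("the two anchor points must have distinct thresholds")
    # Order-independent: compute from the sorted pair.
    if x1 > x2:
        (x1, y1), (x2, y2) = (x2, y2), (x1, y1)
    b = math.log(y2 / y1) / math.log(x2 / x1)
    a = y1 / x1**b
    return FittedModel(
        family="power", params=(a, b), r_squared=None, n=2,
        age_range=(x1, x2),
    )


@dataclass(frozen=True)
class BandProgression:
    """25/60 dB crossing ages, HPT and the fitted curve for one band."""

    band: str
    age_at_lower: float
    age_at_upper: float
    hpt: float
    extrapolated: bool
    model: FittedModel

    def to_dict(self) -> dict:
        return {
            "name": self.band,
            "age_25db": float(self.age_at_lower),
            "age_60db": float(self.age_at_upper),
            "hpt_years": float(self.hpt),
            "extrapolated": self.extrapolated,
            "model": self.model.to_dict(),
        }


@dataclass
class ProgressionSummary:
    """Onset age plus per-band crossing ages and hearing progression times.

    ``errors`` maps a band name to the failure message when that band's fit
    or inversion failed; the remaining bands still carry results.
    """

    onset_age: float
    onset_model: FittedModel
    candidate_fits: list[FittedModel]
    bands: dict[str, BandProgression]
    errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "onset_age_years": float(self.onset_age),
            "onset_model": self.onset_model.to_dict(),
            "model_comparison": [m.to_dict() for m in self.candidate_fits],
            "bands": [self.bands[k].to_dict() for k in sorted(self.bands)],
            "band_errors": dict(sorted(self.errors.items())),
        }


def _saturated(value: float) -> bool:
    """True when a summary threshold sits at the audiometric scale limits.

    Audiometers cannot measure beyond their output limits; a value recorded at
    the extreme of the dB HL scale is a censored "no response"-style reading,
    not a measurement, and is excluded from threshold-vs-age regressions to
    avoid flattening the fitted curve at the ceiling.
    """
    from .audiograms import THRESHOLD_MAX, THRESHOLD_MIN

    return value >= THRESHOLD_MAX or value <= THRESHOLD_MIN


def progression_summary(
    records: list[AudiogramRecord],
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS,
    lower: float = 25.0,
    upper: float = 60.0,
    families=MODEL_FAMILIES,
    band_families=("power",),
) -> ProgressionSummary:
    """Full progression analysis on a cross-sectional cohort.

    Fits every candidate family to PTA vs age and takes the best by R^2 for
    the onset age; fits the power family to each band's mean threshold vs age
    and inverts for the 25/60 dB crossing ages and HPT. Bands whose fit or
    inversion fails are reported in ``errors`` while the rest proceed.
    """
    ages, ptas = [], []
    n_censored = 0
    for rec in records:
        try:
            pta = compute_pta(rec)
        except IncompleteAudiogramError as exc:
            logger.warning("skipping record for PTA regression: %s", exc)
            continue
        if _saturated(pta):
            n_censored += 1
            continue
        ptas.append(pta)
        ages.append(rec.age)
    if n_censored:
        logger.warning(
            "excluded %d PTA value(s) at the audiometric scale limits as censored",
            n_censored,
        )
    if len(ages) < 4:
        raise InsufficientDataError(
            f"progression analysis needs >= 4 subjects with computable PTA, got {len(ages)}"
        )
    fits = fit_all(ages, ptas, families)
    best = select_best(fits)
    onset = onset_age(best, lower)

    band_results: dict[str, BandProgression] = {}
    errors: dict[str, str] = {}
    for band in bands:
        b_ages, b_means = [], []
        b_censored = 0
        for rec in records:
            try:
                bm = band_mean(rec, band)
            except IncompleteAudiogramError:
                continue
            if _saturated(bm):
                b_censored += 1
                continue
            b_means.append(bm)
            b_ages.append(rec.age)
        if b_censored:
            logger.warning(
                "%s band: excluded %d saturated (censored) band mean(s)",
                band.name, b_censored,
            )
        try:
            bfit = select_best(fit_all(b_ages, b_means, band_families))
            a_lo, ex_lo = crossing_age(bfit, lower)
            a_hi, ex_hi = crossing_age(bfit, upper)
        except (InsufficientDataError, DegenerateDataError, FitFailureError,
                NoCrossingError) as exc:
            errors[band.name] = str(exc)
            logger.warning("%s band: %s", band.name, exc)
            continue
        band_results[band.name] = BandProgression(
            band=band.name,
            age_at_lower=a_lo,
            age_at_upper=a_hi,
            hpt=a_hi - a_lo,
            extrapolated=ex_lo or ex_hi,
            model=bfit,
        )
    return ProgressionSummary(
        onset_age=onset, onset_model=best, candidate_fits=fits,
        bands=band_results, errors=errors,
    )
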