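"""Annual threshold deterioration (ATD) and mutation-domain group comparison.

ATD is the rate, in dB/year, at which the hearing threshold at one frequency
worsens with age. For a cross-sectional cohort (one audiogram per subject)
the natural estimator is the pooled ordinary-least-squares slope of threshold
on age across subjects. Group differences (TBC- vs TLDc-domain mutation
carriers) are tested with a label-permutation test on the slope difference:
subjects — not rows — are the exchangeable unit, the statistic is
slope(A) - slope(B), and the two-sided p-value uses the add-one correction
(b + 1) / (B + 1) so it is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .audiograms import AudiogramRecord, CANONICAL_FREQUENCIES
from .exceptions import DegenerateDataError, InsufficientDataError, StratificationError

logger = logging.getLogger("audioprofile")

#: Frequencies reported in the group-comparison table (250 Hz - 8 kHz).
ATD_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)

#: Below this many permutations, reported p-values are too coarse to trust.
MIN_PERMUTATIONS = 1000


def _collect(records: list[AudiogramRecord], frequency: int):
    from .audiograms import THRESHOLD_MAX, THRESHOLD_MIN

    # thresholds at the scale limits are censored (audiometer saturation),
    # not measurements, and would flatten the slope; exclude them
    pairs = [
        (r.age, r.thresholds[frequency])
        for r in records
        if frequency in r.thresholds
        and THRESHOLD_MIN < r.thresholds[frequency] < THRESHOLD_MAX
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"ATD at {frequency} Hz needs >= 3 records carrying that frequency, "
            f"got {len(pairs)}"
        )
    pairs.sort()  # canonical order: slope estimates bit-identical under record order
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.unique(x).size < 2:
        raise DegenerateDataError(f"ATD at {frequency} Hz: all ages identical")
    return x, y


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.linregress(x, y).slope)


def annual_threshold_deterioration(
    records: list[AudiogramRecord], frequency: int
) -> tuple[float, int]:
    """Pooled OLS slope of threshold on age at one frequency, in dB/year.

    Returns ``(slope, n)`` where ``n`` is the number of contributing records.
    """
    x, y = _collect(records, frequency)
    return _slope(x, y), int(x.size)


@dataclass(frozen=True)
class ComparisonResult:
    """Permutation comparison of two groups' ATD at one frequency."""

    difference: float  # slope(A) - slope(B), dB/year
    statistic: float
    p_value: float
    method: str
    permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "difference_db_per_year": float(self.difference),
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "permutations": self.permutations,
            "seed": self.seed,
        }


def _permutation_slope_diff(
    x: np.ndarray, y: np.ndarray, n_a: int, permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of slope(A) - slope(B) under random label assignment.

    Vectorised: draws ``permutations`` independent shuffles of the subject
    indices and computes both group slopes for every shuffle at once.
    """
    n = x.size
    idx = np.tile(np.arange(n), (permutations, 1))
    idx = rng.permuted(idx, axis=1)

    def slopes(cols: np.ndarray) -> np.ndarray:
        xs, ys = x[cols], y[cols]
        xm = xs.mean(axis=1, keepdims=True)
        ym = ys.mean(axis=1, keepdims=True)
        num = np.sum((xs - xm) * (ys - ym), axis=1)
        den = np.sum((xs - xm) ** 2, axis=1)
        # a degenerate shuffle (all ages equal in one group) contributes slope 0
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    return slopes(idx[:, :n_a]) - slopes(idx[:, n_a:])


def compare_atd(
    group_a: list[AudiogramRecord],
    group_b: list[AudiogramRecord],
    frequency: int,
    permutations: int = 10_000,
    seed: int = 0,
) -> ComparisonResult:
    """Two-sided permutation test of the ATD difference between two groups.

    The observed statistic is slope(A) - slope(B) at ``frequency``; the null
    distribution is generated by shuffling group labels over subjects with a
    seeded generator, and the p-value is (b + 1)/(B + 1) where b counts
    permuted |differences| at least as large as the observed one.
    """
    if permutations < MIN_PERMUTATIONS:
        logger.warning(
            "only %d permutations requested; p-values below %d are unreliable",
            permutations, MIN_PERMUTATIONS,
        )
    xa, ya = _collect(group_a, frequency)
    xb, yb = _collect(group_b, frequency)
    observed = _slope(xa, ya) - _slope(xb, yb)

    # Canonicalise the pooled sample (sort by age, then threshold) and size the
    # permuted split by the smaller group. By complement symmetry a random
    # subset of size min(nA, nB) yields the same null distribution of
    # |slope difference| as one of size nA, and the draws are then bit-identical
    # when the two groups are passed in either order with the same seed.
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    rng = np.random.default_rng(seed)
    null = _permutation_slope_diff(x, y, min(xa.size, xb.size), permutations, rng)
    b = int(np.sum(np.abs(null) >= abs(observed) - 1e-15))
    p = (b + 1) / (permutations + 1)
    return ComparisonResult(
        difference=observed,
        statistic=observed,
        p_value=p,
        method="two-sided label-permutation test of pooled OLS slope difference",
        permutations=permutations,
        seed=seed,
    )


@dataclass
class AtdRow:
    """One frequency's ATDs (both groups) and their comparison."""

    frequency: int
    atd_a: float
    n_a: int
    atd_b: float
    n_b: int
    comparison: ComparisonResult

    def to_dict(self) -> dict:
        return {
            "freq_hz": self.frequency,
            "atd_tbc_db_per_year": float(self.atd_a),
            "n_tbc": self.n_a,
            "atd_tldc_db_per_year": float(self.atd_b),
            "n_tldc": self.n_b,
            "comparison": self.comparison.to_dict(),
        }


@dataclass
class AtdTable:
    """Per-frequency ATD for the TBC and TLDc groups with comparison statistics."""

    rows: list[AtdRow]
    permutations: int
    seed: int
    skipped: dict[int, str]

    def to_dict(self) -> dict:
        p_raw = [r.comparison.p_value for r in self.rows]
        m = len(p_raw)
        return {
            "method": "pooled cross-sectional OLS slope (dB/year) per frequency per group",
            "permutations": self.permutations,
            "seed": self.seed,
            "rows": [r.to_dict() for r in self.rows],
            # supplementary Bonferroni column across the reported frequencies
            "p_bonferroni": [min(1.0, p * m) for p in p_raw],
            "skipped": {str(k): v for k, v in sorted(self.skipped.items())},
        }

    def to_frame(self):
        """Wide layout mirroring a published comparison table: one row per
        group plus a p-value row, one column per frequency (kHz)."""
        import pandas as pd

        cols = [f"{r.frequency / 1000:g} kHz" for r in self.rows]
        data = {
            "TBC": [r.atd_a for r in self.rows],
            "TLDc": [r.atd_b for r in self.rows],
            "p-value": [r.comparison.p_value for r in self.rows],
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def atd_table(
    records: list[AudiogramRecord],
    permutations: int = 10_000,
    seed: int = 0,
    frequencies: tuple[int, ...] = ATD_FREQUENCIES,
) -> AtdTable:
    """ATD-by-frequency comparison table between the TBC and TLDc groups.

    Frequencies where either group fails the estimator's preconditions are
    skipped with a warning; a group with no records at all is an error.
    Deterministic for a given seed (each frequency gets an independent
    child seed spawned from it).
    """
    group_a = [r for r in records if r.group == "TBC"]
    group_b = [r for r in records if r.group == "TLDc"]
    if not group_a or not group_b:
        raise StratificationError(
            f"both groups required: {len(group_a)} TBC and {len(group_b)} TLDc records"
        )
    child_seeds = np.random.SeedSequence(seed).generate_state(len(frequencies)) % (2**31)
    rows: list[AtdRow] = []
    skipped: dict[int, str] = {}
    for freq, child in zip(frequencies, child_seeds):
        try:
            atd_a, n_a = annual_threshold_deterioration(group_a, freq)
            atd_b, n_b = annual_threshold_deterioration(group_b, freq)
            cmp_ = compare_atd(group_a, group_b, freq, permutations, int(child))
        except (InsufficientDataError, DegenerateDataError) as exc:
            skipped[freq] = str(exc)
            logger.warning("skipping %d Hz: %s", freq, exc)
            continue
        rows.append(AtdRow(freq, atd_a, n_a, atd_b, n_b, cmp_))
    return AtdTable(rows=rows, permutations=permutations, seed=seed, skipped=skipped)
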