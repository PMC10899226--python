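"""Core audiogram data model and per-record summaries.

An :class:`AudiogramRecord` holds one subject's air-conduction thresholds
(dB HL) across the standard audiometric frequencies at a known age, tagged
with ear and mutation-domain group. Summaries built on it — the four-frequency
pure-tone average (PTA), frequency-band means, and WHO severity grading —
are the scalar responses that downstream threshold-vs-age regressions consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from statistics import fmean

from .exceptions import IncompleteAudiogramError, PairingError

logger = logging.getLogger("audioprofile")

#: Canonical audiometric test frequencies (Hz). 125 Hz is accepted on input
#: but referenced by no analysis (neither the PTA nor any band includes it).
CANONICAL_FREQUENCIES: tuple[int, ...] = (125, 250, 500, 1000, 2000, 4000, 8000)

#: Frequencies entering the four-frequency pure-tone average.
PTA_FREQUENCIES: tuple[int, ...] = (500, 1000, 2000, 4000)

THRESHOLD_MIN = -10.0
THRESHOLD_MAX = 120.0

VALID_EARS = frozenset({"left", "right", "binaural"})
VALID_GROUPS = frozenset({"TBC", "TLDc", "unknown"})


@dataclass(frozen=True)
class FrequencyBand:
    """A named, ordered set of audiometric frequencies (Hz)."""

    name: str
    members: tuple[int, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("band must have at least one member frequency")
        for f in self.members:
            if f not in CANONICAL_FREQUENCIES:
                raise ValueError(f"band member {f} Hz is not a canonical frequency")


LOW_BAND = FrequencyBand("low", (250, 500))
MID_BAND = FrequencyBand("mid", (1000, 2000))
HIGH_BAND = FrequencyBand("high", (4000, 8000))

#: The low/mid/high banding used throughout progressive-hearing-loss
#: audioprofiling: low (250, 500), mid (1000, 2000), high (4000, 8000) Hz.
DEFAULT_BANDS: tuple[FrequencyBand, ...] = (LOW_BAND, MID_BAND, HIGH_BAND)


@dataclass
class AudiogramRecord:
    """One subject's thresholds across frequencies at a single age.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    age
        Age in years at test time; must be positive.
    ear
        ``"left"``, ``"right"`` or ``"binaural"``.
    thresholds
        Mapping frequency (Hz, from the canonical set) to air-conduction
        threshold in dB HL, each within [-10, 120].
    group
        Mutation-domain group: ``"TBC"``, ``"TLDc"`` or ``"unknown"``.
    source
        Free-text provenance tag.
    """

    subject_id: str
    age: float
    ear: str
    thresholds: dict[int, float]
    group: str = "unknown"
    source: str = ""

    def __post_init__(self):
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.ear not in VALID_EARS:
            raise ValueError(f"ear must be one of {sorted(VALID_EARS)}, got {self.ear!r}")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {sorted(VALID_GROUPS)}, got {self.group!r}")
        for freq, thr in self.thresholds.items():
            if freq not in CANONICAL_FREQUENCIES:
                raise ValueError(f"frequency {freq} Hz not in canonical set {CANONICAL_FREQUENCIES}")
            if not (THRESHOLD_MIN <= thr <= THRESHOLD_MAX):
                raise ValueError(
                    f"threshold {thr} dB HL at {freq} Hz outside [{THRESHOLD_MIN}, {THRESHOLD_MAX}]"
                )

    def with_thresholds(self, thresholds: dict[int, float]) -> "AudiogramRecord":
        return replace(self, thresholds=dict(thresholds))


def binaural_average(left: AudiogramRecord, right: AudiogramRecord) -> AudiogramRecord:
    """Average left and right ears into one binaural record.

    At each frequency present in both ears the binaural threshold is the
    arithmetic mean. A frequency present in only one ear carries that ear's
    value, with a logged warning (single-ear fallback).
    """
    if left.subject_id != right.subject_id:
        raise PairingError(
            f"cannot pair ears of different subjects: {left.subject_id!r} vs {right.subject_id!r}"
        )
    if left.age != right.age:
        raise PairingError(
            f"subject {left.subject_id!r}: left/right ages differ ({left.age} vs {right.age})"
        )
    ears = {left.ear, right.ear}
    if ears != {"left", "right"}:
        raise PairingError(f"expected one left and one right ear, got {sorted(ears)}")

    merged: dict[int, float] = {}
    for freq in sorted(set(left.thresholds) | set(right.thresholds)):
        in_left = freq in left.thresholds
        in_right = freq in right.thresholds
        if in_left and in_right:
            merged[freq] = (left.thresholds[freq] + right.thresholds[freq]) / 2.0
        else:
            only = left if in_left else right
            merged[freq] = only.thresholds[freq]
            logger.warning(
                "subject %s: %d Hz present only in %s ear; using single-ear value",
                left.subject_id, freq, only.ear,
            )
    group = left.group if left.group != "unknown" else right.group
    return AudiogramRecord(
        subject_id=left.subject_id,
        age=left.age,
        ear="binaural",
        thresholds=merged,
        group=group,
        source=left.source or right.source,
    )


def compute_pta(record: AudiogramRecord) -> float:
    """Four-frequency pure-tone average: mean threshold over 500/1000/2000/4000 Hz.

    All four constituent frequencies must be present — the PTA is the
    regression response and must be comparable across subjects.
    """
    missing = [f for f in PTA_FREQUENCIES if f not in record.thresholds]
    if missing:
        raise IncompleteAudiogramError(
            f"subject {record.subject_id!r}: PTA requires frequencies "
            f"{list(PTA_FREQUENCIES)}; missing {missing}"
        )
    return fmean(record.thresholds[f] for f in PTA_FREQUENCIES)


def band_mean(record: AudiogramRecord, band: FrequencyBand) -> float:
    """Mean threshold over a band's member frequencies.

    A single missing member is tolerated (the remaining member's value is
    used, with a warning); a band with no member present is an error.
    """
    present = [f for f in band.members if f in record.thresholds]
    if not present:
        raise IncompleteAudiogramError(
            f"subject {record.subject_id!r}: no {band.name}-band frequency "
            f"{list(band.members)} present"
        )
    if len(present) < len(band.members):
        logger.warning(
            "subject %s: %s band has only %s of %s; using partial mean",
            record.subject_id, band.name, present, list(band.members),
        )
    return fmean(record.thresholds[f] for f in present)


#: WHO (1997) hearing-impairment grades by PTA, as (upper bound inclusive, grade).
WHO_1997_GRADES: tuple[tuple[float, str], ...] = (
    (25.0, "normal"),
    (40.0, "mild"),
    (60.0, "moderate"),
    (80.0, "severe"),
    (float("inf"), "profound"),
)


def classify_severity(
    pta: float, grades: tuple[tuple[float, str], ...] = WHO_1997_GRADES
) -> str:
    """Grade a pure-tone average against a cutoff table (WHO 1997 by default).

    Default grades: normal <= 25, mild 26-40, moderate 41-60, severe 61-80,
    profound >= 81 dB HL.
    """
    if not (THRESHOLD_MIN <= pta <= THRESHOLD_MAX):
        raise ValueError(f"PTA {pta} dB HL outside [{THRESHOLD_MIN}, {THRESHOLD_MAX}]")
    for upper, grade in grades:
        if pta <= upper:
            return grade
    raise ValueError("grade table does not cover the PTA range")  # pragma: no cover
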