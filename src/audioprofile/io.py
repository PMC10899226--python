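"""Delimited-text readers and writers for audiogram tables.

The on-disk format is long/tidy CSV, one row per (subject, ear, frequency):

    subject_id,age_years,ear,freq_hz,threshold_db,group[,source]

Rows for the same (subject, ear) are merged into one record's thresholds map.
A binaural record takes precedence over per-ear rows for the same subject;
per-ear rows alongside a binaural row are dropped with a warning so a subject
never counts twice.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .audiograms import AudiogramRecord, VALID_EARS, VALID_GROUPS
from .exceptions import ConflictError, ParseError, SchemaError

logger = logging.getLogger("audioprofile")

REQUIRED_COLUMNS = ("subject_id", "age_years", "ear", "freq_hz", "threshold_db", "group")
OPTIONAL_COLUMNS = ("source",)


def read_audiogram_table(path: str | Path) -> list[AudiogramRecord]:
    """Read a tidy audiogram CSV into a list of :class:`AudiogramRecord`.

    Raises
    ------
    SchemaError
        A required column is missing.
    ParseError
        A non-numeric age/threshold or an invalid ear/group label, reported
        with its row number (1-based, excluding the header).
    ConflictError
        Duplicate (subject, ear, frequency) rows with conflicting thresholds.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: header only, no data rows", path.name)
        return []

    has_source = "source" in df.columns
    # keyed by (subject_id, ear): [age, group, source, {freq: (threshold, row)}]
    partial: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            age = float(row.age_years)
            freq = int(float(row.freq_hz))
            thr = float(row.threshold_db)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path.name} row {i}: non-numeric field ({exc})") from exc
        ear = str(row.ear).strip()
        group = str(row.group).strip() or "unknown"
        if ear not in VALID_EARS:
            raise ParseError(f"{path.name} row {i}: invalid ear {ear!r}")
        if group not in VALID_GROUPS:
            raise ParseError(f"{path.name} row {i}: invalid group {group!r}")
        source = str(getattr(row, "source", "")) if has_source else ""

        key = (str(row.subject_id), ear)
        if key not in partial:
            partial[key] = [age, group, source, {}]
            order.append(key)
        entry = partial[key]
        if entry[0] != age:
            raise ConflictError(
                f"{path.name} row {i}: subject {key[0]!r} ({ear}) has conflicting ages "
                f"{entry[0]} vs {age}"
            )
        if freq in entry[3] and entry[3][freq][0] != thr:
            raise ConflictError(
                f"{path.name} row {i}: duplicate ({key[0]!r}, {ear}, {freq} Hz) with "
                f"conflicting thresholds {entry[3][freq][0]} vs {thr}"
            )
        entry[3][freq] = (thr, i)

    # binaural precedence: drop per-ear entries for subjects that also have binaural
    binaural_subjects = {sid for sid, ear in partial if ear == "binaural"}
    records: list[AudiogramRecord] = []
    for key in order:
        sid, ear = key
        if ear != "binaural" and sid in binaural_subjects:
            logger.warning(
                "%s: subject %r has a binaural record; dropping %s-ear rows to avoid "
                "double counting", path.name, sid, ear,
            )
            continue
        age, group, source, freqs = partial[key]
        thresholds = {f: v[0] for f, v in sorted(freqs.items())}
        try:
            records.append(
                AudiogramRecord(
                    subject_id=sid, age=age, ear=ear,
                    thresholds=thresholds, group=group, source=source,
                )
            )
        except ValueError as exc:
            rows = sorted(v[1] for v in freqs.values())
            logger.warning(
                "%s: rejecting subject %r (%s ear, rows %s): %s",
                path.name, sid, ear, rows, exc,
            )
    return records


def write_audiogram_table(records: list[AudiogramRecord], path: str | Path) -> None:
    """Write records to the tidy CSV format read by :func:`read_audiogram_table`."""
    rows = []
    for rec in records:
        for freq in sorted(rec.thresholds):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "age_years": rec.age,
                    "ear": rec.ear,
                    "freq_hz": freq,
                    "threshold_db": rec.thresholds[freq],
                    "group": rec.group,
                    "source": rec.source,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)).to_csv(
        path, index=False
    )
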