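"""Reading and writing the tidy annotation and result tables.

The annotation table has one row per spine with columns::

    animal_id, group, segment_id, segment_length_um, spine_id,
    position_um, dist_plaque_um, present_<label> ...

Comma-separated by default; tab-separated files are auto-detected.
Lines starting with ``#`` carry metadata (e.g. the generator seed) and
are ignored by the parser.  An empty ``dist_plaque_um`` cell means the
distance is missing (plaque-free dataset), never zero.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DynamicEvent,
    EventKind,
    SegmentDataset,
    SessionAxis,
    SpineTimeline,
    StudyDataset,
    Zone,
    nan_to_none,
)


class SchemaError(ValueError):
    """A mandatory column is missing or malformed."""


class IntegrityError(ValueError):
    """Duplicate identifiers or inconsistent segment metadata."""


class RangeError(ValueError):
    """A numeric value violates its allowed range."""


_BASE_COLUMNS = [
    "animal_id", "group", "segment_id", "segment_length_um",
    "spine_id", "position_um", "dist_plaque_um",
]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_flag(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if float(value) in (0.0, 1.0):
            return bool(value)
        raise SchemaError(f"row {row}: presence flag {column}={value!r} is not 0/1")
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"row {row}: presence flag {column}={value!r} not understood")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return ","


def read_spine_table(path: str | Path, sessions: Optional[SessionAxis | Sequence[str]] = None) -> StudyDataset:
    """Parse an annotation CSV/TSV into a validated :class:`StudyDataset`.

    ``sessions`` may be a :class:`SessionAxis`, a sequence of labels, or
    ``None`` to infer the axis from the ``present_*`` column order.
    Row order in the file does not affect the result (canonical sort by
    animal, segment, spine).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", float_precision="round_trip",
                     dtype={"animal_id": str, "group": str, "segment_id": str, "spine_id": str})
    for col in _BASE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    present_cols = [c for c in df.columns if c.startswith("present_")]
    if sessions is None:
        if len(present_cols) < 2:
            raise SchemaError("need at least two present_<label> columns")
        axis = SessionAxis(tuple(c[len("present_"):] for c in present_cols))
    else:
        axis = sessions if isinstance(sessions, SessionAxis) else SessionAxis(tuple(sessions))
        for lab in axis.labels:
            if f"present_{lab}" not in df.columns:
                raise SchemaError(f"missing mandatory column 'present_{lab}'")

    segments: dict[tuple[str, str], SegmentDataset] = {}
    seen_spines: set[tuple[str, str]] = set()
    for row_idx, row in df.iterrows():
        seg_key = (str(row["animal_id"]), str(row["segment_id"]))
        length = float(row["segment_length_um"])
        if seg_key not in segments:
            segments[seg_key] = SegmentDataset(
                segment_id=seg_key[1], animal_id=seg_key[0],
                group=str(row["group"]), length_um=length,
                spines=[], sessions=axis,
            )
        seg = segments[seg_key]
        if abs(seg.length_um - length) > 1e-9:
            raise IntegrityError(
                f"row {row_idx}: segment {seg_key[1]} has inconsistent lengths "
                f"({seg.length_um} vs {length})")
        spine_key = (seg_key[1], str(row["spine_id"]))
        if spine_key in seen_spines:
            raise IntegrityError(f"row {row_idx}: duplicate spine {spine_key[1]!r} in segment {spine_key[0]!r}")
        seen_spines.add(spine_key)
        pos = float(row["position_um"])
        if not (0.0 <= pos <= length):
            raise RangeError(
                f"row {row_idx}: spine {spine_key[1]!r} at position {pos} um outside "
                f"[0, {length}] um of segment {spine_key[0]!r}")
        presence = tuple(
            _parse_flag(row[f"present_{lab}"], f"present_{lab}", int(row_idx))
            for lab in axis.labels
        )
        seg.spines.append(SpineTimeline(
            spine_id=str(row["spine_id"]), segment_id=seg_key[1],
            position_um=pos, dist_plaque_um=nan_to_none(row["dist_plaque_um"]),
            presence=presence,
        ))

    study = StudyDataset(segments=list(segments.values()), sessions=axis)
    study.sort_canonical()
    return study


def write_spine_table(study: StudyDataset, path: str | Path, metadata: Optional[dict] = None) -> None:
    """Write the annotation table; ``metadata`` becomes ``# key=value`` header lines."""
    path = Path(path)
    rows = []
    for seg in study.segments:
        for sp in seg.spines:
            # repr() keeps float positions exact across the round trip
            row = {
                "animal_id": seg.animal_id, "group": seg.group,
                "segment_id": seg.segment_id, "segment_length_um": repr(seg.length_um),
                "spine_id": sp.spine_id, "position_um": repr(sp.position_um),
                "dist_plaque_um": "" if sp.dist_plaque_um is None else repr(sp.dist_plaque_um),
            }
            for lab, p in zip(study.sessions.labels, sp.presence):
                row[f"present_{lab}"] = int(p)
            rows.append(row)
    cols = _BASE_COLUMNS + [f"present_{lab}" for lab in study.sessions.labels]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


EVENT_COLUMNS = [
    "animal_id", "segment_id", "spine_id", "interval", "interval_label",
    "kind", "position_um", "dist_plaque_um", "zone", "nn_event_dist_um", "cohort",
]


def write_events_table(events: Iterable[DynamicEvent], path: str | Path) -> None:
    """One row per dynamic event, fixed column order; lossless round trip."""
    rows = []
    for ev in events:
        rows.append({
            "animal_id": ev.animal_id, "segment_id": ev.segment_id,
            "spine_id": ev.spine_id, "interval": ev.interval,
            "interval_label": ev.interval_label, "kind": ev.kind.value,
            "position_um": ev.position_um,
            "dist_plaque_um": "" if ev.dist_plaque_um is None else ev.dist_plaque_um,
            "zone": ev.zone.value,
            "nn_event_dist_um": "" if ev.nn_event_dist_um is None else ev.nn_event_dist_um,
            "cohort": "" if ev.cohort is None else ev.cohort,
        })
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_table(path: str | Path) -> list[DynamicEvent]:
    df = pd.read_csv(path, dtype={"animal_id": str, "segment_id": str, "spine_id": str, "cohort": str})
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    events = []
    for _, row in df.iterrows():
        cohort = row["cohort"]
        events.append(DynamicEvent(
            segment_id=str(row["segment_id"]), animal_id=str(row["animal_id"]),
            spine_id=str(row["spine_id"]), interval=int(row["interval"]),
            interval_label=str(row["interval_label"]), kind=EventKind(row["kind"]),
            position_um=float(row["position_um"]),
            dist_plaque_um=nan_to_none(row["dist_plaque_um"]),
            zone=Zone(row["zone"]),
            nn_event_dist_um=nan_to_none(row["nn_event_dist_um"]),
            cohort=None if (cohort is None or (isinstance(cohort, float) and np.isnan(cohort)) or str(cohort) == "" or str(cohort) == "nan") else str(cohort),
        ))
    return events


def validate_dataset(study: StudyDataset) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    violations: list[str] = []
    axis = study.sessions
    if axis.count < 2:
        violations.append("session axis: fewer than 2 sessions")
    seen_pairs: set[tuple[str, str]] = set()
    for seg in study.segments:
        tag = f"segment {seg.segment_id} (animal {seg.animal_id})"
        pair = (seg.animal_id, seg.segment_id)
        if pair in seen_pairs:
            violations.append(f"{tag}: duplicate (animal_id, segment_id) pair")
        seen_pairs.add(pair)
        if seg.sessions is not axis and seg.sessions.labels != axis.labels:
            violations.append(f"{tag}: session axis differs from the study's")
        if seg.length_um <= 0:
            violations.append(f"{tag}: non-positive length")
        seen_ids: set[str] = set()
        for sp in seg.spines:
            stag = f"{tag}, spine {sp.spine_id}"
            if sp.spine_id in seen_ids:
                violations.append(f"{stag}: duplicate spine_id")
            seen_ids.add(sp.spine_id)
            if sp.segment_id != seg.segment_id:
                violations.append(f"{stag}: segment_id mismatch")
            if not (0.0 <= sp.position_um <= seg.length_um):
                violations.append(f"{stag}: position {sp.position_um} um outside [0, {seg.length_um}]")
            if len(sp.presence) != axis.count:
                violations.append(f"{stag}: presence vector length != number of sessions")
            elif not any(sp.presence):
                violations.append(f"{stag}: presence vector is all-false")
            if sp.dist_plaque_um is not None and sp.dist_plaque_um < 0:
                violations.append(f"{stag}: negative plaque distance")
    return violations
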