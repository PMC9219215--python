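"""Spine fate classification and turnover/survival/zone summaries.

Between two consecutive imaging sessions a spine is *formed* (absent
then present), *eliminated* (present then absent), or a survivor.
Survivors split into *survived_new* — the spine first appeared at the
interval's start session, i.e. was formed in the immediately preceding
interval — and *survived_old* otherwise.  Formation and elimination
rates are expressed as % of the spines present at the interval's first
session.  Events are stratified by the spine's pre-measured distance to
the nearest amyloid-plaque edge into proximal (< 25 um), intermediate
(25-60 um) and distal (> 100 um) zones.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import (
    DynamicEvent,
    EventKind,
    FORMATION_KINDS,
    SegmentDataset,
    StudyDataset,
    TurnoverSummary,
    Zone,
)


def assign_zone(
    dist_plaque_um: Optional[float],
    zone_bounds_um: Sequence[float] = (25.0, 60.0, 100.0),
    missing_to_distal: bool = False,
) -> Zone:
    """Map a plaque distance (um) onto its zone.

    ``< b0`` proximal, ``[b0, b1]`` intermediate (bounds inclusive),
    ``(b1, b2]`` unassigned, ``> b2`` distal.  A missing distance maps
    to ``NO_PLAQUE`` (or to distal when ``missing_to_distal``).
    """
    if dist_plaque_um is None:
        return Zone.DISTAL if missing_to_distal else Zone.NO_PLAQUE
    d = float(dist_plaque_um)
    if d < 0:
        raise ValueError(f"plaque distance must be >= 0, got {d}")
    b0, b1, b2 = zone_bounds_um
    if d < b0:
        return Zone.PROXIMAL
    if d <= b1:
        return Zone.INTERMEDIATE
    if d <= b2:
        return Zone.UNASSIGNED_60_100
    return Zone.DISTAL


def assign_zone_2bin(dist_plaque_um: Optional[float], bound_um: float = 25.0) -> str:
    """Secondary two-bin scheme: ``<25um`` vs ``>25um`` (missing -> ``>25um``)."""
    if dist_plaque_um is None or dist_plaque_um >= bound_um:
        return f">{bound_um:g}um"
    return f"<{bound_um:g}um"


def classify_interval_events(
    seg: SegmentDataset,
    interval: int,
    cfg: AnalysisConfig | None = None,
) -> list[DynamicEvent]:
    """Classify every spine of ``seg`` over interval (session i, i+1).

    Restoration vs de-novo re-labelling of formed events is done
    separately by the restoration module.
    """
    cfg = cfg or AnalysisConfig()
    if not (0 <= interval < seg.sessions.n_intervals):
        raise IndexError(f"interval {interval} out of range for {seg.sessions.count} sessions")
    label = seg.sessions.interval_label(interval)
    events: list[DynamicEvent] = []
    for sp in seg.spines:
        p1, p2 = sp.presence[interval], sp.presence[interval + 1]
        if not p1 and not p2:
            continue
        if p1:
            cohort = "new" if sp.is_new_at(interval) else "old"
            kind = (EventKind.SURVIVED_NEW if p2 and cohort == "new"
                    else EventKind.SURVIVED_OLD if p2
                    else EventKind.ELIMINATED)
        else:
            cohort = None
            kind = EventKind.FORMED
        events.append(DynamicEvent(
            segment_id=seg.segment_id, animal_id=seg.animal_id,
            spine_id=sp.spine_id, interval=interval, interval_label=label,
            kind=kind, position_um=sp.position_um,
            dist_plaque_um=sp.dist_plaque_um,
            zone=assign_zone(sp.dist_plaque_um, cfg.zone_bounds_um),
            cohort=cohort,
        ))
    _fill_nn_distances(events)
    return events


def _fill_nn_distances(events: list[DynamicEvent]) -> None:
    """Distance to the nearest same-kind event in the same segment+interval."""
    by_kind: dict[EventKind, list[DynamicEvent]] = {}
    for ev in events:
        by_kind.setdefault(ev.kind, []).append(ev)
    for group in by_kind.values():
        if len(group) < 2:
            for ev in group:
                ev.nn_event_dist_um = None
            continue
        pos = np.array([ev.position_um for ev in group])
        for i, ev in enumerate(group):
            d = np.abs(pos - pos[i])
            d[i] = np.inf
            ev.nn_event_dist_um = float(d.min())


def classify_study_events(study: StudyDataset, cfg: AnalysisConfig | None = None) -> list[DynamicEvent]:
    """All dynamic events of all segments over all intervals."""
    cfg = cfg or AnalysisConfig()
    events: list[DynamicEvent] = []
    for seg in study.segments:
        for i in range(study.sessions.n_intervals):
            events.extend(classify_interval_events(seg, i, cfg))
    return events


def _is_formation(kind: EventKind) -> bool:
    return kind in FORMATION_KINDS


def turnover_summary(
    events: Sequence[DynamicEvent],
    n_start: int,
    unit: str = "segment",
    unit_id: str = "",
) -> TurnoverSummary:
    """Turnover rates for one segment (or pooled unit) over one interval.

    ``n_start`` is the number of spines present at the interval's first
    session.  With ``n_start == 0`` the rates are flagged ``None``
    rather than reported as 0.
    """
    if events:
        interval = events[0].interval
        interval_label = events[0].interval_label
    else:
        interval, interval_label = -1, ""
    n_formed = sum(_is_formation(ev.kind) for ev in events)
    n_elim = sum(ev.kind is EventKind.ELIMINATED for ev in events)
    n_old = sum(ev.cohort == "old" for ev in events)
    n_old_survived = sum(ev.kind is EventKind.SURVIVED_OLD for ev in events)
    n_new = sum(ev.cohort == "new" for ev in events)
    n_new_survived = sum(ev.kind is EventKind.SURVIVED_NEW for ev in events)
    if n_start > 0:
        formation_pct = 100.0 * n_formed / n_start
        elimination_pct = 100.0 * n_elim / n_start
    else:
        formation_pct = elimination_pct = None
    return TurnoverSummary(
        unit=unit, unit_id=unit_id, interval=interval, interval_label=interval_label,
        n_start=n_start, n_formed=n_formed, n_eliminated=n_elim,
        formation_pct=formation_pct, elimination_pct=elimination_pct,
        form_elim_ratio=(n_formed / n_elim) if n_elim > 0 else None,
        survival_old=(n_old_survived / n_old) if n_old > 0 else None,
        survival_new=(n_new_survived / n_new) if n_new > 0 else None,
    )


def survival_fraction(seg: SegmentDataset, cohort: str, interval: int) -> Optional[float]:
    """Fraction of a spine cohort surviving interval (i, i+1).

    ``cohort="pre_existing"``: spines present at session i; ``"new"``:
    spines first formed in the preceding interval (first present at
    session i, which requires i >= 1 hence >= 3 sessions).  Returns
    ``None`` when the cohort is empty.
    """
    if cohort not in ("pre_existing", "new"):
        raise ValueError("cohort must be 'pre_existing' or 'new'")
    if not (0 <= interval < seg.sessions.n_intervals):
        raise IndexError(f"interval {interval} out of range")
    if cohort == "new":
        if interval < 1:
            raise ValueError("cohort='new' needs a preceding interval (>= 3 sessions)")
        members = [sp for sp in seg.spines if sp.presence[interval] and sp.is_new_at(interval)]
    else:
        members = [sp for sp in seg.spines if sp.presence[interval]]
    if not members:
        return None
    return sum(sp.presence[interval + 1] for sp in members) / len(members)


def turnover_table(study: StudyDataset, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Tidy per-segment and per-animal turnover rates.

    Animal-level rows are the unweighted mean of the animal's segment
    rates ("averaged per animal"); spine-count weighting is available
    via ``cfg.weight_animal_mean_by_spines``.
    """
    cfg = cfg or AnalysisConfig()
    rows: list[dict] = []
    for seg in study.segments:
        for i in range(study.sessions.n_intervals):
            ev = classify_interval_events(seg, i, cfg)
            ts = turnover_summary(ev, seg.n_present(i), "segment", seg.segment_id)
            rows.append({
                "unit": "segment", "unit_id": seg.segment_id, "animal_id": seg.animal_id,
                "group": seg.group, "interval": i,
                "interval_label": study.sessions.interval_label(i),
                "n_start": ts.n_start, "n_formed": ts.n_formed,
                "n_eliminated": ts.n_eliminated, "formation_pct": ts.formation_pct,
                "elimination_pct": ts.elimination_pct, "form_elim_ratio": ts.form_elim_ratio,
                "survival_old": ts.survival_old, "survival_new": ts.survival_new,
            })
    df = pd.DataFrame(rows)
    animal_rows: list[dict] = []
    for (animal, interval), sub in df.groupby(["animal_id", "interval"], sort=True):
        weights = sub["n_start"].to_numpy(float) if cfg.weight_animal_mean_by_spines else None

        def wmean(col: str) -> Optional[float]:
            vals = sub[col].to_numpy(float)
            mask = ~np.isnan(vals)
            if not mask.any():
                return None
            if weights is None:
                return float(vals[mask].mean())
            w = weights[mask]
            return float(np.average(vals[mask], weights=w)) if w.sum() > 0 else None

        animal_rows.append({
            "unit": "animal", "unit_id": animal, "animal_id": animal,
            "group": sub["group"].iloc[0], "interval": interval,
            "interval_label": sub["interval_label"].iloc[0],
            "n_start": int(sub["n_start"].sum()), "n_formed": int(sub["n_formed"].sum()),
            "n_eliminated": int(sub["n_eliminated"].sum()),
            "formation_pct": wmean("formation_pct"),
            "elimination_pct": wmean("elimination_pct"),
            "form_elim_ratio": wmean("form_elim_ratio"),
            "survival_old": wmean("survival_old"), "survival_new": wmean("survival_new"),
        })
    return pd.concat([df, pd.DataFrame(animal_rows)], ignore_index=True)


def survival_table(study: StudyDataset, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-segment survival fractions of pre-existing and new cohorts,
    overall and split by the two-bin plaque scheme (<25 um vs >25 um)."""
    cfg = cfg or AnalysisConfig()
    bound = cfg.zone_bounds_um[0]
    rows: list[dict] = []
    for seg in study.segments:
        for i in range(study.sessions.n_intervals):
            for cohort in ("pre_existing", "new"):
                if cohort == "new" and i < 1:
                    continue
                members = [
                    sp for sp in seg.spines
                    if sp.presence[i] and (sp.is_new_at(i) if cohort == "new" else True)
                ]
                for bin_label in ("all", f"<{bound:g}um", f">{bound:g}um"):
                    if bin_label == "all":
                        sub = members
                    else:
                        sub = [sp for sp in members if assign_zone_2bin(sp.dist_plaque_um, bound) == bin_label]
                    rows.append({
                        "animal_id": seg.animal_id, "segment_id": seg.segment_id,
                        "group": seg.group, "interval": i,
                        "interval_label": study.sessions.interval_label(i),
                        "cohort": cohort, "plaque_bin": bin_label, "n": len(sub),
                        "survival": (sum(sp.presence[i + 1] for sp in sub) / len(sub)) if sub else None,
                    })
    return pd.DataFrame(rows)


def dendrospinogram_table(events: Sequence[DynamicEvent]) -> pd.DataFrame:
    """One row per dynamic event, keyed by plaque distance and nearest
    same-kind event distance — the data behind the plaque-centred radial
    event map."""
    rows = [{
        "animal_id": ev.animal_id, "segment_id": ev.segment_id,
        "spine_id": ev.spine_id, "interval": ev.interval,
        "interval_label": ev.interval_label, "kind": ev.kind.value,
        "position_um": ev.position_um, "dist_plaque_um": ev.dist_plaque_um,
        "zone": ev.zone.value, "nn_event_dist_um": ev.nn_event_dist_um,
    } for ev in events]
    df = pd.DataFrame(rows, columns=[
        "animal_id", "segment_id", "spine_id", "interval", "interval_label",
        "kind", "position_um", "dist_plaque_um", "zone", "nn_event_dist_um",
    ])
    if len(df) and df["dist_plaque_um"].isna().all():
        warnings.warn("no plaque distances in dataset; dendrospinogram is empty", stacklevel=2)
        return df.iloc[0:0]
    return df
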