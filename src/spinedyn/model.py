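"""Domain types for longitudinal dendritic-spine annotation data.

The unit of observation is a dendritic spine followed across repeated
imaging sessions of the same dendritic segment.  A spine is described by
its arc-length position along the dendritic shaft (measured from the
segment's proximal end, in micrometres), an optional pre-measured 3-D
distance to the edge of the nearest amyloid plaque, and a boolean
presence flag per session.  All inter-spine distances used downstream
are absolute differences of arc length, never straight-line distances.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple


class Zone(str, enum.Enum):
    """Plaque-distance zones used to stratify dynamic events.

    Proximal (< 25 um), intermediate (25-60 um, bounds inclusive) and
    distal (> 100 um) are the conventional strata of plaque-distance
    analyses; 60-100 um falls in none of the named zones and is kept as
    its own category instead of being merged.  ``NO_PLAQUE`` marks events without a plaque distance
    (plaque-free genotypes).
    """

    PROXIMAL = "proximal"
    INTERMEDIATE = "intermediate"
    UNASSIGNED_60_100 = "unassigned_60_100"
    DISTAL = "distal"
    NO_PLAQUE = "no_plaque"


class EventKind(str, enum.Enum):
    """Fate of a spine over one inter-session interval."""

    FORMED = "formed"
    ELIMINATED = "eliminated"
    SURVIVED_OLD = "survived_old"
    SURVIVED_NEW = "survived_new"
    RESTORED = "restored"   # formed event re-labelled: < 2 um from a lost spine
    DE_NOVO = "de_novo"     # formed event re-labelled: not a restoration


class Verdict(str, enum.Enum):
    CLUSTERED_ABOVE_CHANCE = "clustered_above_chance"
    ABOVE_CHANCE = "above_chance"       # used by the restoration test
    RANDOM = "random"
    BELOW_CHANCE = "below_chance"


FORMATION_KINDS = frozenset({EventKind.FORMED, EventKind.RESTORED, EventKind.DE_NOVO})


@dataclass(frozen=True)
class SessionAxis:
    """Ordered imaging sessions (temporal order, unique labels)."""

    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) < 2:
            raise ValueError("a session axis needs at least 2 sessions")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("session labels must be unique")

    @property
    def count(self) -> int:
        return len(self.labels)

    @property
    def n_intervals(self) -> int:
        return len(self.labels) - 1

    def interval_label(self, i: int) -> str:
        return f"{self.labels[i]}->{self.labels[i + 1]}"


@dataclass
class SpineTimeline:
    """One spine's identity, position and per-session presence."""

    spine_id: str
    segment_id: str
    position_um: float
    dist_plaque_um: Optional[float]
    presence: Tuple[bool, ...]

    def __post_init__(self) -> None:
        self.presence = tuple(bool(p) for p in self.presence)

    def first_present(self) -> int:
        """Index of the first session at which the spine is present."""
        return self.presence.index(True)

    def is_new_at(self, session: int) -> bool:
        """True if the spine first appeared at ``session`` (i.e. was formed
        in the immediately preceding interval)."""
        return session >= 1 and self.first_present() == session


@dataclass
class SegmentDataset:
    """All spine timelines of one dendritic segment."""

    segment_id: str
    animal_id: str
    group: str
    length_um: float
    spines: list[SpineTimeline]
    sessions: SessionAxis

    def present_at(self, session: int) -> list[SpineTimeline]:
        return [s for s in self.spines if s.presence[session]]

    def n_present(self, session: int) -> int:
        return sum(s.presence[session] for s in self.spines)


@dataclass
class StudyDataset:
    """Segments from all animals of a study, sharing one session axis."""

    segments: list[SegmentDataset]
    sessions: SessionAxis

    def __iter__(self) -> Iterator[SegmentDataset]:
        return iter(self.segments)

    @property
    def animal_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.animal_id, None)
        return list(seen)

    def segments_of(self, animal_id: str) -> list[SegmentDataset]:
        return [s for s in self.segments if s.animal_id == animal_id]

    def sort_canonical(self) -> None:
        """Canonical order: (animal_id, segment_id, spine_id)."""
        self.segments.sort(key=lambda s: (s.animal_id, s.segment_id))
        for seg in self.segments:
            seg.spines.sort(key=lambda s: s.spine_id)


@dataclass
class DynamicEvent:
    """A classified spine fate on one inter-session interval."""

    segment_id: str
    animal_id: str
    spine_id: str
    interval: int                       # index i for interval (session i, session i+1)
    interval_label: str
    kind: EventKind
    position_um: float
    dist_plaque_um: Optional[float]
    zone: Zone
    nn_event_dist_um: Optional[float] = None   # nearest same-kind event, same segment+interval
    cohort: Optional[str] = None               # "old"/"new" for spines present at interval start


@dataclass
class TurnoverSummary:
    """Per-segment (or per-animal) turnover rates over one interval.

    Rates use the number of spines present at the interval's first
    session as denominator.  ``form_elim_ratio`` is ``None`` (flagged)
    when no eliminations occurred; survival fractions are ``None`` when
    the corresponding cohort is empty.
    """

    unit: str                 # "segment" or "animal"
    unit_id: str
    interval: int
    interval_label: str
    n_start: int
    n_formed: int
    n_eliminated: int
    formation_pct: Optional[float]
    elimination_pct: Optional[float]
    form_elim_ratio: Optional[float]
    survival_old: Optional[float]
    survival_new: Optional[float]


@dataclass
class ClusterTestResult:
    """Observed clustered proportion versus the randomized-placement null."""

    kind: EventKind
    observed_prop: float
    null_mean: float
    null_sd: float
    null_sem: float
    ci_low: float
    ci_high: float
    z: float
    p_two_tailed: float
    n_perm: int
    n_dynamic: int
    n_candidates: int
    verdict: Verdict
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.null_mean <= self.ci_high):
            raise ValueError("confidence interval must bracket the null mean")


@dataclass
class RestorationResult:
    """Observed restored proportion versus the random re-placement null."""

    n_lost: int
    n_reappeared: int
    n_restored: int
    n_de_novo: int
    observed_restored_prop: float
    null_mean: float
    null_sd: float
    null_sem: float
    ci_low: float
    ci_high: float
    z: float
    n_perm: int
    verdict: Verdict
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_restored + self.n_de_novo != self.n_reappeared:
            raise ValueError("restored + de novo must equal reappeared")


def nan_to_none(x: float) -> Optional[float]:
    """Map NaN (pandas missing) to None; keep numbers as floats."""
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else x
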