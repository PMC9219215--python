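"""Dynamic-spine clustering and its randomized-placement null.

Two or more same-type dynamic events (formations or eliminations)
chained at <= 5 um arc-length spacing form a dynamic cluster; the
clustered proportion is the number of events belonging to any cluster
divided by all events of that type in the interval.

The chance level of that proportion is obtained by a randomized
placement: one dynamic event (the anchor) keeps its observed position
while every other dynamic event of the segment is re-assigned uniformly
at random, without replacement, to the positions of spines observed on
the segment at either session of the interval.  The anchor rotates
across the dynamic events replicate by replicate.  Replicate values are
summarized by a Gaussian fit (mean, SD, SEM = SD/sqrt(n)); the 99.9%
interval is mean +/- z_{0.9995} * SD and the verdict compares the
observed proportion with that interval (two-sided, ties conservatively
called random).

A single short segment carries too few events for this test ever to
leave the null band (the proportion is capped at 1 while the band's
upper limit typically exceeds 1), so the test is also exposed pooled
across all segments of an animal: events are re-placed within their own
segment but the proportion is computed over the animal's events.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .model import ClusterTestResult, DynamicEvent, EventKind, Verdict, Zone
from .dynamics import classify_interval_events

logger = logging.getLogger(__name__)


def detect_clusters(
    positions: Sequence[float],
    window_um: float = 5.0,
    min_size: int = 2,
) -> list[list[int]]:
    """Maximal chains of event indices with consecutive spacing <= window.

    ``positions`` are arc-length positions of same-type events from one
    segment and interval.  Returns index lists into ``positions``;
    chains shorter than ``min_size`` are dropped.
    """
    order = np.argsort(np.asarray(positions, dtype=float), kind="stable")
    pos = np.asarray(positions, dtype=float)[order]
    clusters: list[list[int]] = []
    current: list[int] = []
    for k, idx in enumerate(order):
        if current and pos[k] - pos[k - 1] > window_um:
            if len(current) >= min_size:
                clusters.append(current)
            current = []
        current.append(int(idx))
    if len(current) >= min_size:
        clusters.append(current)
    return clusters


def clustered_proportion(
    positions: Sequence[float],
    clusters: Optional[list[list[int]]] = None,
    window_um: float = 5.0,
    min_size: int = 2,
) -> float:
    """|events in any cluster| / |events|; 0.0 for empty input."""
    n = len(positions)
    if n == 0:
        return 0.0
    if clusters is None:
        clusters = detect_clusters(positions, window_um, min_size)
    return sum(len(c) for c in clusters) / n


def events_of_kind(events: Sequence[DynamicEvent], kind: EventKind) -> list[DynamicEvent]:
    if kind is EventKind.FORMED:
        wanted = {EventKind.FORMED, EventKind.RESTORED, EventKind.DE_NOVO}
    else:
        wanted = {kind}
    return [ev for ev in events if ev.kind in wanted]


# ---------------------------------------------------------------------------
# permutation machinery

def _clustered_counts_rows(pos: np.ndarray, window_um: float, min_size: int) -> np.ndarray:
    """Count clustered events per row of a (reps, n_ev) position matrix."""
    pos = np.sort(pos, axis=1)
    linked = np.diff(pos, axis=1) <= window_um
    if min_size == 2:
        member = np.zeros(pos.shape, dtype=bool)
        member[:, :-1] |= linked
        member[:, 1:] |= linked
        return member.sum(axis=1)
    # generic chain-length path for min_size > 2
    counts = np.empty(pos.shape[0], dtype=np.int64)
    for r in range(pos.shape[0]):
        run, total = 1, 0
        for gap_ok in linked[r]:
            if gap_ok:
                run += 1
            else:
                if run >= min_size:
                    total += run
                run = 1
        if run >= min_size:
            total += run
        counts[r] = total
    return counts


def _replicate_positions(
    observed_idx: np.ndarray,
    candidates: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null placements: (n_perm, n_ev) positions, anchor rotating.

    Replicate r keeps event ``r mod n_ev`` at its observed candidate
    position and re-assigns the others uniformly without replacement
    among the remaining candidate positions.
    """
    n_ev = len(observed_idx)
    n_cand = len(candidates)
    anchor_idx = observed_idx[np.arange(n_perm) % n_ev]
    keys = rng.random((n_perm, n_cand))
    keys[np.arange(n_perm), anchor_idx] = np.inf   # anchor's site excluded for the others
    chosen = np.argpartition(keys, n_ev - 1, axis=1)[:, : n_ev - 1]
    out = np.empty((n_perm, n_ev), dtype=float)
    out[:, 0] = candidates[anchor_idx]
    out[:, 1:] = candidates[chosen]
    return out


def _gaussian_summary(values: np.ndarray, observed: float, ci_level: float,
                      kind: EventKind, n_dynamic: int, n_candidates: int,
                      n_perm: int, seed: Optional[int]) -> ClusterTestResult:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    sem = sd / math.sqrt(len(values)) if len(values) else 0.0
    zq = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    ci_low, ci_high = mean - zq * sd, mean + zq * sd
    if sd > 0:
        z = (observed - mean) / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z = 0.0 if observed == mean else math.copysign(math.inf, observed - mean)
        p = 1.0 if observed == mean else 0.0
    if observed > ci_high:
        verdict = Verdict.CLUSTERED_ABOVE_CHANCE
    elif observed < ci_low:
        verdict = Verdict.BELOW_CHANCE
    else:
        verdict = Verdict.RANDOM          # ties with a bound are conservative
    return ClusterTestResult(
        kind=kind, observed_prop=observed, null_mean=mean, null_sd=sd,
        null_sem=sem, ci_low=ci_low, ci_high=ci_high, z=z, p_two_tailed=p,
        n_perm=n_perm, n_dynamic=n_dynamic, n_candidates=n_candidates,
        verdict=verdict, seed=seed,
    )


def permutation_null(
    event_positions: Sequence[float],
    candidate_positions: Sequence[float],
    n_perm: int = 30_000,
    seed: int = 0,
    window_um: float = 5.0,
    min_size: int = 2,
    ci_level: float = 0.999,
    kind: EventKind = EventKind.FORMED,
) -> Optional[ClusterTestResult]:
    """Monte-Carlo null of the clustered proportion for one segment.

    ``candidate_positions`` are the positions of all spines observed on
    the segment at either session of the interval; the observed event
    positions must be among them.  Returns ``None`` (test undefined)
    for fewer than two dynamic events.
    """
    ev_pos = np.asarray(event_positions, dtype=float)
    cand = np.asarray(candidate_positions, dtype=float)
    n_ev = len(ev_pos)
    if n_ev < 2:
        logger.info("permutation_null skipped: %d dynamic event(s) < 2", n_ev)
        return None
    if len(cand) < n_ev:
        raise ValueError(f"{len(cand)} candidate positions < {n_ev} dynamic events")
    obs_idx = _match_candidate_indices(ev_pos, cand)
    rng = np.random.default_rng(seed)
    placements = _replicate_positions(obs_idx, cand, n_perm, rng)
    counts = _clustered_counts_rows(placements, window_um, min_size)
    values = counts / n_ev
    observed = clustered_proportion(ev_pos, window_um=window_um, min_size=min_size)
    return _gaussian_summary(values, observed, ci_level, kind, n_ev, len(cand), n_perm, seed)


def _match_candidate_indices(event_positions: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Index of each observed event position among the candidates."""
    idx = np.empty(len(event_positions), dtype=np.int64)
    used: set[int] = set()
    for i, p in enumerate(event_positions):
        d = np.abs(candidates - p)
        for j in np.argsort(d, kind="stable"):
            if int(j) not in used:
                if d[j] > 1e-6:
                    raise ValueError(f"event position {p} not among candidate positions")
                idx[i] = int(j)
                used.add(int(j))
                break
    return idx


def pooled_permutation_null(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]],
    n_perm: int = 30_000,
    seed: int = 0,
    window_um: float = 5.0,
    min_size: int = 2,
    ci_level: float = 0.999,
    kind: EventKind = EventKind.FORMED,
) -> Optional[ClusterTestResult]:
    """Cluster test pooled over several segments of one animal.

    Each group is ``(event_positions, candidate_positions)`` of one
    segment; re-placement happens within segments (clusters never span
    segments) while the clustered proportion is computed over all
    events.  Groups with a single event contribute that event to the
    denominator but are not permuted (a lone event is never clustered).
    """
    groups = [(np.asarray(e, float), np.asarray(c, float)) for e, c in groups if len(e) > 0]
    n_total = sum(len(e) for e, _ in groups)
    active = [(e, c) for e, c in groups if len(e) >= 2]
    if n_total < 2 or not active:
        logger.info("pooled test skipped: insufficient dynamic events")
        return None
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_perm, dtype=np.int64)
    observed_count = 0.0
    for ev_pos, cand in groups:
        obs_clusters = detect_clusters(ev_pos, window_um, min_size)
        observed_count += sum(len(c) for c in obs_clusters)
        if len(ev_pos) < 2:
            continue
        if len(cand) < len(ev_pos):
            raise ValueError("candidate positions fewer than dynamic events in a segment")
        obs_idx = _match_candidate_indices(ev_pos, cand)
        placements = _replicate_positions(obs_idx, cand, n_perm, rng)
        counts += _clustered_counts_rows(placements, window_um, min_size)
    values = counts / n_total
    observed = observed_count / n_total
    n_cand_total = sum(len(c) for _, c in groups)
    return _gaussian_summary(values, observed, ci_level, kind, n_total, n_cand_total, n_perm, seed)


def exhaustive_null(
    event_positions: Sequence[float],
    candidate_positions: Sequence[float],
    window_um: float = 5.0,
    min_size: int = 2,
    max_placements: int = 1_000_000,
) -> float:
    """Exact null mean of the clustered proportion by full enumeration.

    Averages over every anchor choice and every without-replacement
    assignment of the remaining events to candidate positions.  Serves
    as the brute-force oracle for :func:`permutation_null` on small
    instances.
    """
    ev_pos = np.asarray(event_positions, dtype=float)
    cand = np.asarray(candidate_positions, dtype=float)
    n_ev = len(ev_pos)
    if n_ev < 2:
        raise ValueError("need at least 2 dynamic events")
    if len(cand) < n_ev:
        raise ValueError("candidate positions fewer than dynamic events")
    n_assign = math.comb(len(cand) - 1, n_ev - 1)
    if n_ev * n_assign > max_placements:
        raise ValueError(
            f"{n_ev * n_assign} placements exceed the {max_placements} bound; "
            "use permutation_null instead")
    obs_idx = _match_candidate_indices(ev_pos, cand)
    total, count = 0.0, 0
    for a in obs_idx:
        rest = [j for j in range(len(cand)) if j != a]
        for combo in itertools.combinations(rest, n_ev - 1):
            placed = np.concatenate(([cand[a]], cand[list(combo)]))
            total += clustered_proportion(placed, window_um=window_um, min_size=min_size)
            count += 1
    return total / count


# ---------------------------------------------------------------------------
# study-level driver

def _zone_match(ev_zone: Zone, zone: Optional[Zone], missing_to_distal: bool) -> bool:
    if zone is None:
        return True
    if missing_to_distal and ev_zone is Zone.NO_PLAQUE:
        ev_zone = Zone.DISTAL
    return ev_zone is zone


def cluster_test_by_zone(
    study,
    kind: EventKind,
    cfg: AnalysisConfig | None = None,
    zone: Optional[Zone] = None,
    interval: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the cluster test per segment and pooled per animal.

    Events (and candidate spine positions) are restricted to ``zone``
    when given; segments with fewer than two in-zone events are skipped
    with a log entry.  Returns ``(per_segment, per_animal)`` tidy
    DataFrames; the per-animal table carries both the mean of segment
    results and the pooled test.
    """
    cfg = cfg or AnalysisConfig()
    from .dynamics import assign_zone  # local import to avoid cycle at import time

    intervals = range(study.sessions.n_intervals) if interval is None else [interval]
    seg_rows: list[dict] = []
    pooled_groups: dict[tuple[str, int], list[tuple[list[float], list[float]]]] = {}
    test_i = 0
    for seg in study.segments:
        for i in intervals:
            events = classify_interval_events(seg, i, cfg)
            evs = [ev for ev in events_of_kind(events, kind)
                   if _zone_match(ev.zone, zone, cfg.missing_plaque_to_distal)]
            cand = [
                sp.position_um for sp in seg.spines
                if (sp.presence[i] or sp.presence[i + 1])
                and _zone_match(assign_zone(sp.dist_plaque_um, cfg.zone_bounds_um), zone,
                                cfg.missing_plaque_to_distal)
            ]
            ev_pos = [ev.position_um for ev in evs]
            pooled_groups.setdefault((seg.animal_id, i), []).append((ev_pos, cand))
            if len(ev_pos) < 2:
                logger.info("segment %s interval %d: %d %s event(s) in zone %s — skipped",
                            seg.segment_id, i, len(ev_pos), kind.value,
                            zone.value if zone else "all")
                continue
            res = permutation_null(
                ev_pos, cand, n_perm=cfg.n_perm_cluster,
                seed=cfg.seed + 7919 * test_i, window_um=cfg.cluster_window_um,
                min_size=cfg.min_cluster_size, ci_level=cfg.ci_level, kind=kind)
            test_i += 1
            seg_rows.append({
                "animal_id": seg.animal_id, "segment_id": seg.segment_id,
                "group": seg.group, "interval": i, "kind": kind.value,
                "zone": zone.value if zone else "all",
                "n_dynamic": res.n_dynamic, "n_candidates": res.n_candidates,
                "observed_prop": res.observed_prop, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "null_sem": res.null_sem,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "z": res.z,
                "p_two_tailed": res.p_two_tailed, "verdict": res.verdict.value,
            })
    per_segment = pd.DataFrame(seg_rows)

    animal_rows: list[dict] = []
    for (animal, i), groups in sorted(pooled_groups.items()):
        res = pooled_permutation_null(
            groups, n_perm=cfg.n_perm_cluster,
            seed=cfg.seed + 104729 + 7919 * len(animal_rows),
            window_um=cfg.cluster_window_um, min_size=cfg.min_cluster_size,
            ci_level=cfg.ci_level, kind=kind)
        if res is None:
            continue
        if len(per_segment):
            sub = per_segment[(per_segment.animal_id == animal) & (per_segment.interval == i)]
        else:
            sub = per_segment
        animal_rows.append({
            "animal_id": animal, "interval": i, "kind": kind.value,
            "zone": zone.value if zone else "all",
            "n_dynamic": res.n_dynamic,
            "mean_observed_prop": float(sub.observed_prop.mean()) if len(sub) else None,
            "mean_null_mean": float(sub.null_mean.mean()) if len(sub) else None,
            "pooled_observed_prop": res.observed_prop,
            "pooled_null_mean": res.null_mean, "pooled_null_sd": res.null_sd,
            "pooled_ci_low": res.ci_low, "pooled_ci_high": res.ci_high,
            "pooled_z": res.z, "pooled_verdict": res.verdict.value,
        })
    return per_segment, pd.DataFrame(animal_rows)
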