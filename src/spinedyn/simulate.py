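"""Synthetic generator for longitudinal spine-annotation datasets.

The generative model is the simplest process consistent with the
analysis assumptions:

* initial spines follow a homogeneous Poisson process along the segment
  (default 0.4 spines/um over 60 um), with a 0.2 um minimum gap between
  spines (annotation resolvability floor);
* per inter-session interval, each present spine is eliminated with a
  Bernoulli probability (default 10%), and new spines arrive with a
  Poisson count whose mean is the formation probability times the
  number of spines present at the interval start;
* a ``clustering_strength`` fraction of dynamic events is placed (or
  chosen) as a *partner* within <= 5 um of another same-type event of
  the same interval — a Neyman-Scott-like thinning along the 1-D shaft;
  the remainder is placed independently;
* an optional plaque field puts plaques on a regular 1-D grid, assigns
  every spine its distance to the nearest plaque, scales elimination
  inside the proximal zone (< 25 um) and formation inside the
  intermediate zone (25-60 um);
* a spine eliminated in interval k reappears with probability
  ``p_restore`` in session k+2, within < 2 um of the lost position,
  encoded as a separate spine row so that identity must be re-derived
  by distance matching downstream.

Ground-truth event labels (formed / eliminated / restored) are emitted
alongside so every downstream estimate can be checked against the
generating process.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dynamics import assign_zone
from .model import SegmentDataset, SessionAxis, SpineTimeline, StudyDataset, Zone

_GT_COLUMNS = ["animal_id", "segment_id", "spine_id", "interval",
               "category", "position_um", "origin_spine_id"]


def _plaque_distance(x: np.ndarray | float, offset: float, spacing: float) -> np.ndarray | float:
    """Distance from arc position ``x`` to the nearest plaque on the
    1-D plaque axis (plaques every ``spacing`` um; the segment starts
    at ``offset`` on that axis)."""
    d = np.mod(offset + x, spacing)
    return np.minimum(d, spacing - d)


def _place_with_gap(rng: np.random.Generator, draw, existing: list[float],
                    gap: float, max_tries: int = 200) -> float:
    """Rejection-sample a position at >= ``gap`` from existing spines."""
    for _ in range(max_tries):
        x = float(draw())
        if all(abs(x - e) >= gap for e in existing):
            return x
    return float(draw())    # crowded segment: accept the last draw


def simulate_segment(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    segment_id: str = "seg1",
    animal_id: str = "a1",
) -> tuple[SegmentDataset, pd.DataFrame]:
    """Simulate one dendritic segment; returns the dataset and its
    ground-truth event table."""
    cfg.validate()
    L = cfg.segment_length_um
    axis = SessionAxis(tuple(f"s{i + 1}" for i in range(cfg.n_sessions)))
    pf = cfg.plaque_field
    offset = float(rng.uniform(0.0, pf.plaque_spacing_um)) if pf else 0.0

    def plaque_dist(x: float) -> Optional[float]:
        return float(_plaque_distance(x, offset, pf.plaque_spacing_um)) if pf else None

    def elim_prob(x: float) -> float:
        p = cfg.p_elim_base
        if pf and assign_zone(plaque_dist(x)) is Zone.PROXIMAL:
            p *= pf.elim_multiplier_proximal
        return min(p, 1.0)

    def form_weight(x: float) -> float:
        if pf and assign_zone(plaque_dist(x)) is Zone.INTERMEDIATE:
            return pf.form_multiplier_intermediate
        return 1.0

    # initial spines: homogeneous Poisson with a resolvability gap
    n0 = int(rng.poisson(cfg.spine_density_per_um * L))
    positions: list[float] = []
    for _ in range(n0):
        positions.append(_place_with_gap(rng, lambda: rng.uniform(0.0, L),
                                         positions, cfg.min_spine_gap_um))

    spines: list[dict] = [
        {"pos": p, "presence": [True] + [False] * (cfg.n_sessions - 1)}
        for p in sorted(positions)
    ]
    gt_rows: list[dict] = []
    # pending restorations: session index -> list of (position, origin index)
    pending: dict[int, list[tuple[float, int]]] = {}

    if pf:
        max_w = max(1.0, pf.form_multiplier_intermediate)

    def draw_seed_position() -> float:
        # formation density proportional to the zone weight
        if not pf:
            return rng.uniform(0.0, L)
        while True:
            x = float(rng.uniform(0.0, L))
            if rng.uniform(0.0, max_w) <= form_weight(x):
                return x

    for t in range(cfg.n_sessions - 1):
        present = [i for i, s in enumerate(spines) if s["presence"][t]]
        # survivors carry over by default
        for i in present:
            spines[i]["presence"][t + 1] = True

        # ---- eliminations: independent Bernoulli fixes the marginal rate;
        #      with clustering, the same count is re-dealt with partner bias
        probs = np.array([elim_prob(spines[i]["pos"]) for i in present])
        flips = rng.random(len(present)) < probs
        n_elim = int(flips.sum())
        if cfg.clustering_strength == 0.0 or n_elim < 2:
            eliminated = [i for i, f in zip(present, flips) if f]
        else:
            eliminated = _deal_clustered_eliminations(
                rng, present, [spines[i]["pos"] for i in present], probs,
                n_elim, cfg.clustering_strength, cfg.cluster_window_um)
        for i in eliminated:
            spines[i]["presence"][t + 1] = False
            gt_rows.append({"animal_id": animal_id, "segment_id": segment_id,
                            "spine_id": None, "interval": t, "category": "eliminated",
                            "position_um": spines[i]["pos"], "origin_spine_id": None,
                            "_idx": i, "_origin_idx": None})
            if cfg.p_restore > 0 and t + 2 < cfg.n_sessions and rng.random() < cfg.p_restore:
                pending.setdefault(t + 2, []).append((spines[i]["pos"], i))

        # ---- formations
        n_new = int(rng.poisson(cfg.p_form_base * len(present) * _mean_form_weight(
            form_weight, L, pf)))
        formed_positions: list[float] = []
        existing = [s["pos"] for s in spines]
        for _ in range(n_new):
            partner = (cfg.clustering_strength > 0.0 and formed_positions
                       and rng.random() < cfg.clustering_strength)
            if partner:
                seed = float(rng.choice(formed_positions))
                w = cfg.cluster_window_um

                def draw():
                    return np.clip(seed + rng.uniform(-w, w), 0.0, L)
            else:
                draw = draw_seed_position
            x = _place_with_gap(rng, draw, existing, cfg.min_spine_gap_um)
            formed_positions.append(x)
            existing.append(x)
            spines.append({"pos": x, "presence": [False] * (t + 1) + [True]
                           + [False] * (cfg.n_sessions - t - 2)})
            gt_rows.append({"animal_id": animal_id, "segment_id": segment_id,
                            "spine_id": None, "interval": t, "category": "formed",
                            "position_um": x, "origin_spine_id": None,
                            "_idx": len(spines) - 1, "_origin_idx": None})

        # ---- restorations landing at session t+1
        for lost_pos, origin in pending.pop(t + 1, []):
            w = cfg.restore_threshold_um

            def draw_restore():
                return np.clip(lost_pos + rng.uniform(-w, w), 0.0, L)

            x = _place_with_gap(rng, draw_restore, [s["pos"] for s in spines],
                                cfg.min_spine_gap_um)
            spines.append({"pos": x, "presence": [False] * (t + 1) + [True]
                           + [False] * (cfg.n_sessions - t - 2)})
            gt_rows.append({"animal_id": animal_id, "segment_id": segment_id,
                            "spine_id": None, "interval": t, "category": "restored",
                            "position_um": x, "origin_spine_id": None,
                            "_idx": len(spines) - 1, "_origin_idx": origin})

    # assemble timelines with stable ids in position order
    order = sorted(range(len(spines)), key=lambda i: (spines[i]["pos"], i))
    id_of = {i: f"sp{k + 1:04d}" for k, i in enumerate(order)}
    timelines = [
        SpineTimeline(
            spine_id=id_of[i], segment_id=segment_id,
            position_um=spines[i]["pos"],
            dist_plaque_um=plaque_dist(spines[i]["pos"]),
            presence=tuple(spines[i]["presence"]),
        )
        for i in order
    ]
    timelines.sort(key=lambda s: s.spine_id)
    for row in gt_rows:
        row["spine_id"] = id_of[row.pop("_idx")]
        origin = row.pop("_origin_idx")
        row["origin_spine_id"] = id_of[origin] if origin is not None else ""
    seg = SegmentDataset(segment_id=segment_id, animal_id=animal_id,
                         group=cfg.group, length_um=L, spines=timelines, sessions=axis)
    return seg, pd.DataFrame(gt_rows, columns=_GT_COLUMNS)


def _mean_form_weight(form_weight, L: float, pf) -> float:
    """Arc-averaged formation weight (1.0 without a plaque field)."""
    if not pf:
        return 1.0
    xs = np.linspace(0.0, L, 241)
    return float(np.mean([form_weight(float(x)) for x in xs]))


def _deal_clustered_eliminations(
    rng: np.random.Generator,
    present: list[int],
    positions: list[float],
    probs: np.ndarray,
    n_elim: int,
    strength: float,
    window_um: float,
) -> list[int]:
    """Choose which spines to eliminate, keeping the count from the
    Bernoulli draw but making a ``strength`` fraction of picks partners
    of an already-picked elimination (within the cluster window)."""
    pos = np.asarray(positions)
    chosen: list[int] = []
    chosen_pos: list[float] = []
    free = list(range(len(present)))
    for k in range(min(n_elim, len(present))):
        partner = chosen and rng.random() < strength
        pick = None
        if partner:
            near = [j for j in free
                    if any(abs(pos[j] - cp) <= window_um for cp in chosen_pos)]
            if near:
                pick = int(rng.choice(near))
        if pick is None:
            w = probs[free]
            w = w / w.sum() if w.sum() > 0 else None
            pick = int(rng.choice(free, p=w))
        free.remove(pick)
        chosen.append(present[pick])
        chosen_pos.append(float(pos[pick]))
    return chosen


def simulate_study(cfg: SimulationConfig) -> tuple[StudyDataset, pd.DataFrame]:
    """Simulate ``n_animals x segments_per_animal`` independent segments.

    Deterministic given ``cfg.seed``; ground-truth tables of all
    segments are concatenated.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    segments: list[SegmentDataset] = []
    gts: list[pd.DataFrame] = []
    for a in range(cfg.n_animals):
        animal_id = f"m{a + 1:03d}"
        for s in range(cfg.segments_per_animal):
            seg_id = f"{animal_id}_seg{s + 1:02d}"
            seg, gt = simulate_segment(cfg, rng, segment_id=seg_id, animal_id=animal_id)
            segments.append(seg)
            gts.append(gt)
    axis = segments[0].sessions
    for seg in segments:
        seg.sessions = axis
    study = StudyDataset(segments=segments, sessions=axis)
    study.sort_canonical()
    gts = [g for g in gts if len(g)]
    gt = (pd.concat(gts, ignore_index=True) if gts
          else pd.DataFrame(columns=_GT_COLUMNS))
    return study, gt
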