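"""Analysis and simulation configuration, with YAML loading and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class AnalysisConfig:
    """Parameters of the spine-dynamics analysis.

    cluster_window_um : float
        Maximum arc-length spacing (um) between consecutive members of a
        dynamic cluster; two or more same-type events chained at <= this
        spacing form a cluster.
    min_cluster_size : int
        Minimum number of events per cluster.
    restore_threshold_um : float
        A reappearing spine closer than this (strict) to a previously
        lost spine counts as a restoration; otherwise de novo.
    zone_bounds_um : (float, float, float)
        Plaque-distance zone bounds: proximal < b0; intermediate in
        [b0, b1]; (b1, b2] unassigned; distal > b2.
    n_perm_cluster, n_perm_restore : int
        Monte-Carlo replicates for the cluster and restoration nulls.
    ci_level : float
        Two-sided confidence level of the null interval.
    missing_plaque_to_distal : bool
        Treat missing plaque distances as distal-equivalent ("no-plaque"
        events join the distal stratum) instead of a separate category.
    weight_animal_mean_by_spines : bool
        Weight the per-animal mean of segment rates by spine count
        (off by default: unweighted mean across segments).
    optimal_matching : bool
        Use minimum-total-distance assignment instead of greedy nearest
        matching for restoration pairing.
    restore_lookahead : int
        How many sessions after the loss interval to search for a
        reappearance (1 = the immediately following session).
    """

    cluster_window_um: float = 5.0
    min_cluster_size: int = 2
    restore_threshold_um: float = 2.0
    zone_bounds_um: Tuple[float, float, float] = (25.0, 60.0, 100.0)
    n_perm_cluster: int = 30_000
    n_perm_restore: int = 10_000
    ci_level: float = 0.999
    seed: int = 0
    missing_plaque_to_distal: bool = True
    weight_animal_mean_by_spines: bool = False
    optimal_matching: bool = False
    restore_lookahead: int = 1

    def validate(self) -> None:
        if self.cluster_window_um <= 0:
            raise ConfigError("cluster_window_um must be > 0")
        if self.min_cluster_size < 2:
            raise ConfigError("min_cluster_size must be >= 2")
        if self.restore_threshold_um <= 0:
            raise ConfigError("restore_threshold_um must be > 0")
        b = tuple(self.zone_bounds_um)
        if len(b) != 3 or not (0 < b[0] < b[1] < b[2]):
            raise ConfigError("zone_bounds_um must be three strictly increasing positives")
        if self.n_perm_cluster < 1 or self.n_perm_restore < 1:
            raise ConfigError("permutation counts must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.restore_lookahead < 1:
            raise ConfigError("restore_lookahead must be >= 1")


@dataclass
class PlaqueField:
    """1-D reduction of plaque geometry: plaques on a regular grid.

    Each segment is dropped at a random offset on a plaque axis with one
    plaque every ``plaque_spacing_um``; a spine's plaque distance is its
    distance to the nearest plaque on that axis.  Elimination is scaled
    by ``elim_multiplier_proximal`` inside the proximal zone, formation
    by ``form_multiplier_intermediate`` inside the intermediate zone.
    """

    plaque_spacing_um: float = 260.0
    elim_multiplier_proximal: float = 1.5
    form_multiplier_intermediate: float = 2.0

    def validate(self) -> None:
        if self.plaque_spacing_um <= 0:
            raise ConfigError("plaque_spacing_um must be > 0")
        if self.elim_multiplier_proximal <= 0 or self.form_multiplier_intermediate <= 0:
            raise ConfigError("plaque multipliers must be > 0")


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic spine-dynamics model.

    Defaults emulate typical in vivo conditions: segments of ~60 um at
    0.4 spines/um imaged over three sessions, with 10% per-interval
    formation and elimination.
    """

    n_animals: int = 5
    segments_per_animal: int = 10
    segment_length_um: float = 60.0
    spine_density_per_um: float = 0.4
    n_sessions: int = 3
    p_elim_base: float = 0.10
    p_form_base: float = 0.10
    clustering_strength: float = 0.0
    plaque_field: Optional[PlaqueField] = None
    p_restore: float = 0.0
    seed: int = 0
    group: str = "synthetic"
    min_spine_gap_um: float = 0.2       # annotation resolvability floor
    cluster_window_um: float = 5.0      # partner-placement window for clustered events
    restore_threshold_um: float = 2.0   # restored spines reappear within < this of the lost site

    def validate(self) -> None:
        if self.n_animals < 1 or self.segments_per_animal < 1:
            raise ConfigError("need at least one animal and one segment per animal")
        if self.segment_length_um <= 0:
            raise ConfigError("segment_length_um must be > 0")
        if self.spine_density_per_um <= 0:
            raise ConfigError("spine_density_per_um must be > 0")
        if self.n_sessions < 2:
            raise ConfigError("n_sessions must be >= 2")
        for name in ("p_elim_base", "p_form_base", "clustering_strength", "p_restore"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.plaque_field is not None:
            self.plaque_field.validate()


def _from_mapping(cls, data: dict):
    if cls is SimulationConfig and "plaque_field" in data and data["plaque_field"] is not None:
        data = dict(data)
        data["plaque_field"] = PlaqueField(**data["plaque_field"])
    if cls is AnalysisConfig and "zone_bounds_um" in data:
        data = dict(data)
        data["zone_bounds_um"] = tuple(data["zone_bounds_um"])
    try:
        obj = cls(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    obj.validate()
    return obj


def load_config(path: str | Path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Read a YAML file with optional ``simulation:`` and ``analysis:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    sim = _from_mapping(SimulationConfig, raw.get("simulation", {}) or {})
    ana = _from_mapping(AnalysisConfig, raw.get("analysis", {}) or {})
    return sim, ana


def config_snapshot(sim: SimulationConfig, ana: AnalysisConfig) -> dict:
    return {"simulation": asdict(sim), "analysis": asdict(ana)}
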