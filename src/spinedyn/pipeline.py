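"""Reproducible pipeline: simulate -> analyze -> cluster-test ->
restore-test -> report, with a deterministic run manifest.

Every stage writes tidy CSV/JSON into the output directory; the
manifest lists each output file with its SHA-256 digest and row count,
so identical (config, seed, inputs) reproduce identical digests.
Wall-clock timestamps go to ``run.log`` only, keeping the manifest
byte-stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, ConfigError, SimulationConfig, config_snapshot, load_config
from .cluster import cluster_test_by_zone
from .dynamics import classify_study_events, dendrospinogram_table, survival_table, turnover_table
from .io import read_spine_table, validate_dataset, write_events_table, write_spine_table
from .model import EventKind, StudyDataset, Zone
from .restoration import restoration_table, restored_vs_de_novo_summary
from .simulate import simulate_study

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _count_rows(path: Path) -> Optional[int]:
    if path.suffix != ".csv":
        return None
    with open(path) as fh:
        return max(sum(1 for line in fh if not line.startswith("#")) - 1, 0)


class Manifest:
    """Deterministic record of a pipeline run."""

    def __init__(self, out_dir: Path, sim: SimulationConfig, ana: AnalysisConfig,
                 input_digests: Optional[dict] = None) -> None:
        self.out_dir = out_dir
        self.data = {
            "package": "spinedyn",
            "version": __version__,
            "seed": {"simulation": sim.seed, "analysis": ana.seed},
            "config": config_snapshot(sim, ana),
            "inputs": input_digests or {},
            "outputs": {},
        }

    def register(self, path: Path) -> None:
        self.data["outputs"][path.name] = {
            "sha256": _sha256(path), "n_rows": _count_rows(path)}

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def run_pipeline(
    out_dir: str | Path,
    sim: Optional[SimulationConfig] = None,
    ana: Optional[AnalysisConfig] = None,
    config_path: Optional[str | Path] = None,
    input_table: Optional[str | Path] = None,
    make_plots: bool = True,
) -> Path:
    """Run every stage in order and write the manifest last.

    Inputs are either a config (whose simulation block generates the
    data) or an existing annotation table.  Returns the manifest path.
    """
    if config_path is not None:
        sim, ana = load_config(config_path)
    sim = sim or SimulationConfig()
    ana = ana or AnalysisConfig()
    sim.validate()
    ana.validate()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("spinedyn")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    input_digests = {}
    try:
        if input_table is not None:
            input_digests[Path(input_table).name] = _sha256(Path(input_table))
        manifest = Manifest(out_dir, sim, ana, input_digests)

        # -- stage: simulate / load ---------------------------------------
        if input_table is None:
            study, gt = simulate_study(sim)
            ann_path = out_dir / "annotations.csv"
            write_spine_table(study, ann_path, metadata={"seed": sim.seed, "generator": "spinedyn"})
            gt_path = out_dir / "ground_truth.csv"
            gt.to_csv(gt_path, index=False)
            manifest.register(ann_path)
            manifest.register(gt_path)
            logger.info("simulate: %d segments, %d spines", len(study.segments),
                        sum(len(s.spines) for s in study.segments))
        else:
            study = read_spine_table(input_table)
            logger.info("load: %d segments from %s", len(study.segments), input_table)
        violations = validate_dataset(study)
        if violations:
            raise ConfigError("input dataset invalid: " + "; ".join(violations[:5]))

        # -- stage: analyze ------------------------------------------------
        events = classify_study_events(study, ana)
        events_path = out_dir / "events.csv"
        write_events_table(events, events_path)
        manifest.register(events_path)

        turnover = turnover_table(study, ana)
        turnover_path = out_dir / "turnover.csv"
        turnover.to_csv(turnover_path, index=False)
        manifest.register(turnover_path)

        survival = survival_table(study, ana)
        survival_path = out_dir / "survival.csv"
        survival.to_csv(survival_path, index=False)
        manifest.register(survival_path)

        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            dspino = dendrospinogram_table(events)
        dspino_path = out_dir / "dendrospinogram.csv"
        dspino.to_csv(dspino_path, index=False)
        manifest.register(dspino_path)
        logger.info("analyze: %d events", len(events))

        # -- stage: cluster-test -------------------------------------------
        seg_frames, animal_frames = [], []
        for kind in (EventKind.FORMED, EventKind.ELIMINATED):
            per_seg, per_animal = cluster_test_by_zone(study, kind, ana)
            seg_frames.append(per_seg)
            animal_frames.append(per_animal)
        cluster_path = out_dir / "cluster_test.csv"
        pd.concat(seg_frames, ignore_index=True).to_csv(cluster_path, index=False)
        manifest.register(cluster_path)
        cluster_animal = pd.concat(animal_frames, ignore_index=True)
        summary = {
            "n_segment_tests": int(sum(len(f) for f in seg_frames)),
            "verdicts": (pd.concat(seg_frames)["verdict"].value_counts().to_dict()
                         if any(len(f) for f in seg_frames) else {}),
            "pooled_animal_tests": cluster_animal.to_dict(orient="records"),
        }
        cluster_summary_path = out_dir / "cluster_test_summary.json"
        with open(cluster_summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        manifest.register(cluster_summary_path)
        logger.info("cluster-test: %d per-segment tests", summary["n_segment_tests"])

        # -- stage: restore-test -------------------------------------------
        if study.sessions.count >= 3:
            resto = restoration_table(study, ana)
            resto_path = out_dir / "restoration.csv"
            resto.to_csv(resto_path, index=False)
            manifest.register(resto_path)
            resto_summary = restored_vs_de_novo_summary(study, ana)
            resto_summary_path = out_dir / "restoration_summary.json"
            with open(resto_summary_path, "w") as fh:
                json.dump(resto_summary.to_dict(orient="records"), fh, indent=2,
                          sort_keys=True, default=_json_default)
                fh.write("\n")
            manifest.register(resto_summary_path)
            logger.info("restore-test: %d segment/interval pairs", len(resto))
        else:
            logger.info("restore-test skipped: fewer than 3 sessions")

        # -- stage: report ---------------------------------------------------
        report = summary_report(out_dir, make_plots=make_plots)
        manifest.register(report)
        for extra in ("dendrospinogram.svg",):
            p = out_dir / extra
            if p.exists():
                manifest.register(p)
        return manifest.write()
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def summary_report(out_dir: str | Path, make_plots: bool = True) -> Path:
    """Assemble a human-readable markdown report from the stage outputs.

    Numbers are read back from the CSVs so the report always equals the
    tables; missing stages are noted, not fatal.
    """
    out_dir = Path(out_dir)
    lines = ["# Spine dynamics report", ""]

    turnover_path = out_dir / "turnover.csv"
    if turnover_path.exists():
        t = pd.read_csv(turnover_path)
        animal = t[t["unit"] == "animal"]
        lines += ["## Turnover (per-animal means)", ""]
        lines.append("| animal | interval | formation % | elimination % | form:elim |")
        lines.append("|---|---|---|---|---|")
        for _, r in animal.iterrows():
            ratio = "n/a" if pd.isna(r["form_elim_ratio"]) else f"{r['form_elim_ratio']:.3f}"
            lines.append(
                f"| {r['unit_id']} | {r['interval_label']} | "
                f"{r['formation_pct']:.2f} | {r['elimination_pct']:.2f} | {ratio} |")
        lines.append("")
    else:
        lines += ["## Turnover", "", "_missing: turnover.csv not found_", ""]

    survival_path = out_dir / "survival.csv"
    if survival_path.exists():
        s = pd.read_csv(survival_path)
        lines += ["## Survival by plaque bin", ""]
        agg = (s.dropna(subset=["survival"])
               .groupby(["cohort", "plaque_bin"])["survival"].mean())
        lines.append("| cohort | plaque bin | mean survival |")
        lines.append("|---|---|---|")
        for (cohort, bin_label), v in agg.items():
            lines.append(f"| {cohort} | {bin_label} | {v:.3f} |")
        lines.append("")
    else:
        lines += ["## Survival", "", "_missing: survival.csv not found_", ""]

    cluster_path = out_dir / "cluster_test.csv"
    if cluster_path.exists():
        c = pd.read_csv(cluster_path)
        lines += ["## Cluster tests (per segment)", ""]
        if len(c):
            for (kind, verdict), n in c.groupby(["kind", "verdict"]).size().items():
                lines.append(f"- {kind}: {verdict} in {n} segment tests")
        else:
            lines.append("- no segment carried enough dynamic events")
        lines.append("")
    else:
        lines += ["## Cluster tests", "", "_missing: cluster_test.csv not found_", ""]

    resto_path = out_dir / "restoration.csv"
    if resto_path.exists():
        r = pd.read_csv(resto_path)
        n_re = int(r["n_reappeared"].sum())
        n_restored = int(r["n_restored"].sum())
        lines += ["## Restoration", "",
                  f"- lost spines: {int(r['n_lost'].sum())}",
                  f"- reappeared: {n_re} (restored {n_restored}, "
                  f"de novo {int(r['n_de_novo'].sum())})"]
        if n_re:
            lines.append(f"- pooled restored proportion: {n_restored / n_re:.3f}")
        lines.append("")
    else:
        lines += ["## Restoration", "", "_missing: restoration.csv not found_", ""]

    dspino_path = out_dir / "dendrospinogram.csv"
    if make_plots and dspino_path.exists():
        d = pd.read_csv(dspino_path)
        if len(d):
            _plot_dendrospinogram(d, out_dir / "dendrospinogram.svg")
            lines += ["![dendrospinogram](dendrospinogram.svg)", ""]

    report_path = out_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path


def _plot_dendrospinogram(df: pd.DataFrame, path: Path) -> None:
    """Radial event map: radius = distance to the nearest plaque edge,
    angle spreads events of one interval; colors by event kind."""
    df = df.dropna(subset=["dist_plaque_um"])
    if not len(df):
        return
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    colors = {"formed": "tab:green", "eliminated": "tab:red",
              "survived_old": "0.7", "survived_new": "tab:blue",
              "restored": "tab:purple", "de_novo": "tab:olive"}
    n = len(df)
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    for kind, color in colors.items():
        mask = (df["kind"] == kind).to_numpy()
        if mask.any():
            ax.scatter(theta[mask], df["dist_plaque_um"].to_numpy()[mask],
                       s=12, c=color, label=kind, alpha=0.7)
    for ring in (25, 60, 100):
        ax.plot(np.linspace(0, 2 * np.pi, 200), [ring] * 200, lw=0.6, c="k", ls=":")
    ax.set_rlabel_position(90)
    ax.set_xticks([])
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    ax.set_title("dynamic events vs distance to nearest plaque (um)")
    # fixed hash salt + stripped date keep the SVG byte-reproducible
    with matplotlib.rc_context({"svg.hashsalt": "spinedyn"}):
        fig.savefig(path, bbox_inches="tight", metadata={"Date": None})
    plt.close(fig)
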