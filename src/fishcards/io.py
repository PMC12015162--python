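"""CSV schemas, run manifests, and the end-to-end pipeline.

The event-log CSV has a fixed header (one row per simulator event, times in
seconds with one decimal); cohort-level logs carry two extra leading columns
identifying the participant. Response-record CSVs round-trip losslessly.
A pipeline run is a pure function of (config, seed): the manifest records
the resolved config hash, the seed, and a SHA-256 per output so reruns can
be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import RECORD_COLUMNS, generate_cohort, run_experiment
from .config import CohortSpec, GameConfig, config_hash, dump_config
from .metrics import summarize_phase

EVENT_COLUMNS = ["t_global", "attempt", "phase", "round_in_streak", "event_type",
                 "card", "points_delta", "bar_after", "hearts_after", "irt_s"]


def events_to_frame(events) -> pd.DataFrame:
    """Convert a list of EventRecord to the canonical event-log frame."""
    rows = [{
        "t_global": ev.t_global, "attempt": ev.attempt, "phase": ev.phase,
        "round_in_streak": ev.round_in_streak, "event_type": ev.event_type,
        "card": ev.card, "points_delta": ev.points_delta,
        "bar_after": ev.bar_after, "hearts_after": ev.hearts_after,
        "irt_s": ev.irt_s,
    } for ev in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _format_events(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["t_global"] = out["t_global"].map(lambda t: f"{t:.1f}")
    out["irt_s"] = out["irt_s"].map(
        lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.1f}")
    out["bar_after"] = out["bar_after"].map(
        lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:g}")
    out["card"] = out["card"].fillna("")
    return out


def write_events_csv(events, path) -> None:
    """Write an event log (list of EventRecord or frame) to CSV."""
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    lead = [c for c in ("participant_id", "age_group") if c in df.columns]
    _format_events(df)[lead + EVENT_COLUMNS].to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"card": "string"})
    df["card"] = df["card"].astype(object).where(df["card"].notna(), None)
    return df


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["in_analysis_window"] = df["in_analysis_window"].astype(bool)
    return df[RECORD_COLUMNS] if set(RECORD_COLUMNS) <= set(df.columns) else df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def pipeline(game: GameConfig, cohort_spec: CohortSpec, seed: int, outdir,
             *, make_plots: bool = True) -> dict:
    """cohort -> simulate -> records -> analyze -> report, deterministically.

    Writes ``events.csv``, ``records.csv``, ``summary.csv``, per-objective
    fit and marginal-means CSVs (and plots), the resolved config, and a
    ``manifest.json``; returns the manifest dict.
    """
    from .analysis import run_objectives

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(game, cohort_spec),
        "seed": int(seed),
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }

    def record_output(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        dump_config(game, cohort_spec, outdir / "config.resolved.yaml")
        record_output("config", outdir / "config.resolved.yaml")

        policies = generate_cohort(cohort_spec, seed)
        records, events, infos = run_experiment(
            policies, game, seed, max_attempts=cohort_spec.max_attempts)
        manifest["stages"].append("cohort")
        manifest["participants"] = {
            "total": len(policies),
            "converged": sum(1 for i in infos if i["converged"]),
        }

        write_events_csv(events, outdir / "events.csv")
        write_records_csv(records, outdir / "records.csv")
        record_output("events", outdir / "events.csv")
        record_output("records", outdir / "records.csv")
        manifest["stages"].append("simulate")

        summary = summarize_phase(events)
        summary.to_csv(outdir / "summary.csv", index=False)
        record_output("summary", outdir / "summary.csv")
        manifest["stages"].append("summarize")

        reports = run_objectives(records)
        fit_rows, selected = [], {}
        for obj, rep in reports.items():
            fit_rows.extend(f.summary_row() for f in rep.fits)
            rep.coef_table.to_csv(outdir / f"objective{obj}_coefficients.csv")
            rep.marginal.to_csv(outdir / f"objective{obj}_marginal_means.csv",
                                index=False)
            record_output(f"objective{obj}_coefficients",
                          outdir / f"objective{obj}_coefficients.csv")
            record_output(f"objective{obj}_marginal_means",
                          outdir / f"objective{obj}_marginal_means.csv")
            selected[obj] = {"model": rep.selected.spec.label,
                             "aic": rep.selected.aic,
                             "significant": rep.significant,
                             "pearson_ratio": rep.diagnostics["pearson_ratio"]}
        pd.DataFrame(fit_rows).to_csv(outdir / "model_grid.csv", index=False)
        record_output("model_grid", outdir / "model_grid.csv")
        manifest["selected_models"] = selected
        manifest["stages"].append("analyze")

        if make_plots:
            from .plots import plot_report
            for obj, rep in reports.items():
                plot_report(rep, outdir / f"objective{obj}.png")
                record_output(f"objective{obj}_plot", outdir / f"objective{obj}.png")
            manifest["stages"].append("plots")
    finally:
        manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
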