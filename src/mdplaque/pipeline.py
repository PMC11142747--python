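"""End-to-end orchestration: config handling, the full analysis pipeline and
group-level report tables (WT vs KO, control vs stimulus)."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome as cn
from . import oscillation as osc
from . import traces as tr
from . import transients as ts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "group_report"]

#: every stage parameter exposed through the flat ``stage.param`` namespace
DEFAULT_PARAMS: dict[str, object] = {
    "baseline.method": "percentile",
    "baseline.q": 20.0,
    "baseline.window_s": 60.0,
    "detect.k_mad": 3.0,
    "detect.min_interval_s": 2.0,
    "detect.min_prominence": 0.5,
    "detect.smooth_window_s": 0.75,
    "connectome.smooth_window_s": 1.0,
    "connectome.detrend": True,
    "connectome.r_threshold": 0.35,
    "connectome.hub_rule": "mean_plus_sd",
    "connectome.hub_param": 1.0,
    "oscillation.expected_period_s": 100.0 / 3.0,
    "oscillation.min_prominence": 0.5,
    "oscillation.max_lag_s": 15.0,
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration; round-trips through YAML unchanged."""

    traces_csv: str
    outdir: str
    metadata_json: str | None = None
    diameter_csv: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    params: dict[str, object] = field(default_factory=dict)

    def resolved_params(self) -> dict[str, object]:
        out = dict(DEFAULT_PARAMS)
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        out.update(self.params)
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Run extract -> normalize -> transients -> connectome -> oscillation.

    Writes every stage artifact plus ``manifest.json`` into the output
    directory and returns it.  Same config and inputs give byte-identical
    non-image outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.resolved_params()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    files: dict[str, str] = {}

    def _stage(name: str):
        def deco(fn):
            def inner(*args, **kwargs):
                try:
                    return fn(*args, **kwargs)
                except PipelineError:
                    raise
                except Exception as exc:  # noqa: BLE001 - tag and re-raise
                    raise PipelineError(name, str(exc)) from exc

            return inner

        return deco

    # --- load
    if not Path(config.traces_csv).exists():
        raise PipelineError("load", f"traces file not found: {config.traces_csv}")
    raw = _stage("load")(tr.read_trace_csv)(config.traces_csv, config.metadata_json)

    # --- normalize
    f0 = _stage("normalize")(tr.estimate_baseline)(
        raw, method=p["baseline.method"], q=p["baseline.q"], window_s=p["baseline.window_s"]
    )
    norm = _stage("normalize")(tr.normalize)(raw, f0, method=str(p["baseline.method"]))
    files["normalized_traces"] = str(outdir / "normalized_traces.csv")
    tr.write_trace_csv(norm, files["normalized_traces"])

    # --- transients
    events = _stage("transients")(ts.detect_transients)(
        norm,
        k_mad=p["detect.k_mad"],
        min_interval_s=p["detect.min_interval_s"],
        min_prominence=p["detect.min_prominence"],
        smooth_window_s=p["detect.smooth_window_s"],
    )
    ev_rows = [
        {k: v for k, v in vars(e).items() if k != "truncated"}
        for evs in events.values()
        for e in evs
    ]
    files["events"] = str(outdir / "events.csv")
    pd.DataFrame(ev_rows, columns=["cell_id", "onset_s", "peak_s", "peak_ffo", "fwhm_s", "auc"]).to_csv(
        files["events"], index=False
    )
    metrics = _stage("transients")(ts.metrics_table)(events, norm)
    if raw.labels:
        metrics["cell_class"] = [raw.labels.get(c) for c in metrics["cell_id"]]
    files["cell_metrics"] = str(outdir / "cell_metrics.csv")
    metrics.to_csv(files["cell_metrics"], index=False)

    # --- connectome
    corr = _stage("connectome")(cn.pairwise_correlation)(
        norm, smooth_window_s=p["connectome.smooth_window_s"], detrend=bool(p["connectome.detrend"])
    )
    graph = _stage("connectome")(cn.threshold_graph)(corr, r_threshold=p["connectome.r_threshold"])
    classes = _stage("connectome")(cn.classify_hub_lone)(
        graph, rule=str(p["connectome.hub_rule"]), param=p["connectome.hub_param"]
    )
    files["correlation_matrix"] = str(outdir / "correlation_matrix.csv")
    cn.write_correlation_csv(corr, files["correlation_matrix"])
    files["edges"] = str(outdir / "edges.csv")
    cn.write_edge_list_csv(graph, corr, files["edges"])
    files["graph"] = str(outdir / "connectome.graphml")
    cn.write_graphml(graph, corr, files["graph"], classes)
    files["heatmap"] = str(outdir / "heatmap.png")
    cn.plot_heatmap(corr, files["heatmap"])
    summary = cn.connectivity_summary(graph, corr)
    summary["cell_classification"] = dict(zip(classes.cell_ids, classes.label))

    # --- oscillation
    signal = _stage("oscillation")(osc.whole_md_signal)(norm)
    metrics_osc = _stage("oscillation")(osc.oscillation_metrics)(
        signal,
        expected_period_s=p["oscillation.expected_period_s"],
        min_prominence=p["oscillation.min_prominence"],
    )
    osc_out = dict(vars(metrics_osc))
    if config.diameter_csv is not None:
        if not Path(config.diameter_csv).exists():
            raise PipelineError("oscillation", f"diameter file not found: {config.diameter_csv}")
        diam = _stage("oscillation")(tr.read_diameter_csv)(config.diameter_csv)
        coupling = _stage("oscillation")(osc.vasomotion_coupling)(
            signal, diam, max_lag_s=p["oscillation.max_lag_s"]
        )
        osc_out["vasomotion_lag_s"] = coupling.lag_s
        osc_out["vasomotion_max_xcorr"] = coupling.max_xcorr
        files["aligned_signals"] = str(outdir / "aligned_signals.csv")
        b = np.interp(signal.time_s, diam.time_s, diam.diameter)
        pd.DataFrame({"time_s": signal.time_s, "whole_md_ffo": signal.value, "diameter_um": b}).to_csv(
            files["aligned_signals"], index=False
        )
    files["oscillation_metrics"] = str(outdir / "oscillation_metrics.json")
    Path(files["oscillation_metrics"]).write_text(json.dumps(_jsonable(osc_out), indent=2))

    # --- manifest (resolved config embedded in every analysis output)
    manifest = {
        "config": dataclasses.asdict(config),
        "resolved_params": _jsonable(p),
        "files": files,
        "n_cells": norm.n_cells,
        "connectivity_summary": _jsonable(summary),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def group_report(metrics: pd.DataFrame, group_col: str = "cell_class",
                 groups: list[str] | None = None) -> pd.DataFrame:
    """Per-group mean / SD / SEM / n for every numeric metric column.

    SEM = SD / sqrt(n) (sample SD, ddof=1); single-member groups report SEM as
    missing.
    """
    if group_col not in metrics.columns:
        raise ValueError(f"no group column {group_col!r}")
    if groups is not None:
        known = set(metrics[group_col].dropna().unique())
        unknown = set(groups) - known
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        metrics = metrics[metrics[group_col].isin(groups)]
    value_cols = [
        c for c in metrics.columns
        if c != group_col and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    rows = []
    for label, sub in metrics.groupby(group_col, sort=True):
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            n = vals.size
            mean = vals.mean() if n else math.nan
            sd = vals.std(ddof=1) if n > 1 else (0.0 if n == 1 else math.nan)
            sem = sd / math.sqrt(n) if n > 1 else math.nan
            rows.append({"group": label, "metric": col, "mean": mean, "sd": sd, "sem": sem, "n": n})
    return pd.DataFrame(rows)
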