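"""Fluorescence trace containers, ROI extraction, baseline estimation and F/F0 normalization.

The central object is :class:`TraceMatrix`: a (cells x frames) matrix of raw
fluorescence with a shared, uniformly sampled time axis.  Normalization divides
each cell's trace by a per-cell baseline ``F0`` estimated from the quiet
fraction of the recording (pacemaker duty cycle is low: ~2 s spikes on a ~33 s
period, so the bulk of samples sit at baseline).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter, uniform_filter1d
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

__all__ = [
    "TraceMatrix",
    "NormalizedTraceMatrix",
    "VasomotionTrace",
    "extract_roi_traces",
    "max_projection",
    "estimate_baseline",
    "normalize",
    "smooth",
    "read_trace_csv",
    "write_trace_csv",
    "read_diameter_csv",
    "write_diameter_csv",
]


def _check_time_axis(time_s: np.ndarray, fs_hz: float) -> None:
    if time_s.ndim != 1 or time_s.size < 1:
        raise ValueError("time axis must be a non-empty 1-D vector")
    if time_s.size > 1:
        dt = np.diff(time_s)
        if np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        # uniformity within 1e-6 of a sample period
        if np.max(np.abs(dt - 1.0 / fs_hz)) > 1e-6 / fs_hz:
            raise ValueError("time axis must be uniform at fs_hz")


@dataclass
class TraceMatrix:
    """Raw per-cell fluorescence (arbitrary units) on a shared time axis.

    Attributes
    ----------
    time_s : (n_frames,) strictly increasing, uniform at ``fs_hz``.
    values : (n_cells, n_frames) non-negative fluorescence.
    cell_ids : unique per-cell labels, row order matches ``values``.
    fs_hz : sampling rate.
    labels : optional per-cell class/condition annotation keyed by cell id.
    """

    time_s: np.ndarray
    values: np.ndarray
    cell_ids: list[str]
    fs_hz: float
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        _check_time_axis(self.time_s, self.fs_hz)
        if self.values.shape != (len(self.cell_ids), self.time_s.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {self.time_s.size} frames"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("negative fluorescence values")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_hz

    def cell(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    def select(self, cell_ids: list[str]) -> "TraceMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return replace(self, values=self.values[idx], cell_ids=list(cell_ids))


@dataclass
class NormalizedTraceMatrix(TraceMatrix):
    """F/F0 traces (dimensionless) with the per-cell baseline that produced them."""

    f0: np.ndarray = field(default_factory=lambda: np.array([]))
    method: str = "percentile"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.f0.size and np.any(self.f0 <= 0):
            raise ValueError("f0 must be positive for every cell")


@dataclass
class VasomotionTrace:
    """Arteriole diameter over time (same sampling conventions as TraceMatrix)."""

    time_s: np.ndarray
    diameter: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time_s.shape != self.diameter.shape:
            raise ValueError("time and diameter must have equal length")
        if self.time_s.size > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time axis must be strictly increasing")


# ---------------------------------------------------------------------------
# ROI extraction / projections


def extract_roi_traces(
    stack: np.ndarray,
    mask: np.ndarray,
    fs_hz: float,
    labels: list[int] | None = None,
    statistic: str = "mean",
) -> TraceMatrix:
    """Reduce an image stack to one trace per ROI label.

    ``value(cell, t)`` is the mean (default) pixel intensity over the cell's
    mask in frame ``t``; cells are ordered by ascending label.  ``labels`` may
    name the labels expected in the mask; a named label with zero pixels is an
    error.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, height, width)")
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask shape must equal frame shape")
    present = np.unique(mask)
    present = present[present > 0]
    if labels is None:
        labels = [int(v) for v in present]
    else:
        missing = sorted(set(labels) - set(int(v) for v in present))
        if missing:
            raise ValueError(f"ROI label(s) with zero pixels: {missing}")
    if not labels:
        raise ValueError("mask contains no nonzero ROI labels")
    if statistic not in ("mean", "sum"):
        raise ValueError(f"unknown ROI statistic {statistic!r}")

    flat_mask = mask.ravel()
    n_frames = stack.shape[0]
    values = np.empty((len(labels), n_frames), dtype=float)
    pix_idx = [np.flatnonzero(flat_mask == lab) for lab in labels]
    flat = stack.reshape(n_frames, -1)
    for i, idx in enumerate(pix_idx):
        roi = flat[:, idx]
        values[i] = roi.mean(axis=1) if statistic == "mean" else roi.sum(axis=1)
    time_s = np.arange(n_frames) / fs_hz
    return TraceMatrix(
        time_s=time_s,
        values=values,
        cell_ids=[f"cell_{lab:03d}" for lab in labels],
        fs_hz=fs_hz,
    )


def max_projection(stack: np.ndarray, mode: str = "max") -> np.ndarray:
    """Pixelwise maximum (or sum) over frames of a time-lapse stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must contain at least one frame")
    if mode == "max":
        return stack.max(axis=0)
    if mode == "sum":
        return stack.sum(axis=0)
    raise ValueError(f"unknown projection mode {mode!r}")


# ---------------------------------------------------------------------------
# Baseline / normalization / smoothing


def estimate_baseline(
    traces: TraceMatrix,
    method: str = "percentile",
    q: float = 20.0,
    window_s: float = 60.0,
) -> np.ndarray:
    """Per-cell baseline F0.

    ``"percentile"``: F0 is the mean of all samples at or below the q-th
    percentile of the full trace (default q=20) — one scalar per cell.
    ``"rolling_percentile"``: per-sample F0 from a centered window percentile,
    edges padded by reflection — shape (cells, frames).
    """
    if not 0 < q <= 50:
        raise ValueError("q must be in (0, 50]")
    v = traces.values
    if method == "percentile":
        thr = np.percentile(v, q, axis=1, keepdims=True)
        sel = v <= thr
        f0 = np.empty(v.shape[0])
        for i in range(v.shape[0]):
            picked = v[i, sel[i]]
            if picked.size == 0:  # degenerate; cannot happen for <= but keep a guard
                logger.warning(
                    "baseline percentile selected no samples for %s; "
                    "falling back to global mean",
                    traces.cell_ids[i],
                )
                f0[i] = v[i].mean()
            else:
                f0[i] = picked.mean()
        return f0
    if method == "rolling_percentile":
        win = int(round(window_s * traces.fs_hz))
        if win < 10:
            raise ValueError("rolling window must span at least 10 samples")
        return percentile_filter(v, q, size=(1, win), mode="reflect")
    raise ValueError(f"unknown baseline method {method!r}")


def normalize(traces: TraceMatrix, f0: np.ndarray, method: str = "percentile") -> NormalizedTraceMatrix:
    """Elementwise F/F0. ``f0`` is per-cell scalar or per-sample (cells x frames)."""
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("baseline must be positive")
    if f0.ndim == 1:
        values = traces.values / f0[:, None]
        f0_out = f0
    else:
        values = traces.values / f0
        f0_out = f0.mean(axis=1)
    return NormalizedTraceMatrix(
        time_s=traces.time_s,
        values=values,
        cell_ids=list(traces.cell_ids),
        fs_hz=traces.fs_hz,
        labels=traces.labels,
        f0=f0_out,
        method=method,
    )


def smooth(traces: TraceMatrix, method: str = "moving_average", window_s: float = 1.0) -> TraceMatrix:
    """Smooth every trace, preserving length and time axis (reflect edges)."""
    win = int(round(window_s * traces.fs_hz))
    win = max(win, 3)
    if win % 2 == 0:
        win += 1
    if win > traces.n_frames:
        raise ValueError("smoothing window longer than trace")
    if method == "moving_average":
        sm = uniform_filter1d(traces.values, size=win, axis=1, mode="reflect")
    elif method == "savitzky_golay":
        sm = savgol_filter(traces.values, window_length=win, polyorder=2, axis=1)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    sm = np.clip(sm, 0.0, None)
    return replace(traces, values=sm)


def smooth_array(x: np.ndarray, fs_hz: float, window_s: float) -> np.ndarray:
    """Moving-average smooth of a bare 1-D/2-D array (reflect edges)."""
    win = max(int(round(window_s * fs_hz)), 1)
    if win <= 1:
        return np.asarray(x, dtype=float)
    if win % 2 == 0:
        win += 1
    return uniform_filter1d(np.asarray(x, dtype=float), size=win, axis=-1, mode="reflect")


# ---------------------------------------------------------------------------
# CSV / JSON I/O (formats shared with the simulator)


def write_trace_csv(traces: TraceMatrix, csv_path: str | Path, metadata_path: str | Path | None = None,
                    genotype: str | None = None) -> None:
    df = pd.DataFrame({"time_s": traces.time_s})
    for cid, row in zip(traces.cell_ids, traces.values):
        df[cid] = row
    df.to_csv(csv_path, index=False)
    if metadata_path is not None:
        meta = {
            "fs_hz": traces.fs_hz,
            "genotype": genotype,
            "cells": [
                {"id": cid, "class": (traces.labels or {}).get(cid)}
                for cid in traces.cell_ids
            ],
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))


def read_trace_csv(csv_path: str | Path, metadata_path: str | Path | None = None) -> TraceMatrix:
    df = pd.read_csv(csv_path)
    if "time_s" not in df.columns:
        raise ValueError(f"{csv_path}: first column must be 'time_s'")
    time_s = df["time_s"].to_numpy(dtype=float)
    cell_ids = [c for c in df.columns if c != "time_s"]
    values = df[cell_ids].to_numpy(dtype=float).T
    labels = None
    fs_hz = None
    if metadata_path is not None:
        meta = json.loads(Path(metadata_path).read_text())
        fs_hz = meta.get("fs_hz")
        cells = meta.get("cells") or []
        labels = {c["id"]: c.get("class") for c in cells if c.get("class") is not None} or None
    if fs_hz is None:
        if time_s.size < 2:
            raise ValueError("cannot infer sampling rate from a single frame")
        fs_hz = 1.0 / float(np.median(np.diff(time_s)))
    return TraceMatrix(time_s=time_s, values=values, cell_ids=cell_ids, fs_hz=float(fs_hz), labels=labels)


def write_diameter_csv(trace: VasomotionTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "diameter_um": trace.diameter}).to_csv(path, index=False)


def read_diameter_csv(path: str | Path) -> VasomotionTrace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "diameter_um" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s, diameter_um")
    return VasomotionTrace(df["time_s"].to_numpy(float), df["diameter_um"].to_numpy(float))
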