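"""Ca2+ transient detection and per-cell activity metrics on F/F0 traces.

Detection is noise-referenced: candidate peaks must exceed ``k_mad`` robust
noise SDs (1.4826 * MAD of the sub-threshold residual, iterated twice so spikes
do not contaminate the noise estimate), with a minimum prominence and a minimum
peak-to-peak separation.  FWHM is measured against a local (pre-onset median)
baseline with linearly interpolated half-height crossings, so drifting plateaus
measure correctly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .traces import NormalizedTraceMatrix, smooth_array

logger = logging.getLogger(__name__)

__all__ = [
    "TransientEvent",
    "CellMetrics",
    "StimulusResponse",
    "detect_transients",
    "event_fwhm",
    "cell_metrics",
    "metrics_table",
    "stimulus_response",
]


@dataclass
class TransientEvent:
    """One detected Ca2+ spike."""

    cell_id: str
    onset_s: float
    peak_s: float
    peak_ffo: float
    fwhm_s: float  # NaN when the half-height is never crossed
    auc: float
    truncated: bool = False  # clipped by a recording edge


@dataclass
class CellMetrics:
    cell_id: str
    frequency_hz: float
    mean_fwhm_s: float
    mean_peak_fold: float
    cumulative_activity: float
    n_events: int


@dataclass
class StimulusResponse:
    cell_id: str
    t_stim_s: float
    delta_steady_state: float
    delta_frequency_hz: float


def _robust_noise_sd(x: np.ndarray, k_mad: float) -> float:
    """1.4826*MAD of the sub-threshold residual, threshold re-estimated twice."""
    center = np.median(x)
    sd = 1.4826 * np.median(np.abs(x - center))
    for _ in range(2):
        sub = x[x <= center + k_mad * sd]
        if sub.size < 10:
            break
        center = np.median(sub)
        sd = 1.4826 * np.median(np.abs(sub - center))
    return float(sd)


def detect_transients(
    norm: NormalizedTraceMatrix,
    k_mad: float = 3.0,
    min_interval_s: float = 2.0,
    min_prominence: float = 0.5,
    smooth_window_s: float = 0.75,
) -> dict[str, list[TransientEvent]]:
    """Detect transient peaks per cell on lightly smoothed (F/F0 - 1).

    Peaks must exceed the noise-referenced threshold AND have prominence >=
    ``min_prominence``; of two peaks closer than ``min_interval_s`` the higher
    one is kept.  ``peak_ffo`` is read from the smoothed trace at the peak
    sample.  Returns events keyed by cell id, sorted by peak time.
    """
    if norm.n_frames < 10:
        raise ValueError("trace too short for detection (< 10 samples)")
    fs = norm.fs_hz
    med = np.median(norm.values)
    if abs(med - 1.0) > 0.25:
        warnings.warn(
            f"input does not look baseline-normalized (median F/F0 = {med:.2f})",
            stacklevel=2,
        )
    distance = max(int(round(min_interval_s * fs)), 1)
    out: dict[str, list[TransientEvent]] = {}
    for cid, row in zip(norm.cell_ids, norm.values):
        x_raw = row - 1.0
        x = smooth_array(x_raw, fs, smooth_window_s)
        noise_sd = _robust_noise_sd(x, k_mad)
        thr = k_mad * noise_sd
        peaks, _ = find_peaks(x, height=thr if thr > 0 else None,
                              prominence=min_prominence, distance=distance)
        events: list[TransientEvent] = []
        for p in peaks:
            height = x[p]
            onset_i = _onset_index(x, p, max(thr, 0.1 * height))
            ev = TransientEvent(
                cell_id=cid,
                onset_s=float(norm.time_s[onset_i]),
                peak_s=float(norm.time_s[p]),
                peak_ffo=float(1.0 + height),
                fwhm_s=math.nan,
                auc=0.0,
                truncated=False,
            )
            end_i = _offset_index(x, p, max(thr, 0.1 * height))
            ev.truncated = onset_i == 0 or end_i == x.size - 1
            seg = np.clip(x_raw[onset_i : end_i + 1], 0.0, None)
            ev.auc = float(np.trapezoid(seg, dx=1.0 / fs))
            ev.fwhm_s = event_fwhm(ev, norm)
            events.append(ev)
        out[cid] = events
    return out


def _onset_index(x: np.ndarray, peak: int, level: float) -> int:
    """Walk left from the peak until below ``level`` or a local minimum."""
    i = peak
    while i > 0 and x[i] > level and x[i - 1] <= x[i]:
        i -= 1
    return i


def _offset_index(x: np.ndarray, peak: int, level: float) -> int:
    """Walk right from the peak until below ``level`` or a local minimum."""
    i = peak
    n = x.size
    while i < n - 1 and x[i] > level and x[i + 1] <= x[i]:
        i += 1
    return i


def event_fwhm(event: TransientEvent, norm: NormalizedTraceMatrix) -> float:
    """Full width at half maximum (s) above a local pre-onset baseline.

    Half height is midway between the peak F/F0 and the median of the 5 s
    preceding onset; crossing times are linearly interpolated between samples.
    Returns NaN when the half level is never crossed on either side.
    """
    x = norm.cell(event.cell_id)
    t = norm.time_s
    fs = norm.fs_hz
    p = int(round(event.peak_s * fs))
    p = min(max(p, 0), x.size - 1)
    onset_i = min(max(int(round(event.onset_s * fs)), 0), x.size - 1)
    lo = max(onset_i - int(round(5.0 * fs)), 0)
    if lo < onset_i:
        local_base = float(np.median(x[lo:onset_i]))
    else:
        local_base = float(x[onset_i])
    half = local_base + 0.5 * (event.peak_ffo - local_base)

    # walk left
    left = math.nan
    for i in range(p, 0, -1):
        if x[i - 1] <= half <= x[i] or x[i - 1] <= half < x[i]:
            frac = (half - x[i - 1]) / (x[i] - x[i - 1]) if x[i] != x[i - 1] else 0.0
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
        if x[i - 1] > x[i] and x[i - 1] > event.peak_ffo:  # climbed into a taller neighbor
            break
    # walk right
    right = math.nan
    for i in range(p, x.size - 1):
        if x[i + 1] <= half <= x[i] or x[i + 1] <= half < x[i]:
            frac = (x[i] - half) / (x[i] - x[i + 1]) if x[i] != x[i + 1] else 0.0
            right = t[i] + frac * (t[i + 1] - t[i])
            break
        if x[i + 1] > x[i] and x[i + 1] > event.peak_ffo:
            break
    if math.isnan(left) or math.isnan(right):
        logger.debug("FWHM half-height never crossed for %s @ %.2f s", event.cell_id, event.peak_s)
        return math.nan
    return float(right - left)


def cell_metrics(
    events: list[TransientEvent],
    norm: NormalizedTraceMatrix,
    cell_id: str,
    window: tuple[float, float] | None = None,
) -> CellMetrics:
    """Per-cell summary over a half-open analysis window [t0, t1).

    Frequency is exactly count/duration.  Edge-truncated events count toward
    frequency but are excluded from FWHM/peak means.  Cumulative activity is
    the trapezoidal integral of max(F/F0 - 1, 0).
    """
    t0, t1 = window if window is not None else (float(norm.time_s[0]), float(norm.time_s[-1] + 1.0 / norm.fs_hz))
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    duration = t1 - t0
    in_win = [e for e in events if t0 <= e.peak_s < t1]
    clean = [e for e in in_win if not e.truncated and not math.isnan(e.fwhm_s)]
    x = norm.cell(cell_id)
    sel = (norm.time_s >= t0) & (norm.time_s < t1)
    activity = float(np.trapezoid(np.clip(x[sel] - 1.0, 0.0, None), dx=1.0 / norm.fs_hz))
    return CellMetrics(
        cell_id=cell_id,
        frequency_hz=len(in_win) / duration,
        mean_fwhm_s=float(np.mean([e.fwhm_s for e in clean])) if clean else math.nan,
        mean_peak_fold=float(np.mean([e.peak_ffo for e in clean])) if clean else math.nan,
        cumulative_activity=activity,
        n_events=len(in_win),
    )


def metrics_table(events_by_cell: dict[str, list[TransientEvent]], norm: NormalizedTraceMatrix,
                  window: tuple[float, float] | None = None):
    """All cells' metrics as a pandas DataFrame (one row per cell)."""
    import pandas as pd

    rows = []
    for cid in norm.cell_ids:
        m = cell_metrics(events_by_cell.get(cid, []), norm, cid, window)
        rows.append(vars(m))
    return pd.DataFrame(rows)


def stimulus_response(
    norm: NormalizedTraceMatrix,
    events_by_cell: dict[str, list[TransientEvent]],
    t_stim_s: float,
    pre_window_s: float = 120.0,
    post_window_s: float | None = None,
) -> list[StimulusResponse]:
    """Pre/post comparison around a stimulus at ``t_stim_s``.

    delta_steady_state = (mean post F/F0 - mean pre F/F0) / mean pre;
    delta_frequency_hz = post - pre event rate.  Windows are half-open and do
    not overlap the stimulus time.
    """
    t_end = float(norm.time_s[-1] + 1.0 / norm.fs_hz)
    if not (norm.time_s[0] <= t_stim_s < t_end):
        raise ValueError(f"t_stim_s={t_stim_s} outside the recording")
    pre0 = max(t_stim_s - pre_window_s, float(norm.time_s[0]))
    post1 = t_stim_s + post_window_s if post_window_s is not None else t_end
    post1 = min(post1, t_end)
    if pre0 >= t_stim_s or post1 <= t_stim_s:
        raise ValueError("pre/post windows do not fit the recording")
    pre_sel = (norm.time_s >= pre0) & (norm.time_s < t_stim_s)
    post_sel = (norm.time_s >= t_stim_s) & (norm.time_s < post1)
    out = []
    for cid, row in zip(norm.cell_ids, norm.values):
        pre_mean = float(row[pre_sel].mean())
        post_mean = float(row[post_sel].mean())
        evs = events_by_cell.get(cid, [])
        pre_f = sum(1 for e in evs if pre0 <= e.peak_s < t_stim_s) / (t_stim_s - pre0)
        post_f = sum(1 for e in evs if t_stim_s <= e.peak_s < post1) / (post1 - t_stim_s)
        out.append(
            StimulusResponse(
                cell_id=cid,
                t_stim_s=t_stim_s,
                delta_steady_state=(post_mean - pre_mean) / pre_mean,
                delta_frequency_hz=post_f - pre_f,
            )
        )
    return out
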