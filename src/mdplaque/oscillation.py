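"""Whole-plaque signal, oscillation regularity metrics and vasomotion coupling.

"Regular" vs "irregular chaotic-like" oscillation is operationalized with two
descriptors only — the coefficient of variation of inter-peak intervals and the
normalized spectral entropy of the Welch periodogram.  Ca2+/arteriole-diameter
coupling is the arg-max of the normalized cross-correlation at integer-sample
lags (positive lag = Ca2+ leads).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .traces import NormalizedTraceMatrix, VasomotionTrace
from .transients import detect_transients

__all__ = [
    "WholeMDSignal",
    "OscillationMetrics",
    "CouplingResult",
    "whole_md_signal",
    "oscillation_metrics",
    "vasomotion_coupling",
]


@dataclass
class WholeMDSignal:
    time_s: np.ndarray
    value: np.ndarray  # mean F/F0 across included cells
    n_cells: int
    fs_hz: float


@dataclass
class OscillationMetrics:
    dominant_frequency_hz: float
    isi_cv: float  # NaN when < 3 peaks
    spectral_entropy: float  # normalized to [0, 1]
    n_peaks: int


@dataclass
class CouplingResult:
    lag_s: float  # positive = first series (Ca2+) leads
    max_xcorr: float


def whole_md_signal(norm: NormalizedTraceMatrix, cell_ids: list[str] | None = None) -> WholeMDSignal:
    """Unweighted mean of F/F0 across the included cells, per frame."""
    ids = cell_ids if cell_ids is not None else list(norm.cell_ids)
    if not ids:
        raise ValueError("empty cell subset")
    idx = [norm.cell_ids.index(c) for c in ids]
    return WholeMDSignal(
        time_s=norm.time_s,
        value=norm.values[idx].mean(axis=0),
        n_cells=len(ids),
        fs_hz=norm.fs_hz,
    )


def oscillation_metrics(
    signal: WholeMDSignal,
    expected_period_s: float = 100.0 / 3.0,
    k_mad: float = 3.0,
    min_interval_s: float = 2.0,
    min_prominence: float = 0.5,
) -> OscillationMetrics:
    """Dominant frequency, inter-peak-interval CV and spectral entropy.

    Peaks come from the transient detector applied to the whole-plaque signal.
    The Welch window spans at least 4 expected periods; the dominant
    frequency is the periodogram arg-max over (0, fs/2]; spectral entropy is
    the Shannon entropy of the normalized periodogram divided by log(#bins).
    """
    n = signal.value.size
    if n / signal.fs_hz < 60.0:
        raise ValueError("need at least 60 s of signal")
    nperseg = min(n, max(int(round(4 * expected_period_s * signal.fs_hz)), 16))
    freqs, pxx = welch(signal.value - signal.value.mean(), fs=signal.fs_hz, nperseg=nperseg)
    nonzero = freqs > 0
    freqs, pxx = freqs[nonzero], pxx[nonzero]
    dominant = float(freqs[np.argmax(pxx)]) if pxx.size else math.nan
    total = pxx.sum()
    if total > 0 and pxx.size > 1:
        p = pxx / total
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum() / np.log(pxx.size))
    else:
        entropy = math.nan

    norm = NormalizedTraceMatrix(
        time_s=signal.time_s,
        values=signal.value[None, :],
        cell_ids=["whole_md"],
        fs_hz=signal.fs_hz,
        f0=np.array([1.0]),
        method="none",
    )
    with warnings.catch_warnings():
        # a plaque-mean signal legitimately sits well above 1 at high duty cycle
        warnings.simplefilter("ignore", UserWarning)
        events = detect_transients(
            norm, k_mad=k_mad, min_interval_s=min_interval_s, min_prominence=min_prominence
        )["whole_md"]
    peak_times = np.array([e.peak_s for e in events])
    if peak_times.size >= 3:
        isis = np.diff(peak_times)
        isi_cv = float(isis.std() / isis.mean()) if isis.mean() > 0 else math.nan
    else:
        isi_cv = math.nan
    return OscillationMetrics(
        dominant_frequency_hz=dominant,
        isi_cv=isi_cv,
        spectral_entropy=entropy,
        n_peaks=int(peak_times.size),
    )


def vasomotion_coupling(
    signal: WholeMDSignal,
    diameter: VasomotionTrace,
    max_lag_s: float = 15.0,
) -> CouplingResult:
    """Arg-max of the normalized cross-correlation within +/- max_lag_s.

    The diameter series is linearly resampled onto the Ca2+ time base when the
    axes differ.  Each candidate lag's correlation is the Pearson r over the
    overlapping segment; ties resolve to the smallest |lag|.
    """
    a = np.asarray(signal.value, dtype=float)
    t = signal.time_s
    duration = t[-1] - t[0]
    if max_lag_s >= duration / 4:
        raise ValueError("max_lag_s must be below a quarter of the duration")
    if diameter.time_s.shape == t.shape and np.allclose(diameter.time_s, t):
        b = np.asarray(diameter.diameter, dtype=float)
    else:
        b = np.interp(t, diameter.time_s, diameter.diameter)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    max_shift = int(round(max_lag_s * signal.fs_hz))
    lags = np.arange(-max_shift, max_shift + 1)
    rs = np.empty(lags.size)
    n = a.size
    for k, lag in enumerate(lags):
        # positive lag: a leads b -> compare a[t] with b[t + lag]
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        sx, sy = x.std(), y.std()
        rs[k] = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)) if sx > 0 and sy > 0 else -np.inf
    best_r = rs.max()
    ties = lags[rs >= best_r - 1e-12]
    best_lag = ties[np.lexsort((ties, np.abs(ties)))][0]
    return CouplingResult(lag_s=float(best_lag / signal.fs_hz), max_xcorr=float(best_r))
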