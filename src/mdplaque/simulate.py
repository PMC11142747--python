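"""Synthetic macula densa plaque simulator with planted ground truth.

Generates per-cell raw fluorescence traces from a coupled-oscillator model: a
latent pacemaker drive (jittered impulse train at ~0.03 Hz) plus per-cell
renewal firing with Gamma-distributed inter-spike intervals.  Each cell locks a
fraction ``c`` of its spikes to the drive (``c`` per class; lone cells have
``c = 0``), each spike is a Gaussian fluorescence bump, and an in-phase
arteriole-diameter signal is derived from the drive.  WT and NGFR-KO presets
mirror the regular vs. fast/irregular firing regimes; all randomness flows from
one seed through named substreams so adding cells never perturbs existing ones.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .traces import TraceMatrix, VasomotionTrace, write_trace_csv, write_diameter_csv

logger = logging.getLogger(__name__)

__all__ = [
    "PlaqueConfig",
    "GroundTruth",
    "SimulatedRecording",
    "preset",
    "simulate_plaque",
    "render_image_stack",
    "default_cell_centers",
    "write_recording",
]

MD_CLASSES = ("pacemaker", "follower_high", "follower_med", "follower_low", "lone")

_PURPOSES = {
    "drive": 0,
    "isi": 1,
    "assign": 2,
    "lock_jitter": 3,
    "baseline": 4,
    "noise": 5,
    "render": 6,
}
_DRIVE_STREAM = 1 << 20  # reserved stream id, outside any plausible cell index


def _rng(seed: int, stream: int, purpose: str) -> np.random.Generator:
    """Named substream: (seed, stream, purpose) -> independent Generator."""
    key = (stream, _PURPOSES[purpose])
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class PlaqueConfig:
    """Simulator parameters; defaults describe a WT-like pacemaker plaque."""

    n_cells: int = 25
    duration_s: float = 600.0
    fs_hz: float = 4.0
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "pacemaker": 2,
            "follower_high": 6,
            "follower_med": 10,
            "follower_low": 6,
            "lone": 1,
        }
    )
    drive_period_s: float = 100.0 / 3.0  # 1 / 0.03 Hz
    drive_phase_jitter_sd_s: float = 0.4
    isi_gamma_shape: float = 25.0
    isi_gamma_scale_s: float = 4.0 / 3.0
    spike_sigma_s: float = 0.85  # FWHM 2 s / 2.3548
    spike_amplitude_fold: float = 3.0  # added on top of baseline -> 4-fold peak
    baseline_au: float = 100.0
    baseline_cell_sd: float = 10.0
    noise_sd_frac: float = 0.02
    coupling_by_class: dict[str, float] = field(
        default_factory=lambda: {
            "pacemaker": 0.95,
            "follower_high": 0.85,
            "follower_med": 0.60,
            "follower_low": 0.30,
            "lone": 0.0,
        }
    )
    amplitude_by_class: dict[str, float] | None = None
    vaso_rel_amplitude: float = 0.1
    vaso_lag_s: float = 0.0
    vaso_baseline_um: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration_s and fs_hz must be positive")
        n_frames = self.fs_hz * self.duration_s
        if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 1:
            raise ValueError("fs_hz * duration_s must be a positive integer frame count")
        if self.n_cells != sum(self.class_counts.values()):
            raise ValueError("n_cells must equal the sum of class_counts")
        if self.spike_sigma_s <= 0:
            raise ValueError("spike_sigma_s must be positive")
        for cls, c in self.coupling_by_class.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling for {cls!r} outside [0, 1]")
        if self.coupling_by_class.get("lone", 0.0) != 0.0:
            raise ValueError("lone cells must have coupling 0")
        for cls in self.class_counts:
            if cls not in self.coupling_by_class:
                raise ValueError(f"no coupling coefficient for class {cls!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fs_hz * self.duration_s))

    def cell_classes(self) -> list[str]:
        """Per-cell class labels in stable (insertion) class order."""
        out: list[str] = []
        for cls, count in self.class_counts.items():
            out.extend([cls] * count)
        return out


@dataclass
class GroundTruth:
    """Planted truth used by recovery tests."""

    cell_class: list[str]
    coupling: np.ndarray
    spike_times_s: list[np.ndarray]
    drive_signal: np.ndarray
    drive_peak_times_s: np.ndarray
    vaso_lag_s: float


@dataclass
class SimulatedRecording:
    traces: TraceMatrix
    diameter: VasomotionTrace
    truth: GroundTruth
    config: PlaqueConfig


def preset(name: str) -> PlaqueConfig:
    """Named configurations: ``wt``, ``ngfr_ko``, ``cc4dp_multiclass``.

    ``wt``: 25-cell plaque, Gamma(25, 4/3 s) ISIs (mean 33.33 s, CV 0.2).
    ``ngfr_ko``: Gamma(2, 25/6 s) ISIs (mean 8.33 s — 4x firing rate, CV 0.71)
    and all coupling coefficients halved (degraded connectivity).
    ``cc4dp_multiclass``: WT plaque plus non-MD cell classes with lower spike
    amplitude, for cumulative-activity comparisons.
    """
    if name == "wt":
        return PlaqueConfig()
    if name == "ngfr_ko":
        cfg = PlaqueConfig(
            isi_gamma_shape=2.0,
            isi_gamma_scale_s=25.0 / 6.0,
        )
        cfg.coupling_by_class = {k: v / 2.0 for k, v in cfg.coupling_by_class.items()}
        return cfg
    if name == "cc4dp_multiclass":
        cfg = PlaqueConfig()
        cfg.class_counts = dict(cfg.class_counts)
        cfg.class_counts.update({"vascular_smooth_muscle": 4, "tubular_epithelial": 4})
        cfg.n_cells = sum(cfg.class_counts.values())
        cfg.coupling_by_class = dict(cfg.coupling_by_class)
        cfg.coupling_by_class.update({"vascular_smooth_muscle": 0.0, "tubular_epithelial": 0.0})
        cfg.amplitude_by_class = {"vascular_smooth_muscle": 1.0, "tubular_epithelial": 0.4}
        return cfg
    raise ValueError(f"unknown preset {name!r}; expected wt, ngfr_ko or cc4dp_multiclass")


def _gaussian_bumps(time_s: np.ndarray, centers: np.ndarray, amplitude: float, sigma: float,
                    out: np.ndarray | None = None) -> np.ndarray:
    """Sum of Gaussian bumps evaluated on ``time_s`` (windowed at +/-6 sigma)."""
    if out is None:
        out = np.zeros_like(time_s)
    half = 6.0 * sigma
    for c in np.atleast_1d(centers):
        i0 = np.searchsorted(time_s, c - half)
        i1 = np.searchsorted(time_s, c + half)
        seg = time_s[i0:i1] - c
        out[i0:i1] += amplitude * np.exp(-0.5 * (seg / sigma) ** 2)
    return out


def _renewal_spike_train(rng: np.random.Generator, shape: float, scale: float, duration: float) -> np.ndarray:
    """Spike centers of a Gamma-ISI renewal process on [0, duration).

    Starts the clock several mean intervals before zero so the process is
    (approximately) stationary at t=0 and the event rate is 1/(shape*scale)
    without start-up bias.
    """
    mean_isi = shape * scale
    t = -5.0 * mean_isi + rng.uniform(0.0, mean_isi)
    times = []
    while t < duration:
        if t >= 0.0:
            times.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(times)


def _drive_peaks(rng: np.random.Generator, period: float, jitter_sd: float, duration: float) -> np.ndarray:
    phase0 = rng.uniform(0.25, 0.75) * period
    n = int(math.ceil(duration / period)) + 1
    base = phase0 + period * np.arange(n)
    jittered = base + rng.normal(0.0, jitter_sd, size=n)
    jittered = np.sort(jittered)
    return jittered[(jittered >= 0.0) & (jittered < duration)]


def simulate_plaque(config: PlaqueConfig) -> SimulatedRecording:
    """Generate one plaque recording (traces + diameter + ground truth).

    Per cell, spike count and timing come from its Gamma-ISI renewal process;
    each spike is then assigned by Bernoulli(c) either to the nearest unused
    latent drive peak (plus a small lock jitter) or kept at its renewal time.
    F_i(t) = B_i * (1 + sum of bumps) + Gaussian noise; bumps add on the
    fractional scale, so overlapping spikes exceed the single-spike fold.
    """
    config.validate()
    n = config.n_frames
    time_s = np.arange(n) / config.fs_hz
    seed = config.seed

    drive_rng = _rng(seed, _DRIVE_STREAM, "drive")
    drive_peaks = _drive_peaks(
        drive_rng, config.drive_period_s, config.drive_phase_jitter_sd_s, config.duration_s
    )
    drive_signal = _gaussian_bumps(time_s, drive_peaks, 1.0, config.spike_sigma_s)

    classes = config.cell_classes()
    coupling = np.array([config.coupling_by_class[cls] for cls in classes])
    amp_by_class = config.amplitude_by_class or {}

    values = np.empty((config.n_cells, n))
    spike_times: list[np.ndarray] = []
    for i, cls in enumerate(classes):
        c = coupling[i]
        amp = amp_by_class.get(cls, config.spike_amplitude_fold)
        renewal = _renewal_spike_train(
            _rng(seed, i, "isi"), config.isi_gamma_shape, config.isi_gamma_scale_s, config.duration_s
        )
        assign_rng = _rng(seed, i, "assign")
        lock_rng = _rng(seed, i, "lock_jitter")
        used = np.zeros(drive_peaks.size, dtype=bool)
        cell_spikes = []
        for rt in renewal:
            if drive_peaks.size and assign_rng.random() < c:
                order = np.argsort(np.abs(drive_peaks - rt))
                placed = False
                for j in order:  # greedy: nearest unused drive peak within half a period
                    if not used[j] and abs(drive_peaks[j] - rt) <= config.drive_period_s / 2.0:
                        used[j] = True
                        st = drive_peaks[j] + lock_rng.normal(0.0, config.drive_phase_jitter_sd_s)
                        cell_spikes.append(st)
                        placed = True
                        break
                if not placed:
                    cell_spikes.append(rt)
            else:
                cell_spikes.append(rt)
        st = np.sort(np.asarray(cell_spikes))
        st = st[(st >= 0.0) & (st < config.duration_s)]
        if st.size > 1:  # enforce strictly increasing truth
            st = st[np.concatenate(([True], np.diff(st) > 1e-9))]
        spike_times.append(st)

        frac = _gaussian_bumps(time_s, st, amp, config.spike_sigma_s)
        b_rng = _rng(seed, i, "baseline")
        b_i = max(config.baseline_au + b_rng.normal(0.0, config.baseline_cell_sd), 0.1 * config.baseline_au)
        noise = _rng(seed, i, "noise").normal(0.0, config.noise_sd_frac * b_i, size=n)
        values[i] = np.clip(b_i * (1.0 + frac) + noise, 1e-6, None)

    cell_ids = [f"cell_{i + 1:03d}" for i in range(config.n_cells)]
    traces = TraceMatrix(
        time_s=time_s,
        values=values,
        cell_ids=cell_ids,
        fs_hz=config.fs_hz,
        labels=dict(zip(cell_ids, classes)),
    )

    # Arteriole diameter: drive-shaped modulation, shifted by vaso_lag_s
    d = drive_signal - drive_signal.mean()
    peak = np.max(np.abs(d))
    if peak > 0:
        d = d / peak
    d_shifted = np.interp(time_s - config.vaso_lag_s, time_s, d)
    diameter = VasomotionTrace(
        time_s=time_s,
        diameter=config.vaso_baseline_um * (1.0 + config.vaso_rel_amplitude * d_shifted),
    )

    truth = GroundTruth(
        cell_class=classes,
        coupling=coupling,
        spike_times_s=spike_times,
        drive_signal=drive_signal,
        drive_peak_times_s=drive_peaks,
        vaso_lag_s=config.vaso_lag_s,
    )
    return SimulatedRecording(traces=traces, diameter=diameter, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Optional image rendering (end-to-end test of the ROI-extraction stage)


def default_cell_centers(n_cells: int, frame_shape: tuple[int, int], blob_sigma_px: float) -> np.ndarray:
    """Well-separated grid of cell centers inside the frame."""
    h, w = frame_shape
    cols = int(math.ceil(math.sqrt(n_cells)))
    rows = int(math.ceil(n_cells / cols))
    margin = 4.0 * blob_sigma_px
    ys = np.linspace(margin, h - 1 - margin, rows)
    xs = np.linspace(margin, w - 1 - margin, cols)
    centers = [(y, x) for y in ys for x in xs][:n_cells]
    return np.asarray(centers)


def render_image_stack(
    recording: SimulatedRecording,
    frame_shape: tuple[int, int] = (96, 96),
    cell_centers: np.ndarray | None = None,
    blob_sigma_px: float = 3.0,
    poisson_noise: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces as 2-D Gaussian blobs; returns (stack, ROI label mask).

    Each frame is a sum of blobs whose integrated intensity is proportional to
    the cell's fluorescence in that frame.  Mask pixels are labeled by the
    nearest generating cell within ``3 * blob_sigma_px``; labels are 1-based in
    trace row order.
    """
    if blob_sigma_px <= 0:
        raise ValueError("blob_sigma_px must be positive")
    values = recording.traces.values
    n_cells, n_frames = values.shape
    h, w = frame_shape
    if n_cells == 0:
        return np.zeros((n_frames, h, w)), np.zeros((h, w), dtype=np.int32)
    if cell_centers is None:
        cell_centers = default_cell_centers(n_cells, frame_shape, blob_sigma_px)
    cell_centers = np.asarray(cell_centers, dtype=float)
    if cell_centers.shape != (n_cells, 2):
        raise ValueError("cell_centers must be (n_cells, 2) (row, col)")
    if np.any(cell_centers < 0) or np.any(cell_centers[:, 0] > h - 1) or np.any(cell_centers[:, 1] > w - 1):
        raise ValueError("cell centers must lie inside the frame")
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            if np.linalg.norm(cell_centers[i] - cell_centers[j]) < 2.0 * blob_sigma_px:
                logger.warning(
                    "cell centers %d and %d closer than 2*blob_sigma_px; ROI cross-talk likely", i, j
                )

    yy, xx = np.mgrid[0:h, 0:w]
    # (cells, h*w) unit-integral blob footprints
    foot = np.empty((n_cells, h * w))
    dist2 = np.empty((n_cells, h * w))
    for i, (cy, cx) in enumerate(cell_centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        g = np.exp(-0.5 * d2 / blob_sigma_px**2)
        foot[i] = (g / g.sum()).ravel()
        dist2[i] = d2.ravel()

    stack = (values.T @ foot).reshape(n_frames, h, w)
    if poisson_noise:
        rng = _rng(recording.config.seed, _DRIVE_STREAM + 1, "render")
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)

    nearest = np.argmin(dist2, axis=0)
    within = dist2[nearest, np.arange(h * w)] <= (3.0 * blob_sigma_px) ** 2
    mask = np.where(within, nearest + 1, 0).astype(np.int32).reshape(h, w)
    return stack, mask


# ---------------------------------------------------------------------------
# Disk output


def write_recording(recording: SimulatedRecording, outdir: str | Path, render: bool = False,
                    genotype: str | None = None) -> dict[str, str]:
    """Write traces/diameter/ground-truth (CSV/JSON) and optional TIFFs; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "traces": str(outdir / "traces.csv"),
        "metadata": str(outdir / "metadata.json"),
        "diameter": str(outdir / "diameter.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    write_trace_csv(recording.traces, files["traces"], files["metadata"], genotype=genotype)
    write_diameter_csv(recording.diameter, files["diameter"])
    truth = recording.truth
    gt = {
        "cell_class": truth.cell_class,
        "coupling": truth.coupling.tolist(),
        "spike_times_s": [st.tolist() for st in truth.spike_times_s],
        "drive_peak_times_s": truth.drive_peak_times_s.tolist(),
        "vaso_lag_s": truth.vaso_lag_s,
        "config": {k: v for k, v in asdict(recording.config).items()},
    }
    Path(files["ground_truth"]).write_text(json.dumps(gt, indent=2))
    if render:
        import tifffile

        stack, mask = render_image_stack(recording)
        files["stack"] = str(outdir / "stack.tif")
        files["mask"] = str(outdir / "mask.tif")
        tifffile.imwrite(files["stack"], stack.astype(np.float32))
        tifffile.imwrite(files["mask"], mask.astype(np.uint16))
    return files
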