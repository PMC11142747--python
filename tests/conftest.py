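import numpy as np
import pytest

from mdplaque import simulate, traces


def make_trace_matrix(values, fs_hz=4.0, cell_ids=None, labels=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_cells, n_frames = values.shape
    if cell_ids is None:
        cell_ids = [f"cell_{i + 1:03d}" for i in range(n_cells)]
    return traces.TraceMatrix(
        time_s=np.arange(n_frames) / fs_hz,
        values=values,
        cell_ids=cell_ids,
        fs_hz=fs_hz,
        labels=labels,
    )


def make_norm(values, fs_hz=4.0, cell_ids=None):
    """Wrap already-normalized (F/F0) values in a NormalizedTraceMatrix."""
    tm = make_trace_matrix(values, fs_hz=fs_hz, cell_ids=cell_ids)
    return traces.NormalizedTraceMatrix(
        time_s=tm.time_s,
        values=tm.values,
        cell_ids=tm.cell_ids,
        fs_hz=tm.fs_hz,
        f0=np.ones(tm.n_cells),
        method="given",
    )


def gaussian_spike_trace(centers, sigma_s=0.85, amplitude=3.0, duration_s=350.0, fs_hz=4.0,
                         baseline=100.0, noise_sd=0.0, seed=0):
    """Raw trace: baseline * (1 + Gaussian bumps) + optional noise."""
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    x = np.zeros_like(t)
    for c in np.atleast_1d(centers):
        x += amplitude * np.exp(-0.5 * ((t - c) / sigma_s) ** 2)
    raw = baseline * (1.0 + x)
    if noise_sd:
        raw = raw + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return make_trace_matrix(raw, fs_hz=fs_hz)


def normalize_default(tm):
    return traces.normalize(tm, traces.estimate_baseline(tm))


def simulate_norm(preset_name, seed, duration_s=600.0):
    cfg = simulate.preset(preset_name)
    cfg.seed = seed
    cfg.duration_s = duration_s
    rec = simulate.simulate_plaque(cfg)
    return rec, normalize_default(rec.traces)


@pytest.fixture(scope="session")
def wt7():
    """WT preset, seed 7, 600 s: (recording, normalized traces)."""
    return simulate_norm("wt", 7)


@pytest.fixture(scope="session")
def wt_recordings_20():
    """20 seeded WT recordings with their normalized traces."""
    return [simulate_norm("wt", seed) for seed in range(20)]


@pytest.fixture(scope="session")
def ko_recordings_20():
    return [simulate_norm("ngfr_ko", seed) for seed in range(20)]
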