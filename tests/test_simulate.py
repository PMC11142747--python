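import dataclasses
import logging

import numpy as np
import pytest

from mdplaque import simulate, traces
from mdplaque.simulate import PlaqueConfig, preset, render_image_stack, simulate_plaque

from conftest import normalize_default


class TestPreset:
    def test_wt_has_25_cells(self):
        assert preset("wt").n_cells == 25

    def test_wt_class_counts(self):
        assert preset("wt").class_counts == {
            "pacemaker": 2,
            "follower_high": 6,
            "follower_med": 10,
            "follower_low": 6,
            "lone": 1,
        }

    def test_ko_to_wt_mean_isi_ratio_is_one_quarter(self):
        wt, ko = preset("wt"), preset("ngfr_ko")
        mean = lambda c: c.isi_gamma_shape * c.isi_gamma_scale_s
        assert mean(ko) / mean(wt) == pytest.approx(0.25, rel=1e-12)

    def test_lone_coupling_zero(self):
        assert preset("wt").coupling_by_class["lone"] == 0.0

    def test_ko_coupling_halved(self):
        wt, ko = preset("wt"), preset("ngfr_ko")
        for cls in wt.coupling_by_class:
            assert ko.coupling_by_class[cls] == pytest.approx(wt.coupling_by_class[cls] / 2)

    def test_multiclass_adds_low_amplitude_classes(self):
        cfg = preset("cc4dp_multiclass")
        assert cfg.n_cells == sum(cfg.class_counts.values()) > 25
        assert cfg.amplitude_by_class
        assert min(cfg.amplitude_by_class.values()) < cfg.spike_amplitude_fold

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("mystery")


class TestConfigValidation:
    def test_cell_count_mismatch(self):
        cfg = preset("wt")
        cfg.n_cells = 24
        with pytest.raises(ValueError, match="class_counts"):
            cfg.validate()

    def test_nonpositive_duration(self):
        cfg = preset("wt")
        cfg.duration_s = -5.0
        with pytest.raises(ValueError):
            simulate_plaque(cfg)

    def test_coupling_out_of_range(self):
        cfg = preset("wt")
        cfg.coupling_by_class = dict(cfg.coupling_by_class, pacemaker=1.5)
        with pytest.raises(ValueError, match="coupling"):
            cfg.validate()

    def test_fractional_frame_count(self):
        cfg = preset("wt")
        cfg.duration_s = 100.1
        cfg.fs_hz = 3.0
        with pytest.raises(ValueError, match="frame count"):
            cfg.validate()


class TestDeterminism:
    @pytest.mark.parametrize("name", ["wt", "ngfr_ko", "cc4dp_multiclass"])
    def test_identical_seed_identical_output(self, name):
        cfg1, cfg2 = preset(name), preset(name)
        cfg1.seed = cfg2.seed = 42
        cfg1.duration_s = cfg2.duration_s = 120.0
        r1, r2 = simulate_plaque(cfg1), simulate_plaque(cfg2)
        np.testing.assert_array_equal(r1.traces.values, r2.traces.values)
        np.testing.assert_array_equal(r1.diameter.diameter, r2.diameter.diameter)
        for a, b in zip(r1.truth.spike_times_s, r2.truth.spike_times_s):
            np.testing.assert_array_equal(a, b)

    def test_adding_cells_preserves_existing_substreams(self):
        cfg = preset("wt")
        cfg.duration_s = 120.0
        bigger = dataclasses.replace(cfg, class_counts=dict(cfg.class_counts))
        bigger.class_counts["extra"] = 3
        bigger.coupling_by_class = dict(cfg.coupling_by_class, extra=0.5)
        bigger.n_cells = cfg.n_cells + 3
        r1, r2 = simulate_plaque(cfg), simulate_plaque(bigger)
        np.testing.assert_array_equal(r1.traces.values, r2.traces.values[: cfg.n_cells])


class TestGenerativeModel:
    def test_noiseless_pacemaker_peak_is_fourfold(self):
        cfg = PlaqueConfig(
            n_cells=1,
            class_counts={"pacemaker": 1},
            coupling_by_class={"pacemaker": 1.0, "lone": 0.0},
            noise_sd_frac=0.0,
            baseline_cell_sd=0.0,
            drive_phase_jitter_sd_s=0.0,
            seed=5,
        )
        rec = simulate_plaque(cfg)
        ffo = rec.traces.values[0] / cfg.baseline_au
        # every isolated spike peaks at F/F0 = 1 + amplitude fold (overlapping
        # spikes add on the fractional scale and may legitimately exceed it)
        st = rec.truth.spike_times_s[0]
        gaps = np.diff(st, prepend=-np.inf, append=np.inf)
        isolated = st[(gaps[:-1] > 6.0) & (gaps[1:] > 6.0)]
        assert isolated.size > 5
        fs = rec.traces.fs_hz
        for s in isolated:
            i = int(round(s * fs))
            window = ffo[max(i - 4, 0) : i + 5]
            assert window.max() == pytest.approx(4.0, abs=0.05)

    def test_all_fluorescence_positive(self, wt7):
        rec, _ = wt7
        assert np.all(rec.traces.values > 0)

    def test_spike_times_strictly_increasing(self, wt7):
        rec, _ = wt7
        for st in rec.truth.spike_times_s:
            assert np.all(np.diff(st) > 0)

    def test_uncoupled_rate_converges_to_gamma_mean(self):
        # empirical rate -> 1/(shape*scale) within 5% at 10 000 s
        cfg = PlaqueConfig(
            n_cells=1,
            class_counts={"pacemaker": 1},
            coupling_by_class={"pacemaker": 0.0, "lone": 0.0},
            duration_s=10_000.0,
            seed=1,
        )
        rec = simulate_plaque(cfg)
        rate = rec.truth.spike_times_s[0].size / cfg.duration_s
        expected = 1.0 / (cfg.isi_gamma_shape * cfg.isi_gamma_scale_s)
        assert rate == pytest.approx(expected, rel=0.05)

    def test_lone_cell_uncorrelated(self, wt_recordings_20):
        rs = []
        for rec, norm in wt_recordings_20:
            lone_idx = rec.truth.cell_class.index("lone")
            r = np.corrcoef(norm.values)[lone_idx]
            rs.extend(np.delete(r, lone_idx))
        assert abs(np.mean(rs)) < 0.05

    def test_follower_high_pairs_more_correlated_than_with_lone(self, wt7):
        rec, norm = wt7
        r = np.corrcoef(norm.values)
        cls = np.array(rec.truth.cell_class)
        hi = np.flatnonzero(cls == "follower_high")
        lone = np.flatnonzero(cls == "lone")
        hi_pairs = [r[i, j] for i in hi for j in hi if i < j]
        cross = [r[i, j] for i in hi for j in lone]
        assert np.mean(hi_pairs) > np.mean(cross)

    def test_vasomotion_in_phase_without_lag(self):
        cfg = preset("wt")
        cfg.noise_sd_frac = 0.0
        cfg.vaso_lag_s = 0.0
        cfg.seed = 3
        rec = simulate_plaque(cfg)
        a = rec.traces.values.mean(axis=0)
        b = rec.diameter.diameter
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        shifts = np.arange(-20, 21)
        rs = [
            np.corrcoef(a[max(0, s):len(a) + min(0, s)], b[max(0, -s):len(b) - max(0, s)])[0, 1]
            for s in shifts
        ]
        best = shifts[int(np.argmax(rs))]
        assert abs(best) <= 1  # zero lag within one sample


class TestRenderImageStack:
    def _recording(self, values, fs=4.0):
        from conftest import make_trace_matrix

        tm = make_trace_matrix(values, fs_hz=fs)
        cfg = PlaqueConfig(
            n_cells=tm.n_cells,
            class_counts={"pacemaker": tm.n_cells},
            coupling_by_class={"pacemaker": 0.0, "lone": 0.0},
            duration_s=tm.n_frames / fs,
            fs_hz=fs,
        )
        truth = simulate.GroundTruth(
            cell_class=["pacemaker"] * tm.n_cells,
            coupling=np.zeros(tm.n_cells),
            spike_times_s=[np.array([])] * tm.n_cells,
            drive_signal=np.zeros(tm.n_frames),
            drive_peak_times_s=np.array([]),
            vaso_lag_s=0.0,
        )
        diam = traces.VasomotionTrace(tm.time_s, np.full(tm.n_frames, 20.0))
        return simulate.SimulatedRecording(tm, diam, truth, cfg)

    def test_constant_cell_gives_identical_frames(self):
        rec = self._recording(np.full((1, 8), 100.0))
        stack, mask = render_image_stack(rec, frame_shape=(32, 32))
        for frame in stack[1:]:
            np.testing.assert_allclose(frame, stack[0])
        assert mask.max() == 1

    def test_empty_cell_list(self):
        rec = self._recording(np.full((1, 4), 100.0))
        rec.traces.values = np.empty((0, 4))
        rec.traces.cell_ids = []
        stack, mask = render_image_stack(rec, frame_shape=(16, 16))
        assert not stack.any() and not mask.any()

    def test_roundtrip_roi_extraction(self, wt7):
        rec, _ = wt7
        sub = dataclasses.replace(rec)
        sub.traces = rec.traces.select(rec.traces.cell_ids[:4])
        sub.traces.values = sub.traces.values[:, :200]
        sub.traces.time_s = rec.traces.time_s[:200]
        stack, mask = render_image_stack(sub, frame_shape=(64, 64), blob_sigma_px=2.5)
        extracted = traces.extract_roi_traces(stack, mask, fs_hz=4.0)
        for i in range(4):
            r = np.corrcoef(extracted.values[i], sub.traces.values[i])[0, 1]
            assert r > 0.99

    def test_close_centers_warn(self, caplog):
        rec = self._recording(np.full((2, 4), 100.0))
        centers = np.array([[16.0, 16.0], [16.0, 18.0]])
        with caplog.at_level(logging.WARNING, logger="mdplaque.simulate"):
            render_image_stack(rec, frame_shape=(32, 32), cell_centers=centers, blob_sigma_px=3.0)
        assert any("cross-talk" in m for m in caplog.messages)

    def test_center_outside_frame_rejected(self):
        rec = self._recording(np.full((1, 4), 100.0))
        with pytest.raises(ValueError, match="inside the frame"):
            render_image_stack(rec, frame_shape=(16, 16), cell_centers=np.array([[40.0, 8.0]]))


class TestWriteRecording:
    def test_files_round_trip(self, tmp_path):
        cfg = preset("wt")
        cfg.seed = 2
        cfg.duration_s = 60.0
        rec = simulate_plaque(cfg)
        files = simulate.write_recording(rec, tmp_path, genotype="wt")
        back = traces.read_trace_csv(files["traces"], files["metadata"])
        np.testing.assert_allclose(back.values, rec.traces.values, rtol=1e-9)
        assert back.fs_hz == rec.traces.fs_hz
        assert back.labels == rec.traces.labels
        diam = traces.read_diameter_csv(files["diameter"])
        np.testing.assert_allclose(diam.diameter, rec.diameter.diameter, rtol=1e-9)
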