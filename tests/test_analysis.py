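"""Tests for sweeps, seizure detection and report export."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ftsts import (ProtocolSpec, SimulationConfig, SweepSpec, build_connectivity,
                   detect_seizures, efficacy_rate, export_report,
                   percent_change_map, run_simulation, run_sweep)
from ftsts.analysis import SweepResult


class TestPercentChangeMap:
    def test_identity_gives_zero(self):
        w = np.random.default_rng(0).random((4, 4)) + 0.5
        assert np.allclose(percent_change_map(w, w), 0.0)

    def test_uniform_scaling(self):
        w = np.ones((3, 3))
        assert np.allclose(percent_change_map(w, 1.5 * w), 50.0)

    def test_zero_baseline_flagged_nan(self):
        w0 = np.array([[1.0, 0.0]])
        out = percent_change_map(w0, np.array([[2.0, 3.0]]))
        assert out[0, 0] == pytest.approx(100.0)
        assert np.isnan(out[0, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_change_map(np.ones((2, 2)), np.ones((3, 2)))


class TestSeizureDetection:
    def _fake_result(self, times, duration, n_e=500):
        from ftsts.engine import SimulationResult
        cfg = SimulationConfig(duration=duration)
        return SimulationResult(
            config=cfg, spike_ids_e=np.zeros(len(times), np.int32),
            spike_times_e=np.asarray(times, float),
            spike_ids_i=np.empty(0, np.int32), spike_times_i=np.empty(0),
            weight_times=np.array([0.0, duration]),
            avg_ei_weight=np.array([100.0, 100.0]), snapshots={})

    def test_quiet_raster_has_no_episodes(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 10000.0, 500)  # ~0.1 Hz/neuron
        assert detect_seizures(self._fake_result(times, 10000.0)) == []

    def test_dense_burst_is_detected(self):
        rng = np.random.default_rng(0)
        # 2 s burst at ~40 Hz/neuron between 3-5 s
        burst = rng.uniform(3000.0, 5000.0, 500 * 40 * 2)
        eps = detect_seizures(self._fake_result(burst, 10000.0))
        assert len(eps) == 1
        lo, hi = eps[0]
        assert lo == pytest.approx(3000.0, abs=200.0)
        assert hi == pytest.approx(5000.0, abs=200.0)

    def test_excluded_window_is_ignored(self):
        rng = np.random.default_rng(0)
        burst = rng.uniform(3000.0, 5000.0, 500 * 40 * 2)
        eps = detect_seizures(self._fake_result(burst, 10000.0),
                              exclude_windows=[(2900.0, 5100.0)])
        assert eps == []


@pytest.fixture(scope="module")
def sweep_base():
    from ftsts import ConnectivitySpec, SeizureInput
    return SimulationConfig(
        duration=1500.0,
        connectivity=ConnectivitySpec(N_E=20, N_I=20, sigma_E=0.1,
                                      sigma_I=0.12),
        seizure=SeizureInput(amplitude=200.0, start=100.0,
                             duration=300.0, targets=(8, 12)),
        record_dt=100.0)


class TestSweep:

    def test_single_cell_matches_direct_run(self, sweep_base):
        spec = SweepSpec(amplitudes=(2.0,), train_offsets=(-0.5,),
                         protocols=("inverted-standard",), seeds=(4,),
                         base=sweep_base, protocol_onset=800.0,
                         protocol_duration=600.0)
        result = run_sweep(spec)
        assert len(result.runs) == 1
        proto = ProtocolSpec(name="inverted-standard", amplitude=2.0,
                             train_offset=-0.5, onset=800.0, duration=600.0)
        cfg = dataclasses.replace(sweep_base, seed=4, electrical=[proto],
                                  record_spikes=False)
        direct = efficacy_rate(
            run_simulation(cfg, weights=build_connectivity(
                sweep_base.connectivity)),
            (800.0, 1400.0))
        assert result.runs["rate"].iloc[0] == pytest.approx(direct)

    def test_row_count_is_cells_times_seeds(self, sweep_base):
        spec = SweepSpec(amplitudes=(1.0, 2.0), train_offsets=(0.0, 1.0),
                         seeds=(1, 2), base=sweep_base,
                         protocol_onset=800.0, protocol_duration=600.0)
        result = run_sweep(spec)
        assert len(result.runs) == 2 * 2 * 2
        assert len(result.summary) == 4
        assert (result.summary["n"] == 2).all()

    def test_failed_cell_recorded_and_sweep_continues(self, sweep_base):
        # width not divisible by dt -> per-cell hard error inside the run
        spec = SweepSpec(widths=(0.7, 1.0), seeds=(1,), base=sweep_base,
                         protocol_onset=800.0, protocol_duration=600.0)
        result = run_sweep(spec)
        assert len(result.runs) == 2
        bad = result.runs[result.runs["width"] == 0.7].iloc[0]
        assert np.isnan(bad["rate"]) and "divide" in bad["error"]
        good = result.runs[result.runs["width"] == 1.0].iloc[0]
        assert np.isfinite(good["rate"])

    def test_empty_grid_rejected(self, sweep_base):
        with pytest.raises(ValueError):
            SweepSpec(amplitudes=(), base=sweep_base)


class TestExport:
    def _tiny_result(self):
        runs = pd.DataFrame([
            {"protocol": "inverted-standard", "amplitude": 2.0, "width": 1.0,
             "inter_pulse_interval": 10.0, "train_offset": -0.5,
             "overlap_fraction": 0.0, "seed": 1, "error": "", "rate": 5.5},
        ])
        summary = runs.groupby(
            ["protocol", "amplitude", "width", "inter_pulse_interval",
             "train_offset", "overlap_fraction"], sort=False)["rate"].agg(
            rate_mean="mean", rate_sd="std", n="count").reset_index()
        return SweepResult(runs=runs, summary=summary)

    def test_single_cell_export(self, tmp_path):
        paths = export_report(self._tiny_result(), tmp_path,
                              make_figures=False)
        summary = pd.read_csv(paths["summary"])
        assert len(summary) == 1
        best = pd.read_csv(paths["best"])
        assert set(best["direction"]) == {"increase", "decrease"}

    def test_empty_result_writes_headers(self, tmp_path):
        empty = SweepResult(runs=pd.DataFrame(), summary=pd.DataFrame())
        paths = export_report(empty, tmp_path, make_figures=False)
        best = pd.read_csv(paths["best"])
        assert list(best.columns)[0] == "direction"
        assert best.empty

    def test_reexport_identical_bytes(self, tmp_path):
        r = self._tiny_result()
        a = export_report(r, tmp_path / "a", make_figures=False)
        b = export_report(r, tmp_path / "b", make_figures=False)
        assert a["summary"].read_bytes() == b["summary"].read_bytes()
        assert a["runs"].read_bytes() == b["runs"].read_bytes()
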