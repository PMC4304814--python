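"""RIDE: shifting, Woody latency estimation, decomposition, reconstruction."""
import numpy as np
import pytest

from riderp.core import EpochSet, ParameterError
from riderp.erp import average_evoked
from riderp.ride import (
    RideConfig,
    _best_lag,
    _lat_samples,
    _stack_shifted,
    decompose_components,
    run_ride,
    shift_waveform,
    update_latencies,
    woody_latency,
)
from riderp.simulate import SimConfig, simulate_trials
from tests.conftest import single_component_config

FS = 500.0


def _bump_epochs(shifts_ms, mu=400.0, width=30.0, n_ch=3, amplitude=5.0):
    """Noise-free trials: one bump per trial at mu + shift."""
    times = np.arange(-100, 500) * 2.0
    data = np.stack(
        [
            amplitude
            * np.tile(np.exp(-0.5 * ((times - mu - s) / width) ** 2), (n_ch, 1))
            for s in shifts_ms
        ]
    )
    montage = ["Cz", "CPz", "Pz"][:n_ch]
    return EpochSet(data, times, np.array(["SEM"] * len(shifts_ms)), montage=montage)


class TestShiftWaveform:
    def test_zero_shift_identity(self, rng):
        w = rng.normal(size=(3, 100))
        assert np.array_equal(shift_waveform(w, 0.0, FS), w)

    def test_impulse_moves_by_shift(self):
        w = np.zeros((1, 300))
        w[0, 100] = 1.0
        out = shift_waveform(w, 20.0, FS, taper_ms=0.0)  # +10 samples
        assert out[0, 110] == 1.0
        assert out.sum() == 1.0

    def test_roundtrip_preserves_interior_bump(self):
        times = np.arange(600) * 2.0
        w = np.exp(-0.5 * ((times - 600.0) / 60.0) ** 2)[None, :]
        back = shift_waveform(shift_waveform(w, 80.0, FS), -80.0, FS)
        interior = slice(100, 500)
        assert np.allclose(back[0, interior], w[0, interior], atol=1e-12)

    def test_nonfinite_shift_rejected(self):
        with pytest.raises(ParameterError):
            shift_waveform(np.zeros((1, 10)), np.nan, FS)


class TestWoodyLatency:
    def test_identical_trials_all_zero(self):
        es = _bump_epochs([0.0] * 6)
        lat = woody_latency(es, (200, 600), ["Cz", "CPz", "Pz"])
        assert np.all(lat == 0.0)

    def test_noise_free_shifts_recovered_exactly(self):
        shifts = [-40.0, 0.0, 40.0] * 3
        es = _bump_epochs(shifts)
        lat = woody_latency(es, (200, 600), ["Cz", "CPz", "Pz"])
        assert np.array_equal(lat, np.array(shifts))

    def test_flat_trials_warn_and_zero(self):
        es = _bump_epochs([0.0, 20.0, -20.0])
        es.data[1] = 0.0
        with pytest.warns(UserWarning, match="flat"):
            lat = woody_latency(es, (200, 600), ["Cz", "CPz", "Pz"])
        assert lat[1] == 0.0

    def test_default_windows(self):
        cfg = RideConfig()
        assert cfg.c1_window == (200.0, 600.0)
        assert cfg.c2_window == (400.0, 800.0)


class TestBestLagTieBreak:
    def test_symmetric_two_peak_prefers_smaller_lag(self):
        """Equal correlation peaks at -10 and +30 samples: -10 wins."""
        n = 600
        i0 = 150
        template = np.exp(-0.5 * ((np.arange(200) - 100) / 8.0) ** 2)
        sig = np.zeros(n)
        for d in (-10, 30):
            sig[i0 + d : i0 + d + 200] += template
        assert _best_lag(sig, template, i0, 100) == -10


class TestDecomposition:
    def test_all_zero_data_all_zero_waveforms(self):
        es = _bump_epochs([0.0] * 4)
        es.data[:] = 0.0
        lats = {"S": np.zeros(4), "C1": np.zeros(4), "C2": np.zeros(4)}
        waves, converged = decompose_components(es, lats, RideConfig())
        assert converged
        for w in waves.values():
            assert np.allclose(w, 0.0)

    def test_stimulus_locked_bump_lands_in_s(self):
        es = _bump_epochs([0.0] * 8, mu=300.0, width=40.0)
        lats = {"S": np.zeros(8), "C1": np.zeros(8), "C2": np.zeros(8)}
        waves, _ = decompose_components(es, lats, RideConfig())
        model = waves["S"] + waves["C1"] + waves["C2"]
        assert np.allclose(model, es.data[0], atol=0.05)
        # the bump is stimulus-locked, so C1/C2 stay (nearly) empty
        assert np.abs(waves["C1"]).max() < 0.05 * np.abs(waves["S"]).max()
        assert np.abs(waves["C2"]).max() < 0.05 * np.abs(waves["S"]).max()

    def test_known_jitter_recovers_c1_shape(self, layout):
        cfg = single_component_config(seed=13, n_trials=80, noise_sd=0.0)
        epochs, truth = simulate_trials(cfg, layout)
        es = epochs[0]
        true_lat = truth.latencies["C1"][0]
        lats = {
            "S": np.zeros(es.n_trials),
            "C1": true_lat - np.median(true_lat),
            "C2": np.zeros(es.n_trials),
        }
        # run the inner loop to its fixed point (standalone use)
        waves, _ = decompose_components(es, lats, RideConfig(max_inner=200))
        cz = es.channel_index("Cz")
        true_wave = 5.0 * truth.waveforms["C1"][cz]
        sl = (es.times >= 250) & (es.times <= 550)
        r = np.corrcoef(waves["C1"][cz, sl], true_wave[sl])[0, 1]
        assert r > 0.99


class TestUpdateLatencies:
    def test_truth_is_fixed_point(self, layout):
        cfg = single_component_config(seed=14, n_trials=40, noise_sd=0.0)
        epochs, truth = simulate_trials(cfg, layout)
        es = epochs[0]
        true_lat = truth.latencies["C1"][0] - np.median(truth.latencies["C1"][0])
        grid_lat = _lat_samples(true_lat, es.fs) * 1000.0 / es.fs  # sample grid
        cz = es.channel_index("Cz")
        waves = {
            "S": np.zeros((es.n_channels, len(es.times))),
            "C1": 5.0 * truth.waveforms["C1"],
            "C2": np.zeros((es.n_channels, len(es.times))),
        }
        lats = {"S": np.zeros(es.n_trials), "C1": grid_lat, "C2": np.zeros(es.n_trials)}
        out = update_latencies(es, waves, lats, "C1", RideConfig())
        # fixed point up to the 1-sample grid
        assert np.abs(out - grid_lat).max() <= 2.0 + 1e-9

    def test_all_zero_template_keeps_latencies(self):
        es = _bump_epochs([0.0] * 4)
        waves = {n: np.zeros((3, 600)) for n in ("S", "C1", "C2")}
        lats = {"S": np.zeros(4), "C1": np.array([0.0, 2.0, -2.0, 4.0]), "C2": np.zeros(4)}
        with pytest.warns(UserWarning, match="all-zero"):
            out = update_latencies(es, waves, lats, "C1", RideConfig())
        assert np.array_equal(out, lats["C1"])


class TestRunRide:
    def test_zero_jitter_zero_noise_equals_conventional(self, layout):
        from riderp.simulate import default_components

        comps = default_components(layout, list(layout.channels))
        for c in comps:
            c.latency_sd = 0.0
        cfg = SimConfig(seed=15, n_subjects=1, trials_per_condition=10,
                        noise_sd=0.0, components=comps, subject_gain_sd=0.0)
        epochs, _ = simulate_trials(cfg, layout)
        es = epochs[0].select_conditions("SEM")
        res = run_ride(es)
        assert res.converged
        assert res.n_iterations <= 2
        conv = average_evoked(es, "SEM")
        num = np.sqrt(np.mean((res.reconstructed.data - conv.data) ** 2, axis=1))
        den = np.sqrt(np.mean(conv.data**2, axis=1)).max()
        assert (num / den).max() < 0.01

    def test_fixed_seed_deterministic(self, layout):
        cfg = single_component_config(seed=16, n_trials=30, noise_sd=1.0)
        epochs, _ = simulate_trials(cfg, layout)
        r1 = run_ride(epochs[0])
        epochs2, _ = simulate_trials(cfg, layout)
        r2 = run_ride(epochs2[0])
        assert np.array_equal(r1.reconstructed.data, r2.reconstructed.data)
        for n in r1.clusters:
            assert np.array_equal(r1.clusters[n].latencies, r2.clusters[n].latencies)

    def test_latency_window_containment(self, jittered_single_component):
        """Estimated latencies keep the component inside its search window."""
        es, _ = jittered_single_component
        res = run_ride(es)
        for name, win in (("C1", (200, 600)), ("C2", (400, 800))):
            half = (win[1] - win[0]) / 2
            assert np.abs(res.clusters[name].latencies).max() <= half

    def test_jitter_recovery_beats_conventional(self, jittered_single_component):
        """sigma = w = 50 ms: conventional peak ~0.71 of truth, RIDE >= 0.90."""
        es, truth = jittered_single_component
        conv = average_evoked(es, "SEM")
        res = run_ride(es)
        cz = es.channel_index("Cz")
        assert conv.data[cz].max() / 5.0 == pytest.approx(0.7071, abs=0.03)
        assert res.reconstructed.data[cz].max() / 5.0 >= 0.90
        r = np.corrcoef(
            res.clusters["C1"].latencies,
            truth.latencies["C1"][0] - np.median(truth.latencies["C1"][0]),
        )[0, 1]
        assert r >= 0.8

    def test_decomposition_completeness(self, jittered_single_component):
        """Average of per-trial shifted cluster sums ~= conventional average."""
        es, _ = jittered_single_component
        res = run_ride(es)
        assert res.converged
        model = np.zeros_like(es.data)
        for cl in res.clusters.values():
            model += _stack_shifted(cl.waveform, _lat_samples(cl.latencies, es.fs), 25)
        conv = es.data.mean(axis=0)
        rel = np.sqrt(np.mean((model.mean(axis=0) - conv) ** 2)) / np.sqrt(
            np.mean(conv**2)
        )
        assert rel < 0.02

    @pytest.mark.parametrize("sigma", [20.0, 40.0, 60.0])
    def test_amplitude_recovery_dominates_conventional(self, layout, sigma):
        """Reconstructed peak error < conventional-average peak error."""
        cfg = single_component_config(seed=17, n_trials=100, latency_sd=sigma,
                                      noise_sd=0.25)
        epochs, _ = simulate_trials(cfg, layout)
        es = epochs[0]
        cz = es.channel_index("Cz")
        conv_err = abs(average_evoked(es, "SEM").data[cz].max() - 5.0)
        res = run_ride(es)
        recon_err = abs(res.reconstructed.data[cz].max() - 5.0)
        assert recon_err < conv_err
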