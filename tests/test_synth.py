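"""Synthetic generator: determinism, threshold model, transients, rendering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ins2p.io import extract_roi_traces
from ins2p.spatial import multiplicity_class
from ins2p.synth import (SyntheticConfig, kernel_peak_time, make_fluence_fields,
                         recruit, render_movie, sample_cells,
                         simulate_experiment, simulate_study, synthesize_traces,
                         transient_kernel)
from ins2p.traces import analyze_trace_array


class TestDeterminism:
    def test_same_seed_bytewise_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=123, n_cells=20)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        np.testing.assert_array_equal(a.traces, b.traces)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for name in pa:
            assert open(pa[name], "rb").read() == open(pb[name], "rb").read()

    def test_different_seed_differs(self):
        a = simulate_experiment(SyntheticConfig(seed=1, n_cells=10))
        b = simulate_experiment(SyntheticConfig(seed=2, n_cells=10))
        assert not np.array_equal(a.traces, b.traces)


class TestSampleCells:
    def test_paper_scale_cell_count(self):
        cells = sample_cells(SyntheticConfig(seed=0, n_cells=294))
        assert len(cells) == 294
        assert cells.x_um.between(0, 300).all()
        assert cells.depth_um.between(96, 255).all()

    def test_degenerate_fov_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(fov_um=(0.0, 0.0))

    def test_nonpositive_cell_count_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_cells=0)


class TestRecruitment:
    def test_low_threshold_center_cell_responds_to_all(self):
        cfg = SyntheticConfig(seed=0, n_cells=2)
        cells = pd.DataFrame({
            "roi_id": [1, 2],
            "x_um": [150.0, 0.0],          # beam center / far corner
            "y_um": [150.0, 0.0],
            "depth_um": [100.0, 100.0],
            "threshold_j_cm2": [0.05, 0.05],
            "f0": [1000.0, 1000.0],
        })
        truth = recruit(cells, make_fluence_fields(cfg))
        center = truth[truth.roi_id == 1]
        corner = truth[truth.roi_id == 2]
        assert center.responds.all()
        assert not corner.responds.any()

    def test_nested_responder_sets_over_threshold_sweep(self):
        """Brute-force sweep: for every threshold and position, responding
        at an energy implies responding at every higher energy."""
        cfg = SyntheticConfig(seed=0, n_cells=1)
        fields = make_fluence_fields(cfg)
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({
            "roi_id": np.arange(500),
            "x_um": rng.uniform(0, 300, 500),
            "y_um": rng.uniform(0, 300, 500),
            "depth_um": rng.uniform(96, 255, 500),
            "threshold_j_cm2": np.geomspace(1e-3, 3.0, 500),
            "f0": np.full(500, 1000.0),
        })
        truth = recruit(cells, fields)
        mat = truth.pivot(index="roi_id", columns="energy_density",
                          values="responds").to_numpy()
        # cumulative from the right: True at e_i implies True at e_{i+1}
        assert np.all(mat[:, :-1] <= mat[:, 1:])

    def test_nonresponders_have_zero_amplitude(self, default_sim):
        truth = default_sim.truth
        assert (truth.loc[~truth.responds, "amplitude"] == 0.0).all()
        assert (truth.loc[truth.responds, "amplitude"] > 0.0).all()


class TestTransientKernel:
    def test_unit_peak_normalization_against_fine_grid(self):
        t = np.linspace(5.0, 8.0, 200_001)
        g = transient_kernel(t, 5.0, 0.08, 0.4)
        assert g.max() == pytest.approx(1.0, abs=1e-8)
        assert np.argmax(g) / 200_000 * 3.0 == pytest.approx(
            kernel_peak_time(0.08, 0.4), abs=1e-4)

    def test_zero_before_onset(self):
        t = np.arange(0, 10, 0.01)
        g = transient_kernel(t, 5.0, 0.08, 0.4)
        assert np.all(g[t <= 5.0] == 0.0)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            transient_kernel(np.arange(3.0), 0.0, -1.0, 0.4)


class TestTraceSynthesis:
    def test_noise_free_nonresponder_is_flat(self):
        cfg = dataclasses.replace(SyntheticConfig(seed=0, n_cells=3),
                                  noise_sd=0.0, threshold_median=100.0)
        sim = simulate_experiment(cfg)
        assert not sim.truth.responds.any()
        f0 = sim.cells.f0.to_numpy()[:, None, None, None]
        np.testing.assert_array_equal(sim.traces, np.broadcast_to(
            f0, sim.traces.shape))

    def test_noise_free_responder_peak_equals_amplitude(self):
        """With the unit-peak kernel the recovered peak dF/F0 equals the
        ground-truth amplitude up to frame sampling of the kernel maximum."""
        cfg = dataclasses.replace(SyntheticConfig(seed=3, n_cells=1),
                                  noise_sd=0.0, threshold_median=1e-3,
                                  threshold_sigma=0.0)
        cells = sample_cells(cfg)
        cells.loc[0, ["x_um", "y_um"]] = cfg.beam_center_um
        truth = recruit(cells, make_fluence_fields(cfg), cfg.amplitude_max,
                        cfg.amplitude_scale)
        truth["amplitude"] = np.where(truth.responds, 0.07, 0.0)
        traces = synthesize_traces(cells, truth, cfg)
        dff = traces[0, 0, 0] / cells.f0[0] - 1.0
        t = np.arange(cfg.n_frames) / cfg.frame_rate
        sampled_peak_factor = transient_kernel(
            t, cfg.stim_onset, cfg.tau_rise, cfg.tau_decay).max()
        assert dff.max() == pytest.approx(0.07 * sampled_peak_factor,
                                          rel=1e-12)
        assert dff.max() == pytest.approx(0.07, rel=1e-3)

    def test_trials_share_amplitude_but_not_noise(self, default_sim):
        tr = default_sim.traces
        assert not np.array_equal(tr[:, :, 0, :], tr[:, :, 1, :])

    def test_poisson_noise_mode(self):
        cfg = dataclasses.replace(SyntheticConfig(seed=4, n_cells=5),
                                  noise_model="poisson")
        sim = simulate_experiment(cfg)
        assert np.all(sim.traces >= 0)
        assert np.allclose(sim.traces, np.round(sim.traces))


class TestEndToEndRecovery:
    def test_fractions_within_binomial_ci_of_truth(self, default_sim,
                                                   default_calls):
        """Recovered responder fractions agree with the generator's ground
        truth within the binomial 95% CI at every energy."""
        n = default_sim.config.n_cells
        for e in default_sim.energies:
            p = default_sim.truth.query("energy_density == @e")["responds"].mean()
            rec = default_calls.query("energy_density == @e")["is_responder"].mean()
            half = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(rec - p) <= half

    def test_near_zero_noise_classification_is_exact(self, lownoise_sim,
                                                     lownoise_calls):
        merged = lownoise_calls.merge(lownoise_sim.truth,
                                      on=["roi_id", "energy_density"])
        assert (merged.is_responder == merged.responds).all()

    def test_amplitude_recovery_slope_near_one(self, lownoise_sim,
                                               lownoise_calls):
        merged = lownoise_calls.merge(lownoise_sim.truth,
                                      on=["roi_id", "energy_density"])
        resp = merged[merged.responds & (merged.amplitude > 0.01)]
        slope = np.polyfit(resp.amplitude, resp.peak_dff, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_recruitment_monotone_and_saturating(self, default_sim):
        # monotone at the default size (exact under nestedness)
        fr = default_sim.ground_truth_fractions()["fraction_pct"].to_numpy()
        assert np.all(np.diff(fr) >= 0)
        # saturating shape assessed at large n (population property)
        cfg = SyntheticConfig(seed=5, n_cells=20_000)
        truth = recruit(sample_cells(cfg), make_fluence_fields(cfg))
        fr_big = truth.groupby("energy_density")["responds"].mean().to_numpy()
        steps = np.diff(fr_big)
        assert np.all(steps >= 0)
        assert np.all(np.diff(steps) <= 0)   # shrinking increments

    def test_multi_responders_more_central_than_single(self):
        """Noise-free threshold model at large n: higher multiplicity means
        tighter spatial spread and larger central share."""
        cfg = SyntheticConfig(seed=5, n_cells=20_000)
        cells = sample_cells(cfg)
        truth = recruit(cells, make_fluence_fields(cfg))
        nresp = truth.groupby("roi_id")["responds"].sum()
        cells = cells.set_index("roi_id")
        cells["label"] = multiplicity_class(nresp).values
        sig = {lab: cells.loc[cells.label == lab, "x_um"].std(ddof=1)
               for lab in ("1x", "2x", "3x+4x")}
        assert sig["3x+4x"] < sig["2x"] < sig["1x"]


class TestStudySimulation:
    def test_offsets_move_the_recruited_cluster(self):
        cfg = SyntheticConfig(seed=9, n_cells=400)
        study = simulate_study(cfg, [(0.0, 0.0), (40.0, -30.0)])
        centers = {}
        for eid, sim in study.items():
            nresp = sim.truth.groupby("roi_id")["responds"].sum()
            multi = sim.cells.set_index("roi_id").loc[nresp >= 3]
            centers[eid] = (multi.x_um.mean(), multi.y_um.mean())
        dx = centers["exp2"][0] - centers["exp1"][0]
        dy = centers["exp2"][1] - centers["exp1"][1]
        assert dx == pytest.approx(40.0, abs=20.0)
        assert dy == pytest.approx(-30.0, abs=20.0)


class TestBleaching:
    def test_bleached_baseline_declines_exponentially(self):
        from ins2p.traces import baseline_stability, frame_window
        cfg = dataclasses.replace(SyntheticConfig(seed=22, n_cells=250),
                                  bleach_rate=0.02)
        sim = simulate_experiment(cfg)
        b0, b1 = frame_window(3.0, 4.5, cfg.frame_rate)
        f0s = sim.traces[..., b0:b1].mean(axis=-1)
        recs = [f0s[:, e, t] for e in range(4) for t in range(5)]
        out = baseline_stability(recs)
        assert np.all(np.diff(out.f0_normalized) < 0)
        expected = np.exp(-0.02 * np.arange(20))
        np.testing.assert_allclose(out.f0_normalized, expected, atol=5e-3)


class TestMovieRendering:
    @pytest.fixture()
    def small_setup(self):
        cfg = dataclasses.replace(SyntheticConfig(seed=6, n_cells=4),
                                  fov_um=(200.0, 200.0))
        cells = pd.DataFrame({
            "roi_id": [1, 2, 3, 4],
            "x_um": [40.0, 150.0, 40.0, 150.0],
            "y_um": [40.0, 40.0, 150.0, 150.0],
        })
        rng = np.random.default_rng(0)
        traces = 1000 + rng.uniform(-50, 50, (4, 30))
        return cfg, cells, traces

    def test_round_trip_extraction(self, small_setup):
        cfg, cells, traces = small_setup
        movie, mask = render_movie(cells, traces, cfg)
        roi_ids, got = extract_roi_traces(movie, mask)
        np.testing.assert_array_equal(roi_ids, [1, 2, 3, 4])
        np.testing.assert_allclose(got, traces, atol=1.0)

    def test_empty_cells_give_background_only(self, small_setup):
        cfg, _, _ = small_setup
        movie, mask = render_movie(pd.DataFrame(columns=["roi_id", "x_um",
                                                         "y_um"]),
                                   np.empty((0, 10)), cfg)
        assert movie.max() == 0 and mask.max() == 0

    def test_saturating_frame_clamps_with_warning(self, small_setup):
        cfg, cells, traces = small_setup
        traces = traces.copy()
        traces[0, 5] = 1e9
        with pytest.warns(UserWarning, match="clamp"):
            movie, _ = render_movie(cells, traces, cfg)
        assert movie.max() == np.iinfo(np.uint16).max

    def test_too_small_grid_rejected(self, small_setup):
        cfg, cells, traces = small_setup
        with pytest.raises(ValueError, match="too small"):
            render_movie(cells, traces, cfg, px_size_um=100.0)
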