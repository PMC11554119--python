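"""Synthetic-data generator: feature hierarchy, BOLD, behavior, ground truth."""

import numpy as np
import pandas as pd
import pytest

from conftest import spaced_events
from pescale.design import generate_localizer, generate_run
from pescale.features import average_rdms, correlation_rdm, trial_surprise
from pescale.glm import build_design, fit_glm, highpass
from pescale.lss import lss
from pescale.synth import (default_ground_truth, synth_behavior, synth_bold,
                           synth_feature_hierarchy, synth_localizer_bold,
                           synth_nuisance, synth_trial_betas)


class TestFeatureHierarchy:
    def test_degenerate_mixing_pins_layers_to_latents(self):
        # with zero noise, first layer carries only the low latent and last
        # layer only the high latent; their RDMs must match the RDMs of pure
        # latent projections regenerated from the same seeds
        layers = synth_feature_hierarchy(n_stimuli=12, noise_sd=0.0,
                                         rng_seed=3, feature_dim=500)
        first = correlation_rdm(layers[0]).lower_triangle()
        last = correlation_rdm(layers[-1]).lower_triangle()
        # latent RDMs via an independent draw of the same latents
        rng = np.random.default_rng(3)
        low = rng.normal(size=(12, 6))
        high = rng.normal(size=(12, 6))
        low_rdm = correlation_rdm(
            type(layers[0])(layer_id="low", matrix=low,
                            stimulus_ids=layers[0].stimulus_ids))
        high_rdm = correlation_rdm(
            type(layers[0])(layer_id="high", matrix=high,
                            stimulus_ids=layers[0].stimulus_ids))
        # random projection to many features approximately preserves geometry
        assert np.corrcoef(first, low_rdm.lower_triangle())[0, 1] > 0.9
        assert np.corrcoef(last, high_rdm.lower_triangle())[0, 1] > 0.9
        assert np.corrcoef(first, high_rdm.lower_triangle())[0, 1] < 0.5

    def test_adjacent_layers_more_similar_than_extremes(self):
        wins = 0
        for seed in range(10):
            layers = synth_feature_hierarchy(n_stimuli=20, rng_seed=seed)
            tri = [correlation_rdm(fs).lower_triangle() for fs in layers]
            adjacent = np.mean([np.corrcoef(tri[k], tri[k + 1])[0, 1]
                                for k in range(7)])
            extreme = np.corrcoef(tri[0], tri[7])[0, 1]
            wins += adjacent > extreme
        assert wins == 10

    def test_instance_averaging_denoises(self):
        # the noise-free reference is the RDM of the mixed latent factors
        # themselves; instances vary by projection and feature noise
        closer = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            low = rng.normal(size=(10, 6))
            high = rng.normal(size=(10, 6))
            w = np.linspace(0, 1, 8)[4]
            latent_mixed = np.hstack([(1 - w) * low, w * high])
            from pescale.features import FeatureSpace
            clean = correlation_rdm(FeatureSpace(
                layer_id="latent", matrix=latent_mixed,
                stimulus_ids=tuple(f"stim{i:03d}" for i in range(10))))
            noisy = [correlation_rdm(synth_feature_hierarchy(
                n_stimuli=10, noise_sd=1.0, rng_seed=seed, instance_id=i)[4])
                for i in range(10)]
            avg = average_rdms(noisy)
            d_avg = np.linalg.norm(avg.values - clean.values)
            d_single = np.linalg.norm(noisy[0].values - clean.values)
            closer += d_avg < d_single
        assert closer >= 9

    def test_monotone_schedule_required(self):
        with pytest.raises(ValueError, match="monotone"):
            synth_feature_hierarchy(mixing_schedule=np.array(
                [0.0, 0.5, 0.3, 0.6, 0.7, 0.8, 0.9, 1.0]))


class TestSynthBold:
    def test_no_scaling_means_identical_unexpected_responses(self, stimuli):
        events = spaced_events(n_trials=10, spacing=40.0, stimuli=stimuli)
        truth = default_ground_truth(grid=(4, 2, 2), high_slope=0.0,
                                     rng_seed=0)
        z = np.linspace(-1.5, 1.5, (events["condition"] == "unexpected").sum())
        from pescale.features import SurpriseVector
        unexpected_idx = events.index[events["condition"] == "unexpected"].to_numpy()
        sv = SurpriseVector(model_id="layer8", trial_index=unexpected_idx,
                            raw=z, z=(z - z.mean()) / z.std())
        bold = synth_bold(events, {"layer8": sv}, truth, noise_sd=0.0,
                          rng_seed=0)
        betas = lss(bold, events).betas
        sel = (events["condition"] == "unexpected").to_numpy()[
            (events["condition"] != "nogo").to_numpy()]
        spread = betas[sel].std(axis=0)
        assert np.allclose(spread, 0.0, atol=1e-8)

    def test_peak_difference_closed_form(self, stimuli):
        # isolated trials: peak response difference between the max- and
        # min-surprise trials equals slope * (z_max - z_min) * kernel peak
        events = spaced_events(n_trials=8, spacing=60.0, stimuli=stimuli)
        events["condition"] = "unexpected"
        events["trial_type"] = "unexpected"
        truth = default_ground_truth(grid=(4, 2, 2), high_slope=2.0,
                                     baseline=0.0, rng_seed=0)
        from pescale.features import SurpriseVector
        z = np.linspace(-1.0, 1.0, 8)
        z = (z - z.mean()) / z.std()
        sv = SurpriseVector(model_id="layer8", trial_index=events.index.to_numpy(),
                            raw=z, z=z)
        bold = synth_bold(events, {"layer8": sv}, truth, noise_sd=0.0, rng_seed=0)
        vox = truth.voxels_in("high_scaling")[0]
        ts = bold.timeseries()[:, vox]
        # kernel peak of the convolved 500 ms boxcar
        from pescale.glm import _convolve_events
        kernel = _convolve_events(np.array([0.0]), np.array([0.5]),
                                  np.array([1.0]), 40, 1.0)
        k_peak_idx = int(np.argmax(kernel))
        # signed response sampled at the kernel peak lag of each trial
        peaks = [ts[int(row["onset"]) + k_peak_idx]
                 for _, row in events.iterrows()]
        expected_diff = 2.0 * (z.max() - z.min()) * kernel.max()
        assert max(peaks) - min(peaks) == pytest.approx(expected_diff, rel=1e-3)

    def test_seeds_differ_only_in_noise(self, stimuli):
        events = spaced_events(n_trials=6, stimuli=stimuli)
        truth = default_ground_truth(grid=(2, 2, 2), rng_seed=0)
        clean_a = synth_bold(events, {}, truth, noise_sd=0.0, rng_seed=1)
        clean_b = synth_bold(events, {}, truth, noise_sd=0.0, rng_seed=2)
        assert np.array_equal(clean_a.data, clean_b.data)
        noisy = synth_bold(events, {}, truth, noise_sd=1.0, rng_seed=1)
        assert not np.array_equal(noisy.data, clean_a.data)

    def test_drift_removed_by_highpass(self, stimuli):
        events = spaced_events(n_trials=6, stimuli=stimuli)
        truth = default_ground_truth(grid=(2, 2, 2), rng_seed=0)
        drifty = synth_bold(events, {}, truth, noise_sd=0.0,
                            drift_amplitude=5.0, rng_seed=3)
        clean = synth_bold(events, {}, truth, noise_sd=0.0, rng_seed=3)
        resid = highpass(drifty.timeseries()) - highpass(clean.timeseries())
        assert np.abs(resid).max() < 0.05 * np.abs(clean.timeseries()).max()

    def test_glm_parameter_recovery_noise_free(self, run_events, layer_rdms,
                                               stimuli):
        # full-recovery invariant: fitting the GLM on clean synthetic data
        # returns the planted slopes to numerical precision
        sv = trial_surprise(layer_rdms["layer8"], run_events, stimuli,
                            model_id="layer8")
        truth = default_ground_truth(grid=(4, 2, 2), high_slope=0.8, rng_seed=1)
        bold = synth_bold(run_events, {"layer8": sv}, truth, noise_sd=0.0,
                          rng_seed=0)
        design = build_design(run_events, [sv], bold.n_scans)
        fit = fit_glm(bold.timeseries(), design)
        col = design.names.index("mod_layer8")
        high = truth.voxels_in("high_scaling")
        assert np.allclose(fit.beta[col, high], 0.8, rtol=1e-6)


class TestSynthLocalizer:
    def test_patterns_recoverable_at_zero_noise(self, stimuli):
        loc = generate_localizer(stimuli, rng_seed=4)
        truth = default_ground_truth(grid=(4, 4, 2), rng_seed=5)
        bold = synth_localizer_bold(loc, truth, noise_sd=0.0, rng_seed=0)
        stack = lss(bold, loc)      # model intact and scrambled miniblocks
        intact = loc[loc["condition"] == "intact"]
        stim_ids = sorted(intact["stim_id"].unique())
        selective = truth.population != "non_selective"
        for k, stim in enumerate(stim_ids):
            sel = (stack.trials["stim_id"] == stim).to_numpy()
            mean_beta = stack.betas[sel].mean(axis=0)
            planted = truth.baseline + truth.stimulus_patterns[k]
            assert np.allclose(mean_beta[selective], planted[selective],
                               atol=1e-6)

    def test_intact_exceeds_scrambled_in_selective_voxels(self, stimuli):
        loc = generate_localizer(stimuli, rng_seed=6)
        truth = default_ground_truth(grid=(4, 4, 2), rng_seed=7)
        bold = synth_localizer_bold(loc, truth, noise_sd=0.0, rng_seed=0)
        stack = lss(bold, loc)      # all miniblocks (no no-go in localizer)
        intact = (stack.trials["condition"] == "intact").to_numpy()
        selective = truth.population != "non_selective"
        diff = (stack.betas[intact].mean(axis=0)
                - stack.betas[~intact].mean(axis=0))
        assert (diff[selective] > 0).mean() > 0.95

    def test_decoding_approaches_limits_with_noise(self, stimuli):
        from pescale.decode import cross_validated_accuracy
        loc = generate_localizer(stimuli, rng_seed=8)
        truth = default_ground_truth(grid=(4, 4, 2), rng_seed=9)
        sel_vox = np.where(truth.population != "non_selective")[0]
        accs = {}
        # noise relative to the convolved block response (amplitude ~ 10 x
        # the summed kernel): tiny noise -> perfect, huge noise -> chance
        for noise in (0.05, 5000.0):
            bold = synth_localizer_bold(loc, truth, noise_sd=noise, rng_seed=1)
            stack = lss(bold, loc)
            intact_rows = (stack.trials["condition"] == "intact").to_numpy()
            accs[noise] = cross_validated_accuracy(
                stack.betas[intact_rows][:, sel_vox],
                stack.trials.loc[intact_rows, "stim_id"].to_numpy())
        assert accs[0.05] == 1.0
        assert abs(accs[5000.0] - 0.125) < 0.2


class TestSynthTrialBetas:
    def test_planted_linear_model(self):
        z = np.linspace(-2, 2, 50)
        betas = synth_trial_betas(z, slope=1.5, noise_sd=0.0, baseline=3.0)
        assert np.allclose(betas[:, 0], 3.0 + 1.5 * z)

    def test_noise_controls_per_subject_r(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=448)
        z = (z - z.mean()) / z.std()
        sigma = np.sqrt(1 / 0.1 ** 2 - 1)    # target per-subject r ~ 0.1
        rs = [np.corrcoef(z, synth_trial_betas(z, 1.0, sigma, rng=rng)[:, 0])[0, 1]
              for _ in range(200)]
        assert np.mean(rs) == pytest.approx(0.1, abs=0.01)


class TestSynthBehavior:
    def test_planted_rt_ordering(self, tpm, stimuli):
        rts = {c: [] for c in ("expected", "unexpected_same", "unexpected_diff")}
        for seed in range(50):
            events = generate_run(tpm, rng_seed=seed)
            resp = synth_behavior(events, stimuli, rng_seed=seed)
            for cond in rts:
                rts[cond].extend(resp.loc[resp["condition3"] == cond, "rt_ms"])
        means = {c: np.mean(v) for c, v in rts.items()}
        assert means["expected"] < means["unexpected_same"] < means["unexpected_diff"]
        assert means["expected"] == pytest.approx(501, abs=8)
        assert means["unexpected_diff"] == pytest.approx(524, abs=8)

    def test_zero_error_rate_gives_full_accuracy(self, run_events, stimuli):
        resp = synth_behavior(run_events, stimuli,
                              error_rates={"expected": 0.0, "unexpected_same": 0.0,
                                           "unexpected_diff": 0.0},
                              false_alarm_rate=0.0, rng_seed=0)
        assert resp["correct"].all()

    def test_zero_sd_gives_exact_means(self, run_events, stimuli):
        resp = synth_behavior(run_events, stimuli, rt_sd=0.0, rng_seed=0)
        go = resp[resp["condition3"] != "nogo"]
        for cond, grp in go.groupby("condition3"):
            expected = {"expected": 501.0, "unexpected_same": 509.0,
                        "unexpected_diff": 524.0}[cond]
            assert np.allclose(grp["rt_ms"], expected)


def test_nuisance_has_all_columns_and_is_seeded():
    a = synth_nuisance(100, rng_seed=1)
    b = synth_nuisance(100, rng_seed=1)
    assert list(a.columns) == ["trans_x", "trans_y", "trans_z", "rot_x",
                               "rot_y", "rot_z", "fd", "csf", "wm"]
    pd.testing.assert_frame_equal(a, b)
    assert (a["fd"] >= 0).all()
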