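"""HRF, design construction, filtering, smoothing, OLS fits, VIF, group tests."""

import numpy as np
import pandas as pd
import pytest

from pescale.design import run_duration
from pescale.features import trial_surprise
from pescale.glm import (DesignMatrix, build_design, cluster_inference,
                         cohens_dz, dct_highpass_basis, fit_glm, fixed_effects,
                         group_test, highpass, hrf_double_gamma, smooth,
                         t_to_z, vif)
from pescale.synth import default_ground_truth, synth_bold, synth_nuisance


class TestHrf:
    def test_shape_properties(self):
        t = np.arange(0, 32, 0.01)
        h = hrf_double_gamma(t)
        assert h[0] == 0.0
        peak_t = t[np.argmax(h)]
        assert 4.0 <= peak_t <= 7.0
        assert h.min() < 0
        assert abs(h.min()) < h.max()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            hrf_double_gamma(np.array([-1.0, 0.0, 1.0]))


class TestBuildDesign:
    def test_column_bookkeeping(self, run_events, layer_rdms, stimuli):
        svs = [trial_surprise(layer_rdms[m], run_events, stimuli, model_id=m)
               for m in ("layer2", "layer8")]
        n_scans = int(np.ceil(run_duration(run_events)))
        nuis = synth_nuisance(n_scans, rng_seed=0)
        design = build_design(run_events, svs, n_scans, nuisance=nuis)
        # 3 conditions + 2 modulators, same again as derivatives, 9 nuisance,
        # 1 constant
        assert len(design.names) == 3 + 2 + 5 + 9 + 1
        assert len(design.columns_of_class("modulator")) == 2
        assert len(design.columns_of_class("derivative")) == 5

    def test_no_unexpected_trials_warns_and_drops_modulators(self, run_events,
                                                             layer_rdms, stimuli):
        expected_only = run_events[run_events["condition"] == "expected"]
        sv = trial_surprise(layer_rdms["layer8"], run_events, stimuli,
                            model_id="layer8")
        n_scans = int(np.ceil(run_duration(run_events)))
        with pytest.warns(UserWarning, match="no unexpected"):
            design = build_design(expected_only, [sv], n_scans,
                                  add_derivatives=False)
        assert design.columns_of_class("modulator") == []

    def test_modulator_nearly_orthogonal_to_main_effect(self, tpm, layer_rdms,
                                                        stimuli):
        from pescale.design import generate_run
        for seed in range(10):
            events = generate_run(tpm, rng_seed=100 + seed)
            sv = trial_surprise(layer_rdms["layer8"], events, stimuli,
                                model_id="layer8")
            n_scans = int(np.ceil(run_duration(events)))
            design = build_design(events, [sv], n_scans, add_derivatives=False)
            x = design.frame
            r = np.corrcoef(x["unexpected"], x["mod_layer8"])[0, 1]
            assert abs(r) < 0.3

    def test_rank_deficiency_detected(self, run_events):
        n_scans = int(np.ceil(run_duration(run_events)))
        dup = pd.DataFrame({"a": np.sin(np.arange(n_scans) / 10),
                            "b": np.sin(np.arange(n_scans) / 10)})
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(run_events, [], n_scans, nuisance=dup,
                         add_derivatives=False)


class TestHighpass:
    def test_constant_removed(self):
        out = highpass(np.full(300, 7.0))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_slow_cosine_attenuated(self):
        t = np.arange(400)          # TR 1 s, 256 s period < cutoff frequency
        y = np.cos(2 * np.pi * t / 256)
        out = highpass(y, tr=1.0, cutoff_s=128.0)
        assert out.std() / y.std() < 0.05

    def test_white_noise_variance_reduction_bounded(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(500, 50))
        out = highpass(y, tr=1.0, cutoff_s=128.0)
        dim = dct_highpass_basis(500, 1.0, 128.0).shape[1] + 1
        reduction = 1 - out.var(axis=0).mean() / y.var(axis=0).mean()
        assert reduction <= dim / 500 + 0.02

    def test_filter_then_fit_equals_cosine_nuisance(self, run_events):
        # projection equivalence: filtering Y and X equals appending the
        # cosine basis to the design
        rng = np.random.default_rng(1)
        n_scans = 400
        x = rng.normal(size=(n_scans, 3))
        y = x @ np.array([2.0, -1.0, 0.5]) + rng.normal(size=n_scans)
        y = y + 3 * np.cos(2 * np.pi * np.arange(n_scans) / 300)

        basis = np.column_stack([np.ones(n_scans),
                                 dct_highpass_basis(n_scans, 1.0, 128.0)])
        xf, yf = highpass(x), highpass(y)
        beta_filtered, *_ = np.linalg.lstsq(xf, yf, rcond=None)
        full = np.column_stack([x, basis])
        beta_joint, *_ = np.linalg.lstsq(full, y, rcond=None)
        assert np.allclose(beta_filtered, beta_joint[:3], atol=1e-8)


class TestSmooth:
    def test_zero_fwhm_is_identity(self):
        vol = np.random.default_rng(0).normal(size=(8, 8, 8))
        assert np.array_equal(smooth(vol, 0.0), vol)

    def test_delta_recovers_sigma(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        fwhm, voxel = 5.0, 2.0
        out = smooth(vol, fwhm, voxel)
        # fit sigma from second moment along one axis through the peak
        profile = out[:, 10, 10]
        x = np.arange(21)
        sigma_fit = np.sqrt(np.sum(profile * (x - 10) ** 2) / profile.sum())
        assert sigma_fit == pytest.approx(fwhm / 2.3548 / voxel, rel=0.05)

    def test_sum_preserved_inside_mask(self):
        vol = np.zeros((20, 20, 20))
        vol[10, 10, 10] = 1.0
        out = smooth(vol, 4.0, 2.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)


class TestFitGlm:
    def test_noise_free_recovery(self, run_events, layer_rdms, stimuli):
        svs = [trial_surprise(layer_rdms[m], run_events, stimuli, model_id=m)
               for m in ("layer2", "layer8")]
        truth = default_ground_truth(grid=(4, 4, 2), high_slope=1.5,
                                     rng_seed=0)
        bold = synth_bold(run_events, {s.model_id: s for s in svs}, truth,
                          noise_sd=0.0, rng_seed=0)
        design = build_design(run_events, svs, bold.n_scans)
        fit = fit_glm(bold.timeseries(), design)
        col = design.names.index("mod_layer8")
        high = truth.voxels_in("high_scaling")
        assert np.allclose(fit.beta[col, high], 1.5, rtol=1e-6)
        null = truth.voxels_in("null")
        assert np.allclose(fit.beta[col, null], 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, run_events):
        n_scans = int(np.ceil(run_duration(run_events)))
        design = build_design(run_events, [], n_scans, add_derivatives=False)
        rng = np.random.default_rng(2)
        y = rng.normal(size=(n_scans, 5))
        fit = fit_glm(y, design)
        resid = y - design.matrix @ fit.beta
        assert np.allclose(design.matrix.T @ resid, 0.0, atol=1e-8)

    def test_zero_contrast_gives_zero_t(self, run_events):
        n_scans = int(np.ceil(run_duration(run_events)))
        design = build_design(run_events, [], n_scans, add_derivatives=False)
        y = np.random.default_rng(3).normal(size=(n_scans, 4))
        fit = fit_glm(y, design)
        t = fit.contrast_t({"expected": 0.0})
        assert np.allclose(t, 0.0)

    def test_dof_error(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 1.2]})
        frame["c"] = [1.0, 1.0]
        design = DesignMatrix(frame=frame,
                              column_classes={"a": "condition", "b": "condition",
                                              "c": "constant"}, tr=1.0)
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_glm(np.ones((2, 1)), design)


class TestFixedEffects:
    def test_closed_forms(self):
        est, var = fixed_effects([np.array([1.0]), np.array([3.0])],
                                 [np.array([1.0]), np.array([1.0])])
        assert est[0] == pytest.approx(2.0)
        assert var[0] == pytest.approx(0.5)

    def test_identical_runs_scale_variance(self):
        e = np.array([2.0, -1.0])
        v = np.array([0.5, 0.8])
        est, var = fixed_effects([e, e, e], [v, v, v])
        assert np.allclose(est, e)
        assert np.allclose(var, v / 3)

    def test_single_run_identity(self):
        e, v = np.array([1.5]), np.array([0.2])
        est, var = fixed_effects([e], [v])
        assert np.allclose(est, e) and np.allclose(var, v)


class TestVif:
    def _design_from(self, cols: dict) -> DesignMatrix:
        frame = pd.DataFrame(cols)
        classes = {c: "nuisance" for c in frame.columns}
        frame["constant"] = 1.0
        classes["constant"] = "constant"
        return DesignMatrix(frame=frame, column_classes=classes, tr=1.0)

    def test_orthogonal_columns_unit_vif(self):
        n = 200
        t = np.arange(n)
        design = self._design_from({
            "s1": np.sin(2 * np.pi * t / 20), "s2": np.cos(2 * np.pi * t / 20),
        })
        assert np.allclose(vif(design), 1.0, atol=1e-10)

    def test_two_correlated_columns_closed_form(self):
        rng = np.random.default_rng(4)
        n = 100_000                      # large n: sample r ~ population r
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        design = self._design_from({"a": a, "b": b})
        assert vif(design)["a"] == pytest.approx(1 / (1 - 0.64), rel=0.02)

    def test_perfect_collinearity_reported_infinite(self):
        a = np.random.default_rng(5).normal(size=50)
        design = self._design_from({"a": a, "b": 2 * a})
        assert np.isinf(vif(design)).all()


class TestGroupTests:
    def test_antisymmetric_sample(self):
        res = group_test(np.array([-2.0, -1.0, 1.0, 2.0]), test="t")
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_dz_arithmetic(self):
        assert cohens_dz(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0)

    def test_zero_variance_flagged(self):
        res = group_test(np.array([1.0, 1.0, 1.0]), test="t")
        assert "flag" in res

    def test_wilcoxon_effect_size_sign(self):
        res = group_test(np.array([1.0, 2.0, 3.0, -0.5]), test="wilcoxon")
        assert 0 < res["effect_size"] <= 1


class TestClusterInference:
    def test_planted_blob_detected(self):
        rng = np.random.default_rng(6)
        maps = rng.normal(0, 1, size=(12, 10, 10, 6))
        maps[:, 2:6, 2:6, 1:4] += 4.0            # huge planted cluster
        mask = np.ones((10, 10, 6), bool)
        table = cluster_inference(maps, mask, n_permutations=199, rng_seed=0)
        assert len(table) >= 1
        assert table.iloc[0]["p_fwe"] <= 1 / 200 + 1e-12

    def test_empty_when_subthreshold(self):
        rng = np.random.default_rng(7)
        maps = rng.normal(0, 0.01, size=(8, 6, 6, 4))
        table = cluster_inference(maps, np.ones((6, 6, 4), bool),
                                  n_permutations=99, rng_seed=0)
        assert len(table) == 0

    def test_null_false_positive_rate_controlled(self):
        # modest simulation: cluster-level FWE at nominal 0.05 stays near 0.05
        rng = np.random.default_rng(8)
        hits = 0
        n_sims = 60
        for _ in range(n_sims):
            maps = rng.normal(size=(10, 8, 8, 4))
            table = cluster_inference(maps, np.ones((8, 8, 4), bool),
                                      formation_z=2.3,   # liberal: more clusters
                                      n_permutations=99,
                                      rng_seed=int(rng.integers(2 ** 31)))
            if len(table) and (table["p_fwe"] < 0.05).any():
                hits += 1
        assert hits / n_sims <= 0.12        # 0.05 nominal + simulation slack


def test_t_to_z_preserves_tail_probability():
    from scipy import stats
    t = np.array([2.5, -1.0, 0.0])
    z = t_to_z(t, dof=20)
    assert np.allclose(stats.norm.sf(np.abs(z)), stats.t.sf(np.abs(t), 20))
    assert np.sign(z[1]) == -1 and z[2] == 0
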