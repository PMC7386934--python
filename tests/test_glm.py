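"""Prewhitened GLM, contrasts, fixed effects, cluster inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import cordmap.glm as gl
from cordmap.protocol import DesignMatrix


def small_design(t=60, n_cols=4, seed=0):
    rng = np.random.default_rng(seed)
    cols = {f"x{j}": rng.standard_normal(t) for j in range(n_cols)}
    df = pd.DataFrame(cols)
    return DesignMatrix(matrix=df, task_columns=list(df.columns),
                        volume_times=np.arange(t, dtype=float))


class TestFitGLM:
    def test_white_noise_matches_ols(self):
        rng = np.random.default_rng(1)
        t = 1500
        d = small_design(t=t, n_cols=3)
        y = rng.standard_normal((t, 50))
        fit = gl.fit_glm(y, d)
        xc = np.column_stack([d.values, np.ones(t)])
        beta_ols, *_ = np.linalg.lstsq(xc, y, rcond=None)
        # AR coefficients are near zero, so whitening is a near no-op
        np.testing.assert_allclose(fit.betas, beta_ols, atol=2e-2)
        assert np.abs(fit.ar1).mean() < 0.05

    def test_recovers_known_coefficient(self):
        rng = np.random.default_rng(2)
        d = small_design(t=120, n_cols=2)
        x0 = d.matrix["x0"].to_numpy()
        y = (2.0 * x0 + 1e-8 * rng.standard_normal(120))[:, None]
        fit = gl.fit_glm(y, d)
        assert fit.betas[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_gls_oracle_equivalence(self):
        """Brute-force generalized least squares with the AR(1) covariance
        implied by the fitted coefficient reproduces the betas exactly."""
        rng = np.random.default_rng(3)
        t, v = 60, 5
        d = small_design(t=t, n_cols=3, seed=4)
        y = rng.standard_normal((t, v)) + d.values @ np.array([1.0, -2., .5])[:, None]
        fit = gl.fit_glm(y, d, ar_bin_width=0.01)
        xc = np.column_stack([d.values, np.ones(t)])
        for j in range(v):
            rho = fit.bin_index[j] * 0.01
            cov = rho ** np.abs(np.subtract.outer(np.arange(t),
                                                  np.arange(t)))
            cov /= (1 - rho**2) if abs(rho) < 1 else 1.0
            ci = np.linalg.inv(cov)
            beta_gls = np.linalg.solve(xc.T @ ci @ xc, xc.T @ ci @ y[:, j])
            np.testing.assert_allclose(fit.betas[:, j], beta_gls, atol=1e-8)

    def test_rank_deficient_design_names_columns(self):
        d = small_design(t=50, n_cols=3)
        d.matrix["x2"] = d.matrix["x0"]
        with pytest.raises(ValueError, match="x2"):
            gl.fit_glm(np.random.default_rng(0).standard_normal((50, 3)), d)

    def test_dof_accounting(self):
        d = small_design(t=100, n_cols=2)
        y = np.random.default_rng(0).standard_normal((100, 4))
        fit = gl.fit_glm(y, d, dof_loss=10)
        assert fit.dof == 100 - 3 - 10


class TestContrasts:
    def test_zero_contrast_gives_zero_cope(self):
        d = small_design(t=80, n_cols=2)
        y = np.random.default_rng(0).standard_normal((80, 10))
        fit = gl.fit_glm(y, d)
        m = gl.contrast_z(fit, gl.ContrastSpec("null", {"x0": 0.0}))
        np.testing.assert_array_equal(m.cope, 0.0)

    def test_difference_antisymmetry(self):
        d = small_design(t=80, n_cols=2)
        y = np.random.default_rng(1).standard_normal((80, 10))
        fit = gl.fit_glm(y, d)
        ab = gl.contrast_z(fit, gl.ContrastSpec("a-b", {"x0": 1, "x1": -1}))
        ba = gl.contrast_z(fit, gl.ContrastSpec("b-a", {"x0": -1, "x1": 1}))
        np.testing.assert_allclose(ab.cope, -ba.cope, atol=1e-12)
        np.testing.assert_allclose(ab.z, -ba.z, atol=1e-12)

    def test_unknown_column_rejected(self):
        d = small_design()
        fit = gl.fit_glm(np.random.default_rng(0).standard_normal((60, 2)), d)
        with pytest.raises(ValueError, match="unknown column"):
            gl.contrast_z(fit, gl.ContrastSpec("bad", {"nope": 1.0}))

    def test_max_z_inside_true_region(self, analyzed, truth, atlas):
        zvol = analyzed.maps["L"].volume("z")
        peak = np.unravel_index(np.argmax(zvol), zvol.shape)
        # peak may sit on the smoothed halo edge; require truth or neighbor
        dil = ndimage.binary_dilation(truth.mask, iterations=2)
        assert dil[peak]

    def test_trialwise_mean_equals_blockwise_beta_noise_free(self, protocol):
        """Linearity: the average of the 20 trial betas equals the beta of
        the single union regressor when the data are an exact multiple of
        the union response."""
        from cordmap.protocol import build_design, task_regressor

        left = task_regressor(protocol, sides=("left",))
        right = task_regressor(protocol, sides=("right",))
        y = np.column_stack([0.7 * left + 0.7 * right,
                             1.3 * left + 0.2 * right])
        d = build_design(protocol)
        fit = gl.fit_glm(y, d)
        trial_mean_left = np.mean([fit.betas[i] for i in range(20)], axis=0)

        dfu = pd.DataFrame({"union_l": left, "union_r": right})
        du = DesignMatrix(matrix=dfu, task_columns=["union_l", "union_r"],
                          volume_times=d.volume_times)
        fit_u = gl.fit_glm(y, du)
        np.testing.assert_allclose(trial_mean_left, fit_u.betas[0],
                                   atol=1e-6)
        np.testing.assert_allclose(fit_u.betas[0], [0.7, 1.3], atol=1e-6)


class TestFixedEffects:
    def test_two_identical_inputs(self):
        c = np.array([1.0, 2.0]); v = np.array([0.5, 0.5])
        out = gl.fixed_effects([c, c], [v, v])
        np.testing.assert_allclose(out.cope, c)
        np.testing.assert_allclose(out.varcope, v / 2)

    def test_single_input_identity(self):
        c = np.array([1.0, -1.0]); v = np.array([2.0, 3.0])
        out = gl.fixed_effects([c], [v])
        np.testing.assert_allclose(out.cope, c)
        np.testing.assert_allclose(out.varcope, v)

    def test_equal_variances_give_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        copes = [rng.standard_normal(6) for _ in range(4)]
        v = np.ones(6)
        out = gl.fixed_effects(copes, [v] * 4)
        np.testing.assert_allclose(out.cope, np.mean(copes, axis=0))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        copes = [rng.standard_normal(5) for _ in range(5)]
        varcs = [rng.uniform(0.5, 2.0, 5) for _ in range(5)]
        a = gl.fixed_effects(copes, varcs)
        order = [3, 1, 4, 0, 2]
        b = gl.fixed_effects([copes[i] for i in order],
                             [varcs[i] for i in order])
        np.testing.assert_allclose(a.cope, b.cope)
        np.testing.assert_allclose(a.z, b.z)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="varcope"):
            gl.fixed_effects([np.ones(3)], [np.zeros(3)])


class TestClusterThreshold:
    def _map(self, z_vol, mask):
        flat = z_vol[mask]
        return gl.StatMap(z=flat, cope=flat, varcope=np.ones_like(flat),
                          mask=mask, name="t")

    def test_zero_map_empty_active(self):
        mask = np.ones((10, 10, 6), dtype=bool)
        out = gl.cluster_threshold(self._map(np.zeros(mask.shape), mask),
                                   n_null=100, seed=0)
        assert out.active.sum() == 0

    def test_huge_blob_fully_retained(self):
        mask = np.ones((12, 12, 8), dtype=bool)
        z = np.zeros(mask.shape)
        z[2:10, 2:10, 2:6] = 5.0
        out = gl.cluster_threshold(self._map(z, mask), n_null=100, seed=0)
        assert out.active.sum() == 8 * 8 * 4

    def test_small_null_rejected(self):
        mask = np.ones((4, 4, 2), dtype=bool)
        with pytest.raises(ValueError, match="n_null"):
            gl.cluster_threshold(self._map(np.zeros(mask.shape), mask),
                                 n_null=50)

    def test_mass_statistic_supported(self):
        mask = np.ones((10, 10, 4), dtype=bool)
        z = np.zeros(mask.shape)
        z[3:7, 3:7, 1:3] = 6.0
        out = gl.cluster_threshold(self._map(z, mask), n_null=100, seed=1,
                                   statistic="mass")
        assert out.active.sum() == 4 * 4 * 2


class TestSmoothnessEstimate:
    def test_smoothed_field_has_larger_fwhm(self):
        rng = np.random.default_rng(0)
        mask = np.ones((20, 20, 12), dtype=bool)
        raw = rng.standard_normal((20, 20, 12, 4))
        sm = ndimage.gaussian_filter(raw, (1.5, 1.5, 1.5, 0))
        assert gl.estimate_smoothness(sm, mask) > \
            gl.estimate_smoothness(raw, mask) + 1.0


class TestPercentSignalChange:
    def test_zero_cope_zero_psc(self):
        psc, n = gl.percent_signal_change(np.zeros(5), 1.0, np.full(5, 100.0))
        np.testing.assert_array_equal(psc, 0.0)
        assert n == 0

    def test_linearity(self):
        cope = np.array([1.0, 2.0])
        p1, _ = gl.percent_signal_change(cope, 0.5, np.full(2, 100.0))
        p2, _ = gl.percent_signal_change(2 * cope, 0.5, np.full(2, 100.0))
        np.testing.assert_allclose(p2, 2 * p1)

    def test_nonpositive_baseline_excluded(self):
        psc, n = gl.percent_signal_change(np.ones(3), 1.0,
                                          np.array([100.0, 0.0, -5.0]))
        assert n == 2
        assert np.isnan(psc[1]) and np.isnan(psc[2])


class TestSignFlip:
    def test_strong_effect_small_p(self):
        rng = np.random.default_rng(0)
        copes = 1.0 + 0.1 * rng.standard_normal((12, 30))
        t, p = gl.sign_flip_group_test(copes, n_perm=500, seed=1)
        assert np.all(p < 0.01)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(1)
        copes = rng.standard_normal((12, 200))
        _, p = gl.sign_flip_group_test(copes, n_perm=300, seed=2)
        assert p.mean() == pytest.approx(0.5, abs=0.06)
        assert (p < 0.05).mean() < 0.12
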