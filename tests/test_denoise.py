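"""Phase assignment, RETROICOR basis, CSF PCA, DVARS, filtering, smoothing."""

import numpy as np
import pytest

import cordmap.denoise as dn
from cordmap.cordsim import PhysioTrace


def constant_cardiac(duration=100.0, period=1.0):
    peaks = np.arange(0.0, duration + 2 * period, period)
    return PhysioTrace(samples=np.cos(2 * np.pi * np.arange(0, duration, .05)),
                       sampling_rate=20.0, kind="cardiac", peak_times=peaks)


class TestPhases:
    def test_phase_zero_at_peak(self):
        card = constant_cardiac()
        assert dn.cardiac_phase_at(np.array([5.0]), card.peak_times)[0] == 0.0

    def test_phase_pi_midway(self):
        card = constant_cardiac()
        p = dn.cardiac_phase_at(np.array([5.5]), card.peak_times)[0]
        assert p == pytest.approx(np.pi)

    def test_quarter_period_gives_half_pi(self):
        card = constant_cardiac(period=1.0)
        p = dn.cardiac_phase_at(np.array([3.25]), card.peak_times)[0]
        assert p == pytest.approx(np.pi / 2)

    def test_out_of_coverage_rejected(self):
        card = constant_cardiac(duration=10.0)
        with pytest.raises(ValueError, match="coverage"):
            dn.cardiac_phase_at(np.array([500.0]), card.peak_times)

    def test_respiratory_phase_spans_cycle(self):
        t = np.arange(0, 100, 0.05)
        resp = 0.5 * (1 - np.cos(2 * np.pi * 0.25 * t))
        times = np.arange(1, 99, 0.33)
        ph = dn.respiratory_phase_at(times, resp, 20.0)
        assert np.all((ph >= 0) & (ph < 2 * np.pi))
        # inspiration (rising amplitude) maps below pi, expiration above
        assert ph.std() > 1.0

    def test_assign_phases_shapes(self):
        card = constant_cardiac(duration=120.0)
        t = np.arange(0, 120, 0.05)
        resp = PhysioTrace(0.5 * (1 - np.cos(2 * np.pi * 0.25 * t)), 20.0,
                           "respiratory")
        pa = dn.assign_phases(card, resp, np.array([0.0, 0.5, 1.0]),
                              tr=2.0, n_volumes=50)
        assert pa.cardiac_phase.shape == (3, 50)
        assert pa.resp_phase.shape == (3, 50)


class TestPhysioBasis:
    def test_block_structure_16_plus_16(self):
        rng = np.random.default_rng(0)
        pa = dn.PhaseAssignment(rng.uniform(0, 2 * np.pi, (3, 40)),
                                rng.uniform(0, 2 * np.pi, (3, 40)))
        block, labels = dn.physio_basis(pa)
        assert block.shape == (3, 40, 32)
        assert sum(1 for l in labels if not l.startswith("inter")) == 16
        assert sum(1 for l in labels if l.startswith("inter")) == 16

    def test_zero_phases_give_trivial_columns(self):
        pa = dn.PhaseAssignment(np.zeros((1, 10)), np.zeros((1, 10)))
        block, labels = dn.physio_basis(pa)
        for j, lab in enumerate(labels):
            col = block[0, :, j]
            if "sin" in lab:
                np.testing.assert_allclose(col, 0.0, atol=1e-12)
            else:
                np.testing.assert_allclose(col, 1.0, atol=1e-12)


class TestCsfPca:
    def test_recovers_common_time_course(self):
        rng = np.random.default_rng(1)
        common = np.sin(np.arange(80) / 3.0)
        vol = np.zeros((4, 4, 2, 80))
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[:2, :2, :] = True
        vol[mask] = common[None, :] + 0.05 * rng.standard_normal((8, 80))
        block, labels = dn.csf_pca(vol, mask)
        r = np.corrcoef(block[0, :, 0], common)[0, 1]
        assert abs(r) > 0.99
        assert block.shape[-1] == 5

    def test_components_orthogonal(self):
        rng = np.random.default_rng(2)
        vol = rng.standard_normal((3, 3, 1, 60))
        mask = np.ones((3, 3, 1), dtype=bool)
        block, _ = dn.csf_pca(vol, mask)
        g = block[0].T @ block[0]
        np.testing.assert_allclose(g - np.diag(np.diag(g)), 0.0, atol=1e-8)

    def test_few_voxels_warns_and_truncates(self):
        rng = np.random.default_rng(3)
        vol = rng.standard_normal((2, 1, 1, 50))
        mask = np.ones((2, 1, 1), dtype=bool)
        with pytest.warns(UserWarning, match="components"):
            block, labels = dn.csf_pca(vol, mask)
        assert len(labels[0]) == 2

    def test_empty_slice_rejected(self):
        vol = np.zeros((2, 2, 2, 20))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[:, :, 0] = True
        with pytest.raises(ValueError, match="empty"):
            dn.csf_pca(vol, mask)


class TestDvars:
    def test_constant_series_no_outliers(self):
        vol = np.ones((3, 3, 2, 20))
        flags, onehot, dvars = dn.dvars_outliers(vol, np.ones((3, 3, 2),
                                                             dtype=bool))
        assert len(flags) == 0
        np.testing.assert_array_equal(dvars, 0.0)

    def test_spike_flags_two_adjacent_volumes(self):
        # a step at volume 100 perturbs the differences at 100 and 101;
        # the box-plot cutoff may flag a few more tail volumes of the
        # white-noise DVARS distribution, but both spike-adjacent volumes
        # must be among them
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((12, 12, 8, 200))
        vol[..., 100] += 10.0
        flags, onehot, dvars = dn.dvars_outliers(
            vol, np.ones((12, 12, 8), dtype=bool))
        assert {100, 101}.issubset(set(flags))
        assert len(flags) <= 6
        assert onehot.shape == (200, len(flags))
        assert dvars[100] > dvars[50]

    def test_scale_and_offset_invariance(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((4, 4, 2, 100))
        vol[..., 40] += 8.0
        mask = np.ones((4, 4, 2), dtype=bool)
        f0, _, d0 = dn.dvars_outliers(vol, mask)
        f1, _, d1 = dn.dvars_outliers(3.0 * vol + 7.0, mask)
        np.testing.assert_array_equal(f0, f1)
        np.testing.assert_allclose(d1, 3.0 * d0, rtol=1e-9)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            dn.dvars_outliers(np.ones((2, 2, 1, 2)), np.ones((2, 2, 1),
                                                             dtype=bool))


class TestHighpass:
    def test_constant_preserved(self):
        x = np.full(450, 7.0)
        np.testing.assert_allclose(dn.highpass(x, 100.0, 2.0), 7.0)

    def test_fast_oscillation_retained(self):
        t = np.arange(450) * 2.0
        x = np.sin(2 * np.pi * t / 50.0)
        y = dn.highpass(x, 100.0, 2.0)
        assert np.linalg.norm(y - y.mean()) >= 0.9 * np.linalg.norm(x)

    def test_slow_oscillation_removed(self):
        t = np.arange(450) * 2.0
        x = np.sin(2 * np.pi * t / 400.0)
        y = dn.highpass(x, 100.0, 2.0)
        assert np.linalg.norm(y - y.mean()) <= 0.1 * np.linalg.norm(x)

    def test_cutoff_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            dn.highpass(np.zeros(100), 3.0, 2.0)


class TestRegressNuisance:
    def _set(self, t, cols):
        return dn.NuisanceSet(physio_block=cols[None, :, :],
                              csf_block=np.zeros((1, t, 0)))

    def test_pure_nuisance_reduced_to_mean(self):
        t = 100
        col = np.sin(np.arange(t) / 5.0)
        vol = np.tile(col, (2, 2, 1, 1)) + 3.0
        out = dn.regress_nuisance(vol, self._set(t, col[:, None]))
        np.testing.assert_allclose(out, 3.0, atol=1e-5)

    def test_orthogonal_nuisance_leaves_data(self):
        t = 200
        data_sig = np.cos(2 * np.pi * np.arange(t) / 10.0)
        nui = np.sin(2 * np.pi * np.arange(t) / 10.0)   # orthogonal
        vol = np.tile(data_sig, (2, 2, 1, 1))
        out = dn.regress_nuisance(vol, self._set(t, nui[:, None]))
        np.testing.assert_allclose(out, vol, atol=1e-6)

    def test_protected_subspace_not_drained(self):
        rng = np.random.default_rng(0)
        t = 120
        task = np.sin(2 * np.pi * np.arange(t) / 30.0)
        nui = task * 0.5 + 0.1 * rng.standard_normal(t)  # task-correlated
        vol = np.tile(task, (2, 2, 1, 1))
        out = dn.regress_nuisance(vol, self._set(t, nui[:, None]),
                                  protect=task[:, None])
        np.testing.assert_allclose(out, vol, atol=1e-8)

    def test_phase_locked_cardiac_power_removed(self, atlas, protocol,
                                                physio, noisy_run):
        """Round trip with the simulator: injected cardiac contamination is
        almost entirely captured by the RETROICOR basis."""
        card = physio[0]
        nz = atlas.grid_shape[2]
        t = protocol.n_volumes
        pa = dn.assign_phases(card, physio[1], noisy_run.slice_times,
                              protocol.tr, t)
        block, _ = dn.physio_basis(pa)
        nuis = dn.NuisanceSet(physio_block=block,
                              csf_block=np.zeros((nz, t, 0)))
        canal = atlas["canal_csf"].astype(bool)
        out = dn.regress_nuisance(noisy_run.data, nuis, mask=canal)

        # phase-locked cardiac power: squared projection of each canal
        # voxel's series onto the first cardiac harmonic at its own slice
        def locked_power(vol):
            total = 0.0
            for z in range(nz):
                m = canal[:, :, z]
                basis = np.column_stack([np.cos(pa.cardiac_phase[z]),
                                         np.sin(pa.cardiac_phase[z])])
                q, _ = np.linalg.qr(basis - basis.mean(axis=0))
                ts = vol[:, :, z, :][m].T
                ts = ts - ts.mean(axis=0)
                total += float(np.sum((q.T @ ts) ** 2))
            return total

        before = locked_power(noisy_run.data.astype(float))
        after = locked_power(out.astype(float))
        assert after < 0.05 * before


class TestSmoothing:
    def test_uniform_field_unchanged_in_mask(self, atlas):
        vol = np.where(atlas["cord"], 5.0, 0.0)
        out = dn.smooth(vol, atlas["cord"], 2.0, atlas.voxel_size)
        np.testing.assert_allclose(out[atlas["cord"]], 5.0, atol=1e-6)

    def test_impulse_halfwidth_matches_fwhm(self):
        mask = np.ones((41, 41, 1), dtype=bool)
        vol = np.zeros((41, 41, 1))
        vol[20, 20, 0] = 1.0
        out = dn.smooth(vol, mask, fwhm_mm=4.0, voxel_size_mm=(1, 1, 1))
        profile = out[:, 20, 0]
        half = profile.max() / 2
        width = (profile >= half).sum()
        assert width == pytest.approx(4.0, abs=1.0)

    def test_smoothing_raises_tsnr(self, noisy_run, atlas):
        cord = atlas["cord"].astype(bool)
        _, raw, _ = dn.tsnr_map(noisy_run.data, cord)
        sm = dn.smooth(noisy_run.data, cord, 2.0, atlas.voxel_size)
        _, smoothed, _ = dn.tsnr_map(sm, cord)
        assert smoothed > raw

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dn.smooth(np.zeros((4, 4, 2, 5)), np.zeros((4, 4, 2), dtype=bool))


class TestSliceTiming:
    @pytest.mark.parametrize("method", ["sinc", "linear"])
    def test_slice_at_volume_midpoint_unchanged(self, method):
        # a slice acquired exactly at TR/2 needs no shift
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((2, 2, 2, 60)).astype(np.float32)
        out = dn.slice_timing_correct(vol, np.array([1.0, 0.0]), 2.0,
                                      method=method)
        np.testing.assert_allclose(out[:, :, 0, :], vol[:, :, 0, :],
                                   atol=1e-4)

    def test_sinc_preserves_sinusoid_amplitude(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * t / 45.0)
        vol = np.tile(sig, (1, 1, 2, 1)).astype(np.float32)
        out = dn.slice_timing_correct(vol, np.array([0.0, 1.5]), 2.0)
        mid = slice(20, 180)
        amp = out[0, 0, 1, mid].max()
        assert amp == pytest.approx(1.0, abs=0.01)


class TestTsnr:
    def test_known_ratio(self):
        rng = np.random.default_rng(0)
        vol = 100.0 + 4.0 * rng.standard_normal((6, 6, 3, 400))
        mask = np.ones((6, 6, 3), dtype=bool)
        _, mean_tsnr, n_excl = dn.tsnr_map(vol, mask)
        assert mean_tsnr == pytest.approx(25.0, rel=0.05)
        assert n_excl == 0

    def test_noiseless_voxels_excluded(self):
        vol = np.ones((2, 2, 1, 20))
        _, mean_tsnr, n_excl = dn.tsnr_map(vol, np.ones((2, 2, 1),
                                                        dtype=bool))
        assert n_excl == 4
        assert np.isnan(mean_tsnr)

    def test_doubling_noise_halves_tsnr(self):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((5, 5, 2, 300))
        mask = np.ones((5, 5, 2), dtype=bool)
        _, t1, _ = dn.tsnr_map(100 + 2 * noise, mask)
        _, t2, _ = dn.tsnr_map(100 + 4 * noise, mask)
        # temporal means differ slightly between the two series, so the
        # ratio is 2 only up to that second-order term
        assert t1 / t2 == pytest.approx(2.0, rel=1e-2)
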