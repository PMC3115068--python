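import numpy as np
import pytest

from pmdti.correction import (average_repeats, correct_series,
                              mutual_information, register_drift,
                              register_eddy)
from pmdti.distortion import AffineMap, DistortionModel, apply_affine, \
    distort_series
from pmdti.dwi_io import DWISeries, GradientTable, VolumeGeometry
from pmdti.phantom import simulate_dwi


class TestMutualInformation:
    def test_self_information_equals_entropy(self, phantom32):
        a = phantom32.s0
        mi = mutual_information(a, a)
        # MI(A, A) = H(A): recompute the marginal entropy independently
        counts, _ = np.histogram(a[a != 0], bins=64)
        p = counts / counts.sum()
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(h, rel=1e-6)

    def test_invariant_to_monotone_rescaling(self, phantom32):
        # strictly positive image so the nonzero-support mask is unchanged
        # by the affine intensity map
        a = phantom32.s0 + 10.0
        assert mutual_information(a, 2 * a + 5) == pytest.approx(
            mutual_information(a, a), rel=0.02)

    def test_independent_noise_has_near_zero_mi(self):
        rng = np.random.default_rng(0)
        a = rng.random((100, 100, 100))
        b = rng.random((100, 100, 100))
        assert mutual_information(a, b) < 0.01

    def test_constant_image_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones((8, 8, 8)),
                                      np.ones((8, 8, 8))) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones((4, 4, 4)), np.ones((5, 5, 5)))


class TestDriftRegistration:
    def test_zero_shift_on_identical_volumes(self, phantom32):
        r = register_drift(phantom32.s0, phantom32.s0, 2)
        assert abs(r.map.translation[2]) < 0.05

    def test_recovers_subvoxel_shift(self, phantom32):
        moving = apply_affine(phantom32.s0, AffineMap(translation=(0, 0, 2.3)))
        r = register_drift(moving, phantom32.s0, 2)
        assert r.map.translation[2] == pytest.approx(2.3, abs=0.1)

    def test_invariant_to_intensity_scaling(self, phantom32):
        moving = apply_affine(phantom32.s0, AffineMap(translation=(0, 0, 1.7)))
        r1 = register_drift(moving, phantom32.s0, 2)
        r2 = register_drift(2.0 * moving, phantom32.s0, 2)
        assert r1.map.translation[2] == pytest.approx(r2.map.translation[2],
                                                      abs=0.05)


class TestAverageRepeats:
    def _series(self, data, bvals, bvecs):
        return DWISeries(data, GradientTable(bvals=bvals, bvecs=bvecs),
                         VolumeGeometry((1, 1, 1), data.shape[2:]))

    def test_identical_repeats_average_to_input(self, series32):
        out = average_repeats(series32)
        # mean b0 first, then the six directions
        assert out.data.shape[1] == 7
        assert np.allclose(out.data[0, 0], series32.data[0, 0])
        assert np.allclose(out.data[0, 1:], series32.data[0, 1:])

    def test_mean_of_signal_and_zero(self):
        data = np.stack([np.full((1, 4, 4, 4), 8.0),
                         np.zeros((1, 4, 4, 4))])
        s = self._series(data, [1000.0], [[1.0, 0, 0]])
        assert np.allclose(average_repeats(s).data, 4.0)

    def test_noise_shrinks_as_sqrt_repeats(self):
        rng = np.random.default_rng(0)
        data = 100.0 + rng.normal(0, 5.0, (3, 1, 40, 40, 40))
        s = self._series(data, [1000.0], [[1.0, 0, 0]])
        out = average_repeats(s)
        assert out.data.std() == pytest.approx(5.0 / np.sqrt(3), rel=0.05)


class TestEddyRegistration:
    def test_null_registration_near_identity(self, phantom32):
        r = register_eddy(phantom32.s0, phantom32.s0)
        p = r.map.params()
        assert np.all(np.abs(p[0:3]) < 0.05)       # voxels
        assert np.all(np.abs(p[3:6]) < 0.2)        # degrees
        assert np.all(np.abs(p[6:9] - 1) < 0.002)  # scale
        assert np.all(np.abs(p[9:12]) < 0.002)     # shear

    def test_recovers_known_scale_and_shear(self, phantom32):
        truth = AffineMap(scale=(1.02, 1.02, 1.02), shear=(0.01, 0.0, 0.0))
        moving = apply_affine(phantom32.s0, truth)
        r = register_eddy(moving, phantom32.s0)
        p = r.map.params()
        assert np.all(np.abs(p[6:9] - 1.02) < 0.005)
        assert np.all(np.abs(p[9:12] - [0.01, 0, 0]) < 0.005)

    def test_mi_beats_least_squares_across_contrast(self, gtab6):
        """DW-to-b0 registration needs MI; an SSD cost misses the optimum
        because the diffusion attenuation violates its intensity-match
        assumption."""
        from pmdti.phantom import build_specimen_phantom

        ph = build_specimen_phantom((48, 48, 48), seed=1)
        series = simulate_dwi(ph, gtab6, repeats=1)
        truth = AffineMap(scale=(1.02, 1.02, 1.02))
        moving = apply_affine(series.data[0, 1], truth)
        fixed = series.data[0, 0]
        err = {}
        for cost in ("mi", "ssd"):
            r = register_eddy(moving, fixed, cost=cost)
            err[cost] = np.abs(r.map.params()[6:9] - 1.02).max()
        assert err["mi"] < 0.5 * err["ssd"]
        assert err["mi"] < 0.02


class TestCorrectSeries:
    def test_distortion_free_input_preserved(self, phantom32, gtab6):
        series = simulate_dwi(phantom32, gtab6, repeats=2)
        out, log = correct_series(series)
        # residual transforms are near identity and the data is preserved
        # to within one resampling of a near-identity map
        ref = average_repeats(series)
        scale = series.data.max()
        assert np.median(np.abs(out.data - ref.data)) < 0.01 * scale

    def test_transform_log_covers_all_stages(self, phantom32, gtab6):
        series = simulate_dwi(phantom32, gtab6, repeats=2)
        model = DistortionModel(drift_rate=0.5, eddy_alpha=0.02,
                                eddy_beta=0.01)
        dis, truth = distort_series(series, model)
        out, log = correct_series(dis)
        assert (log.stage == "drift").sum() == series.gtab.n  # repeat 1 only
        assert (log.stage == "eddy").sum() == 6
        drift_est = log[(log.stage == "drift")]["tz"].to_numpy()
        assert np.allclose(drift_est, 0.5, atol=0.15)

    def test_mean_b0_alignment_residual(self, phantom32, gtab6):
        series = simulate_dwi(phantom32, gtab6, repeats=2)
        model = DistortionModel(drift_rate=0.5, eddy_alpha=0.0, eddy_beta=0.0)
        dis, _ = distort_series(series, model)
        out, _ = correct_series(dis)

        def com(v, axis):
            idx = np.indices(v.shape)[axis]
            return (idx * v).sum() / v.sum()

        axis = series.geom.slow_pe_axis
        resid = com(out.data[0, 0], axis) - com(series.data[0, 0], axis)
        assert abs(resid) < 0.1
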