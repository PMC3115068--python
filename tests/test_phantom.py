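import numpy as np
import pandas as pd
import pytest

from pmdti.phantom import (BACKGROUND, CORTEX, DARK_BAND, WM_SLAB1, WM_SLAB2,
                           CohortConfig, axial_radial_from_md_fa, build_cohort,
                           build_specimen_phantom, cohort_roi_table, fa_axial,
                           md_axial, simulate_dwi, add_rician_noise,
                           tensor_from_axial)
from pmdti.tensor import TensorField, scalar_maps


class TestAxialTensor:
    def test_cc_mean_diffusivity(self):
        # fixed-tissue corpus-callosum parameterization
        D = tensor_from_axial(0.098, 0.062, (1.0, 0.0, 0.0))
        assert np.isclose(np.trace(D) / 3.0, 0.074)

    def test_isotropic_has_zero_fa(self):
        D = tensor_from_axial(0.08, 0.08, (0.0, 1.0, 0.0))
        assert np.isclose(scalar_maps(TensorField.from_matrices(D[None])).fa[0], 0.0)

    def test_cc_tensor_fa_closed_form(self):
        # FA of the mean tensor, not the (larger) mean of per-specimen FAs
        assert np.isclose(fa_axial(0.098, 0.062), 0.2738, atol=5e-4)

    def test_eigen_structure(self):
        v = np.array([1.0, 2.0, -1.0])
        v /= np.linalg.norm(v)
        D = tensor_from_axial(0.1, 0.05, v)
        vals, vecs = np.linalg.eigh(D)
        assert np.allclose(sorted(vals), [0.05, 0.05, 0.1])
        assert np.isclose(abs(vecs[:, -1] @ v), 1.0)

    def test_rejects_inverted_diffusivities(self):
        with pytest.raises(ValueError):
            tensor_from_axial(0.05, 0.1, (1, 0, 0))

    def test_md_fa_inversion_round_trip(self):
        ax, rad = axial_radial_from_md_fa(0.094, 0.25)
        assert np.isclose(md_axial(ax, rad), 0.094)
        assert np.isclose(fa_axial(ax, rad), 0.25)


class TestSpecimenPhantom:
    def test_background_signal_exactly_zero(self, phantom32):
        assert np.all(phantom32.s0[phantom32.labels == BACKGROUND] == 0.0)

    def test_dark_band_at_most_two_voxels_thick(self, phantom32):
        band = phantom32.labels == DARK_BAND
        assert band.any()
        assert band.sum(axis=2).max() <= 2

    def test_cortex_pdd_radial(self, phantom32):
        maps = scalar_maps(TensorField.from_matrices(phantom32.tensors))
        ctx = phantom32.labels == CORTEX
        normals = phantom32.meta["cortex_normals"][ctx]
        dots = np.abs(np.sum(maps.pdd[ctx] * normals, axis=1))
        assert (dots > np.cos(np.deg2rad(20))).mean() >= 0.9

    def test_fa_and_md_tissue_ordering(self, phantom32):
        maps = scalar_maps(TensorField.from_matrices(phantom32.tensors))
        lab = phantom32.labels
        fa_wm = maps.fa[np.isin(lab, [WM_SLAB1, WM_SLAB2])].mean()
        fa_ctx = maps.fa[lab == CORTEX].mean()
        fa_band = maps.fa[lab == DARK_BAND].mean()
        assert fa_wm > fa_ctx > fa_band
        assert maps.md[lab == CORTEX].mean() > maps.md[lab == WM_SLAB1].mean()

    def test_deterministic_given_seed(self):
        a = build_specimen_phantom((32, 32, 32), seed=7)
        b = build_specimen_phantom((32, 32, 32), seed=7)
        assert np.array_equal(a.s0, b.s0)
        assert np.array_equal(a.labels, b.labels)

    def test_rejects_small_shape(self):
        with pytest.raises(ValueError):
            build_specimen_phantom((16, 16, 16))


class TestForwardModel:
    def test_b0_returns_s0(self, phantom32, gtab6):
        series = simulate_dwi(phantom32, gtab6, repeats=1)
        assert np.allclose(series.data[0, 0], phantom32.s0)

    def test_isotropic_attenuation_closed_form(self):
        # b = 4500, D = 0.074e-3 -> S/S0 = exp(-0.333) = 0.7165
        from pmdti.dwi_io import GradientTable, VolumeGeometry
        from pmdti.phantom import Phantom

        D = np.broadcast_to(0.074 * np.eye(3), (1, 1, 1, 3, 3)).copy()
        ph = Phantom(labels=np.ones((1, 1, 1), dtype=int), tensors=D,
                     s0=np.ones((1, 1, 1)),
                     geom=VolumeGeometry(voxel_size=(1, 1, 1), shape=(1, 1, 1)))
        gt = GradientTable(bvals=[4500.0], bvecs=[[1.0, 0.0, 0.0]])
        s = simulate_dwi(ph, gt, repeats=1)
        assert np.isclose(s.data[0, 0, 0, 0, 0], np.exp(-4500 * 0.074e-3),
                          atol=1e-6)

    def test_radial_direction_attenuation(self):
        from pmdti.dwi_io import GradientTable, VolumeGeometry
        from pmdti.phantom import Phantom

        D = tensor_from_axial(0.098, 0.062, (1.0, 0.0, 0.0))[None, None, None]
        ph = Phantom(labels=np.ones((1, 1, 1), dtype=int), tensors=D.copy(),
                     s0=np.full((1, 1, 1), 500.0),
                     geom=VolumeGeometry(voxel_size=(1, 1, 1), shape=(1, 1, 1)))
        gt = GradientTable(bvals=[4500.0], bvecs=[[0.0, 1.0, 0.0]])
        s = simulate_dwi(ph, gt, repeats=1)
        assert np.isclose(s.data[0, 0, 0, 0, 0] / 500.0,
                          np.exp(-4500 * 0.062e-3))

    def test_repeats_identical_noiseless(self, phantom32, gtab6):
        series = simulate_dwi(phantom32, gtab6, repeats=3)
        assert np.array_equal(series.data[0], series.data[2])


class TestRicianNoise:
    def test_zero_sigma_identity(self, series32):
        out = add_rician_noise(series32, 0.0, seed=1)
        assert np.array_equal(out.data, series32.data)

    def test_negative_sigma_rejected(self, series32):
        with pytest.raises(ValueError):
            add_rician_noise(series32, -1.0)

    def test_rayleigh_mean_at_zero_signal(self):
        """|0 + noise| follows a Rayleigh law with mean sigma*sqrt(pi/2)."""
        from pmdti.dwi_io import DWISeries, GradientTable, VolumeGeometry

        data = np.zeros((1, 1, 100, 100, 100))
        series = DWISeries(data, GradientTable(bvals=[0.0], bvecs=[[0, 0, 0]]),
                           VolumeGeometry((1, 1, 1), (100, 100, 100)))
        out = add_rician_noise(series, 1.0, seed=3)
        assert abs(out.data.mean() - np.sqrt(np.pi / 2)) < 0.01

    def test_high_snr_mean(self):
        from pmdti.dwi_io import DWISeries, GradientTable, VolumeGeometry

        data = np.full((1, 1, 100, 100, 100), 100.0)
        series = DWISeries(data, GradientTable(bvals=[0.0], bvecs=[[0, 0, 0]]),
                           VolumeGeometry((1, 1, 1), (100, 100, 100)))
        out = add_rician_noise(series, 1.0, seed=4)
        assert abs(out.data.mean() - np.sqrt(100.0**2 + 1.0)) < 0.02

    def test_deterministic(self, series32):
        a = add_rician_noise(series32, 10.0, seed=5)
        b = add_rician_noise(series32, 10.0, seed=5)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_truncation_bounds_respected(self):
        for seed in range(20):
            cohort = build_cohort(CohortConfig(seed=seed))
            for sp in cohort:
                assert 21 <= sp.pmi_hours <= 69
                assert 2 <= sp.si_months <= 40

    def test_zero_slope_gives_identical_specimens(self):
        cfg = CohortConfig(slope_md=0.0, slope_dax=0.0, seed=0)
        cohort = build_cohort(cfg)
        ref = cohort[0].roi_params
        for sp in cohort[1:]:
            for roi in ref:
                assert sp.roi_params[roi] == ref[roi]

    def test_noiseless_md_slope_recovery(self):
        import statsmodels.api as sm

        cohort = build_cohort(CohortConfig(seed=11))
        table = cohort_roi_table(cohort)
        wide = table[table.roi.isin(["CC", "SLF", "Opt", "Cing", "PLIC"])]
        avg = wide.groupby("specimen").agg({"MD": "mean", "pmi_hours": "first"})
        fit = sm.OLS(avg.MD, sm.add_constant(avg.pmi_hours)).fit()
        assert abs(fit.params["pmi_hours"] - (-0.0122)) < 1e-6

    def test_pmi_mean_matches_truncated_normal(self):
        means = [np.mean([sp.pmi_hours for sp in
                          build_cohort(CohortConfig(seed=s))])
                 for s in range(200)]
        assert abs(np.mean(means) - 46.2) < 2 * 19.9 / np.sqrt(11)

    def test_unattainable_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(r_target=0.95)

    def test_excessive_slope_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(slope_md=-0.2)

    def test_roi_table_noise_reproducible(self):
        cohort = build_cohort(CohortConfig(seed=2))
        a = cohort_roi_table(cohort, noise_sd={"MD": 0.01}, seed=9)
        b = cohort_roi_table(cohort, noise_sd={"MD": 0.01}, seed=9)
        pd.testing.assert_frame_equal(a, b)
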