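import numpy as np
import pytest

from pmdti.dwi_io import VolumeGeometry
from pmdti.phantom import WM_SLAB1, WM_SLAB2
from pmdti.tensor import TensorField, scalar_maps
from pmdti.tracts import (TrackingParams, global_track,
                          streamline_voxels, track)


@pytest.fixture(scope="module")
def uniform_field():
    shape = (30, 30, 30)
    pdd = np.zeros(shape + (3,))
    pdd[..., 0] = 1.0
    fa = np.full(shape, 0.5)
    return pdd, fa, VolumeGeometry((1, 1, 1), shape)


@pytest.fixture(scope="module")
def arc_field():
    """Quarter-circle tract of radius 20 voxels in the x-y plane."""
    n = 40
    xi, yi = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(xi - 5, yi - 5)
    band = np.abs(r - 20) <= 2.5
    tang = np.stack([-(yi - 5) / np.maximum(r, 1e-6),
                     (xi - 5) / np.maximum(r, 1e-6),
                     np.zeros_like(r)], axis=-1)
    pdd = np.zeros((n, n, 9, 3))
    pdd[:] = tang[:, :, None, :]
    fa = np.where(band, 0.5, 0.0)[:, :, None] * np.ones(9)
    return pdd, fa, VolumeGeometry((1, 1, 1), (n, n, 9))


@pytest.fixture(scope="module")
def crossing_phantom(phantom32):
    maps = scalar_maps(TensorField.from_matrices(phantom32.tensors))
    return phantom32, maps


class TestTrack:
    def test_uniform_field_spans_fov(self, uniform_field):
        pdd, fa, geom = uniform_field
        sl = track(pdd, fa, (15.0, 15.0, 15.0), TrackingParams(), geom)
        assert sl.reason == "left FOV"
        assert sl.points[:, 0].min() < 1.0
        assert sl.points[:, 0].max() > 28.0
        assert np.abs(sl.points[:, 1] - 15.0).max() < 1e-9

    def test_step_size_respected(self, uniform_field):
        pdd, fa, geom = uniform_field
        sl = track(pdd, fa, (15.0, 15.0, 15.0), TrackingParams(step_mm=0.5),
                   geom)
        spacing = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        assert np.allclose(spacing, 0.5, atol=1e-6)

    def test_arc_phantom_within_one_voxel(self, arc_field):
        pdd, fa, geom = arc_field
        sl = track(pdd, fa, (25.0, 5.0, 4.0), TrackingParams(step_mm=0.5),
                   geom)
        r = np.hypot(sl.points[:, 0] - 5, sl.points[:, 1] - 5)
        assert len(sl) > 30
        assert np.abs(r - 20).max() < 1.0

    def test_seed_below_threshold_terminates_immediately(self, arc_field):
        pdd, fa, geom = arc_field
        sl = track(pdd, fa, (6.0, 6.0, 4.0), TrackingParams(), geom)
        assert len(sl) == 0
        assert sl.reason == "seed below threshold"

    def test_invalid_angle_rejected(self, uniform_field):
        pdd, fa, geom = uniform_field
        with pytest.raises(ValueError):
            track(pdd, fa, (15, 15, 15),
                  TrackingParams(max_angle_deg=120.0), geom)


class TestGlobalTrack:
    def _gates(self, ph):
        slab = ph.labels == WM_SLAB1
        x = np.arange(ph.labels.shape[0])[:, None, None]
        a = slab & (x <= 2)
        b = slab & (x >= ph.labels.shape[0] - 3)
        return slab, a, b

    def test_retained_follow_gated_slab_not_crossing_one(self,
                                                         crossing_phantom):
        from scipy.ndimage import binary_dilation

        ph, maps = crossing_phantom
        slab, a, b = self._gates(ph)
        seeds = ph.roi_mask(WM_SLAB1, core=True)
        retained, lines, counts = global_track(
            maps.pdd, maps.fa, seeds, a, b, TrackingParams(seed=0), ph.geom)
        assert len(retained) > 0
        dil = binary_dilation(slab, iterations=1)
        slab2_only = (ph.labels == WM_SLAB2) & ~dil
        for sl in retained:
            v = streamline_voxels(sl, ph.geom)
            v = v[np.all((v >= 0) & (v < 32), axis=1)]
            assert dil[v[:, 0], v[:, 1], v[:, 2]].all()
            assert not slab2_only[v[:, 0], v[:, 1], v[:, 2]].any()

    def test_retained_set_matches_brute_force_oracle(self, crossing_phantom):
        ph, maps = crossing_phantom
        slab, a, b = self._gates(ph)
        seeds = ph.roi_mask(WM_SLAB1, core=True)
        retained, lines, counts = global_track(
            maps.pdd, maps.fa, seeds, a, b, TrackingParams(seed=0), ph.geom)

        def hits(sl, mask):
            v = streamline_voxels(sl, ph.geom)
            v = v[np.all((v >= 0) & (v < np.array(mask.shape)), axis=1)]
            return bool(mask[v[:, 0], v[:, 1], v[:, 2]].any())

        oracle = [sl for sl in lines if hits(sl, a) and hits(sl, b)]
        assert len(oracle) == len(retained)
        for x, y in zip(oracle, retained):
            assert np.array_equal(x.points, y.points)

    def test_gate_order_symmetric(self, crossing_phantom):
        ph, maps = crossing_phantom
        slab, a, b = self._gates(ph)
        seeds = ph.roi_mask(WM_SLAB1, core=True)
        r1, _, c1 = global_track(maps.pdd, maps.fa, seeds, a, b,
                                 TrackingParams(seed=0), ph.geom)
        r2, _, c2 = global_track(maps.pdd, maps.fa, seeds, b, a,
                                 TrackingParams(seed=0), ph.geom)
        assert len(r1) == len(r2)
        assert np.array_equal(c1, c2)

    def test_count_map_zero_outside_retained(self, crossing_phantom):
        ph, maps = crossing_phantom
        slab, a, b = self._gates(ph)
        seeds = ph.roi_mask(WM_SLAB1, core=True)
        retained, _, counts = global_track(
            maps.pdd, maps.fa, seeds, a, b, TrackingParams(seed=0), ph.geom)
        visited = np.zeros_like(counts, dtype=bool)
        for sl in retained:
            v = streamline_voxels(sl, ph.geom)
            v = v[np.all((v >= 0) & (v < 32), axis=1)]
            visited[v[:, 0], v[:, 1], v[:, 2]] = True
        assert np.all(counts[~visited] == 0)
        assert counts.sum() > 0

    def test_overlapping_masks_rejected(self, crossing_phantom):
        ph, maps = crossing_phantom
        slab, a, b = self._gates(ph)
        with pytest.raises(ValueError, match="disjoint"):
            global_track(maps.pdd, maps.fa, slab, a, a,
                         TrackingParams(), ph.geom)

    def test_empty_mask_rejected(self, crossing_phantom):
        ph, maps = crossing_phantom
        slab, a, b = self._gates(ph)
        with pytest.raises(ValueError, match="nonempty"):
            global_track(maps.pdd, maps.fa, slab, np.zeros_like(a), b,
                         TrackingParams(), ph.geom)
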