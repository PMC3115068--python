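"""Deterministic streamline tractography with global inclusion-mask gating.

Streamlines follow the principal diffusion direction (tensor-line
integration with sign continuity) and stop on low FA, sharp bending, the
volume boundary or a length cap.  The gating strategy seeds a broad region
and retains only streamlines that pass through both inclusion masks — no
exclusion masks.  An optional per-step angular jitter emulates the spread
of probabilistic tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Streamline", "TrackingParams", "track", "global_track",
           "streamline_voxels"]


@dataclass
class Streamline:
    points: np.ndarray        # (n, 3) positions in mm
    reason: str               # 'low FA' | 'high curvature' | 'left FOV' | 'max length' | 'seed below threshold'

    def __len__(self):
        return len(self.points)


@dataclass
class TrackingParams:
    """Integration controls; lengths in mm, angles in degrees."""

    step_mm: float | None = None       # default: half the smallest voxel
    fa_threshold: float = 0.10
    max_angle_deg: float = 45.0
    max_length_mm: float | None = None
    seeds_per_voxel: int = 1
    jitter_deg: float = 0.0
    seed: int = 0

    def resolve(self, geom):
        step = self.step_mm or 0.5 * min(geom.voxel_size)
        fov = np.asarray(geom.shape) * np.asarray(geom.voxel_size)
        max_len = self.max_length_mm or 2.0 * float(np.linalg.norm(fov))
        if not (0 < self.max_angle_deg < 90):
            raise ValueError("max bending angle must be in (0, 90) degrees")
        if step <= 0 or max_len <= 0 or self.fa_threshold < 0:
            raise ValueError("tracking parameters must be positive")
        return step, max_len


def _trilinear(field_arr, v):
    """Trilinear interpolation of a (X,Y,Z,...) array at voxel coords v."""
    shape = field_arr.shape[:3]
    v = np.clip(v, 0, np.asarray(shape) - 1.000001)
    i0 = v.astype(int)
    f = v - i0
    i1 = np.minimum(i0 + 1, np.asarray(shape) - 1)
    out = 0.0
    for dx, wx in ((0, 1 - f[0]), (1, f[0])):
        for dy, wy in ((0, 1 - f[1]), (1, f[1])):
            for dz, wz in ((0, 1 - f[2]), (1, f[2])):
                idx = (i1[0] if dx else i0[0],
                       i1[1] if dy else i0[1],
                       i1[2] if dz else i0[2])
                out = out + wx * wy * wz * field_arr[idx]
    return out


def _sample_direction(pdd, v, ref):
    """Sign-aligned trilinear PDD sample (align corners to ref, normalize)."""
    shape = pdd.shape[:3]
    vc = np.clip(v, 0, np.asarray(shape) - 1.000001)
    i0 = vc.astype(int)
    f = vc - i0
    i1 = np.minimum(i0 + 1, np.asarray(shape) - 1)
    acc = np.zeros(3)
    for dx, wx in ((0, 1 - f[0]), (1, f[0])):
        for dy, wy in ((0, 1 - f[1]), (1, f[1])):
            for dz, wz in ((0, 1 - f[2]), (1, f[2])):
                d = pdd[i1[0] if dx else i0[0],
                        i1[1] if dy else i0[1],
                        i1[2] if dz else i0[2]]
                if np.dot(d, ref) < 0:
                    d = -d
                acc += wx * wy * wz * d
    n = np.linalg.norm(acc)
    return acc / n if n > 0 else ref


def _in_fov(v, shape):
    return np.all(v >= 0) and np.all(v <= np.asarray(shape) - 1)


def track(pdd: np.ndarray, fa: np.ndarray, seed_mm, params: TrackingParams,
          geom, rng=None) -> Streamline:
    """Bidirectional Euler integration of the PDD field from one seed (mm)."""
    step, max_len = params.resolve(geom)
    vox = np.asarray(geom.voxel_size)
    shape = fa.shape
    seed_v = np.asarray(seed_mm, dtype=float) / vox
    if not _in_fov(seed_v, shape):
        return Streamline(np.empty((0, 3)), "left FOV")
    if _trilinear(fa, seed_v) < params.fa_threshold:
        return Streamline(np.empty((0, 3)), "seed below threshold")

    cos_max = np.cos(np.deg2rad(params.max_angle_deg))
    d0 = _sample_direction(pdd, seed_v, np.array([1.0, 0.0, 0.0]))
    halves, reasons = [], []
    for sign in (1.0, -1.0):
        pts = []
        p = np.asarray(seed_mm, dtype=float)
        d_prev = sign * d0
        length = 0.0
        reason = "max length"
        while length < max_len / 2:
            v = p / vox
            d = _sample_direction(pdd, v, d_prev)
            if params.jitter_deg > 0 and rng is not None:
                d = _jitter(d, params.jitter_deg, rng)
            if np.dot(d, d_prev) < cos_max:
                reason = "high curvature"
                break
            p_new = p + step * d
            v_new = p_new / vox
            if not _in_fov(v_new, shape):
                reason = "left FOV"
                break
            if _trilinear(fa, v_new) < params.fa_threshold:
                reason = "low FA"
                break
            pts.append(p_new)
            p, d_prev = p_new, d
            length += step
        halves.append(pts)
        reasons.append(reason)
    points = np.array(
        list(reversed(halves[1])) + [np.asarray(seed_mm, dtype=float)]
        + halves[0]
    )
    return Streamline(points, reasons[0])


def _jitter(d, jitter_deg, rng):
    perp = np.cross(d, rng.standard_normal(3))
    n = np.linalg.norm(perp)
    if n == 0:
        return d
    angle = np.deg2rad(jitter_deg) * rng.standard_normal()
    out = np.cos(angle) * d + np.sin(angle) * perp / n
    return out / np.linalg.norm(out)


def streamline_voxels(sl: Streamline, geom) -> np.ndarray:
    """Unique voxel indices visited by a streamline (nearest-voxel rule)."""
    if len(sl) == 0:
        return np.empty((0, 3), dtype=int)
    v = np.rint(sl.points / np.asarray(geom.voxel_size)).astype(int)
    return np.unique(v, axis=0)


def _intersects(sl: Streamline, mask: np.ndarray, geom) -> bool:
    vox = streamline_voxels(sl, geom)
    if len(vox) == 0:
        return False
    inside = np.all((vox >= 0) & (vox < np.asarray(mask.shape)), axis=1)
    vox = vox[inside]
    return bool(mask[vox[:, 0], vox[:, 1], vox[:, 2]].any())


def global_track(pdd, fa, seed_mask, mask_a, mask_b,
                 params: TrackingParams, geom):
    """Seed everywhere in ``seed_mask``; keep streamlines crossing A and B.

    Returns (retained streamlines, all streamlines, count map).  The count
    map holds, per voxel, the number of retained streamlines that visit it.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("inclusion masks must be nonempty")
    if (mask_a & mask_b).any():
        raise ValueError("inclusion masks must be disjoint")
    rng = np.random.default_rng(params.seed)
    vox = np.asarray(geom.voxel_size)
    seeds = np.argwhere(np.asarray(seed_mask, dtype=bool))
    lines = []
    for s in seeds:
        for k in range(params.seeds_per_voxel):
            offset = 0.0 if k == 0 else rng.uniform(-0.49, 0.49, 3)
            lines.append(track(pdd, fa, (s + offset) * vox, params, geom,
                               rng=rng))
    retained = [sl for sl in lines
                if _intersects(sl, mask_a, geom) and _intersects(sl, mask_b, geom)]
    counts = np.zeros(fa.shape, dtype=int)
    for sl in retained:
        v = streamline_voxels(sl, geom)
        inside = np.all((v >= 0) & (v < np.asarray(fa.shape)), axis=1)
        v = v[inside]
        counts[v[:, 0], v[:, 1], v[:, 2]] += 1
    if not retained:
        import warnings

        warnings.warn("no streamlines passed both inclusion masks")
    return retained, lines, counts
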