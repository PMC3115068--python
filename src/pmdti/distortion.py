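"""Simulated acquisition artifacts: B0 drift and eddy-current affines.

Two mechanisms dominate misalignment in segmented-EPI post-mortem data
(fixed tissue cannot move):

* **B0 drift** — gradient heating slowly shifts the image along the slowest
  phase-encode axis; modelled as a translation linear in repeat index.
* **Eddy currents** — each diffusion-encoding direction acquires its own
  small affine distortion (mainly scale and shear), identical across
  repeats of the same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform

from .dwi_io import DWISeries

__all__ = ["AffineMap", "DistortionModel", "apply_affine", "distort_series"]

PARAM_NAMES = [
    "tx", "ty", "tz", "rx", "ry", "rz",
    "sx", "sy", "sz", "hxy", "hxz", "hyz",
]


@dataclass(frozen=True)
class AffineMap:
    """12-parameter affine in voxel coordinates, centred on the volume.

    translation in voxels, rotation as Euler angles in degrees (applied
    x-then-y-then-z), per-axis scale factors, and three shear terms
    (xy, xz, yz planes).  The map acts in pull-back convention:
    ``output(p) = input(C + R Z S (p - C) + t)`` with C the volume centre,
    so a scale factor > 1 shrinks the apparent object.
    """

    translation: tuple = (0.0, 0.0, 0.0)
    rotation: tuple = (0.0, 0.0, 0.0)
    scale: tuple = (1.0, 1.0, 1.0)
    shear: tuple = (0.0, 0.0, 0.0)

    @classmethod
    def from_params(cls, p) -> "AffineMap":
        p = np.asarray(p, dtype=float)
        if p.size != 12:
            raise ValueError("expected 12 affine parameters")
        return cls(tuple(p[0:3]), tuple(p[3:6]), tuple(p[6:9]), tuple(p[9:12]))

    def params(self) -> np.ndarray:
        return np.array([*self.translation, *self.rotation,
                         *self.scale, *self.shear], dtype=float)

    def linear(self) -> np.ndarray:
        """The 3x3 linear part R @ Z @ S."""
        rx, ry, rz = np.deg2rad(self.rotation)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        Z = np.diag(self.scale)
        hxy, hxz, hyz = self.shear
        S = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]], dtype=float)
        M = Rz @ Ry @ Rx @ Z @ S
        if abs(np.linalg.det(M)) < 1e-12:
            raise ValueError("affine map is singular")
        return M

    def matrix(self, shape) -> np.ndarray:
        """4x4 voxel-space matrix mapping output coords to input coords."""
        M = self.linear()
        c = (np.asarray(shape, dtype=float) - 1) / 2.0
        A = np.eye(4)
        A[:3, :3] = M
        A[:3, 3] = c - M @ c + np.asarray(self.translation, dtype=float)
        return A

    def is_identity(self, tol: float = 0.0) -> bool:
        ident = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)
        return bool(np.all(np.abs(self.params() - ident) <= tol))

    def compose(self, other: "AffineMap", shape) -> np.ndarray:
        """Matrix of self-then-other sampling (pull-back composition)."""
        return self.matrix(shape) @ other.matrix(shape)


def apply_affine(volume: np.ndarray, amap: AffineMap | np.ndarray,
                 order: int = 1) -> np.ndarray:
    """Resample a 3D volume through an affine (linear interp, zero fill)."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("apply_affine expects a 3D volume")
    if isinstance(amap, AffineMap):
        if amap.is_identity():
            return volume.copy()
        A = amap.matrix(volume.shape)
    else:
        A = np.asarray(amap, dtype=float)
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")
    return affine_transform(
        volume, A[:3, :3], offset=A[:3, 3], order=order,
        mode="constant", cval=0.0, prefilter=order > 1,
    )


@dataclass(frozen=True)
class DistortionModel:
    """Drift + eddy parameterization.

    drift_rate: voxels per repeat along the slow phase-encode axis.
    eddy_alpha: per-axis scale perturbation gain, scale_i = 1 + alpha |g_i|.
    eddy_beta: shear gain in the two planes containing the fast-PE axis,
    shear(fast, i) = beta * g_fast * g_i.
    """

    drift_rate: float = 0.3
    eddy_alpha: float = 0.02
    eddy_beta: float = 0.01

    def drift_map(self, repeat: int, slow_axis: int) -> AffineMap:
        t = [0.0, 0.0, 0.0]
        t[slow_axis] = self.drift_rate * repeat
        return AffineMap(translation=tuple(t))

    def eddy_map(self, g, fast_axis: int) -> AffineMap:
        """Direction-dependent scale/shear; deterministic in g."""
        g = np.asarray(g, dtype=float)
        if np.linalg.norm(g) == 0:
            return AffineMap()
        scale = tuple(1.0 + self.eddy_alpha * np.abs(g))
        shear = [0.0, 0.0, 0.0]
        # shear planes: (x,y) -> hxy, (x,z) -> hxz, (y,z) -> hyz
        plane = {frozenset({0, 1}): 0, frozenset({0, 2}): 1, frozenset({1, 2}): 2}
        for i in range(3):
            if i == fast_axis:
                continue
            shear[plane[frozenset({fast_axis, i})]] = (
                self.eddy_beta * g[fast_axis] * g[i]
            )
        return AffineMap(scale=scale, shear=tuple(shear))


def distort_series(series: DWISeries, model: DistortionModel,
                   seed: int = 0) -> tuple[DWISeries, pd.DataFrame]:
    """Apply drift (per repeat) and eddy (per direction) distortions.

    Both effects are composed into a single resampling per volume to avoid
    double interpolation.  Returns the distorted series and a truth table
    (repeat, volume, the 12 affine parameters of the composed map).
    ``seed`` is accepted for interface symmetry; the model is deterministic.
    """
    fast, slow = series.geom.phase_axes
    shape = series.shape
    out = np.zeros_like(series.data)
    rows = []
    for k in range(series.n_repeats):
        drift = model.drift_map(k, slow)
        for j in range(series.gtab.n):
            if series.gtab.bvals[j] > 0:
                eddy = model.eddy_map(series.gtab.bvecs[j], fast)
            else:
                eddy = AffineMap()
            A = drift.compose(eddy, shape)
            out[k, j] = apply_affine(series.data[k, j], A)
            combined = AffineMap(
                translation=tuple(
                    np.asarray(drift.translation) + np.asarray(eddy.translation)
                ),
                rotation=eddy.rotation, scale=eddy.scale, shear=eddy.shear,
            )
            rows.append({"repeat": k, "volume": j,
                         **dict(zip(PARAM_NAMES, combined.params()))})
        if model.drift_rate * k > min(shape) / 2:
            warnings.warn("drift has pushed content beyond half the FOV")
    truth = pd.DataFrame(rows)
    return DWISeries(out, series.gtab, series.geom), truth
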