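"""Readers/writers for diffusion volumes, gradient tables, masks and cohort tables.

Gradient tables use the FSL text dialect: ``bvals`` is a single
whitespace-separated row of N values, ``bvecs`` is three rows of N entries
(x, y, z components).  Directions are interpreted in the voxel coordinate
frame; world coordinates are voxel index times voxel size (axis-aligned
geometry only, which is all the synthetic phantoms produce).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientTable",
    "VolumeGeometry",
    "DWISeries",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
    "generate_directions",
    "direction_energy",
]

#: unit-norm tolerance for diffusion-encoding directions with b > 0
UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """Per-volume diffusion-encoding directions and b-values.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weightings in s/mm^2; non-negative.
    bvecs : (N, 3) array
        Unit encoding directions (voxel frame).  Zero vectors are allowed
        (and conventional) where the b-value is zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} incompatible with {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (bvals > 0) & (np.abs(norms - 1.0) > UNIT_TOL)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} directions with b>0 are not unit-norm "
                f"(worst |norm-1| = {np.abs(norms[bad] - 1).max():.3g})"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def validate_for_fit(self) -> None:
        """Require >=1 b=0 volume and >=6 non-collinear DW directions."""
        if self.b0_mask.sum() < 1:
            raise ValueError("tensor fitting requires at least one b=0 volume")
        dw = self.bvecs[self.dwi_mask]
        if dw.shape[0] < 6:
            raise ValueError(
                f"tensor fitting requires >=6 DW directions, got {dw.shape[0]}"
            )
        # rank of the quadratic-form design must be 6
        g = dw
        design = np.column_stack(
            [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
             g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2]]
        )
        if np.linalg.matrix_rank(design) < 6:
            raise ValueError("DW directions are collinear/degenerate for tensor fit")


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel geometry plus the phase-encode axis ordering.

    ``phase_axes`` is (fast PE, slow PE); the slow axis is where B0 drift
    manifests in segmented 3D EPI.
    """

    voxel_size: tuple = (1.0, 1.0, 1.0)
    shape: tuple = (0, 0, 0)
    phase_axes: tuple = (1, 2)

    def __post_init__(self):
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be positive")
        fast, slow = self.phase_axes
        if fast == slow or not {fast, slow} <= {0, 1, 2}:
            raise ValueError("phase-encode axes must be distinct and in {0,1,2}")
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "phase_axes", (int(fast), int(slow)))

    @property
    def slow_pe_axis(self) -> int:
        return self.phase_axes[1]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


@dataclass
class DWISeries:
    """A diffusion acquisition organized as repeats x volumes.

    ``data`` has shape (n_repeats, n_volumes, X, Y, Z); each repeat holds
    the full gradient table in the same volume order.
    """

    data: np.ndarray
    gtab: GradientTable
    geom: VolumeGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 4:
            self.data = self.data[None]
        if self.data.ndim != 5:
            raise ValueError("DWISeries data must be 5D (repeats, volumes, X, Y, Z)")
        if self.data.shape[1] != self.gtab.n:
            raise ValueError(
                f"series has {self.data.shape[1]} volumes but gradient table "
                f"has {self.gtab.n}"
            )

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[2:]

    def flat(self) -> np.ndarray:
        """Collapse repeats into the volume axis -> 4D (X, Y, Z, N*R)."""
        r, n = self.data.shape[:2]
        return np.moveaxis(self.data.reshape(r * n, *self.shape), 0, -1)


# ---------------------------------------------------------------------------
# NIfTI + gradient text I/O


def read_bvals_bvecs(path_bval, path_bvec) -> GradientTable:
    bvals = np.loadtxt(path_bval).ravel()
    bvecs = np.loadtxt(path_bvec)
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got shape {bvecs.shape}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bvec has {bvecs.shape[1]} columns but bval has {bvals.size} entries"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs.T)


def write_bvals_bvecs(gtab: GradientTable, path_bval, path_bvec) -> None:
    np.savetxt(path_bval, gtab.bvals[None], fmt="%.8g")
    np.savetxt(path_bvec, gtab.bvecs.T, fmt="%.10f")


def read_dwi(path_volume, path_bval, path_bvec):
    """Load a 4D NIfTI plus FSL-style gradient files.

    Returns
    -------
    (data, GradientTable, VolumeGeometry)
        ``data`` is 4D with the volume axis last, matching the table length.
    """
    img = nib.load(str(path_volume))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D volume, got {data.ndim}D")
    gtab = read_bvals_bvecs(path_bval, path_bvec)
    if data.shape[3] != gtab.n:
        raise ValueError(
            f"volume has {data.shape[3]} frames but gradient table has {gtab.n}"
        )
    zooms = img.header.get_zooms()[:3]
    geom = VolumeGeometry(voxel_size=zooms, shape=data.shape[:3])
    return data, gtab, geom


def write_dwi(data, gtab: GradientTable, geom: VolumeGeometry, path_volume,
              path_bval=None, path_bvec=None) -> None:
    """Write a 4D array + gradient table; creates the target directory."""
    data = np.asarray(data)
    if data.ndim != 4:
        raise ValueError("write_dwi expects a 4D array (X, Y, Z, N)")
    if data.shape[3] != gtab.n:
        raise ValueError("4th dimension must match the gradient table length")
    path_volume = str(path_volume)
    d = os.path.dirname(path_volume)
    if d:
        os.makedirs(d, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), geom.affine())
    img.header.set_zooms((*geom.voxel_size, 1.0))
    nib.save(img, path_volume)
    if path_bval is None:
        path_bval = _sibling(path_volume, "bvals")
    if path_bvec is None:
        path_bvec = _sibling(path_volume, "bvecs")
    write_bvals_bvecs(gtab, path_bval, path_bvec)


def _sibling(path_volume: str, name: str) -> str:
    base = path_volume
    for suf in (".nii.gz", ".nii"):
        if base.endswith(suf):
            base = base[: -len(suf)]
            break
    return base + "." + name


def read_mask(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return np.rint(data).astype(int)


def write_mask(labels, geom: VolumeGeometry, path) -> None:
    path = str(path)
    d = os.path.dirname(path)
    if d:
        os.makedirs(d, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), geom.affine())
    nib.save(img, path)


COHORT_COLUMNS = ["specimen", "pmi_hours", "si_months"]


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    d = os.path.dirname(str(path))
    if d:
        os.makedirs(d, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Isotropic direction sets


def direction_energy(dirs: np.ndarray) -> float:
    """Electrostatic energy of an antipodally-symmetrized point set.

    Each direction contributes charges at +g and -g; energy is the sum of
    inverse pairwise distances between distinct charges (self-antipode pairs
    excluded, each unordered pair counted once).
    """
    g = np.asarray(dirs, dtype=float)
    n = g.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d1 = np.linalg.norm(g[i] - g[j])
            d2 = np.linalg.norm(g[i] + g[j])
            e += 1.0 / max(d1, 1e-12) + 1.0 / max(d2, 1e-12)
    return e


def _energy_grad(x: np.ndarray, n: int):
    g = x.reshape(n, 3)
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    u = g / norms
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    d1 = np.linalg.norm(diff, axis=-1)
    d2 = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(d1, np.inf)
    np.fill_diagonal(d2, np.inf)
    d1 = np.maximum(d1, 1e-9)
    d2 = np.maximum(d2, 1e-9)
    energy = 0.5 * np.sum(1.0 / d1) + 0.5 * np.sum(1.0 / d2)
    # gradient wrt the unit vectors
    gu = -np.sum(diff / d1[..., None] ** 3, axis=1) - np.sum(
        summ / d2[..., None] ** 3, axis=1
    )
    # chain rule through the normalization
    gx = (gu - u * np.sum(gu * u, axis=1, keepdims=True)) / norms
    return energy, gx.ravel()


def generate_directions(n: int, seed: int = 0) -> np.ndarray:
    """Antipodally-symmetric electrostatic-repulsion direction set.

    Minimizes the Coulomb energy of n charge pairs on the unit sphere from a
    seeded random start, so the layout is deterministic given ``seed``.
    """
    from scipy.optimize import minimize

    if n < 6:
        raise ValueError("need at least 6 directions for tensor encoding")
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n, 3))
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
    res = minimize(
        _energy_grad, x0.ravel(), args=(n,), jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    g = res.x.reshape(n, 3)
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    # canonical hemisphere: flip so the largest-magnitude component is positive
    idx = np.argmax(np.abs(g), axis=1)
    sign = np.sign(g[np.arange(n), idx])
    return g * sign[:, None]


def min_pairwise_angle(dirs: np.ndarray) -> float:
    """Minimum pairwise angle (radians) treating g and -g as the same axis."""
    g = np.asarray(dirs, dtype=float)
    c = np.abs(g @ g.T)
    np.fill_diagonal(c, -np.inf)
    return float(np.arccos(np.clip(c.max(), -1, 1)))
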