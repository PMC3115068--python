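"""Voxelwise diffusion tensor estimation and scalar maps.

The fit is a two-pass weighted log-linear least squares: an ordinary
least-squares pass on log-signal provides predicted signals whose squares
become the weights of the second pass.  This is the standard compromise for
low-SNR magnitude data — the log transform makes the model linear but
inflates noise where the signal is small, which the weights undo to first
order.  Tensors are reported in 10^-3 mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwi_io import DWISeries, GradientTable
from .phantom import DIFFUSIVITY_SCALE

__all__ = ["TensorField", "ScalarMaps", "fit_tensor", "scalar_maps"]


@dataclass
class TensorField:
    """Per-voxel symmetric tensor (lower-triangular order) + S0 estimate.

    ``elements`` stacks (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in 10^-3 mm^2/s.
    ``flags`` marks voxels where intensities had to be clamped or the
    decomposition was degenerate; flagged voxels are excluded from ROI
    statistics downstream.
    """

    elements: np.ndarray      # (..., 6)
    s0: np.ndarray            # (...)
    flags: np.ndarray         # (...) bool

    def matrices(self) -> np.ndarray:
        e = self.elements
        D = np.empty(e.shape[:-1] + (3, 3))
        D[..., 0, 0] = e[..., 0]
        D[..., 1, 1] = e[..., 1]
        D[..., 2, 2] = e[..., 2]
        D[..., 0, 1] = D[..., 1, 0] = e[..., 3]
        D[..., 0, 2] = D[..., 2, 0] = e[..., 4]
        D[..., 1, 2] = D[..., 2, 1] = e[..., 5]
        return D

    @classmethod
    def from_matrices(cls, D, s0=None, flags=None) -> "TensorField":
        D = np.asarray(D)
        e = np.stack(
            [D[..., 0, 0], D[..., 1, 1], D[..., 2, 2],
             D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]], axis=-1
        )
        if s0 is None:
            s0 = np.ones(D.shape[:-2])
        if flags is None:
            flags = np.zeros(D.shape[:-2], dtype=bool)
        return cls(elements=e, s0=np.asarray(s0), flags=np.asarray(flags))


@dataclass
class ScalarMaps:
    """Derived scalar maps; diffusivities in 10^-3 mm^2/s."""

    fa: np.ndarray
    md: np.ndarray
    d_ax: np.ndarray
    d_rad: np.ndarray
    pdd: np.ndarray          # (..., 3) unit principal direction
    color_fa: np.ndarray     # (..., 3) |PDD| * FA
    eigenvalues: np.ndarray  # (..., 3) sorted descending
    flags: np.ndarray


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    g, b = gtab.bvecs, gtab.bvals
    return np.column_stack([
        np.ones(gtab.n),
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def fit_tensor(series: DWISeries, gtab: GradientTable | None = None) -> TensorField:
    """Two-pass WLS tensor fit at every voxel.

    Non-positive intensities are clamped to 1e-6 of the series maximum and
    the affected voxels flagged.  Repeats, if still present, are averaged
    arithmetically before fitting.
    """
    gtab = gtab or series.gtab
    gtab.validate_for_fit()
    X = _design_matrix(gtab)
    if np.linalg.matrix_rank(X) < 7:
        u, s, _ = np.linalg.svd(X)
        raise ValueError(
            "rank-deficient tensor design matrix; singular values "
            f"{np.round(s, 6)} — check direction set for collinearity"
        )
    data = series.data.mean(axis=0)            # (N, X, Y, Z)
    signals = np.moveaxis(data, 0, -1)          # (X, Y, Z, N)
    shape = signals.shape[:-1]
    S = signals.reshape(-1, gtab.n)

    eps = 1e-6 * max(S.max(), 1e-30)
    bad = S <= 0
    flags = bad.any(axis=1)
    S = np.where(bad, eps, S)
    y = np.log(S)

    # pass 1: OLS
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T         # (V, 7)
    # pass 2: WLS with weights = predicted signal squared
    w = np.exp(2.0 * np.clip(X @ beta.T, -700, 700)).T      # (V, N)
    AtA = np.einsum("vn,ni,nj->vij", w, X, X, optimize=True)
    Atb = np.einsum("vn,ni->vi", w * y, X)
    try:
        beta = np.linalg.solve(AtA, Atb[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T

    s0 = np.exp(np.clip(beta[:, 0], -700, 700)).reshape(shape)
    # design absorbs b in s/mm^2 against D in mm^2/s; rescale to 10^-3 units
    elements = (beta[:, 1:] / DIFFUSIVITY_SCALE).reshape(shape + (6,))
    background = signals.max(axis=-1) <= eps
    elements[background] = 0.0
    s0[background] = 0.0
    return TensorField(elements=elements, s0=s0,
                       flags=flags.reshape(shape) | background)


def scalar_maps(field: TensorField) -> ScalarMaps:
    """Eigen-derived maps: FA, MD, axial/radial diffusivity, PDD, colour FA.

    Negative eigenvalues are clamped to zero for FA/MD (voxel flagged);
    an all-zero tensor yields FA = 0, not NaN.
    """
    D = field.matrices()
    vals, vecs = np.linalg.eigh(D)
    # eigh returns ascending; report descending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    neg = (vals < 0).any(axis=-1)
    clamped = np.clip(vals, 0.0, None)
    md = clamped.mean(axis=-1)
    d_ax = clamped[..., 0]
    d_rad = clamped[..., 1:].mean(axis=-1)
    norm2 = np.sum(clamped**2, axis=-1)
    dev = clamped - md[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum(dev**2, axis=-1) / np.where(norm2 > 0, norm2, 1.0))
    degenerate = norm2 == 0
    fa = np.where(~degenerate, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    neg = neg | degenerate
    pdd = vecs[..., :, 0]
    color = np.abs(pdd) * fa[..., None]
    return ScalarMaps(
        fa=fa, md=md, d_ax=d_ax, d_rad=d_rad, pdd=pdd, color_fa=color,
        eigenvalues=clamped, flags=field.flags | neg,
    )
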