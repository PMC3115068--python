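"""Partial-volume simulation: blur raw DWI to a coarser effective resolution.

High-resolution post-mortem data lets one ask what the same tissue would
look like at typical in-vivo resolution.  The raw diffusion-weighted
volumes are convolved with a Gaussian whose FWHM is the quadrature
difference between the target and native voxel sizes, and the tensor is
re-fitted on the native grid.  Shortcuts — blurring the FA map, or
blurring the tensor elements and recomputing FA — are provided for
comparison; they fail to different degrees because FA is a strongly
non-linear function of the signal.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .dwi_io import DWISeries
from .tensor import TensorField, fit_tensor, scalar_maps

__all__ = [
    "gaussian_sigma_mm",
    "blur_raw_and_refit",
    "blur_scalar",
    "blur_tensor",
    "apparent_thickness",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


def gaussian_sigma_mm(native_mm: float, target_mm: float) -> float:
    """Kernel sigma (mm) bringing native resolution to the target.

    Effective resolutions add in quadrature, so the kernel FWHM is
    sqrt(target^2 - native^2).
    """
    if target_mm < native_mm:
        raise ValueError("target resolution must be at least the native one")
    return float(np.sqrt(target_mm**2 - native_mm**2) / FWHM_TO_SIGMA)


def _sigma_voxels(geom, target_mm):
    return [gaussian_sigma_mm(v, target_mm) / v for v in geom.voxel_size]


def _blur(vol, sigma_vox):
    if max(sigma_vox) == 0:
        return np.asarray(vol, dtype=float).copy()
    return gaussian_filter(np.asarray(vol, dtype=float), sigma_vox,
                           mode="constant", cval=0.0)


def blur_raw_and_refit(series: DWISeries, target_mm: float):
    """Blur every raw volume with the same kernel, then refit the tensor.

    Returns the ScalarMaps of the refit on the native grid (the reference
    behaviour data acquired at the coarse resolution would show).
    """
    sigma = _sigma_voxels(series.geom, target_mm)
    data = series.data.copy()
    for k in range(data.shape[0]):
        for j in range(data.shape[1]):
            data[k, j] = _blur(data[k, j], sigma)
    blurred = DWISeries(data, series.gtab, series.geom)
    return scalar_maps(fit_tensor(blurred))


def blur_scalar(scalar_map: np.ndarray, geom, target_mm: float) -> np.ndarray:
    """Blur a derived scalar map (e.g. FA) with the same kernel."""
    return _blur(scalar_map, _sigma_voxels(geom, target_mm))


def blur_tensor(field: TensorField, geom, target_mm: float):
    """Blur the six tensor elements, then recompute the scalar maps."""
    sigma = _sigma_voxels(geom, target_mm)
    e = np.stack([_blur(field.elements[..., i], sigma) for i in range(6)],
                 axis=-1)
    s0 = _blur(field.s0, sigma)
    return scalar_maps(TensorField(elements=e, s0=s0, flags=field.flags.copy()))


def apparent_thickness(fa: np.ndarray, axis: int, region: np.ndarray,
                       threshold: float, voxel_mm: float = 1.0) -> float:
    """Mean cross-sectional extent (mm) where FA exceeds the threshold.

    ``region`` restricts the in-plane footprint over which profiles along
    ``axis`` are measured (it should cover the tract's cross-section);
    the thickness of each profile is the count of suprathreshold voxels.
    """
    fa = np.asarray(fa, dtype=float)
    supra = (fa > threshold) & np.asarray(region, dtype=bool)
    if not supra.any():
        warnings.warn("no voxels above the FA threshold; thickness = 0")
        return 0.0
    counts = supra.sum(axis=axis)
    used = counts[counts > 0]
    return float(used.mean() * voxel_mm)
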