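"""Pre-processing pipeline: drift correction, repeat averaging, eddy correction.

Stage order follows the acquisition physics: B0 drift accumulates over
repeats, so each repeat is first registered back to the first repeat with a
translation constrained to the slowest phase-encode axis.  Repeats are then
averaged (eddy distortions are consistent across repeats, so averaging does
not blur them), and each mean diffusion-weighted volume is registered to the
mean b=0 with a 12-degree-of-freedom affine.  Because the diffusion-weighted
contrast differs from the b=0 contrast, the affine stage is driven by a
mutual-information cost; a least-squares cost is provided for comparison
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .distortion import PARAM_NAMES, AffineMap, apply_affine
from .dwi_io import DWISeries, GradientTable

__all__ = [
    "RegistrationResult",
    "mutual_information",
    "register_drift",
    "average_repeats",
    "register_eddy",
    "correct_series",
]

IDENTITY_PARAMS = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)


@dataclass
class RegistrationResult:
    """Estimated forward distortion map plus optimizer diagnostics.

    Applying the inverse of ``map`` to the moving image aligns it with the
    fixed image; ``cost`` is the final mutual information (nats) unless a
    different cost was requested.
    """

    map: AffineMap
    cost: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# mutual information


def _joint_histogram_pv(a, b, bins):
    """Joint histogram with bilinear partial-volume weighting.

    Each sample spreads its unit mass over the four neighbouring bins, which
    makes the MI surface smooth under sub-voxel resampling.
    """
    fa = (a - a.min()) / (np.ptp(a) or 1.0)
    fb = (b - b.min()) / (np.ptp(b) or 1.0)
    fa = np.clip(fa * (bins - 1), 0, bins - 1 - 1e-9)
    fb = np.clip(fb * (bins - 1), 0, bins - 1 - 1e-9)
    ia, ib = fa.astype(int), fb.astype(int)
    wa, wb = fa - ia, fb - ib
    hist = np.zeros(bins * bins)
    for da, ddb, w in (
        (0, 0, (1 - wa) * (1 - wb)),
        (1, 0, wa * (1 - wb)),
        (0, 1, (1 - wa) * wb),
        (1, 1, wa * wb),
    ):
        hist += np.bincount((ia + da) * bins + (ib + ddb), weights=w,
                            minlength=bins * bins)
    return hist.reshape(bins, bins)


def _entropy(p):
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(a, b, bins: int = 64) -> float:
    """MI in nats from a joint histogram, MI = H(A) + H(B) - H(A,B).

    Only voxels where either image is nonzero contribute (the zero-signal
    immersion background would otherwise dominate the histogram).  Hard
    binning, so MI(A, A) = H(A) exactly; the registration cost uses a
    partial-volume-weighted variant internally for smoothness.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have equal shapes")
    if bins < 8:
        raise ValueError("need at least 8 bins")
    mask = (a != 0) | (b != 0)
    av, bv = a[mask], b[mask]
    if av.size == 0 or np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("constant image: mutual information undefined, returning 0")
        return 0.0
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    joint /= joint.sum()
    return _entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0)) - _entropy(
        joint.ravel()
    )


def _registration_mask(fixed):
    """Eroded support of the fixed image.

    Restricting the histogram to a transform-independent mask well inside
    the fixed image keeps the cost from being gamed by moving background
    in or out of the overlap region.
    """
    m = fixed > 1e-3 * fixed.max()
    er = ndimage.binary_erosion(m, iterations=3)
    return er if er.any() else m


def _masked_mi(moving, fixed, mask, bins):
    av, bv = moving[mask], fixed[mask]
    if av.size == 0 or np.ptp(av) == 0 or np.ptp(bv) == 0:
        return 0.0
    joint = _joint_histogram_pv(av, bv, bins)
    joint /= joint.sum()
    return _entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0)) - _entropy(
        joint.ravel()
    )


# ---------------------------------------------------------------------------
# drift registration (1 DOF)


def _shifted_mi(moving, fixed, shift, axis, bins, mask=None):
    vec = [0.0, 0.0, 0.0]
    vec[axis] = shift
    m = ndimage.shift(moving, vec, order=1, mode="constant", cval=0.0,
                      prefilter=False)
    if mask is None:
        return mutual_information(m, fixed, bins)
    return _masked_mi(m, fixed, mask, bins)


def register_drift(moving, fixed, slow_axis: int, max_shift: float = 5.0,
                   bins: int = 64) -> RegistrationResult:
    """Estimate a translation along the slow phase-encode axis.

    The returned map is the forward drift (the shift the moving image has
    suffered); correcting means resampling with its inverse.  Search is a
    coarse bracket over +-max_shift followed by bounded parabolic
    refinement of the MI cost.
    """
    # pre-smoothing both images equalizes the interpolation-induced blur of
    # the resampled moving image, suppressing the integer-shift artifacts a
    # histogram MI cost otherwise exhibits
    moving = ndimage.gaussian_filter(np.asarray(moving, dtype=float), 1.0)
    fixed = ndimage.gaussian_filter(np.asarray(fixed, dtype=float), 1.0)
    mask = _registration_mask(fixed)
    grid = np.arange(-max_shift, max_shift + 0.26, 0.5)
    scores = np.array([_shifted_mi(moving, fixed, s, slow_axis, bins, mask)
                       for s in grid])
    k = int(np.argmax(scores))
    at_edge = k in (0, len(grid) - 1)
    # fine bracket + parabolic refinement of the top sample
    fine = np.arange(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)] + 0.026,
                     0.05)
    fine_scores = np.array([_shifted_mi(moving, fixed, s, slow_axis, bins, mask)
                            for s in fine])
    kf = int(np.argmax(fine_scores))
    best_shift, best_score = float(fine[kf]), float(fine_scores[kf])
    if 0 < kf < len(fine) - 1:
        y0, y1, y2 = fine_scores[kf - 1: kf + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # concave triple: parabolic vertex
            best_shift += 0.05 * 0.5 * (y0 - y2) / denom
            best_score = float(_shifted_mi(moving, fixed, best_shift,
                                           slow_axis, bins, mask))
            if best_score < y1:  # spiky optimum: keep the grid sample
                best_shift, best_score = float(fine[kf]), float(y1)
    # ndimage.shift moves content by +s while a forward drift map with
    # translation t moves content by -t; the best content shift s therefore
    # equals the forward drift translation directly.
    translation = [0.0, 0.0, 0.0]
    translation[slow_axis] = best_shift
    return RegistrationResult(
        map=AffineMap(translation=tuple(translation)),
        cost=best_score,
        iterations=len(grid) + len(fine) + 1,
        converged=not at_edge,
    )


# ---------------------------------------------------------------------------
# repeat averaging


def average_repeats(series: DWISeries) -> DWISeries:
    """Mean across repeats; all b=0 volumes are merged into one mean b=0."""
    mean = series.data.mean(axis=0)
    b0 = series.gtab.b0_mask
    if b0.any():
        b0_mean = mean[b0].mean(axis=0)
        dw_idx = np.flatnonzero(~b0)
        data = np.concatenate([b0_mean[None], mean[dw_idx]], axis=0)
        gtab = GradientTable(
            bvals=np.concatenate([[0.0], series.gtab.bvals[dw_idx]]),
            bvecs=np.concatenate([[[0.0, 0.0, 0.0]], series.gtab.bvecs[dw_idx]]),
        )
    else:
        data, gtab = mean, series.gtab
    return DWISeries(data[None], gtab, series.geom)


# ---------------------------------------------------------------------------
# eddy registration (12 DOF)


def _downsample(vol, factor):
    """Anti-aliased downsampling plus one voxel of smoothing at the level.

    The extra smoothing keeps the MI cost free of the grid-aligned
    interpolation artifacts that otherwise trap the affine search.
    """
    if factor > 1:
        sm = ndimage.gaussian_filter(vol, sigma=factor / 2.0)
        vol = ndimage.zoom(sm, 1.0 / factor, order=1, prefilter=False)
    return ndimage.gaussian_filter(vol, sigma=1.0)


def _centroid(vol):
    w = np.abs(vol)
    total = w.sum()
    if total == 0:
        return (np.asarray(vol.shape, dtype=float) - 1) / 2.0
    idx = np.indices(vol.shape, dtype=float)
    return np.array([float((i * w).sum() / total) for i in idx])


def _matrix_about(params, centre):
    """4x4 pull-back matrix of 12 params centred on an arbitrary point."""
    amap = AffineMap.from_params(params)
    M = amap.linear()
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = centre - M @ centre + np.asarray(amap.translation)
    return A


def _coordinate_polish(obj, params, sweeps=4):
    """Per-parameter parabolic refinement around the Powell solution.

    Powell can stall in shallow valleys of the histogram cost; a few
    coordinate sweeps with shrinking probes reliably reach the per-axis
    optimum, which is where the cost's maximum sits on well-conditioned
    fixtures.
    """
    deltas = np.array([0.2] * 3 + [0.2] * 3 + [0.004] * 6)
    best = obj(params)
    nfev = 1
    for _ in range(sweeps):
        for i in range(12):
            d = deltas[i]
            probe_p, probe_m = params.copy(), params.copy()
            probe_p[i] += d
            probe_m[i] -= d
            fp, fm = obj(probe_p), obj(probe_m)
            nfev += 2
            denom = fp - 2 * best + fm
            if denom > 0:
                step = np.clip(0.5 * (fm - fp) / denom * d, -d, d)
            elif fp < best:
                step = d
            elif fm < best:
                step = -d
            else:
                continue
            cand = params.copy()
            cand[i] += step
            fc = obj(cand)
            nfev += 1
            if fc < best:
                params, best = cand, fc
        deltas = deltas * 0.5
    return params, nfev


#: Powell step scaling: voxels, degrees, scale fraction, shear
PARAM_STEPS = np.array([0.5] * 3 + [0.5] * 3 + [0.01] * 3 + [0.01] * 3)


def register_eddy(moving, fixed, bins: int = 64, levels=(4, 2, 1),
                  cost: str = "mi", max_iter: int = 200) -> RegistrationResult:
    """Estimate a 12-DOF affine (forward distortion) of moving w.r.t. fixed.

    Coarse-to-fine derivative-free (Powell) maximization of MI, identity
    initialization.  The inverse of the estimated map aligns the moving
    volume to the fixed one.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("images must have equal shapes")
    if cost not in ("mi", "ssd"):
        raise ValueError(f"unknown cost '{cost}'")
    # optimizing about the content centroid decouples translation from the
    # scale/shear terms (off-centre tissue otherwise couples them strongly);
    # the result is converted back to the volume-centred parameterization.
    centroid = _centroid(fixed)
    params = IDENTITY_PARAMS.copy()   # centroid-centred during the search
    nfev = 0
    success = True
    blocks = [list(range(0, 3)),                        # translation
              list(range(0, 3)) + list(range(6, 12)),   # + scale, shear
              list(range(12))]                          # full 12 DOF
    final_objective = None
    for factor in levels:
        if min(moving.shape) // factor < 8:
            continue
        mv = _downsample(moving, factor)
        fx = _downsample(fixed, factor)
        mask = _registration_mask(fx)
        coords = np.argwhere(mask).T.astype(float)      # (3, N)
        fxv = fx[mask]
        c_f = centroid / factor

        def objective_full(p, mv=mv, fxv=fxv, coords=coords, c_f=c_f,
                           factor=factor):
            p_level = p.copy()
            p_level[0:3] = p_level[0:3] / factor
            inv = np.linalg.inv(_matrix_about(p_level, c_f))
            sample = inv[:3, :3] @ coords + inv[:3, 3:4]
            mvals = ndimage.map_coordinates(mv, sample, order=1,
                                            mode="constant", cval=0.0,
                                            prefilter=False)
            if cost == "ssd":
                return float(np.mean((mvals - fxv) ** 2))
            if np.ptp(mvals) == 0:
                return 0.0
            joint = _joint_histogram_pv(mvals, fxv, bins)
            joint /= joint.sum()
            return -(_entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0))
                     - _entropy(joint.ravel()))

        final_objective = objective_full
        for block in blocks:
            def objective(x, block=block, objective_full=objective_full):
                p = params.copy()
                p[block] = x * PARAM_STEPS[block] + IDENTITY_PARAMS[block]
                return objective_full(p)

            x0 = (params[block] - IDENTITY_PARAMS[block]) / PARAM_STEPS[block]
            res = optimize.minimize(
                objective, x0, method="Powell",
                options={"maxiter": max_iter, "xtol": 2e-2, "ftol": 1e-7},
            )
            nfev += int(res.nfev)
            success = success and bool(res.success)
            params = params.copy()
            params[block] = res.x * PARAM_STEPS[block] + IDENTITY_PARAMS[block]

    params, nfev_polish = _coordinate_polish(final_objective, params)
    nfev += nfev_polish
    final = final_objective(params)
    identity_cost = final_objective(IDENTITY_PARAMS.copy())
    # convert centroid-centred translation to the volume-centred convention
    amap_c = AffineMap.from_params(params)
    M = amap_c.linear()
    cg = (np.asarray(moving.shape, dtype=float) - 1) / 2.0
    t = np.asarray(amap_c.translation) + (M - np.eye(3)) @ (cg - centroid)
    params = params.copy()
    params[0:3] = t
    amap = AffineMap.from_params(params)
    if final > identity_cost:
        return RegistrationResult(
            map=AffineMap(), cost=float(-identity_cost if cost == "mi" else identity_cost),
            iterations=nfev, converged=False,
        )
    return RegistrationResult(
        map=amap, cost=float(-final if cost == "mi" else final),
        iterations=nfev, converged=success,
    )


# ---------------------------------------------------------------------------
# full pipeline


def correct_series(series: DWISeries, bins: int = 64,
                   eddy_levels=(4, 2, 1),
                   final_order: int = 3) -> tuple[DWISeries, pd.DataFrame]:
    """Drift-correct each repeat, average, then eddy-correct each direction.

    Registration runs on cheaply (linearly) resampled intermediates, but the
    output is produced by resampling each raw volume exactly once through
    the composed drift+eddy inverse with spline interpolation of
    ``final_order`` — repeated interpolation would blur the data and bias
    the tensor fit.  Returns the corrected single-repeat series (one mean
    b=0 first, then the diffusion directions) and a per-volume transform log.
    """
    slow = series.geom.slow_pe_axis
    shape = series.shape
    rows = []
    drift_maps = {}
    drifted = series.data.copy()
    for k in range(series.n_repeats):
        for j in range(series.gtab.n):
            if k == 0:
                drift_maps[(k, j)] = AffineMap()
                continue  # reference repeat defines the target frame
            try:
                reg = register_drift(series.data[k, j], series.data[0, j],
                                     slow, bins=bins)
            except Exception as err:  # pragma: no cover - propagation path
                raise RuntimeError(
                    f"drift registration failed at repeat {k}, volume {j}"
                ) from err
            drift_maps[(k, j)] = reg.map
            inv = np.linalg.inv(reg.map.matrix(shape))
            drifted[k, j] = apply_affine(series.data[k, j], inv)
            rows.append({"stage": "drift", "repeat": k, "volume": j,
                         "converged": reg.converged,
                         **dict(zip(PARAM_NAMES, reg.map.params()))})
    avg = average_repeats(DWISeries(drifted, series.gtab, series.geom))

    mean_b0 = avg.data[0, 0]
    dw_idx = np.flatnonzero(series.gtab.dwi_mask)
    eddy_maps = {j: AffineMap() for j in range(series.gtab.n)}
    for jj, j_orig in enumerate(dw_idx, start=1):
        try:
            reg = register_eddy(avg.data[0, jj], mean_b0, bins=bins,
                                levels=eddy_levels)
        except Exception as err:  # pragma: no cover - propagation path
            raise RuntimeError(
                f"eddy registration failed at direction volume {jj}"
            ) from err
        eddy_maps[int(j_orig)] = reg.map
        rows.append({"stage": "eddy", "repeat": -1, "volume": int(j_orig),
                     "converged": reg.converged,
                     **dict(zip(PARAM_NAMES, reg.map.params()))})

    # single-interpolation output: raw volume -> composed inverse resample
    final = np.zeros_like(series.data)
    for k in range(series.n_repeats):
        for j in range(series.gtab.n):
            A = drift_maps[(k, j)].compose(eddy_maps[j], shape)
            final[k, j] = apply_affine(series.data[k, j], np.linalg.inv(A),
                                       order=final_order)
    out = average_repeats(DWISeries(final, series.gtab, series.geom))
    return out, pd.DataFrame(rows)
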