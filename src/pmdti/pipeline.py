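"""End-to-end orchestration of the synthetic analysis workflow.

A run builds a digital specimen, simulates the acquisition with drift and
eddy distortions plus Rician noise, corrects it, fits tensors, and executes
the downstream analyses (cohort regression, partial-volume simulation,
inclusion-mask tractography, protocol timing).  Per-stage seeds are derived
deterministically from the master seed and the stage name, so stages stay
reproducible independently of one another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correction, cohort_stats, distortion, phantom, protocol
from . import resolution, tensor, tracts
from .dwi_io import GradientTable, generate_directions, write_dwi, write_mask

log = logging.getLogger("pmdti")

STAGE_ORDER = ["phantom", "distort", "correct", "fit", "stats", "pvsim",
               "track", "protocol"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


def _checksum(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Flat configuration for a full run."""

    out_dir: str = "pmdti_run"
    master_seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    shape: tuple = (48, 48, 48)
    n_directions: int = 12
    bvalue: float = 4500.0
    n_b0: int = 2
    repeats: int = 3
    noise_sigma: float = 0.0
    drift_rate: float = 0.5
    eddy_alpha: float = 0.02
    eddy_beta: float = 0.01
    cohort_n: int = 11
    pv_targets: tuple = (2.0, 3.5)

    def __post_init__(self):
        order = {s: i for i, s in enumerate(STAGE_ORDER)}
        unknown = [s for s in self.stages if s not in order]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        idx = [order[s] for s in self.stages]
        if idx != sorted(idx):
            raise ValueError("stages must respect the pipeline order "
                             f"{STAGE_ORDER}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_gradient_table(config: RunConfig) -> GradientTable:
    dirs = generate_directions(config.n_directions,
                               seed=stage_seed(config.master_seed, "directions"))
    bvals = np.concatenate([np.zeros(config.n_b0),
                            np.full(config.n_directions, config.bvalue)])
    bvecs = np.concatenate([np.zeros((config.n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the machine-readable summary."""
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(),
                     "master_seed": config.master_seed, "stages": {}}
    ctx: dict = {}
    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            _STAGES[stage](config, ctx, summary)
        except Exception as err:
            summary["failed_stage"] = stage
            _write_summary(config, summary)
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
    _write_summary(config, summary)
    return summary


def _write_summary(config, summary):
    path = os.path.join(config.out_dir, "summary.json")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)


def _stage_phantom(config, ctx, summary):
    seed = stage_seed(config.master_seed, "phantom")
    ph = phantom.build_specimen_phantom(config.shape, seed=seed)
    gtab = build_gradient_table(config)
    series = phantom.simulate_dwi(ph, gtab, repeats=config.repeats)
    if config.noise_sigma > 0:
        series = phantom.add_rician_noise(
            series, config.noise_sigma, seed=stage_seed(config.master_seed, "noise"))
    ctx.update(phantom=ph, gtab=gtab, clean_series=series)
    write_mask(ph.labels, ph.geom, os.path.join(config.out_dir, "labels.nii.gz"))
    write_dwi(series.flat(), _tiled_gtab(gtab, series.n_repeats), ph.geom,
              os.path.join(config.out_dir, "dwi_raw.nii.gz"))
    summary["stages"]["phantom"] = {
        "seed": seed, "shape": list(config.shape),
        "labels_checksum": _checksum(ph.labels),
        "s0_checksum": _checksum(ph.s0),
    }


def _tiled_gtab(gtab, repeats):
    return GradientTable(bvals=np.tile(gtab.bvals, repeats),
                         bvecs=np.tile(gtab.bvecs, (repeats, 1)))


def _stage_distort(config, ctx, summary):
    model = distortion.DistortionModel(
        drift_rate=config.drift_rate, eddy_alpha=config.eddy_alpha,
        eddy_beta=config.eddy_beta)
    series, truth = distortion.distort_series(ctx["clean_series"], model)
    ctx.update(distorted=series, distortion_truth=truth, model=model)
    truth.to_csv(os.path.join(config.out_dir, "distortion_truth.csv"), index=False)
    summary["stages"]["distort"] = {
        "drift_rate": config.drift_rate, "eddy_alpha": config.eddy_alpha,
        "eddy_beta": config.eddy_beta, "data_checksum": _checksum(series.data),
    }


def _stage_correct(config, ctx, summary):
    series = ctx.get("distorted", ctx["clean_series"])
    corrected, transforms = correction.correct_series(series)
    ctx["corrected"] = corrected
    transforms.to_csv(os.path.join(config.out_dir, "transforms.csv"), index=False)
    entry = {"n_transforms": len(transforms),
             "data_checksum": _checksum(corrected.data)}
    truth = ctx.get("distortion_truth")
    if truth is not None:
        entry["recovery"] = recovery_correlation(truth, transforms)
    summary["stages"]["correct"] = entry


def recovery_pairs(truth: pd.DataFrame, transforms: pd.DataFrame):
    """(true, estimated) parameter pairs for a corrected series.

    Pools every estimated parameter with its true counterpart: drift
    translations per (repeat, volume) plus eddy scale/shear per direction
    (scales are compared as deviations from 1 so all entries share the
    dimensionless small-deviation scale).
    """
    pairs_t, pairs_e = [], []
    drift = transforms[transforms.stage == "drift"]
    for _, row in drift.iterrows():
        # row["repeat"], not row.repeat: the latter is the Series method
        tr = truth[(truth["repeat"] == row["repeat"])
                   & (truth["volume"] == row["volume"])]
        if len(tr):
            for p in ("tx", "ty", "tz"):
                pairs_t.append(float(tr.iloc[0][p]))
                pairs_e.append(float(row[p]))
    eddy = transforms[transforms.stage == "eddy"]
    for _, row in eddy.iterrows():
        tr = truth[(truth["repeat"] == 0) & (truth["volume"] == row["volume"])]
        if len(tr):
            for p in ("sx", "sy", "sz"):
                pairs_t.append(float(tr.iloc[0][p]) - 1.0)
                pairs_e.append(float(row[p]) - 1.0)
            for p in ("hxy", "hxz", "hyz"):
                pairs_t.append(float(tr.iloc[0][p]))
                pairs_e.append(float(row[p]))
    return np.asarray(pairs_t), np.asarray(pairs_e)


def recovery_correlation(truth: pd.DataFrame, transforms: pd.DataFrame) -> dict:
    """Pooled correlation of recovered transform parameters with truth."""
    t, e = recovery_pairs(truth, transforms)
    out = {"n_parameters": int(t.size)}
    if t.size > 2 and np.std(t) > 0 and np.std(e) > 0:
        out["pooled_r"] = float(np.corrcoef(t, e)[0, 1])
        out["rms_error"] = float(np.sqrt(np.mean((t - e) ** 2)))
    return out


def _stage_fit(config, ctx, summary):
    series = ctx.get("corrected", ctx.get("distorted", ctx["clean_series"]))
    field_ = tensor.fit_tensor(series)
    maps = tensor.scalar_maps(field_)
    ctx.update(tensor_field=field_, maps=maps)
    import nibabel as nib

    ph = ctx["phantom"]
    for name, arr in (("FA", maps.fa), ("MD", maps.md), ("Dax", maps.d_ax),
                      ("Drad", maps.d_rad), ("V1", maps.pdd)):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32),
                                 ph.geom.affine()),
                 os.path.join(config.out_dir, f"{name}.nii.gz"))
    truth_maps = tensor.scalar_maps(
        tensor.TensorField.from_matrices(ph.tensors))
    wm = ph.roi_mask(phantom.WM_SLAB1, phantom.WM_SLAB2, core=True)
    summary["stages"]["fit"] = {
        "median_wm_fa_error": float(np.median(
            np.abs(maps.fa[wm] - truth_maps.fa[wm]))),
        "fa_checksum": _checksum(maps.fa),
    }


def _stage_stats(config, ctx, summary):
    cfg = phantom.CohortConfig(n=config.cohort_n,
                               seed=stage_seed(config.master_seed, "cohort"))
    cohort = phantom.build_cohort(cfg)
    table = phantom.cohort_roi_table(cohort)
    table.to_csv(os.path.join(config.out_dir, "roi_table.csv"), index=False)
    report = cohort_stats.analyze_cohort(table)
    report.reported.to_csv(os.path.join(config.out_dir, "regression_report.csv"))
    summary["stages"]["stats"] = {
        "md_pmi_slope_average": float(
            report.coefficients.loc[("PMI", "MD"), "Average"]),
        "report_checksum": hashlib.sha256(
            report.coefficients.round(10).to_csv().encode()).hexdigest()[:16],
    }


def _stage_pvsim(config, ctx, summary):
    # the partial-volume analysis runs on its own gray--white boundary
    # fixture at the high-resolution voxel size (the interesting effects
    # live at the tissue--tissue interface, not the immersion boundary)
    ph = phantom.build_gray_white_slab()
    gtab = build_gradient_table(config)
    series = phantom.simulate_dwi(ph, gtab, repeats=1)
    field_ = tensor.fit_tensor(series)
    maps = tensor.scalar_maps(field_)
    geom = series.geom
    wm = ph.labels == phantom.WM_SLAB1
    thr = 0.5 * (maps.fa[wm].mean() + maps.fa[~wm].mean())
    region = np.ones_like(wm)
    entry = {"apparent_thickness_mm": {"native": resolution.apparent_thickness(
        maps.fa, 2, region, thr, geom.voxel_size[2])}}
    interior = np.zeros_like(wm)
    interior[6:-6, 6:-6, 6:-6] = True
    for target in config.pv_targets:
        refit = resolution.blur_raw_and_refit(series, target)
        fa_blur = resolution.blur_scalar(maps.fa, geom, target)
        tensor_blur = resolution.blur_tensor(field_, geom, target)
        entry[f"{target:g}mm"] = {
            "rms_vs_blurred_fa": float(np.sqrt(np.mean(
                (refit.fa[interior] - fa_blur[interior]) ** 2))),
            "rms_vs_blurred_tensor": float(np.sqrt(np.mean(
                (refit.fa[interior] - tensor_blur.fa[interior]) ** 2))),
        }
        entry["apparent_thickness_mm"][f"{target:g}mm"] = (
            resolution.apparent_thickness(refit.fa, 2, region, thr,
                                          geom.voxel_size[2]))
    summary["stages"]["pvsim"] = entry


def _stage_track(config, ctx, summary):
    ph = ctx["phantom"]
    maps = ctx.get("maps") or tensor.scalar_maps(
        tensor.TensorField.from_matrices(ph.tensors))
    slab = ph.labels == phantom.WM_SLAB1
    xs = np.argwhere(slab)[:, 0]
    a = slab & (np.arange(ph.labels.shape[0])[:, None, None] <= xs.min() + 1)
    b = slab & (np.arange(ph.labels.shape[0])[:, None, None] >= xs.max() - 1)
    params = tracts.TrackingParams(seed=stage_seed(config.master_seed, "track"))
    retained, lines, counts = tracts.global_track(
        maps.pdd, maps.fa, slab, a, b, params, ph.geom)
    write_mask(counts, ph.geom, os.path.join(config.out_dir, "tract_counts.nii.gz"))
    with open(os.path.join(config.out_dir, "streamlines.txt"), "w") as fh:
        for i, sl in enumerate(retained):
            for p in sl.points:
                fh.write(f"{i} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
    summary["stages"]["track"] = {
        "n_seeded": len(lines), "n_retained": len(retained),
    }


def _stage_protocol(config, ctx, summary):
    spec = protocol.PRIMARY_PROTOCOL
    hi = protocol.HIGHRES_PROTOCOL
    vt = protocol.volume_time(spec)
    total_s, total_h = protocol.session_time(spec)
    hi_s, hi_h = protocol.session_time(hi)
    summary["stages"]["protocol"] = {
        "volume_time_s": vt,
        "volume_time_mmss": protocol.format_mmss(vt),
        "session_hours": total_h,
        "highres_volume_time_min": protocol.volume_time(hi) / 60.0,
        "highres_session_hours": hi_h,
    }


_STAGES = {
    "phantom": _stage_phantom,
    "distort": _stage_distort,
    "correct": _stage_correct,
    "fit": _stage_fit,
    "stats": _stage_stats,
    "pvsim": _stage_pvsim,
    "track": _stage_track,
    "protocol": _stage_protocol,
}
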