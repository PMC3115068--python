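"""Digital specimens of fixed post-mortem brain tissue.

The generator emulates the imaging situation of whole, formalin-fixed human
brains scanned in a proton-free immersion fluid:

* diffusivities an order of magnitude below in-vivo values (white-matter
  MD around 0.07--0.09 x 10^-3 mm^2/s) probed at b = 4500 s/mm^2;
* white-matter slabs with coherent axial anisotropy, two of which cross;
* a folded cortical ribbon whose principal diffusion direction is radial
  (perpendicular to the pial surface);
* a low-FA "dark band" 0--2 voxels thick in the deep cortical layers at
  the gray--white border;
* exactly zero signal outside the tissue (proton-free immersion).

Cohorts of such specimens carry post-mortem interval (PMI, hours from death
to fixation) and scan interval (SI, months from death to scan) covariates
with a configurable PMI-linear decline of the tissue diffusivities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dwi_io import DWISeries, GradientTable, VolumeGeometry

__all__ = [
    "DIFFUSIVITY_SCALE",
    "ROI_REFERENCE",
    "WM_ROIS",
    "GM_ROIS",
    "TissueClass",
    "Phantom",
    "CohortConfig",
    "Specimen",
    "tensor_from_axial",
    "fa_axial",
    "md_axial",
    "axial_radial_from_md_fa",
    "build_specimen_phantom",
    "simulate_dwi",
    "add_rician_noise",
    "build_cohort",
    "cohort_roi_table",
]

#: diffusivities throughout this package are expressed in 10^-3 mm^2/s;
#: this factor converts them to mm^2/s for the signal equation.
DIFFUSIVITY_SCALE = 1e-3

#: Reference (d_ax, d_rad) per ROI in 10^-3 mm^2/s for fixed tissue.
#: The caudate axial value is 0.201, not the occasionally-quoted 2.01,
#: which is inconsistent with MD = (d_ax + 2 d_rad) / 3 = 0.184.
ROI_REFERENCE = {
    "CC": (0.098, 0.062),
    "PLIC": (0.102, 0.075),
    "SLF": (0.116, 0.082),
    "Opt": (0.097, 0.065),
    "Cing": (0.092, 0.061),
    "Thal": (0.166, 0.141),
    "Caud": (0.201, 0.175),
    "Put": (0.191, 0.167),
}

WM_ROIS = ["CC", "SLF", "Opt", "Cing", "PLIC"]
GM_ROIS = ["Thal", "Caud", "Put"]

# phantom label codes
BACKGROUND = 0
WM_SLAB1 = 1      # corpus-callosum analog (crossing slab, along x)
WM_SLAB2 = 2      # second slab, along y
WM_GYRAL = 3      # white matter under the cortical ribbon
CORTEX = 4
DARK_BAND = 5
DEEP_GRAY = 6     # thalamus analog
PV_RIM = 7        # partial-volume shell at the tissue/immersion interface

LABEL_NAMES = {
    BACKGROUND: "background",
    WM_SLAB1: "wm_slab1",
    WM_SLAB2: "wm_slab2",
    WM_GYRAL: "wm_gyral",
    CORTEX: "cortex",
    DARK_BAND: "dark_band",
    DEEP_GRAY: "deep_gray",
    PV_RIM: "pv_rim",
}


# ---------------------------------------------------------------------------
# axially-symmetric tensor algebra


def tensor_from_axial(d_ax: float, d_rad: float, direction) -> np.ndarray:
    """3x3 tensor with eigenvalues {d_ax, d_rad, d_rad}, principal axis given.

    ``direction`` must be unit-norm; ``d_ax >= d_rad >= 0``.
    """
    if d_ax < d_rad:
        raise ValueError(f"d_ax ({d_ax}) must be >= d_rad ({d_rad})")
    if d_rad < 0:
        raise ValueError("diffusivities must be non-negative")
    v = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError("principal direction must be unit-norm")
    return d_rad * np.eye(3) + (d_ax - d_rad) * np.outer(v, v)


def md_axial(d_ax: float, d_rad: float) -> float:
    return (d_ax + 2.0 * d_rad) / 3.0


def fa_axial(d_ax, d_rad):
    """FA of an axially-symmetric tensor (closed form)."""
    a = np.asarray(d_ax, dtype=float)
    r = np.asarray(d_rad, dtype=float)
    denom = np.sqrt(a**2 + 2 * r**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (a - r) / denom, 0.0)
    return out if out.ndim else float(out)


def axial_radial_from_md_fa(md: float, fa: float):
    """Invert (MD, FA) -> (d_ax, d_rad) for an axially-symmetric tensor."""
    if not 0 <= fa < 1:
        raise ValueError("FA must be in [0, 1)")
    s = np.sqrt(3.0 - 2.0 * fa**2)
    return md * (1 + 2 * fa / s), md * (1 - fa / s)


# ---------------------------------------------------------------------------
# phantom construction


@dataclass(frozen=True)
class TissueClass:
    """Diffusion parameters of one tissue compartment."""

    name: str
    d_ax: float            # 10^-3 mm^2/s
    d_rad: float           # 10^-3 mm^2/s
    s0: float              # arbitrary intensity units
    orientation: str       # 'fixed' | 'radial' | 'tangent_blend'
    direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if not (self.d_ax >= self.d_rad >= 0):
            raise ValueError(f"{self.name}: need d_ax >= d_rad >= 0")


def default_tissue_spec() -> dict:
    """Tissue classes for the default specimen (fixed-tissue values).

    Cortex has higher MD than white matter and intermediate FA; the dark
    band is nearly isotropic so its FA sits below both neighbours.
    """
    return {
        WM_SLAB1: TissueClass("wm_slab1", *ROI_REFERENCE["CC"], 1000.0, "fixed", (1, 0, 0)),
        WM_SLAB2: TissueClass("wm_slab2", *ROI_REFERENCE["SLF"], 1000.0, "fixed", (0, 1, 0)),
        WM_GYRAL: TissueClass("wm_gyral", *ROI_REFERENCE["Cing"], 1000.0, "tangent"),
        CORTEX: TissueClass("cortex", 0.175, 0.140, 900.0, "radial"),
        DARK_BAND: TissueClass("dark_band", 0.155, 0.150, 900.0, "tangent_blend"),
        DEEP_GRAY: TissueClass("deep_gray", *ROI_REFERENCE["Thal"], 950.0, "fixed", (0, 0, 1)),
    }


@dataclass
class Phantom:
    """Label volume + ground-truth tensor field + proton-density map."""

    labels: np.ndarray           # (X, Y, Z) int
    tensors: np.ndarray          # (X, Y, Z, 3, 3) in 10^-3 mm^2/s
    s0: np.ndarray               # (X, Y, Z)
    geom: VolumeGeometry
    tissue: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.s0[self.labels == BACKGROUND] != 0):
            raise ValueError("background voxels must have exactly zero signal")

    def roi_mask(self, *labels, core: bool = False) -> np.ndarray:
        """Voxels carrying any of the given labels.

        With ``core=True`` the mask is eroded by two voxels, mimicking
        hand-drawn ROIs placed in tract interiors away from boundary
        partial-volume effects.
        """
        m = np.isin(self.labels, labels)
        if core:
            from scipy.ndimage import binary_erosion

            er = binary_erosion(m, iterations=2)
            if er.any():
                m = er
        return m


def _ribbon_surface(nx, ny, nz, amp, z0):
    """Generating surface z_s(x, y) of the folded ribbon and its gradient.

    The folding is aperiodic (incommensurate harmonics) along both in-plane
    axes: real cortex is irregular, and a periodic fold would be nearly
    self-similar under small shears, which destroys registration
    identifiability.
    """
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    phx = 2 * np.pi * x / nx
    phy = 2 * np.pi * y / ny
    zs = z0 + amp * (0.6 * np.sin(2.0 * phx) + 0.35 * np.sin(3.3 * phx + 1.1)
                     + 0.55 * np.cos(1.5 * phy) + 0.3 * np.sin(2.6 * phy + 0.4))
    dzdx = (amp * (0.6 * 2.0 * np.cos(2.0 * phx)
                   + 0.35 * 3.3 * np.cos(3.3 * phx + 1.1))
            * 2 * np.pi / nx * np.ones_like(phy))
    dzdy = (amp * (-0.55 * 1.5 * np.sin(1.5 * phy)
                   + 0.3 * 2.6 * np.cos(2.6 * phy + 0.4))
            * 2 * np.pi / ny * np.ones_like(phx))
    return zs, dzdx, dzdy


def build_specimen_phantom(shape=(48, 48, 48), tissue: dict | None = None,
                           seed: int = 0, voxel_size=(0.94, 0.94, 0.94)) -> Phantom:
    """Build one digital specimen.

    Geometry: two straight white-matter slabs crossing at the volume centre
    (along x and y), a sinusoidally folded cortical ribbon near the top with
    radial anisotropy and a 0--2 voxel dark band at its gray--white border,
    a deep-gray sphere, and zero-signal background.  Deterministic given
    ``seed`` (which only drives a mild smooth S0 texture).
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("phantom shape must be at least 32 voxels per axis")
    tissue = dict(default_tissue_spec() if tissue is None else tissue)
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)
    xi, yi, zi = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")

    hw = max(3, nx // 12)  # slab half-width in voxels
    cy, cz = ny // 2, int(0.35 * nz)
    cx = nx // 2
    slab2 = (np.abs(xi - cx) <= hw) & (np.abs(zi - cz) <= hw)
    slab1 = (np.abs(yi - cy) <= hw) & (np.abs(zi - cz) <= hw)
    labels[slab2] = WM_SLAB2
    labels[slab1] = WM_SLAB1          # crossing region keeps slab-1 orientation

    # deep gray sphere plus satellite blobs scattered through the volume so
    # every axis carries intensity structure (registration identifiability)
    gc = np.array([0.72 * nx, 0.25 * ny, 0.18 * nz])
    rad = max(3, nz // 12)
    sphere = (xi - gc[0]) ** 2 + (yi - gc[1]) ** 2 + (zi - gc[2]) ** 2 <= rad**2
    labels[sphere & (labels == BACKGROUND)] = DEEP_GRAY
    satellites = [(0.22, 0.75, 0.15), (0.80, 0.80, 0.30), (0.25, 0.25, 0.52),
                  (0.60, 0.18, 0.55), (0.18, 0.55, 0.30)]
    r2 = max(2, nz // 16) ** 2
    for fx_, fy_, fz_ in satellites:
        c = np.array([fx_ * nx, fy_ * ny, fz_ * nz])
        blob = (xi - c[0]) ** 2 + (yi - c[1]) ** 2 + (zi - c[2]) ** 2 <= r2
        labels[blob & (labels == BACKGROUND)] = DEEP_GRAY

    # folded cortical ribbon: gyral WM below the generating surface z_s(x,y),
    # cortex above, dark band as the deepest cortical shell
    amp = max(2.0, nz / 16.0)
    z0 = 0.72 * nz
    zs, dzdx, dzdy = _ribbon_surface(nx, ny, nz, amp, z0)
    zs3 = zs[:, :, None]
    t_wm, t_ctx = 4, 4
    gyral = (zi >= zs3 - t_wm) & (zi < zs3)
    cortex = (zi >= zs3) & (zi < zs3 + t_ctx)
    labels[gyral & (labels == BACKGROUND)] = WM_GYRAL
    labels[cortex & (labels == BACKGROUND)] = CORTEX
    # band thickness varies 0..2 voxels along the ribbon
    t_band = 1.0 + np.cos(2 * np.pi * 1.0 * np.arange(nx) / nx + 0.7)
    band = (labels == CORTEX) & (zi < zs3 + t_band[:, None, None])
    labels[band] = DARK_BAND

    # analytic surface normal / tangent of the ribbon (independent of labels)
    normal = np.stack([-dzdx, -dzdy, np.ones_like(zs)], axis=-1)
    normal /= np.linalg.norm(normal, axis=-1, keepdims=True)
    tangent = np.stack([np.ones_like(zs), np.zeros_like(zs), dzdx], axis=-1)
    tangent /= np.linalg.norm(tangent, axis=-1, keepdims=True)

    def column_tensors(dirs, d_ax, d_rad):
        """(nx, ny, 3) direction field -> (nx, ny, 3, 3) tensors."""
        vv = np.einsum("xyi,xyj->xyij", dirs, dirs)
        return d_rad * np.eye(3) + (d_ax - d_rad) * vv

    tensors = np.zeros(shape + (3, 3))
    s0 = np.zeros(shape)
    for code, tc in tissue.items():
        m = labels == code
        if not m.any():
            continue
        s0[m] = tc.s0
        if tc.orientation == "fixed":
            v = np.asarray(tc.direction, dtype=float)
            v = v / np.linalg.norm(v)
            tensors[m] = tensor_from_axial(tc.d_ax, tc.d_rad, v)
        else:
            if tc.orientation == "radial":
                dirs = normal
            elif tc.orientation == "tangent":
                dirs = tangent
            else:  # tangent_blend: oblique mix, low anisotropy anyway
                dirs = normal + tangent
                dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
            col = np.broadcast_to(
                column_tensors(dirs, tc.d_ax, tc.d_rad)[:, :, None],
                shape + (3, 3),
            )
            tensors[m] = col[m]

    rng = np.random.default_rng(seed)
    # multi-scale multiplicative texture: real tissue is not piecewise
    # constant, and intensity-based registration needs within-class features
    from scipy import ndimage as ndi

    tex = np.zeros(shape)
    for sigma, amp in ((1.5, 0.12), (3.0, 0.12)):
        t = ndi.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        tex += amp * t / max(t.std(), 1e-12)
    s0 *= 1.0 + tex

    # acquisition point-spread function: soften tissue interfaces over about
    # one voxel (razor-sharp single-voxel edges do not exist at 0.94 mm in
    # magnitude MRI) while keeping the immersion background at exactly zero.
    psf_sigma = 0.8
    tissue_ind = (labels > 0).astype(float)
    soft = ndi.gaussian_filter(tissue_ind, psf_sigma)
    apod = np.clip((soft - 0.15) / 0.7, 0.0, 1.0)
    s0 = ndi.gaussian_filter(s0, psf_sigma) * apod
    for c in range(3):
        for r in range(3):
            tensors[..., c, r] = ndi.gaussian_filter(tensors[..., c, r],
                                                     psf_sigma)
    tensors[apod == 0] = 0.0
    # the softened rim becomes its own partial-volume shell label so that
    # `background` stays the exactly-zero-signal region and tissue ROIs
    # keep their core voxels only
    rim = (apod > 0) & (labels == BACKGROUND)
    labels[rim] = PV_RIM
    s0[labels == BACKGROUND] = 0.0
    tensors[labels == BACKGROUND] = 0.0

    geom = VolumeGeometry(voxel_size=voxel_size, shape=shape)
    normal_field = np.broadcast_to(normal[:, :, None, :], shape + (3,)).copy()
    return Phantom(
        labels=labels, tensors=tensors, s0=s0, geom=geom, tissue=tissue,
        meta={
            "cortex_normals": normal_field,
            "ribbon_surface": zs,
            "slab_axis": {WM_SLAB1: 0, WM_SLAB2: 1},
            "seed": seed,
        },
    )


def build_gray_white_slab(shape=(48, 48, 48), slab_half: int = 4,
                          voxel_size=(0.73, 0.73, 0.73)) -> Phantom:
    """Two-compartment gray--white boundary fixture for partial-volume work.

    A white-matter slab (principal direction x) of thickness
    ``2 * slab_half + 1`` voxels runs through cortex-like tissue with the
    same MD but perpendicular anisotropy (z).  There is no zero-signal
    background: the point is the tissue--tissue boundary, where mixing
    perpendicular tensors depresses FA — the mechanism that makes tracts
    look thinner than they are at coarse resolution.  Equal MD isolates
    that anisotropy mixing from diffusivity gradients.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("fixture shape must be at least 32 voxels per axis")
    nz = shape[2]
    labels = np.full(shape, CORTEX, dtype=np.int16)
    zc = nz // 2
    zi = np.arange(nz)
    slab = np.abs(zi - zc) <= slab_half
    labels[:, :, slab] = WM_SLAB1
    ctx_ax, ctx_rad = axial_radial_from_md_fa(
        md_axial(*ROI_REFERENCE["CC"]), 0.132)
    tensors = np.empty(shape + (3, 3))
    tensors[...] = tensor_from_axial(ctx_ax, ctx_rad, (0.0, 0.0, 1.0))
    tensors[:, :, slab] = tensor_from_axial(*ROI_REFERENCE["CC"], (1.0, 0.0, 0.0))
    s0 = np.full(shape, 1000.0)
    geom = VolumeGeometry(voxel_size=voxel_size, shape=shape)
    return Phantom(labels=labels, tensors=tensors, s0=s0, geom=geom,
                   tissue=default_tissue_spec(),
                   meta={"slab_half": slab_half, "slab_axis": 2})


# ---------------------------------------------------------------------------
# forward signal model


def simulate_dwi(phantom: Phantom, gtab: GradientTable, repeats: int = 1) -> DWISeries:
    """Noiseless DW signal S = S0 exp(-b g^T D g), replicated over repeats."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    D = phantom.tensors * DIFFUSIVITY_SCALE
    g = gtab.bvecs
    b = gtab.bvals
    # quadratic form per direction: (X,Y,Z,N)
    q = np.einsum("...ij,ni,nj->...n", D, g, g)
    signal = phantom.s0[..., None] * np.exp(-b * q)
    data = np.broadcast_to(
        np.moveaxis(signal, -1, 0)[None], (repeats, gtab.n) + phantom.labels.shape
    ).copy()
    return DWISeries(data=data, gtab=gtab, geom=phantom.geom)


def add_rician_noise(series: DWISeries, sigma: float, seed: int = 0) -> DWISeries:
    """Magnitude-image (Rician) noise: |S + n1 + i n2|, n ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DWISeries(series.data.copy(), series.gtab, series.geom)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, series.data.shape)
    n2 = rng.normal(0.0, sigma, series.data.shape)
    data = np.hypot(series.data + n1, n2)
    return DWISeries(data=data, gtab=series.gtab, geom=series.geom)


# ---------------------------------------------------------------------------
# cohort generator

PMI_REF_HOURS = 46.2  # cohort reference PMI; slopes are applied about this point


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sampling distributions and PMI effect sizes.

    PMI and SI are drawn from truncated Gaussians coupled by a Gaussian
    copula to approximate the target correlation.  Diffusivity slopes are
    in 10^-3 mm^2/s per hour of PMI, negative (diffusivity declines with
    delayed fixation); the radial slope is derived from the MD and axial
    slopes so that MD = (d_ax + 2 d_rad)/3 stays exactly linear with the
    configured MD slope.
    """

    n: int = 11
    pmi_mean: float = 46.2
    pmi_sd: float = 19.9
    pmi_range: tuple = (21.0, 69.0)
    si_mean: float = 25.2
    si_sd: float = 14.5
    si_range: tuple = (2.0, 40.0)
    r_target: float = 0.32
    slope_md: float = -0.0122
    slope_dax: float = -0.0149
    #: optional linear FA decline for the SLF analog (per hour); disabled by
    #: default because the printed magnitude (0.019/h) drives FA outside
    #: [0, 1] across the PMI window — see the methods note.
    slope_fa_slf: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for s in (self.slope_md, self.slope_dax):
            if not (0 <= abs(s) <= 0.05):
                raise ValueError("slope magnitudes must be in [0, 0.05]")
        if abs(self.r_target) > 0.9:
            raise ValueError("PMI-SI correlation target unattainable (|r| > 0.9)")

    @property
    def slope_drad(self) -> float:
        return (3.0 * self.slope_md - self.slope_dax) / 2.0


@dataclass
class Specimen:
    """One cohort member: covariates + per-ROI diffusion indices.

    ``roi_params`` maps ROI name -> dict with keys FA, MD, D_ax, D_rad
    (diffusivities in 10^-3 mm^2/s).  These are linear-model values; at
    extreme PMI with the printed slope magnitudes they can leave the
    physical range, in which case building an image phantom clips them.
    """

    specimen: str
    pmi_hours: float
    si_months: float
    roi_params: dict


def _truncnorm_copula(rng, n, rho, specs):
    """Sample correlated truncated normals through a Gaussian copula."""
    from scipy import stats

    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=n)
    u = stats.norm.cdf(z)
    out = []
    for k, (mean, sd, lo, hi) in enumerate(specs):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        out.append(stats.truncnorm.ppf(u[:, k], a, b, loc=mean, scale=sd))
    return out


def build_cohort(config: CohortConfig) -> list[Specimen]:
    """Draw a cohort of specimens with PMI-linear diffusivity decline.

    Every WM ROI's axial/radial diffusivity declines linearly from its
    reference value about PMI = 46.2 h; gray-matter ROIs are PMI-independent.
    The SLF analog optionally also carries a linear FA trend, implemented by
    re-deriving (d_ax, d_rad) from the trended (MD, FA) pair.
    """
    rng = np.random.default_rng(config.seed)
    pmi, si = _truncnorm_copula(
        rng, config.n, config.r_target,
        [(config.pmi_mean, config.pmi_sd, *config.pmi_range),
         (config.si_mean, config.si_sd, *config.si_range)],
    )
    specimens = []
    for i in range(config.n):
        dp = pmi[i] - PMI_REF_HOURS
        params = {}
        for roi, (ax_ref, rad_ref) in ROI_REFERENCE.items():
            if roi not in WM_ROIS:
                ax, rad = ax_ref, rad_ref
                fa = fa_axial(ax, rad)
            elif roi == "SLF" and config.slope_fa_slf != 0.0:
                md = md_axial(ax_ref, rad_ref) + config.slope_md * dp
                fa = float(np.clip(
                    fa_axial(ax_ref, rad_ref) + config.slope_fa_slf * dp,
                    0.0, 0.99,
                ))
                ax, rad = axial_radial_from_md_fa(md, fa)
            else:
                ax = ax_ref + config.slope_dax * dp
                rad = rad_ref + config.slope_drad * dp
                fa = fa_axial(ax, rad)
            params[roi] = {
                "FA": float(fa),
                "MD": md_axial(ax, rad),
                "D_ax": float(ax),
                "D_rad": float(rad),
            }
        specimens.append(
            Specimen(
                specimen=f"SPC{i + 1:02d}",
                pmi_hours=float(pmi[i]),
                si_months=float(si[i]),
                roi_params=params,
            )
        )
    return specimens


def cohort_roi_table(specimens: list[Specimen], noise_sd: dict | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Long-format ROI table (one row per specimen x ROI).

    ``noise_sd`` maps index name -> Gaussian measurement-noise sd added to
    the per-ROI means (e.g. residual specimen-to-specimen variation);
    omit or pass zeros for the noiseless limit.
    """
    rng = np.random.default_rng(seed)
    noise_sd = noise_sd or {}
    rows = []
    for sp in specimens:
        for roi, vals in sp.roi_params.items():
            row = {"specimen": sp.specimen, "roi": roi,
                   "pmi_hours": sp.pmi_hours, "si_months": sp.si_months}
            for idx in ("FA", "MD", "D_ax", "D_rad"):
                v = vals[idx]
                sd = float(noise_sd.get(idx, 0.0))
                if sd > 0:
                    v = v + rng.normal(0.0, sd)
                row[idx] = v
            rows.append(row)
    return pd.DataFrame(rows)


def specimen_phantom_from_cohort(sp: Specimen, shape=(48, 48, 48),
                                 seed: int = 0) -> Phantom:
    """Image phantom whose slab/ribbon tissues carry a specimen's ROI values.

    Diffusivities are floored at 1e-4 (10^-3 mm^2/s units) to keep tensors
    positive semidefinite when the linear PMI model leaves the physical
    range; a warning is issued when flooring occurs.
    """
    tissue = default_tissue_spec()
    mapping = {WM_SLAB1: "CC", WM_SLAB2: "SLF", WM_GYRAL: "Cing",
               DEEP_GRAY: "Thal"}
    floor = 1e-4
    for code, roi in mapping.items():
        ax = sp.roi_params[roi]["D_ax"]
        rad = sp.roi_params[roi]["D_rad"]
        if min(ax, rad) < floor:
            warnings.warn(
                f"{sp.specimen}/{roi}: linear PMI model gives non-physical "
                "diffusivity; flooring for the image phantom"
            )
        rad = max(rad, floor)
        ax = max(ax, rad)
        tissue[code] = replace(tissue[code], d_ax=ax, d_rad=rad)
    return build_specimen_phantom(shape=shape, tissue=tissue, seed=seed)
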