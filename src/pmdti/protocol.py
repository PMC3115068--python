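"""Acquisition timing and SNR-efficiency arithmetic for segmented 3D EPI.

A 3D segmented-EPI diffusion volume needs ``ceil(PE lines / lines per
segment)`` excitations per k-space plane and one plane per slice-encode
step, each costing one TR.  Timing here ignores the partial-Fourier factor:
the printed per-volume times of the fixed-brain protocols (6:22 at 0.94 mm,
17 min at 0.73 mm) are consistent only with full phase-encode coverage.
Pass ``partial_fourier_timing=True`` to scale the line count instead.

The SNR-efficiency model is a fully-spoiled steady state: signal
``sin(a) (1 - E1) / (1 - E1 cos(a))`` with ``E1 = exp(-TR/T1)``, divided by
``sqrt(TR)`` to express SNR per unit scan time.  It is one plausible
reading of the TR trade-off for short-T1 fixed tissue and is exploratory:
its optimum for fixed white matter need not match quoted working ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ProtocolSpec",
    "PRIMARY_PROTOCOL",
    "HIGHRES_PROTOCOL",
    "volume_time",
    "session_time",
    "snr_efficiency",
    "optimal_tr",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Matrix/segmentation/timing description of one diffusion protocol.

    ``matrix`` is (readout, phase-encode, slice-encode); times in seconds,
    flip angle in degrees, b in s/mm^2.
    """

    matrix: tuple = (168, 192, 120)
    lines_per_segment: int = 32
    tr_s: float = 0.530
    te_s: float = 0.122
    flip_deg: float = 75.0
    partial_fourier: float = 5.0 / 8.0
    b_s_mm2: float = 4500.0
    n_directions: int = 54
    n_b0: int = 6
    repeats: int = 3
    t1_s: float = 0.340
    t2_s: float = 0.050

    def __post_init__(self):
        if any(m <= 0 for m in self.matrix) or self.tr_s <= 0 or self.te_s <= 0:
            raise ValueError("matrix and timing entries must be positive")
        if not (0.5 < self.partial_fourier <= 1.0):
            raise ValueError("partial Fourier factor must be in (0.5, 1]")
        if self.lines_per_segment > self.matrix[1]:
            raise ValueError("segment cannot exceed the phase-encode dimension")

    @property
    def pe_lines(self) -> int:
        return self.matrix[1]

    @property
    def slices(self) -> int:
        return self.matrix[2]


#: 24-hour whole-brain protocol at 0.94 mm isotropic
PRIMARY_PROTOCOL = ProtocolSpec()

#: 5-day single-brain protocol at 0.73 mm isotropic
HIGHRES_PROTOCOL = ProtocolSpec(
    matrix=(254, 254, 192), lines_per_segment=32, tr_s=0.670, te_s=0.114,
    flip_deg=77.0, b_s_mm2=3050.0, n_directions=64, n_b0=5, repeats=5,
)


def volume_time(spec: ProtocolSpec, partial_fourier_timing: bool = False) -> float:
    """Seconds per diffusion-weighted volume."""
    lines = spec.pe_lines * (spec.partial_fourier if partial_fourier_timing else 1.0)
    segments = math.ceil(lines / spec.lines_per_segment)
    return segments * spec.slices * spec.tr_s


def session_time(spec: ProtocolSpec, **kw) -> tuple[float, float]:
    """Total diffusion session (seconds, hours) over directions and repeats."""
    total = (spec.n_directions + spec.n_b0) * spec.repeats * volume_time(spec, **kw)
    return total, total / 3600.0


def format_mmss(seconds: float) -> str:
    m, s = divmod(int(round(seconds)), 60)
    return f"{m}:{s:02d}"


def snr_efficiency(tr_s, t1_s: float, flip_deg: float):
    """Steady-state SNR per sqrt(unit time) as a function of TR."""
    tr = np.asarray(tr_s, dtype=float)
    if np.any(tr <= 0) or t1_s <= 0 or not (0 < flip_deg <= 90):
        raise ValueError("TR, T1 must be positive and flip in (0, 90] degrees")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr / t1_s)
    eff = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a)) / np.sqrt(tr)
    return eff if eff.ndim else float(eff)


def optimal_tr(t1_s: float, flip_deg: float,
               bracket=(1e-4, 20.0)) -> tuple[float, bool]:
    """TR maximizing the efficiency model; returns (TR seconds, in-range flag).

    The flag is False (with a warning) when the optimum falls outside the
    500--700 ms working range quoted for fixed white matter — the simple
    spoiled-steady-state model is not expected to reproduce that range.
    """
    res = optimize.minimize_scalar(
        lambda tr: -snr_efficiency(tr, t1_s, flip_deg),
        bounds=bracket, method="bounded", options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(f"TR optimization failed in bracket {bracket}")
    tr = float(res.x)
    in_range = 0.5 <= tr <= 0.7
    if not in_range:
        import warnings

        warnings.warn(
            f"model-optimal TR {tr * 1e3:.0f} ms lies outside the quoted "
            "500-700 ms working range for fixed white matter"
        )
    return tr, in_range
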