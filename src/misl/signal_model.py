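"""Closed-form MISL signal equations.

MISL (magnetization-transfer indirect spin labeling) labels parenchymal
water with an off-resonance MT pulse train; the labeled water exchanges
into CSF and is read out as a fractional CSF signal drop ΔZ.  This module
implements the two analytic pieces of the quantification:

* the tissue MT buildup curve  ΔZ_tissue(t) = α·(1 − exp(−R1ρ,tissue·t)),
  whose asymptote α is the labeling efficiency and whose rate R1ρ,tissue
  is the tissue rotating-frame longitudinal relaxation rate during the
  train, and

* the compartmental exchange model linking ΔZ in a CSF compartment to the
  tissue-to-CSF flow TCF (mL of tissue water delivered per 100 mL of CSF
  per minute),

      ΔZ = α · (TCF/6000) · (1/R1,CSF)
             · [1 + e^(−R1ρ·t)·R1,CSF/R1,app − e^(−R1,CSF·t)·R1ρ/R1,app],

  with R1,app = R1ρ,tissue − R1,CSF.  ΔZ is linear in TCF, so the inverse
  map (ΔZ → TCF) is exact.  The removable singularity at R1,app = 0 is
  handled by a series expansion.

Units contract: ΔZ is a dimensionless fraction everywhere inside the
package (percent only at report boundaries); TCF is mL/100 mL/min; model
time is seconds, acquisition timing configs are milliseconds with explicit
converters (`total_saturation_time` returns ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SaturationScheme",
    "MISLModelParams",
    "SaturationCurve",
    "SaturationFit",
    "ModelDomainError",
    "MINUTES_PER_100ML",
    "total_saturation_time",
    "delta_z_tissue",
    "fit_saturation_curve",
    "misl_forward",
    "tcf_from_delta_z",
]

#: Converts TCF in mL/100 mL/min to a fractional CSF water turnover rate in
#: s^-1: divide by 100 (per-mL fraction) and by 60 (per second).
MINUTES_PER_100ML = 6000.0

#: |R1,app| below this (s^-1) switches the exchange bracket to its series
#: expansion around the degenerate point R1ρ,tissue = R1,CSF.
R1_APP_SERIES_THRESHOLD = 1e-4


class ModelDomainError(ValueError):
    """Raised when parameters put the exchange model outside its domain."""


@dataclass(frozen=True)
class SaturationScheme:
    """MT labeling pulse train: N shaped pulses separated by delays.

    Timing fields are in milliseconds, amplitude in μT, offset in ppm.
    """

    n_pulses: int = 50
    pulse_width_ms: float = 50.0
    interpulse_delay_ms: float = 25.0
    peak_b1_uT: float = 3.0
    offset_ppm: float = -10.0
    shape_name: str = "sincgauss"

    def __post_init__(self) -> None:
        if int(self.n_pulses) != self.n_pulses or self.n_pulses < 1:
            raise ValueError(f"n_pulses must be a positive integer, got {self.n_pulses}")
        if self.pulse_width_ms <= 0:
            raise ValueError(f"pulse_width_ms must be > 0, got {self.pulse_width_ms}")
        if self.interpulse_delay_ms < 0:
            raise ValueError(
                f"interpulse_delay_ms must be >= 0, got {self.interpulse_delay_ms}"
            )

    @property
    def total_saturation_time_ms(self) -> float:
        return total_saturation_time(self)

    @property
    def total_saturation_time_s(self) -> float:
        return total_saturation_time(self) / 1000.0


@dataclass(frozen=True)
class MISLModelParams:
    """Quantification constants: labeling efficiency and relaxation rates.

    alpha is the steady-state tissue MT saturation fraction (measured per
    subject as ΔZ_tissue at full saturation time); r1rho_tissue_s1 the
    tissue rotating-frame R1ρ during the train; r1_csf_s1 the CSF
    longitudinal rate (literature default 0.23 s^-1).
    """

    alpha: float = 0.42
    r1rho_tissue_s1: float = 1.72
    r1_csf_s1: float = 0.23

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.r1rho_tissue_s1 <= 0:
            raise ValueError(f"r1rho_tissue_s1 must be > 0, got {self.r1rho_tissue_s1}")
        if self.r1_csf_s1 <= 0:
            raise ValueError(f"r1_csf_s1 must be > 0, got {self.r1_csf_s1}")

    @property
    def r1_app_s1(self) -> float:
        """Apparent rate R1ρ,tissue − R1,CSF (derived, may be ≈ 0)."""
        return self.r1rho_tissue_s1 - self.r1_csf_s1


@dataclass(frozen=True)
class SaturationCurve:
    """Measured tissue MT buildup: ΔZ_tissue at increasing saturation times."""

    t_sat_values_s: tuple[float, ...]
    delta_z_values: tuple[float, ...]

    def __init__(self, t_sat_values_s: Sequence[float], delta_z_values: Sequence[float]):
        t = tuple(float(v) for v in t_sat_values_s)
        z = tuple(float(v) for v in delta_z_values)
        if len(t) != len(z) or len(t) < 2:
            raise ValueError("need equal-length t_sat and delta_z arrays with >= 2 points")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("t_sat values must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in z):
            raise ValueError("delta_z values must lie in [0, 1]")
        object.__setattr__(self, "t_sat_values_s", t)
        object.__setattr__(self, "delta_z_values", z)


@dataclass(frozen=True)
class SaturationFit:
    """Result of fitting the mono-exponential buildup to a SaturationCurve."""

    alpha: float
    r1rho_tissue_s1: float
    residual_norm: float
    covariance: np.ndarray = field(repr=False)
    n_points: int = 0


def total_saturation_time(scheme: SaturationScheme) -> float:
    """Total saturation time of the train in ms (no trailing delay):

    t_sat = N·(t_p + t_d) − t_d.
    """
    return (
        scheme.n_pulses * (scheme.pulse_width_ms + scheme.interpulse_delay_ms)
        - scheme.interpulse_delay_ms
    )


def delta_z_tissue(params: MISLModelParams, t_sat_s):
    """Tissue MT signal buildup ΔZ_tissue(t) = α·(1 − e^(−R1ρ·t)).

    `t_sat_s` is in seconds and may be a scalar or array; negative times are
    rejected.  Monotonically increasing with asymptote α.
    """
    t = np.asarray(t_sat_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_sat must be >= 0")
    out = params.alpha * (1.0 - np.exp(-params.r1rho_tissue_s1 * t))
    return float(out) if np.isscalar(t_sat_s) else out


def _buildup(t, alpha, r1rho):
    return alpha * (1.0 - np.exp(-r1rho * t))


def fit_saturation_curve(curve: SaturationCurve) -> SaturationFit:
    """Least-squares fit of (α, R1ρ,tissue) to a measured buildup curve.

    Requires >= 3 points spanning at least a factor of 3 in t_sat.
    Initialization: α₀ = max(ΔZ), R1ρ₀ = 1/t at half-max; bounds α ∈ [0, 1],
    R1ρ ∈ (0, 100].  A flat curve (no buildup) makes R1ρ unidentifiable and
    is rejected rather than silently returned.
    """
    t = np.asarray(curve.t_sat_values_s)
    z = np.asarray(curve.delta_z_values)
    if len(t) < 3:
        raise ValueError(f"need >= 3 points to fit, got {len(t)}")
    if t[-1] < 3.0 * t[0]:
        raise ValueError(
            f"t_sat range too narrow to identify R1rho: {t[0]:g}..{t[-1]:g} s "
            "(need a factor >= 3)"
        )
    if np.ptp(z) < 1e-12:
        raise ValueError(
            "all delta_z values are equal: R1rho is unidentifiable from a flat curve"
        )
    alpha0 = float(np.max(z))
    half = alpha0 / 2.0
    t_half = float(np.interp(half, z, t)) if z[0] < half else float(t[0])
    r1rho0 = 1.0 / max(t_half, 1e-3)
    try:
        popt, pcov = curve_fit(
            _buildup,
            t,
            z,
            p0=[alpha0, min(r1rho0, 100.0)],
            bounds=([0.0, 1e-9], [1.0, 100.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise RuntimeError(f"saturation-curve fit did not converge: {exc}") from exc
    resid = z - _buildup(t, *popt)
    return SaturationFit(
        alpha=float(popt[0]),
        r1rho_tissue_s1=float(popt[1]),
        residual_norm=float(np.linalg.norm(resid)),
        covariance=pcov,
        n_points=len(t),
    )


def exchange_bracket(r1rho_s1: float, r1_csf_s1: float, t_sat_s: float) -> float:
    """Dimensionless bracket of the exchange model.

    B(t) = 1 + e^(−R1ρ·t)·R1,CSF/R1,app − e^(−R1,CSF·t)·R1ρ/R1,app with
    R1,app = R1ρ − R1,CSF.  Near R1,app = 0 the two poles cancel; a
    second-order series around the degenerate point,
    B ≈ 1 − e^(−r·t)(1 + r·t) + R1,app·e^(−r·t)·r·t²/2 − R1,app²·e^(−r·t)·r·t³/6
    (r = R1,CSF), is used instead, making B continuous across it.
    """
    r1app = r1rho_s1 - r1_csf_s1
    r, t = r1_csf_s1, t_sat_s
    if abs(r1app) < R1_APP_SERIES_THRESHOLD:
        # second-order series in r1app around the degenerate point
        e = np.exp(-r * t)
        return (
            1.0
            - e * (1.0 + r * t)
            + r1app * e * r * t * t / 2.0
            - r1app**2 * e * r * t**3 / 6.0
        )
    return 1.0 + np.exp(-r1rho_s1 * t) * r / r1app - np.exp(-r * t) * r1rho_s1 / r1app


def misl_forward(params: MISLModelParams, tcf, t_sat_s: float):
    """Forward exchange model: ΔZ in a CSF compartment for a given TCF.

    ΔZ = α·(TCF/6000)·(1/R1,CSF)·B(t_sat); linear in TCF.  `tcf` in
    mL/100 mL/min (scalar or array, >= 0), `t_sat_s` in seconds (> 0).
    """
    tcf_arr = np.asarray(tcf, dtype=float)
    if np.any(tcf_arr < 0):
        raise ValueError("tcf must be >= 0 in the forward model")
    if t_sat_s <= 0:
        raise ValueError("t_sat must be > 0")
    bracket = exchange_bracket(params.r1rho_tissue_s1, params.r1_csf_s1, t_sat_s)
    if bracket <= 0:
        raise ModelDomainError(
            f"exchange bracket is non-positive ({bracket:.3g}) for "
            f"R1rho={params.r1rho_tissue_s1}, R1csf={params.r1_csf_s1}, t={t_sat_s}"
        )
    out = params.alpha * (tcf_arr / MINUTES_PER_100ML) / params.r1_csf_s1 * bracket
    return float(out) if np.isscalar(tcf) else out


def tcf_from_delta_z(params: MISLModelParams, delta_z, t_sat_s: float):
    """Invert the exchange model: TCF (mL/100 mL/min) from measured ΔZ.

    Exact algebraic inverse of `misl_forward` (ΔZ is linear in TCF).
    Negative ΔZ yields negative TCF, returned as-is — downstream QC flags
    such voxels; clamping here would bias ROI means.  NaN propagates.
    """
    if t_sat_s <= 0:
        raise ValueError("t_sat must be > 0")
    bracket = exchange_bracket(params.r1rho_tissue_s1, params.r1_csf_s1, t_sat_s)
    if bracket <= 0:
        raise ModelDomainError(
            f"exchange bracket is non-positive ({bracket:.3g}); cannot invert"
        )
    dz = np.asarray(delta_z, dtype=float)
    out = dz * MINUTES_PER_100ML * params.r1_csf_s1 / (params.alpha * bracket)
    return float(out) if np.isscalar(delta_z) else out
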