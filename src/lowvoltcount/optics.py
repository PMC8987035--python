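"""Analytic electron-optics calculators for low-voltage imaging.

Relativistic electron parameters, the chromatic-aberration envelope and
its effect on frequency-resolved SNR, the linear dependence of relative
radiation damage on 1/beta^2, and the information coefficient (IFC).

Units: acceleration voltage in volts, chromatic aberration coefficient
Cc in mm, energy spread in eV, spatial frequency in 1/Å, wavelength in Å.
The electron rest energy is fixed at 510998.95 eV so derived values are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .snr_metrics import RadialCurve, fsc_to_snr, snr_to_fsc

__all__ = [
    "ELECTRON_REST_ENERGY_EV",
    "OpticsParams",
    "DamageFit",
    "IFCParams",
    "wavelength",
    "beta2",
    "cc_envelope",
    "depressed_snr",
    "depressed_fsc",
    "damage_fit",
    "ifc",
]

ELECTRON_REST_ENERGY_EV = 510998.95
_MM_TO_ANGSTROM = 1e7


@dataclass
class OpticsParams:
    """Chromatic-envelope parameters.

    ``dI_over_I`` and ``dV_over_V`` (lens-current and voltage stability)
    default to 0; the energy-spread term dominates typical field-emission
    instruments.
    """

    V: float                    # acceleration voltage, volts
    Cc_mm: float = 2.7          # chromatic aberration coefficient, mm
    dE_eV: float = 0.7          # energy spread, eV
    dI_over_I: float = 0.0
    dV_over_V: float = 0.0

    def __post_init__(self):
        if self.V <= 0:
            raise ValueError("voltage must be positive")
        if self.Cc_mm < 0 or self.dE_eV < 0:
            raise ValueError("Cc and dE must be non-negative")


@dataclass
class DamageFit:
    """OLS fit of relative radiation damage y against 1/beta^2."""

    intercept: float
    slope: float
    r_square: float
    points: list[tuple[float, float]]
    slope_stderr: float = np.nan
    intercept_stderr: float = np.nan

    def predict(self, V: float) -> float:
        return self.intercept + self.slope / beta2(V)


@dataclass
class IFCParams:
    """Transmission and cross-sections entering the information coefficient."""

    T: float
    sigma_e: float
    sigma_i: float

    def __post_init__(self):
        if not (0 < self.T <= 1):
            raise ValueError("transmission T must be in (0, 1]")
        if self.sigma_e <= 0 or self.sigma_i <= 0:
            raise ValueError("cross-sections must be positive")


def wavelength(V) -> float:
    """Relativistic de Broglie wavelength in Å for voltage ``V`` (volts).

    lambda = 12.2643 / sqrt(V * (1 + 0.978476e-6 V)).
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("voltage must be positive")
    out = 12.2643 / np.sqrt(V * (1.0 + 0.978476e-6 * V))
    return out.item() if out.ndim == 0 else out


def beta2(V) -> float:
    """(v/c)^2 for electrons accelerated through ``V`` volts."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("voltage must be positive")
    gamma = 1.0 + V / ELECTRON_REST_ENERGY_EV
    out = 1.0 - 1.0 / gamma**2
    return out.item() if out.ndim == 0 else out


def focus_spread(p: OpticsParams) -> float:
    """Chromatic focus spread delta in Å:
    delta = Cc * sqrt(4 (dI/I)^2 + (dE/V)^2 + (dV/V)^2)."""
    cc = p.Cc_mm * _MM_TO_ANGSTROM
    return cc * np.sqrt(4.0 * p.dI_over_I**2 + (p.dE_eV / p.V)**2
                        + p.dV_over_V**2)


def cc_envelope(u, p: OpticsParams):
    """Chromatic-aberration envelope E(u) = exp[-0.5 (pi lambda delta)^2 u^4].

    ``u`` in 1/Å.  E(0) = 1 exactly; strictly decreasing in u, Cc and dE.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("spatial frequency must be >= 0")
    lam = wavelength(p.V)
    delta = focus_spread(p)
    out = np.exp(-0.5 * (np.pi * lam * delta)**2 * u**4)
    return out.item() if out.ndim == 0 else out


def depressed_snr(snr: RadialCurve, p_ref: OpticsParams,
                  p_new: OpticsParams) -> RadialCurve:
    """Rescale a frequency-resolved SNR measured under ``p_ref`` optics to
    the ``p_new`` optics: SNR'(u) = E_new(u)^2 * SNR(u) / E_ref(u)^2.

    Shells are physical frequencies in 1/Å.  Shells where the reference
    envelope underflows are flagged invalid (NaN, listed in ``meta``).
    """
    e_ref = np.asarray(cc_envelope(snr.shells, p_ref))
    e_new = np.asarray(cc_envelope(snr.shells, p_new))
    bad = e_ref < 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(bad, np.nan, snr.values * (e_new / e_ref)**2)
    out = RadialCurve(snr.shells.copy(), vals, snr.n_terms.copy())
    if np.any(bad):
        out.meta["invalid_shells"] = snr.shells[bad].tolist()
    return out


def depressed_fsc(fsc: RadialCurve, p_ref: OpticsParams,
                  p_new: OpticsParams) -> RadialCurve:
    """Companion helper: FSC -> SNR -> chromatic depression -> FSC'."""
    return snr_to_fsc(depressed_snr(fsc_to_snr(fsc), p_ref, p_new))


def damage_fit(points) -> DamageFit:
    """Least squares of relative damage y on 1/beta^2.

    ``points`` is a sequence of ``(V_volts, y)``.  Returns intercept,
    slope, R^2 and the standard errors of both coefficients.
    """
    pts = [(float(v), float(y)) for v, y in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    x = np.array([1.0 / beta2(v) for v, _ in pts])
    y = np.array([yy for _, yy in pts])
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate abscissae: voltages give equal beta^2")
    n = len(pts)
    sxx = np.sum((x - x.mean())**2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean())**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if n > 2:
        s2 = ss_res / (n - 2)
        se_slope = np.sqrt(s2 / sxx)
        se_int = np.sqrt(s2 * (1.0 / n + x.mean()**2 / sxx))
    else:
        se_slope = se_int = 0.0
    return DamageFit(intercept=float(intercept), slope=float(slope),
                     r_square=float(r2), points=pts,
                     slope_stderr=float(se_slope),
                     intercept_stderr=float(se_int))


def ifc(p: IFCParams) -> float:
    """Information coefficient IFC = T * sigma_e / sigma_i."""
    return p.T * p.sigma_e / p.sigma_i
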