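"""Monte-Carlo backscattered-electron (BSE) simulation in a silicon slab.

Single-scattering trajectory model of the kind used by SEM-oriented
simulators: relativistic screened-Rutherford elastic events separated by
exponential free paths, with continuous (CSDA) energy loss between them.

Physics:

* Elastic cross-section: screened Rutherford with Joy's screening
  parameter alpha = 3.4e-3 Z^0.67 / E and the relativistic momentum
  factor; polar angles sampled from the closed-form inverse CDF
  cos(theta) = 1 - 2 alpha R / (1 + alpha - R).
* Stopping power: relativistic Berger–Seltzer collision stopping above
  10 keV, Joy–Luo-modified Bethe below (the two agree to ~2% at the
  seam); mean ionization potential from the Berger–Seltzer formula.
* Termination: an electron is scored backscattered when it re-exits the
  entrance surface, transmitted through the bottom, and absorbed when it
  drops below 0.5 keV, leaves laterally, or its residual CSDA range can
  no longer reach either surface (an exact pruning for these tallies).

Validation anchors (no tuning): stopping power at 100 keV in Si is
0.762 keV/µm vs ESTAR's ≈0.764; the bulk backscatter coefficient at
30 keV is ≈0.156 vs the experimental ≈0.15.

The simulator is vectorised over electrons and fully reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "SlabGeometry",
    "BSEResult",
    "stopping_power",
    "elastic_mean_free_path",
    "screening_parameter",
    "sample_elastic",
    "simulate",
    "exit_radius_quantile",
]

REST_ENERGY_KEV = 510.99895
AVOGADRO = 6.02214076e23
TERMINATION_KEV = 0.5
MIN_ENERGY_KEV = 0.05


@dataclass(frozen=True)
class Material:
    """Target material (defaults describe nothing; use :meth:`silicon`)."""

    Z: float
    A: float            # g/mol
    density: float      # g/cm^3

    def __post_init__(self):
        if self.Z <= 0 or self.A <= 0 or self.density <= 0:
            raise ValueError("material parameters must be positive")

    @classmethod
    def silicon(cls) -> "Material":
        return cls(Z=14.0, A=28.0855, density=2.33)

    @property
    def J_keV(self) -> float:
        """Berger–Seltzer mean ionization potential (keV)."""
        return (9.76 * self.Z + 58.5 * self.Z**-0.19) * 1e-3

    @property
    def atoms_per_cm3(self) -> float:
        return AVOGADRO * self.density / self.A


@dataclass(frozen=True)
class SlabGeometry:
    """A slab of given thickness; electrons enter the centre of the top."""

    thickness_um: float
    lateral_um: float = 1400.0

    def __post_init__(self):
        if self.thickness_um <= 0 or self.lateral_um <= 0:
            raise ValueError("geometry dimensions must be positive")


@dataclass
class BSEResult:
    n_electrons: int
    n_backscattered: int
    n_transmitted: int
    n_absorbed: int
    exit_radii_um: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def coefficient(self) -> float:
        return self.n_backscattered / self.n_electrons

    @property
    def transmission(self) -> float:
        return self.n_transmitted / self.n_electrons


# ---------------------------------------------------------------------------
# Cross-sections and stopping
# ---------------------------------------------------------------------------

def screening_parameter(E_keV, m: Material):
    """Joy screening parameter alpha(E, Z)."""
    return 3.4e-3 * m.Z**0.67 / np.asarray(E_keV, dtype=float)


def elastic_cross_section(E_keV, m: Material):
    """Relativistic screened-Rutherford total elastic cross-section (cm^2)."""
    E = np.asarray(E_keV, dtype=float)
    a = screening_parameter(E, m)
    rel = ((E + REST_ENERGY_KEV) / (E + 2.0 * REST_ENERGY_KEV))**2
    return 5.21e-21 * (m.Z**2 / E**2) * (4.0 * np.pi / (a * (1.0 + a))) * rel


def elastic_mean_free_path(E_keV, m: Material):
    """Elastic mean free path in µm."""
    return 1.0 / (m.atoms_per_cm3 * elastic_cross_section(E_keV, m)) * 1e4


def stopping_power(E_keV, m: Material):
    """Collision stopping power dE/ds in keV/µm.

    Berger–Seltzer relativistic formula for E >= 10 keV; Joy–Luo-modified
    Bethe below.  Raises for energies below 0.05 keV where neither form
    is meaningful.
    """
    E = np.asarray(E_keV, dtype=float)
    if np.any(E <= MIN_ENERGY_KEV):
        raise ValueError(f"energy below {MIN_ENERGY_KEV} keV cutoff")
    J = m.J_keV
    tau = E / REST_ENERGY_KEV
    b2 = 1.0 - 1.0 / (1.0 + tau)**2
    pref = 0.153536 * (m.Z / m.A) * m.density / b2          # MeV/cm
    arg = tau**2 * (tau + 2.0) / 2.0 / (J / REST_ENERGY_KEV)**2
    F = 1.0 - b2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) \
        / (tau + 1.0)**2
    berger = pref * (np.log(np.maximum(arg, 1.0001)) + F) * 0.1  # keV/um
    joy_luo = 78500.0 * m.density * m.Z / (m.A * E) \
        * np.log(np.maximum(1.166 * (E + 0.85 * J) / J, 1.0001)) * 1e-4
    out = np.where(E >= 10.0, berger, joy_luo)
    return out.item() if out.ndim == 0 else out


def _range_table(m: Material, e_max: float = 400.0):
    E = np.geomspace(TERMINATION_KEV, e_max, 800)
    S = stopping_power(E, m)
    R = np.concatenate([[0.0],
                        np.cumsum(0.5 * (1.0 / S[1:] + 1.0 / S[:-1])
                                  * np.diff(E))])
    return E, R


def csda_range(E_keV, m: Material, _cache={}):
    """Residual CSDA range in µm (linear interpolation of a cached table)."""
    key = (m.Z, m.A, m.density)
    if key not in _cache:
        _cache[key] = _range_table(m)
    Eg, Rg = _cache[key]
    return np.interp(E_keV, Eg, Rg)


def sample_elastic(E_keV: float, m: Material, rng: np.random.Generator,
                   size: int | None = None):
    """Sample one (or ``size``) elastic scattering events at energy E.

    Returns ``(theta, phi, s)``: polar scattering angle from the inverse
    CDF of the screened-Rutherford distribution, uniform azimuth, and an
    exponential free path (µm) with mean equal to the elastic mean free
    path.
    """
    a = screening_parameter(E_keV, m)
    n = size or 1
    R = rng.random(n)
    cos_t = 1.0 - 2.0 * a * R / (1.0 + a - R)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = rng.random(n) * 2.0 * np.pi
    s = rng.exponential(elastic_mean_free_path(E_keV, m), n)
    if size is None:
        return theta[0], phi[0], s[0]
    return theta, phi, s


def theta_median(E_keV: float, m: Material) -> float:
    """Closed-form median polar angle of the screened-Rutherford law."""
    a = screening_parameter(E_keV, m)
    return float(np.arccos(1.0 - a / (0.5 + a)))


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def _scatter(d: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit directions ``d`` by polar angle theta and azimuth phi."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    ref = np.where(np.abs(d[:, 2:3]) < 0.9,
                   np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]]))
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    nd = cos_t[:, None] * d + sin_t[:, None] * (
        np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    nd /= np.linalg.norm(nd, axis=1, keepdims=True)
    return nd


def simulate(V: float, geom: SlabGeometry, m: Material | None = None,
             n: int = 10000, seed: int | None = None,
             max_step_fraction: float = 0.2) -> BSEResult:
    """Track ``n`` electrons of energy ``V`` volts through the slab.

    Electrons start at the centre of the top face travelling normal to
    it.  Each is followed through elastic scattering events with
    continuous energy loss until it re-exits the top (backscattered,
    exit radius recorded), exits the bottom (transmitted), or is absorbed
    (energy cutoff, lateral escape, or residual range too short to reach
    any surface).  Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one electron")
    m = m or Material.silicon()
    E0 = V / 1000.0
    rng = np.random.default_rng(seed)
    half = geom.lateral_um / 2.0
    thick = geom.thickness_um
    pos = np.zeros((n, 3))
    d = np.tile([0.0, 0.0, 1.0], (n, 1))
    E = np.full(n, E0)
    alive = np.ones(n, bool)
    n_back = n_trans = 0
    radii: list[float] = []
    while alive.any():
        idx = np.nonzero(alive)[0]
        Ei = E[idx]
        lam = elastic_mean_free_path(Ei, m)
        s = rng.exponential(lam)
        S = stopping_power(Ei, m)
        s = np.minimum(s, max_step_fraction * Ei / S)
        newpos = pos[idx] + d[idx] * s[:, None]
        Enew = np.maximum(Ei - S * s, 1e-3)
        z1 = newpos[:, 2]
        back = z1 < 0.0
        trans = (z1 > thick) & ~back
        lateral = ((np.abs(newpos[:, 0]) > half)
                   | (np.abs(newpos[:, 1]) > half)) & ~back & ~trans
        if back.any():
            jj = np.nonzero(back)[0]
            t = -pos[idx[jj], 2] / d[idx[jj], 2]
            ex = pos[idx[jj], 0] + d[idx[jj], 0] * t
            ey = pos[idx[jj], 1] + d[idx[jj], 1] * t
            radii.extend(np.hypot(ex, ey).tolist())
            n_back += jj.size
        n_trans += int(trans.sum())
        residual = csda_range(Enew, m)
        hopeless = ((residual < np.minimum(z1, thick - z1))
                    | (Enew < TERMINATION_KEV))
        done = back | trans | lateral | hopeless
        keep = idx[~done]
        pos[keep] = newpos[~done]
        E[keep] = Enew[~done]
        alive[idx[done]] = False
        if keep.size:
            a = screening_parameter(E[keep], m)
            R = rng.random(keep.size)
            cos_t = 1.0 - 2.0 * a * R / (1.0 + a - R)
            phi = rng.random(keep.size) * 2.0 * np.pi
            d[keep] = _scatter(d[keep], cos_t, phi)
    n_abs = n - n_back - n_trans
    return BSEResult(n_electrons=n, n_backscattered=n_back,
                     n_transmitted=n_trans, n_absorbed=n_abs,
                     exit_radii_um=np.asarray(radii), seed=seed,
                     meta={"voltage": V, "thickness_um": thick,
                           "material_Z": m.Z})


def exit_radius_quantile(result: BSEResult, q) -> float:
    """Empirical quantile of the backscattered-electron exit radii (µm)."""
    if result.n_backscattered < 1 or result.exit_radii_um.size == 0:
        raise ValueError("no backscattered electrons in this run")
    out = np.quantile(result.exit_radii_um, q)
    return float(out) if np.ndim(out) == 0 else out
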