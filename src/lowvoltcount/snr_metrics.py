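"""Frequency-resolved detector and image quality metrics.

Everything here lives on :class:`RadialCurve`: a quantity sampled on
Fourier shells (rings, for the 2-D desk-scale case).  Frequencies are in
cycles/pixel of the stored grid, so Nyquist is 0.5; when a pixel size is
known the shells can be converted to 1/Å by dividing by it.

Provided metrics:

* ``frc`` — Fourier ring correlation between two images.
* ``fsc_to_snr`` / ``snr_to_fsc`` — Grigorieff's SNR = 2 FSC / (1 - FSC).
* ``nps`` — noise power spectrum of structure-free exposures, normalized
  per pixel so that ideal Poisson counting gives a flat spectrum equal to
  the dose (events/pixel).
* ``knife_edge_mtf`` — slanted-edge MTF: fit the edge line, build an
  oversampled edge-spread function, differentiate, Fourier transform.
* ``dqe`` — detected_fraction * MTF^2 * dose / NPS (ideal counter = 1 at DC).
* ``snr_gain_fit`` — per-shell SNR ratio of two curves with a linear fit
  over a window expressed in fractions of Nyquist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .frames_io import FrameStack

__all__ = [
    "RadialCurve",
    "frc",
    "fsc_to_snr",
    "snr_to_fsc",
    "nps",
    "fit_edge",
    "knife_edge_mtf",
    "dqe",
    "snr_gain_fit",
    "save_curve",
    "load_curve",
]

FSC_CAP = 1.0 - 1e-12   # documented maximum before SNR diverges


@dataclass
class RadialCurve:
    """A function of spatial frequency sampled on shells.

    ``shells`` are strictly increasing frequencies (cycles/pixel unless
    stated otherwise), ``values`` the per-shell quantity and ``n_terms``
    the number of Fourier samples averaged in each shell.
    """

    shells: np.ndarray
    values: np.ndarray
    n_terms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.shells = np.asarray(self.shells, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.shells.shape != self.values.shape:
            raise ValueError("shells and values must have the same shape")
        if np.any(np.diff(self.shells) <= 0):
            raise ValueError("shells must be strictly increasing")
        if self.n_terms is None:
            self.n_terms = np.ones_like(self.shells, dtype=int)
        else:
            self.n_terms = np.asarray(self.n_terms, dtype=int)

    def __len__(self):
        return self.shells.size

    def interp(self, u) -> np.ndarray:
        """Linear interpolation (end values extended beyond the range)."""
        return np.interp(u, self.shells, self.values)

    def threshold_crossing(self, level: float) -> float:
        """First frequency at which the curve falls below ``level``.

        Convenience for FSC = 0.143 / 0.5 resolution readouts.  Returns
        the last shell frequency if the curve never crosses.
        """
        below = np.nonzero(self.values < level)[0]
        if below.size == 0:
            return float(self.shells[-1])
        i = below[0]
        if i == 0:
            return float(self.shells[0])
        u0, u1 = self.shells[i - 1], self.shells[i]
        v0, v1 = self.values[i - 1], self.values[i]
        if v0 == v1:
            return float(u1)
        return float(u0 + (v0 - level) * (u1 - u0) / (v0 - v1))

    def scaled(self, factor) -> "RadialCurve":
        return RadialCurve(self.shells.copy(), self.values * factor,
                           self.n_terms.copy(), dict(self.meta))


def save_curve(curve: RadialCurve, path) -> None:
    """Serialize a RadialCurve as JSON (shells/values/n_terms/meta)."""
    import json
    with open(path, "w") as fh:
        json.dump({"shells": curve.shells.tolist(),
                   "values": curve.values.tolist(),
                   "n_terms": curve.n_terms.tolist(),
                   "meta": curve.meta}, fh, indent=1)


def load_curve(path) -> RadialCurve:
    import json
    with open(path) as fh:
        d = json.load(fh)
    return RadialCurve(np.asarray(d["shells"]), np.asarray(d["values"]),
                       np.asarray(d.get("n_terms")) if d.get("n_terms")
                       else None, d.get("meta", {}))


def _check_same_shells(a: RadialCurve, b: RadialCurve) -> None:
    if len(a) != len(b) or not np.allclose(a.shells, b.shells):
        raise ValueError("curves are sampled on different shells")


def _shell_index(shape: tuple[int, int], shell_width: float | None):
    """Radial Fourier binning for a 2-D grid.

    Returns (bin index per Fourier sample, shell centre frequencies).
    Shell 0 (DC) is excluded from the returned shells.
    """
    ny, nx = shape
    n = min(ny, nx)
    w = shell_width if shell_width else 1.0 / n
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    r = np.hypot(fy, fx)
    k = np.rint(r / w).astype(int)
    kmax = int(np.floor(0.5 / w + 1e-9))
    k[k > kmax] = -1          # beyond Nyquist: ignored
    shells = np.arange(1, kmax + 1) * w
    return k, shells


def _radial_mean(power: np.ndarray, k: np.ndarray, nshell: int):
    flat_k = k.ravel() + 1                       # shift: -1 -> 0 (discard bin)
    sums = np.bincount(flat_k, weights=power.ravel(), minlength=nshell + 2)
    counts = np.bincount(flat_k, minlength=nshell + 2)
    return sums[2:nshell + 2], counts[2:nshell + 2]   # drop discard + DC bins


def frc(a: np.ndarray, b: np.ndarray,
        shell_width: float | None = None) -> RadialCurve:
    """Fourier ring correlation between two equally sized images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    k, shells = _shell_index(a.shape, shell_width)
    ns = shells.size
    num, n_terms = _radial_mean((fa * np.conj(fb)).real, k, ns)
    pa, _ = _radial_mean(np.abs(fa)**2, k, ns)
    pb, _ = _radial_mean(np.abs(fb)**2, k, ns)
    denom = np.sqrt(pa * pb)
    vals = np.zeros(ns)
    ok = denom > 0
    if not np.all(ok):
        warnings.warn("zero-power shell(s) in FRC set to 0")
    vals[ok] = num[ok] / denom[ok]
    return RadialCurve(shells, vals, n_terms)


def fsc_to_snr(fsc):
    """Grigorieff's conversion SNR = 2 FSC / (1 - FSC).

    Accepts a scalar, array or RadialCurve.  FSC equal to 1 (infinite
    SNR) raises; values above :data:`FSC_CAP` are capped there.
    """
    if isinstance(fsc, RadialCurve):
        return RadialCurve(fsc.shells.copy(), fsc_to_snr(fsc.values),
                           fsc.n_terms.copy(), dict(fsc.meta))
    arr = np.asarray(fsc, dtype=float)
    if np.any(arr == 1.0):
        raise ValueError("FSC = 1 corresponds to infinite SNR")
    capped = np.minimum(arr, FSC_CAP)
    out = 2.0 * capped / (1.0 - capped)
    return out.item() if np.isscalar(fsc) or arr.ndim == 0 else out


def snr_to_fsc(snr):
    """Inverse conversion FSC = SNR / (2 + SNR)."""
    if isinstance(snr, RadialCurve):
        return RadialCurve(snr.shells.copy(), snr_to_fsc(snr.values),
                           snr.n_terms.copy(), dict(snr.meta))
    arr = np.asarray(snr, dtype=float)
    out = arr / (2.0 + arr)
    return out.item() if np.isscalar(snr) or arr.ndim == 0 else out


def nps(realizations, shell_width: float | None = None) -> RadialCurve:
    """Noise power spectrum of statistically flat realizations.

    Each realization is mean-subtracted; its periodogram ``|F|^2 / Npix``
    is radially averaged and the result averaged over realizations.  With
    this normalization, ideal Poisson point counting at dose d
    (events/pixel) has a white NPS equal to d.
    """
    if isinstance(realizations, FrameStack):
        frames = list(realizations.frames)
    elif isinstance(realizations, np.ndarray) and realizations.ndim == 2:
        frames = [realizations]
    else:
        frames = [np.asarray(f, dtype=float) for f in realizations]
    if len(frames) == 0:
        raise ValueError("need at least one realization")
    shape = frames[0].shape
    if len(frames) == 1:
        f = frames[0]
        by = f.shape[0] // 4 or 1
        bx = f.shape[1] // 4 or 1
        blocks = f[:4 * by, :4 * bx].reshape(4, by, 4, bx).mean(axis=(1, 3))
        m = np.abs(f).mean()
        if m > 0 and blocks.std() / m > 0.1:
            warnings.warn("single realization does not look flat; "
                          "NPS may contain structure")
    k, shells = _shell_index(shape, shell_width)
    ns = shells.size
    acc = np.zeros(ns)
    n_terms = None
    npix = shape[0] * shape[1]
    for f in frames:
        if f.shape != shape:
            raise ValueError("realizations must share dimensions")
        g = f - f.mean()
        power = np.abs(np.fft.fft2(g))**2 / npix
        s, cnt = _radial_mean(power, k, ns)
        acc += np.divide(s, cnt, out=np.zeros(ns), where=cnt > 0)
        n_terms = cnt
    return RadialCurve(shells, acc / len(frames), n_terms)


# ---------------------------------------------------------------------------
# Slanted knife-edge MTF
# ---------------------------------------------------------------------------

class EdgeFitError(Exception):
    """The straight-edge fit failed (image has no usable slanted edge)."""


def fit_edge(image: np.ndarray, r2_threshold: float = 0.2):
    """Fit the (near-vertical, slightly tilted) edge line of an edge image.

    Returns ``(angle_deg, x0, slope, r_squared)`` where the edge is
    ``x = x0 + slope * y`` and ``angle_deg`` is its tilt from vertical.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    lo = np.median(img[:, :max(2, nx // 8)])
    hi = np.median(img[:, -max(2, nx // 8):])
    if hi < lo:                      # bright side on the left
        img = img[:, ::-1]
        flipped = True
        lo, hi = np.median(img[:, :max(2, nx // 8)]), np.median(img[:, -max(2, nx // 8):])
    else:
        flipped = False
    # per-row edge estimate: centroid of the (positive) row gradient of a
    # lightly smoothed profile — robust to counting noise, sub-pixel exact
    # for a symmetric edge-spread function
    from scipy import ndimage as _ndi
    thr = 0.5 * (lo + hi)
    span = hi - lo
    coarse = _ndi.gaussian_filter1d(img, 5.0, axis=1, mode="nearest")
    sm = _ndi.gaussian_filter1d(img, 1.5, axis=1, mode="nearest")
    grad = np.diff(sm, axis=1)
    centres = np.arange(grad.shape[1]) + 0.5
    ys, xs = [], []
    for y in range(ny):
        above = np.nonzero(coarse[y] > thr)[0]
        if above.size == 0 or above[0] == 0:
            continue
        x_coarse = above[0]
        w0 = max(0, x_coarse - 8)
        w1 = min(grad.shape[1], x_coarse + 8)
        g = np.maximum(grad[y, w0:w1], 0.0)**2
        tot = g.sum()
        if tot <= 0 or span <= 0:
            continue
        ys.append(y)
        xs.append(float((g * centres[w0:w1]).sum() / tot))
    if len(ys) < 3:
        raise EdgeFitError("too few usable rows for the edge fit")
    ys = np.asarray(ys, dtype=float)
    xs = np.asarray(xs, dtype=float)
    slope, x0 = np.polyfit(ys, xs, 1)
    pred = x0 + slope * ys
    ss_res = np.sum((xs - pred)**2)
    ss_tot = np.sum((xs - xs.mean())**2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < r2_threshold:
        raise EdgeFitError(
            f"edge line fit R^2 = {r2:.3f} < {r2_threshold} "
            "(the slanted-edge method needs a tilted edge)")
    if flipped:
        x0 = (nx - 1) - x0
        slope = -slope
    angle = np.degrees(np.arctan(abs(slope)))
    return angle, x0, slope, r2


def knife_edge_mtf(edge_stack, oversample: int = 4,
                   max_distance: float = 12.0,
                   r2_threshold: float = 0.2,
                   n_freq: int = 33) -> RadialCurve:
    """Slanted-edge MTF of a knife-edge exposure.

    The frames are summed, the edge line fitted, pixels binned by signed
    distance to the edge into an ESF oversampled ``oversample``-fold, the
    ESF differentiated into an LSF, and the LSF Fourier-transformed.  The
    finite-difference and binning transfer functions (a sinc each) are
    divided out; the curve is normalized to 1 at zero frequency.
    """
    if isinstance(edge_stack, FrameStack):
        img = edge_stack.frames.sum(axis=0)
    else:
        img = np.asarray(edge_stack, dtype=float)
    ny, nx = img.shape
    angle, x0, slope, r2 = fit_edge(img, r2_threshold)
    yy, xx = np.mgrid[0:ny, 0:nx]
    # signed perpendicular distance to the fitted line
    d = (xx - (x0 + slope * yy)) / np.hypot(1.0, slope)
    delta = 1.0 / oversample
    edges = np.arange(-max_distance, max_distance + delta, delta)
    centres = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(d.ravel(), edges) - 1
    ok = (which >= 0) & (which < centres.size)
    sums = np.bincount(which[ok], weights=img.ravel()[ok],
                       minlength=centres.size)
    cnts = np.bincount(which[ok], minlength=centres.size)
    esf = np.divide(sums, cnts, out=np.zeros_like(sums), where=cnts > 0)
    missing = cnts == 0
    if np.any(missing):
        esf[missing] = np.interp(centres[missing], centres[~missing],
                                 esf[~missing])
    lsf = np.diff(esf) / delta
    pos = centres[:-1] + 0.5 * delta
    total = lsf.sum() * delta
    if total == 0:
        raise EdgeFitError("degenerate edge: flat ESF")
    shells = np.linspace(0, 0.5, n_freq)[1:]
    resp = np.abs(np.exp(-2j * np.pi * pos[None, :] * shells[:, None])
                  @ lsf * delta) / abs(total)
    corr = np.sinc(shells * delta)**2     # binning box + finite difference
    vals = resp / corr
    curve = RadialCurve(shells, vals,
                        np.full(shells.shape, cnts.sum(), dtype=int))
    curve.meta.update(edge_angle_deg=angle, r_squared=r2)
    return curve


def dqe(mtf: RadialCurve, nps_curve: RadialCurve, counted_dose: float,
        detected_fraction: float = 1.0) -> RadialCurve:
    """DQE(u) = detected_fraction * MTF(u)^2 * dose / NPS(u).

    ``counted_dose`` is in events/pixel of the grid the NPS was measured
    on.  With the per-pixel NPS normalization used here an ideal counter
    (every electron detected at its true position) gives DQE(0) = 1, so
    the normalization constant is 1 and is recorded in ``meta``.
    """
    _check_same_shells(mtf, nps_curve)
    if np.any(nps_curve.values <= 0):
        raise ValueError("NPS must be positive at every shell")
    vals = detected_fraction * mtf.values**2 * counted_dose / nps_curve.values
    out = RadialCurve(mtf.shells.copy(), vals, nps_curve.n_terms.copy())
    out.meta["normalization"] = 1.0
    return out


def snr_gain_fit(curve_a: RadialCurve, curve_b: RadialCurve,
                 fit_lo: float = 0.30, fit_hi: float = 0.80,
                 from_fsc: bool = False, nyquist: float = 0.5):
    """Per-shell SNR ratio a/b with a linear fit over a Nyquist window.

    ``fit_lo``/``fit_hi`` are fractions of ``nyquist``; ``fit_hi`` may
    exceed 1 only for super-resolution grids whose shells extend past the
    native Nyquist.  Returns ``(ratio_at_half_nyquist, ratio_at_nyquist,
    slope, intercept)`` where slope is per unit Nyquist fraction.
    """
    _check_same_shells(curve_a, curve_b)
    a = fsc_to_snr(curve_a.values) if from_fsc else curve_a.values
    b = fsc_to_snr(curve_b.values) if from_fsc else curve_b.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b != 0, a / b, np.nan)
    frac = curve_a.shells / nyquist
    sel = (frac >= fit_lo) & (frac <= fit_hi) & np.isfinite(ratio)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 shells inside the fit window")
    slope, intercept = np.polyfit(frac[sel], ratio[sel], 1)
    return (intercept + slope * 0.5, intercept + slope * 1.0,
            slope, intercept)
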