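"""Single-electron event detection in raw DDD frames.

An incident electron stimulates a small group of neighbouring pixels —
a *cluster*.  Detection follows the classic blob-detection recipe:

1. convolve the raw frame with a negated Laplacian-of-Gaussian kernel
   (zero-sum, positive centre), which responds to pixel-scale bumps;
2. estimate the noise level of the convolved frame robustly
   (median absolute deviation x 1.4826);
3. threshold at ``threshold_k`` times that noise level;
4. group marked pixels into connected components (4- or 8-connectivity);
5. each component becomes a :class:`Cluster` carrying the *raw* pixel
   values minus the raw-frame median (floored at a small positive value
   so that negative pattern exponents stay finite).

Clusters touching the frame border are discarded: their truncated charge
biases every position estimator.

Size taxonomy: 1–2 pixels are 'small', 3–4 'medium', >= 5 'large'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames_io import FrameStack

__all__ = [
    "Cluster",
    "DetectionParams",
    "log_kernel",
    "detect_events",
    "detect_stack",
    "classify_cluster",
    "split_by_class",
]

VALUE_FLOOR = 1e-6


@dataclass
class Cluster:
    """One single-electron event candidate.

    ``pixels`` is an (k, 2) integer array of (x, y) coordinates and
    ``values`` the matching background-subtracted detector counts (> 0).
    """

    pixels: np.ndarray
    values: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.pixels.shape[0] != self.values.shape[0]:
            raise ValueError("pixels and values length mismatch")
        if self.pixels.shape[0] < 1:
            raise ValueError("cluster must contain at least one pixel")
        if np.any(self.values <= 0):
            raise ValueError("cluster values must be positive")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def size_class(self) -> str:
        return classify_cluster(self)


@dataclass
class DetectionParams:
    """Kernel and threshold configuration for :func:`detect_events`."""

    kernel_sigma: float = 0.8
    kernel_radius: int = 1
    threshold_k: float = 4.0
    connectivity: int = 8

    def __post_init__(self):
        if self.kernel_radius < 1:
            raise ValueError("kernel_radius must be >= 1")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def log_kernel(sigma: float = 0.8, radius: int = 1) -> np.ndarray:
    """Negated Laplacian-of-Gaussian kernel, normalized to zero sum.

    Sampled at integer offsets on a (2*radius+1)^2 grid; the centre value
    is positive so the kernel responds positively to bright blobs.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    # -LoG up to a positive scale: (2*sigma^2 - r^2) * exp(-r^2 / 2 sigma^2)
    k = (2.0 * sigma**2 - r2) * np.exp(-r2 / (2.0 * sigma**2))
    k -= k.mean()          # zero net response to constant background
    return k


def _structure(connectivity: int) -> np.ndarray:
    return (np.ones((3, 3), dtype=int) if connectivity == 8
            else ndimage.generate_binary_structure(2, 1))


def detect_events(frame: np.ndarray, params: DetectionParams | None = None,
                  frame_index: int = 0) -> list[Cluster]:
    """Find clusters in one raw frame.

    Returns the clusters not touching the frame border.  An all-constant
    frame yields an empty list (the noise estimate is floored, never zero).
    """
    params = params or DetectionParams()
    frame = np.asarray(frame, dtype=float)
    kern = log_kernel(params.kernel_sigma, params.kernel_radius)
    if min(frame.shape) < kern.shape[0]:
        raise ValueError("frame smaller than the kernel")
    conv = ndimage.convolve(frame, kern, mode="mirror")
    med = np.median(conv)
    mad = np.median(np.abs(conv - med))
    sigma = max(mad * 1.4826, 1e-12 * max(1.0, abs(med)), 1e-300)
    mask = conv - med > params.threshold_k * sigma
    labels, n = ndimage.label(mask, structure=_structure(params.connectivity))
    if n == 0:
        return []
    raw_med = np.median(frame)
    ny, nx = frame.shape
    clusters = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        ys, xs = np.nonzero(labels[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        if (xs.min() == 0 or ys.min() == 0 or
                xs.max() == nx - 1 or ys.max() == ny - 1):
            continue  # border cluster: truncated charge
        vals = np.maximum(frame[ys, xs] - raw_med, VALUE_FLOOR)
        clusters.append(Cluster(pixels=np.column_stack([xs, ys]),
                                values=vals, frame_index=frame_index))
    return clusters


def detect_stack(stack: FrameStack,
                 params: DetectionParams | None = None) -> list[Cluster]:
    """Detect clusters in every frame of a stack (frame_index recorded)."""
    out = []
    for i, frame in enumerate(stack):
        out.extend(detect_events(frame, params, frame_index=i))
    return out


def classify_cluster(cluster: Cluster) -> str:
    """'small' (1–2 px), 'medium' (3–4 px) or 'large' (>= 5 px)."""
    n = cluster.size
    if n <= 2:
        return "small"
    if n <= 4:
        return "medium"
    return "large"


def split_by_class(clusters: list[Cluster],
                   subsample_per_class: int | None = None,
                   seed: int | None = None,
                   ) -> tuple[list[Cluster], list[Cluster], list[Cluster]]:
    """Partition clusters into (small, medium, large) lists.

    With ``subsample_per_class`` set, each list is an equal-size random
    selection without replacement (seeded), mirroring the equal-count
    sub-images used when comparing per-class counting quality.
    """
    groups = {"small": [], "medium": [], "large": []}
    for c in clusters:
        groups[classify_cluster(c)].append(c)
    if subsample_per_class is None:
        return groups["small"], groups["medium"], groups["large"]
    rng = np.random.default_rng(seed)
    out = []
    for name in ("small", "medium", "large"):
        g = groups[name]
        if len(g) < subsample_per_class:
            raise ValueError(
                f"class {name!r} has only {len(g)} clusters, "
                f"need {subsample_per_class}")
        idx = rng.choice(len(g), size=subsample_per_class, replace=False)
        out.append([g[i] for i in sorted(idx)])
    return tuple(out)
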