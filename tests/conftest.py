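import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cluster(pixel_values, frame_index=0):
    """Build a Cluster from a {(x, y): value} dict."""
    from lowvoltcount.cluster_detect import Cluster
    pixels = np.array(list(pixel_values.keys()), dtype=int)
    values = np.array(list(pixel_values.values()), dtype=float)
    return Cluster(pixels=pixels, values=values, frame_index=frame_index)


def probe_specimen(dims, probes=((0.10, 10), (0.25, 70), (0.42, 160)),
                   amplitude=0.15, base=0.5):
    """Cosine probe-grating intensity map (a synthetic 'specimen')."""
    yy, xx = np.mgrid[0:dims, 0:dims]
    lam = np.full((dims, dims), float(base))
    for u, adeg in probes:
        a = np.radians(adeg)
        lam += amplitude * np.cos(2 * np.pi * u * (xx * np.cos(a)
                                                   + yy * np.sin(a)))
    return np.clip(lam, 0, 1)


def shell_at(curve, u):
    """Value of the shell closest to frequency u."""
    return float(curve.values[int(np.argmin(np.abs(curve.shells - u)))])
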