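"""Frame-stack and event-stream I/O.

Movie stacks from a direct detection device (DDD) are stored as MRC/MRCS
volumes.  A minimal MRC2014 codec is included (modes 0, 1, 2 and 6,
little-endian); it round-trips pixel data bit-exactly and reads the pixel
size from the ``cella``/``mx`` header words.

Counted electrons are stored in a bespoke, versioned, line-based text
format (``.evt``).  Only the *semantics* of an event-based representation
are kept: frame index, continuous position, size class, a single
weight-flag bit, and an optional normalized pattern.

Coordinate convention (used package-wide): pixel indices are 0-based,
``(x, y)`` with ``x`` the column and ``y`` the row, and a pixel's centre
sits at integer coordinates.  Arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FormatError",
    "FrameStack",
    "EventRecord",
    "EventStream",
    "read_stack",
    "write_stack",
    "sum_frames",
    "read_events",
    "write_events",
]

SIZE_CLASSES = ("small", "medium", "large")

_EVT_MAGIC = "#EVT"
_EVT_VERSION = 1

# MRC2014 mode -> dtype (little-endian)
_MRC_DTYPES = {0: "<i1", 1: "<i2", 2: "<f4", 6: "<u2"}
_MRC_MODES = {np.dtype(v): k for k, v in _MRC_DTYPES.items()}


class FormatError(Exception):
    """Raised for malformed files or version mismatches."""


@dataclass
class FrameStack:
    """An ordered stack of equally sized 2-D detector frames.

    Parameters
    ----------
    frames : ndarray, shape (n, ny, nx)
        Pixel data in detector counts (arbitrary units).
    pixel_size : float
        Length per pixel; the unit (Å or µm) is the caller's declaration.
    voltage : float or None
        Acceleration voltage in volts, optional metadata.
    """

    frames: np.ndarray
    pixel_size: float = 1.0
    voltage: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, ny, nx) array")
        if self.frames.shape[0] < 1 or 0 in self.frames.shape:
            raise ValueError("frame stack must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("pixel values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __iter__(self):
        return iter(self.frames)


@dataclass
class EventRecord:
    """One counted electron.

    ``pattern``, if present, maps integer pixel offsets ``(dx, dy)``
    (relative to the nearest integer pixel to ``position``) to
    non-negative weights summing to 1.
    """

    frame_index: int
    x: float
    y: float
    size_class: str
    weight_flag: bool = False
    pattern: dict[tuple[int, int], float] | None = None

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.pattern is not None:
            total = sum(self.pattern.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("pattern values must sum to 1 within 1e-9")
            if any(v < 0 for v in self.pattern.values()):
                raise ValueError("pattern values must be non-negative")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class EventStream:
    """Ordered counted-electron records plus detector metadata."""

    records: list[EventRecord]
    nx: int
    ny: int
    sr_factor: int = 1
    method: str = ""
    voltage: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("detector dims must be positive")
        idx = [r.frame_index for r in self.records]
        if any(b < a for a, b in zip(idx, idx[1:])):
            self.records = sorted(self.records, key=lambda r: r.frame_index)

    def __len__(self) -> int:
        return len(self.records)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions."""
        return np.array([[r.x, r.y] for r in self.records], dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# MRC / MRCS
# ---------------------------------------------------------------------------

def _pack_header(nz: int, ny: int, nx: int, mode: int, pixel_size: float,
                 dmin: float, dmax: float, dmean: float, rms: float) -> bytes:
    h = bytearray(1024)
    struct.pack_into("<10i", h, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", h, 40,
                     nx * pixel_size, ny * pixel_size, nz * pixel_size,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, 1, 2, 3)
    struct.pack_into("<3f", h, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", h, 88, 0, 0)          # ispg, nsymbt
    struct.pack_into("<3f", h, 196, 0.0, 0.0, 0.0)  # origin
    h[208:212] = b"MAP "
    h[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", h, 216, rms)
    struct.pack_into("<i", h, 220, 1)
    h[224:224 + 80] = b"lowvoltcount".ljust(80)
    return bytes(h)


def write_stack(stack: FrameStack, path) -> None:
    """Write a FrameStack as an MRCS file (mode chosen from dtype)."""
    data = stack.frames
    kind = data.dtype.kind
    if kind in "ui":
        if data.min() >= np.iinfo("<i2").min and data.max() <= np.iinfo("<i2").max:
            out = data.astype("<i2")
        else:
            out = data.astype("<f4")
    else:
        out = data.astype("<f4")
    mode = _MRC_MODES[out.dtype]
    header = _pack_header(out.shape[0], out.shape[1], out.shape[2], mode,
                          stack.pixel_size,
                          float(out.min()), float(out.max()), float(out.mean()),
                          float(out.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(out).tobytes())


def read_stack(path, gain: np.ndarray | None = None) -> FrameStack:
    """Read an MRC/MRCS file into a FrameStack.

    Parameters
    ----------
    gain : ndarray, optional
        Multiplicative per-pixel gain map applied on read.  Default is
        identity (no gain correction).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: file shorter than an MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: missing MRC2014 'MAP ' magic")
    if mode not in _MRC_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise ValueError(f"{path}: empty stack (nx={nx}, ny={ny}, nz={nz})")
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    dtype = np.dtype(_MRC_DTYPES[mode])
    need = 1024 + nsymbt + nx * ny * nz * dtype.itemsize
    if len(raw) < need:
        raise FormatError(
            f"{path}: header promises {need} bytes, file has {len(raw)}")
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz,
                         offset=1024 + nsymbt).reshape(nz, ny, nx).copy()
    cella_x = struct.unpack_from("<f", raw, 40)[0]
    mx = struct.unpack_from("<i", raw, 28)[0]
    if cella_x > 0 and mx > 0:
        pixel_size = cella_x / mx
    else:
        warnings.warn(f"{path}: no pixel size in header, assuming 1.0")
        pixel_size = 1.0
    if gain is not None:
        gain = np.asarray(gain, dtype=float)
        if gain.shape != (ny, nx):
            raise ValueError("gain map shape does not match frames")
        data = data.astype(np.float32) * gain[None]
    return FrameStack(frames=data, pixel_size=pixel_size)


def write_image(array: np.ndarray, path, pixel_size: float = 1.0) -> None:
    """Write a single 2-D image (e.g. a counted image) as MRC mode 2."""
    write_stack(FrameStack(np.asarray(array, dtype=np.float32)[None],
                           pixel_size=pixel_size), path)


# ---------------------------------------------------------------------------
# Frame summing
# ---------------------------------------------------------------------------

def sum_frames(stack: FrameStack, p: int) -> FrameStack:
    """Sum every ``p`` consecutive frames (the counting programmes' ``-p``).

    Returns ceil(N/p) frames; the last group may be shorter.  The total of
    all pixel values is conserved.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if p == 1:
        return FrameStack(stack.frames.copy(), stack.pixel_size, stack.voltage)
    n = stack.n_frames
    groups = [stack.frames[i:i + p].sum(axis=0) for i in range(0, n, p)]
    # integer input stays integer (exact conservation)
    out = np.stack(groups)
    return FrameStack(out, stack.pixel_size, stack.voltage)


# ---------------------------------------------------------------------------
# Event streams (.evt, versioned line-based text)
# ---------------------------------------------------------------------------
#
# Format (documented, fixed):
#   line 1 : "#EVT 1"
#   line 2 : "#HEADER <json>"  with keys nx, ny, sr_factor, method, voltage, extra
#   then one line per record:
#   "<frame_index> <x> <y> <size_class> <0|1>[ <dx>:<dy>:<value> ...]"
# Floats are written with repr precision; the round trip is lossless.

def write_events(stream: EventStream, path) -> None:
    header = {"nx": stream.nx, "ny": stream.ny, "sr_factor": stream.sr_factor,
              "method": stream.method, "voltage": stream.voltage,
              "extra": stream.extra}
    with open(path, "w") as fh:
        fh.write(f"{_EVT_MAGIC} {_EVT_VERSION}\n")
        fh.write(f"#HEADER {json.dumps(header)}\n")
        for r in stream.records:
            parts = [str(r.frame_index), repr(r.x), repr(r.y),
                     r.size_class, "1" if r.weight_flag else "0"]
            if r.pattern is not None:
                parts += [f"{dx}:{dy}:{v!r}" for (dx, dy), v in
                          sorted(r.pattern.items())]
            fh.write(" ".join(parts) + "\n")


def read_events(path) -> EventStream:
    with open(path) as fh:
        magic = fh.readline().split()
        if len(magic) != 2 or magic[0] != _EVT_MAGIC:
            raise FormatError(f"{path}: not an .evt file")
        if int(magic[1]) != _EVT_VERSION:
            raise FormatError(
                f"{path}: .evt version {magic[1]} != supported {_EVT_VERSION}")
        hline = fh.readline()
        if not hline.startswith("#HEADER "):
            raise FormatError(f"{path}: missing #HEADER line")
        header = json.loads(hline[len("#HEADER "):])
        records = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            pattern = None
            if len(parts) > 5:
                pattern = {}
                for tok in parts[5:]:
                    dx, dy, v = tok.split(":")
                    pattern[(int(dx), int(dy))] = float(v)
            records.append(EventRecord(
                frame_index=int(parts[0]), x=float(parts[1]), y=float(parts[2]),
                size_class=parts[3], weight_flag=parts[4] == "1",
                pattern=pattern))
    return EventStream(records=records, nx=header["nx"], ny=header["ny"],
                       sr_factor=header["sr_factor"], method=header["method"],
                       voltage=header["voltage"], extra=header.get("extra", {}))
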