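"""I/O and geometry for 5x5 SPAD-array photon-counting traces.

The detector is a 5x5 single-photon avalanche diode (SPAD) array read out as
25 parallel photon-count time traces with a fixed bin width (500 ns by
default).  Pixels are numbered row-major from 0 (top left) to 24 (bottom
right); pixel 12 is the central element, aligned with the optical axis.  One
pixel unit corresponds to a lateral shift of the detection volume in sample
space of 75 nm at the magnification used here.

Three on-disk dialects are supported:

``packed``
    The ``spadffs-packed-v1`` dialect: one 16-byte (128-bit) record per time
    bin, with more bits allocated to pixels near the centre of the array
    (8 bits for the central pixel, 6 bits for its 8 nearest neighbours,
    4 bits for the 16 outer pixels, 8 zero padding bits).  Counts that
    exceed a field saturate at the field maximum.  This mirrors the
    fixed-width real-time stream of the acquisition hardware; at a 0.5 us
    bin width the stream rate is 16 B / 0.5 us = 30.5 MiB/s.
``plain``
    Little-endian unsigned 16-bit integers, pixel-major within each bin
    (lossless).
``text``
    Comma-delimited text, one bin per row, 25 columns (lossless).

A sidecar metadata file (``<path>.meta``, ``key=value`` lines) carries the
bin width, excluded pixels and free-form acquisition metadata.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidInputError

N_PIXELS = 25
_RECORD_BYTES = 16

# Field widths of the spadffs-packed-v1 dialect, indexed by pixel.
_RING1 = frozenset({6, 7, 8, 11, 13, 16, 17, 18})
_FIELD_WIDTHS = tuple(
    8 if i == 12 else (6 if i in _RING1 else 4) for i in range(N_PIXELS)
)
_FIELD_OFFSETS = tuple(
    sum(_FIELD_WIDTHS[:i]) for i in range(N_PIXELS)
)  # bit offset from the MSB of the 128-bit block
_FIELD_MAX = tuple((1 << w) - 1 for w in _FIELD_WIDTHS)
assert sum(_FIELD_WIDTHS) == 120  # + 8 padding bits = 128


@dataclass(frozen=True)
class PixelGrid:
    """Static geometry of the 5x5 SPAD detector.

    ``pixel_offsets[i]`` is the integer ``(dx, dy)`` position of pixel *i*
    relative to the central pixel, in pixel units; ``pitch_sample`` converts
    one pixel unit into a lateral shift of the detection volume in sample
    space (micrometres).
    """

    n_side: int = 5
    center_index: int = 12
    pitch_sample: float = 0.075  # um in sample space per pixel unit

    @property
    def n_pixels(self) -> int:
        return self.n_side * self.n_side

    @property
    def pixel_offsets(self) -> np.ndarray:
        """Integer ``(dx, dy)`` offsets from the centre, row-major, shape (25, 2)."""
        half = self.n_side // 2
        idx = np.arange(self.n_pixels)
        dx = idx % self.n_side - half
        dy = idx // self.n_side - half
        return np.stack([dx, dy], axis=1)

    @property
    def rho(self) -> np.ndarray:
        """Euclidean distance of each pixel from the centre, in pixel units."""
        off = self.pixel_offsets
        return np.hypot(off[:, 0], off[:, 1])


@dataclass
class IntensityTrace:
    """Per-pixel photon counts per time bin plus acquisition metadata.

    ``counts`` has shape ``(n_bins, 25)``; pixels listed in
    ``excluded_pixels`` (the hot pixel 1 by default) are retained in storage
    but skipped by analysis functions unless explicitly included.
    """

    counts: np.ndarray
    bin_width: float = 5e-7  # s
    excluded_pixels: frozenset[int] = frozenset({1})
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_PIXELS:
            raise InvalidInputError(
                f"counts must have shape (n_bins, {N_PIXELS}); got {self.counts.shape}"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if np.any(self.counts < 0) or np.any(self.counts != np.floor(self.counts)):
                raise InvalidInputError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        elif np.issubdtype(self.counts.dtype, np.signedinteger):
            if self.counts.size and int(self.counts.min()) < 0:
                raise InvalidInputError("counts must be non-negative")
        if self.bin_width <= 0:
            raise InvalidInputError("bin_width must be positive")
        self.excluded_pixels = frozenset(int(i) for i in self.excluded_pixels)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def active_pixels(self, include_excluded: bool = False) -> np.ndarray:
        """Indices of pixels that analysis should use."""
        if include_excluded:
            return np.arange(N_PIXELS)
        return np.array(
            [i for i in range(N_PIXELS) if i not in self.excluded_pixels], dtype=int
        )


@dataclass
class FingerprintMap:
    """Time-averaged photon count rate (PCR) image of the detection volume.

    ``percent_of_center`` is each pixel's mean PCR as a percentage of the
    central pixel's; it is NaN (with ``valid=False``) when the centre
    recorded no photons.
    """

    mean_pcr: np.ndarray  # Hz, shape (25,)
    percent_of_center: np.ndarray  # %, shape (25,)
    valid: bool = True


# ---------------------------------------------------------------------------
# 128-bit record packing (spadffs-packed-v1)
# ---------------------------------------------------------------------------

def pack_frame(counts25) -> bytes:
    """Pack 25 per-pixel counts of one time bin into a 16-byte record.

    Counts exceeding their field width saturate at the field maximum
    (255 / 63 / 15 depending on the pixel).  Negative counts are rejected.
    """
    c = np.asarray(counts25)
    if c.shape != (N_PIXELS,):
        raise InvalidInputError(f"expected {N_PIXELS} counts, got shape {c.shape}")
    if np.any(c < 0):
        raise InvalidInputError("counts must be non-negative")
    block = 0
    for i in range(N_PIXELS):
        v = min(int(c[i]), _FIELD_MAX[i])
        block = (block << _FIELD_WIDTHS[i]) | v
    block <<= 8  # padding
    return block.to_bytes(_RECORD_BYTES, "big")


def unpack_frame(block: bytes) -> np.ndarray:
    """Inverse of :func:`pack_frame` on its image (exact for in-range counts)."""
    if len(block) != _RECORD_BYTES:
        raise FormatError(
            f"packed record must be {_RECORD_BYTES} bytes, got {len(block)}"
        )
    v = int.from_bytes(block, "big") >> 8
    out = np.empty(N_PIXELS, dtype=np.int64)
    for i in range(N_PIXELS - 1, -1, -1):
        out[i] = v & _FIELD_MAX[i]
        v >>= _FIELD_WIDTHS[i]
    return out


def _pack_array(counts: np.ndarray) -> tuple[bytes, int]:
    """Vectorised packing of an (n_bins, 25) array; returns (bytes, n_clipped).

    No field of the v1 layout straddles the 64-bit boundary, so each record
    is assembled as two big-endian 64-bit words.
    """
    c = counts.astype(np.uint64)
    maxima = np.asarray(_FIELD_MAX, dtype=np.uint64)
    n_clipped = int(np.count_nonzero(counts > maxima[None, :]))
    c = np.minimum(c, maxima[None, :])
    hi = np.zeros(len(c), dtype=np.uint64)
    lo = np.zeros(len(c), dtype=np.uint64)
    for i in range(N_PIXELS):
        off, w = _FIELD_OFFSETS[i], _FIELD_WIDTHS[i]
        if off + w <= 64:
            hi |= c[:, i] << np.uint64(64 - off - w)
        else:
            lo |= c[:, i] << np.uint64(128 - off - w)
    out = np.empty((len(c), 2), dtype=">u8")
    out[:, 0] = hi
    out[:, 1] = lo
    return out.tobytes(), n_clipped


def _unpack_array(raw: bytes) -> np.ndarray:
    words = np.frombuffer(raw, dtype=">u8").reshape(-1, 2).astype(np.uint64)
    hi, lo = words[:, 0], words[:, 1]
    out = np.empty((len(hi), N_PIXELS), dtype=np.int64)
    for i in range(N_PIXELS):
        off, w = _FIELD_OFFSETS[i], _FIELD_WIDTHS[i]
        if off + w <= 64:
            out[:, i] = ((hi >> np.uint64(64 - off - w)) & np.uint64(_FIELD_MAX[i])).astype(np.int64)
        else:
            out[:, i] = ((lo >> np.uint64(128 - off - w)) & np.uint64(_FIELD_MAX[i])).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Trace files
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta")


def _write_sidecar(path, trace: IntensityTrace, dialect: str, n_clipped: int) -> None:
    lines = [
        f"dialect={dialect}",
        f"bin_width={trace.bin_width!r}",
        f"n_bins={trace.n_bins}",
        "excluded_pixels=" + ",".join(str(i) for i in sorted(trace.excluded_pixels)),
    ]
    if n_clipped:
        lines.append(f"clipped_counts={n_clipped}")
    for k, v in trace.metadata.items():
        if k not in {"dialect", "bin_width", "n_bins", "excluded_pixels"}:
            lines.append(f"{k}={v}")
    _sidecar_path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path) -> dict:
    """Parse a ``key=value`` sidecar file into a dict (absent file -> empty)."""
    sp = _sidecar_path(path)
    meta: dict = {}
    if not sp.exists():
        return meta
    for line in sp.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, _, v = line.partition("=")
        meta[k.strip()] = v.strip()
    return meta


def write_trace(trace: IntensityTrace, path, dialect: str = "plain") -> int:
    """Write a trace; returns the number of counts clipped by saturation.

    ``plain`` and ``text`` are lossless; ``packed`` saturates counts at the
    per-pixel field maxima and reports how many values were clipped.
    """
    path = Path(path)
    n_clipped = 0
    if dialect == "packed":
        raw, n_clipped = _pack_array(np.asarray(trace.counts))
        path.write_bytes(raw)
    elif dialect == "plain":
        c = np.asarray(trace.counts)
        if c.size and int(c.max()) > np.iinfo(np.uint16).max:
            raise InvalidInputError("plain dialect stores uint16; count too large")
        path.write_bytes(np.ascontiguousarray(c, dtype="<u2").tobytes())
    elif dialect == "text":
        np.savetxt(path, np.asarray(trace.counts), fmt="%d", delimiter=",")
    else:
        raise InvalidInputError(f"unknown dialect {dialect!r}")
    _write_sidecar(path, trace, dialect, n_clipped)
    return n_clipped


def read_trace(
    path,
    dialect: str = "plain",
    bin_width: float | None = None,
    excluded_pixels=None,
    metadata: dict | None = None,
) -> IntensityTrace:
    """Read a trace file in the given dialect.

    The bin width is taken from the explicit argument, else the sidecar, else
    the 0.5 us default.  Truncated binary files (length not a multiple of the
    record size) raise :class:`FormatError` naming the offending byte offset.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    side = read_sidecar(path)
    if bin_width is None:
        bin_width = float(side.get("bin_width", 5e-7))
    if excluded_pixels is None:
        if "excluded_pixels" in side:
            s = side["excluded_pixels"]
            excluded_pixels = frozenset(int(x) for x in s.split(",") if x.strip())
        else:
            excluded_pixels = frozenset({1})
    meta = {
        k: v
        for k, v in side.items()
        if k not in {"dialect", "bin_width", "n_bins", "excluded_pixels"}
    }
    if metadata:
        meta.update(metadata)

    if dialect == "packed":
        raw = path.read_bytes()
        if len(raw) % _RECORD_BYTES:
            raise FormatError(
                f"truncated packed file: length {len(raw)} is not a multiple of "
                f"{_RECORD_BYTES}; last whole record ends at byte "
                f"{len(raw) - len(raw) % _RECORD_BYTES}"
            )
        counts = (
            _unpack_array(raw) if raw else np.zeros((0, N_PIXELS), dtype=np.int64)
        )
    elif dialect == "plain":
        raw = path.read_bytes()
        rec = 2 * N_PIXELS
        if len(raw) % rec:
            raise FormatError(
                f"truncated plain file: length {len(raw)} is not a multiple of "
                f"{rec}; last whole record ends at byte {len(raw) - len(raw) % rec}"
            )
        # keep the compact dtype: large traces would triple in memory as int64
        counts = np.frombuffer(raw, dtype="<u2").reshape(-1, N_PIXELS).copy()
    elif dialect == "text":
        if os.path.getsize(path) == 0:
            counts = np.zeros((0, N_PIXELS), dtype=np.int64)
        else:
            try:
                arr = np.loadtxt(path, delimiter=",", ndmin=2)
            except ValueError as e:
                raise FormatError(f"malformed text trace {path}: {e}") from e
            if arr.shape[1] != N_PIXELS:
                raise FormatError(
                    f"text trace must have {N_PIXELS} columns, got {arr.shape[1]}"
                )
            if np.any(arr < 0):
                raise InvalidInputError("negative count in text trace")
            counts = arr.astype(np.int64)
    else:
        raise InvalidInputError(f"unknown dialect {dialect!r}")

    return IntensityTrace(
        counts=counts,
        bin_width=bin_width,
        excluded_pixels=excluded_pixels,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Fingerprint map
# ---------------------------------------------------------------------------

def fingerprint(trace: IntensityTrace, grid: PixelGrid | None = None) -> FingerprintMap:
    """Mean photon count rate per pixel and its percentage of the centre pixel.

    The fingerprint map is the time-integrated image of the detection volume
    on the detector array; for a well-aligned confocal system it is
    Gaussian-like and peaks at the central pixel.
    """
    if trace.duration <= 0:
        raise InvalidInputError("fingerprint requires a trace of positive duration")
    grid = grid or PixelGrid()
    totals = trace.counts.sum(axis=0, dtype=np.float64)
    mean_pcr = totals / trace.duration
    center = mean_pcr[grid.center_index]
    if center <= 0:
        warnings.warn(
            "central pixel recorded no photons; percentages undefined", stacklevel=2
        )
        pct = np.full(N_PIXELS, np.nan)
        return FingerprintMap(mean_pcr=mean_pcr, percent_of_center=pct, valid=False)
    pct = 100.0 * mean_pcr / center
    return FingerprintMap(mean_pcr=mean_pcr, percent_of_center=pct, valid=True)


def rebin(trace: IntensityTrace, factor: int) -> IntensityTrace:
    """Merge ``factor`` consecutive time bins (trailing remainder dropped).

    Coarser bins speed up lag-limited analyses (e.g. STICS) without touching
    the information at lags above the new bin width.
    """
    if factor < 1 or int(factor) != factor:
        raise InvalidInputError("rebin factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return trace
    n = (trace.n_bins // factor) * factor
    c = np.asarray(trace.counts[:n], dtype=np.int64)
    c = c.reshape(-1, factor, N_PIXELS).sum(axis=1)
    return IntensityTrace(
        counts=c,
        bin_width=trace.bin_width * factor,
        excluded_pixels=trace.excluded_pixels,
        metadata={**trace.metadata, "rebinned_by": factor},
    )


def packed_stream_rate(bin_width: float = 5e-7) -> float:
    """Data rate of the packed dialect in MiB/s (one 16-byte record per bin)."""
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be positive")
    return _RECORD_BYTES / bin_width / 2**20


def field_maxima() -> np.ndarray:
    """Per-pixel saturation values of the packed dialect (255/63/15)."""
    return np.asarray(_FIELD_MAX, dtype=np.int64)
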