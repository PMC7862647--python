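"""Pixel grouping and multiple-tau correlation.

Correlations are fluctuation-normalized,

    G(tau) = <da(t) db(t+tau)> / (<a><b>),   da = a - <a>,

so G -> 0 at long lags; any residual offset is a fit parameter, not a
correlator output.  Lags follow the multiple-tau scheme: ``m`` linear lags
per level, with the traces rebinned by a factor of two between levels, which
yields quasi-logarithmic lag spacing from one bin width up to ``max_lag``
(0.1 s by default) at O(N log N) cost.  Means are level-local: each lag uses
the means of the two overlapping trace segments at that level's resolution,
which keeps G of a constant trace identically zero.

Long measurements are split into chunks (10 s by default), correlated per
chunk and averaged; the per-lag sample standard deviation across chunks is
the statistical weight used by the fitting routines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, NormalizationError
from .spadio import N_PIXELS, IntensityTrace, PixelGrid

DEFAULT_M = 16
DEFAULT_MAX_LAG = 0.1  # s
DEFAULT_CHUNK = 10.0  # s


@dataclass
class CorrelationCurve:
    """A correlation curve on the multiple-tau lag grid."""

    lags: np.ndarray  # s, strictly increasing
    G: np.ndarray
    G_std: np.ndarray  # per-lag sample std across chunks (0 if single chunk)
    n_chunks: int = 1
    label: dict = field(default_factory=dict)

    def cropped(self, min_lag: float = 0.0, max_lag: float = np.inf) -> "CorrelationCurve":
        keep = (self.lags >= min_lag) & (self.lags <= max_lag)
        return CorrelationCurve(
            self.lags[keep], self.G[keep], self.G_std[keep], self.n_chunks, dict(self.label)
        )


@dataclass
class ShiftCorrelationSeries:
    """Spatial-shift correlation matrices G(xi, psi; tau) for STICS.

    ``matrices[l]`` is the 9x9 matrix at ``lag_times[l]`` indexed by integer
    pixel shifts (xi, psi) in [-4, 4]^2 (row = psi + 4, column = xi + 4);
    ``pair_counts`` gives the number of ordered pixel pairs contributing to
    each shift class (25 at the centre, 1 at the corners for the full array).
    Shift classes left empty by pixel exclusions hold NaN.
    """

    lag_times: np.ndarray  # s
    matrices: np.ndarray  # (n_lags, 9, 9)
    pair_counts: np.ndarray  # (9, 9) int
    n_chunks: int = 1


# ---------------------------------------------------------------------------
# Pixel grouping
# ---------------------------------------------------------------------------

_NAMED_SELECTIONS = ("center", "sum3x3", "sum5x5", "checker_even", "checker_odd")


def selection_mask(selection, grid: PixelGrid | None = None) -> np.ndarray:
    """Boolean mask (length 25) for a named or explicit pixel selection."""
    grid = grid or PixelGrid()
    if isinstance(selection, str):
        off = grid.pixel_offsets
        idx = np.arange(grid.n_pixels)
        if selection == "center":
            return idx == grid.center_index
        if selection == "sum3x3":
            return (np.abs(off[:, 0]) <= 1) & (np.abs(off[:, 1]) <= 1)
        if selection == "sum5x5":
            return np.ones(grid.n_pixels, dtype=bool)
        if selection == "checker_even":
            return idx % 2 == 0
        if selection == "checker_odd":
            return idx % 2 == 1
        raise InvalidInputError(
            f"unknown selection {selection!r}; named selections: {_NAMED_SELECTIONS}"
        )
    mask = np.zeros(grid.n_pixels, dtype=bool)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.shape != (grid.n_pixels,):
            raise InvalidInputError("boolean mask must have length 25")
        return sel.copy()
    mask[sel.astype(int)] = True
    return mask


def sum_pixels(
    trace: IntensityTrace,
    selection,
    include_excluded: bool = False,
    grid: PixelGrid | None = None,
) -> np.ndarray:
    """Per-bin sum of the selected pixels (excluded pixels dropped by default)."""
    mask = selection_mask(selection, grid)
    if not include_excluded:
        mask = mask.copy()
        for i in trace.excluded_pixels:
            mask[i] = False
    if not mask.any():
        raise InvalidInputError("empty pixel selection after exclusions")
    # select columns first, then accumulate in float64: avoids materializing
    # a float64 copy of the whole (n_bins, 25) array for long traces
    return trace.counts[:, mask].sum(axis=1, dtype=np.float64)


def rho_classes(grid: PixelGrid | None = None) -> dict[float, list[int]]:
    """Pixels grouped by Euclidean distance rho from the centre (centre excluded).

    The 24 off-centre pixels fall into five classes,
    rho in {1, sqrt(2), 2, sqrt(5), 2*sqrt(2)} with 4, 4, 4, 8 and 4 members.
    """
    grid = grid or PixelGrid()
    rho = grid.rho
    classes: dict[float, list[int]] = {}
    for i in range(grid.n_pixels):
        if i == grid.center_index:
            continue
        key = round(float(rho[i]), 9)
        classes.setdefault(key, []).append(i)
    return {k: classes[k] for k in sorted(classes)}


# ---------------------------------------------------------------------------
# Multiple-tau core
# ---------------------------------------------------------------------------

def _mt_lag_plan(n_bins: int, m: int, bin_width: float, max_lag: float):
    """Yield (level, k, lag_seconds, n_level_bins) for the multiple-tau grid."""
    level = 0
    n = n_bins
    while n >= 2 * m:
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        dt = bin_width * (1 << level)
        for k in ks:
            lag = k * dt
            if lag > max_lag:
                return
            yield level, k, lag, n
        n //= 2
        level += 1


def _rebin2(x: np.ndarray) -> np.ndarray:
    n = (len(x) // 2) * 2
    return 0.5 * (x[0:n:2] + x[1:n:2])


def correlate_pair(
    a,
    b=None,
    m: int = DEFAULT_M,
    bin_width: float = 5e-7,
    max_lag: float = DEFAULT_MAX_LAG,
    label: dict | None = None,
) -> CorrelationCurve:
    """Multiple-tau auto- (b is None) or cross-correlation of two count traces.

    The zero lag is excluded.  Raises :class:`NormalizationError` if either
    trace segment has zero mean at some level.
    """
    a = np.asarray(a, dtype=np.float64)
    b_arr = a if b is None else np.asarray(b, dtype=np.float64)
    if a.shape != b_arr.shape or a.ndim != 1:
        raise InvalidInputError("traces must be 1-D and of equal length")
    if len(a) < 2 * m:
        raise InvalidInputError(f"trace too short: need at least {2 * m} bins")
    lags, G = [], []
    aa, bb = a, b_arr
    cur_level = 0
    for level, k, lag, n in _mt_lag_plan(len(a), m, bin_width, max_lag):
        while cur_level < level:
            aa = _rebin2(aa)
            bb = _rebin2(bb)
            cur_level += 1
        na = n - k
        ma = aa[:na].mean()
        mb = bb[k : k + na].mean()
        if ma <= 0 or mb <= 0:
            raise NormalizationError(
                f"zero-mean trace segment at level {level}; cannot normalize"
            )
        g = float(np.dot(aa[:na], bb[k : k + na])) / (na * ma * mb) - 1.0
        lags.append(lag)
        G.append(g)
    lags = np.asarray(lags)
    G = np.asarray(G)
    return CorrelationCurve(lags, G, np.zeros_like(G), 1, label or {})


def _chunk_G_matrix(a, b, m, bin_width, chunk_length, max_lag):
    """Per-chunk multiple-tau curves; returns (lags, G matrix (n_chunks, n_lags))."""
    n_per = int(round(chunk_length / bin_width))
    n_chunks = len(a) // n_per
    if n_chunks == 0:
        warnings.warn(
            "trace shorter than one chunk; falling back to a single whole-trace chunk",
            stacklevel=3,
        )
        c = correlate_pair(a, b, m=m, bin_width=bin_width, max_lag=max_lag)
        return c.lags, c.G[None, :]
    rows = []
    lags = None
    for i in range(n_chunks):
        s = slice(i * n_per, (i + 1) * n_per)
        c = correlate_pair(
            a[s], None if b is None else b[s], m=m, bin_width=bin_width, max_lag=max_lag
        )
        lags = c.lags
        rows.append(c.G)
    return lags, np.vstack(rows)


def chunked_correlate(
    a,
    b=None,
    bin_width: float = 5e-7,
    chunk_length: float = DEFAULT_CHUNK,
    m: int = DEFAULT_M,
    max_lag: float = DEFAULT_MAX_LAG,
    label: dict | None = None,
) -> CorrelationCurve:
    """Split into chunks, correlate each, average; G_std is the per-lag sample
    standard deviation across chunks.  A trailing partial chunk is dropped."""
    a = np.asarray(a, dtype=np.float64)
    bb = None if b is None else np.asarray(b, dtype=np.float64)
    lags, Gm = _chunk_G_matrix(a, bb, m, bin_width, chunk_length, max_lag)
    n_chunks = Gm.shape[0]
    G = Gm.mean(axis=0)
    G_std = Gm.std(axis=0, ddof=1) if n_chunks > 1 else np.zeros_like(G)
    return CorrelationCurve(lags, G, G_std, n_chunks, label or {})


def cross_center_by_rho(
    trace: IntensityTrace,
    m: int = DEFAULT_M,
    chunk_length: float = DEFAULT_CHUNK,
    max_lag: float = DEFAULT_MAX_LAG,
    include_excluded: bool = False,
    grid: PixelGrid | None = None,
) -> dict[float, CorrelationCurve]:
    """Cross-correlate the centre pixel against every other usable pixel and
    average the curves within each interpixel-distance class rho.

    Returns a mapping rho -> averaged curve (classes emptied by exclusions
    are omitted with a warning).  G_std pools the spread over both chunks and
    class members.
    """
    grid = grid or PixelGrid()
    if not include_excluded and grid.center_index in trace.excluded_pixels:
        raise InvalidInputError("centre pixel is excluded; cannot cross-correlate")
    counts = trace.counts
    center = counts[:, grid.center_index].astype(np.float64)
    out: dict[float, CorrelationCurve] = {}
    for rho, members in rho_classes(grid).items():
        usable = [
            j
            for j in members
            if include_excluded or j not in trace.excluded_pixels
        ]
        if not usable:
            warnings.warn(f"rho class {rho} empty after exclusions; omitted", stacklevel=2)
            continue
        stacks = []
        lags = None
        for j in usable:
            lags, Gm = _chunk_G_matrix(
                center, counts[:, j].astype(np.float64), m, trace.bin_width,
                chunk_length, max_lag
            )
            stacks.append(Gm)
        allG = np.vstack(stacks)  # (n_members * n_chunks, n_lags)
        G = allG.mean(axis=0)
        G_std = allG.std(axis=0, ddof=1) if allG.shape[0] > 1 else np.zeros_like(G)
        out[rho] = CorrelationCurve(
            lags,
            G,
            G_std,
            n_chunks=allG.shape[0],
            label={"group_a": "center", "group_b": f"rho={rho:g}", "rho": rho,
                   "n_pixels": len(usable)},
        )
    return out


# ---------------------------------------------------------------------------
# STICS: spatial-shift-class correlation
# ---------------------------------------------------------------------------

def _stics_chunk(A, m, bin_width, max_lag):
    """All-pairs correlations of one chunk; returns (lags, list of 25x25 G)."""
    lags, mats = [], []
    Al = A
    cur_level = 0
    n_bins = A.shape[1]
    for level, k, lag, n in _mt_lag_plan(n_bins, m, bin_width, max_lag):
        while cur_level < level:
            nn = (Al.shape[1] // 2) * 2
            Al = 0.5 * (Al[:, 0:nn:2] + Al[:, 1:nn:2])
            cur_level += 1
        na = n - k
        ma = Al[:, :na].mean(axis=1)
        mb = Al[:, k : k + na].mean(axis=1)
        denom = np.outer(ma, mb) * na
        C = Al[:, :na] @ Al[:, k : k + na].T
        with np.errstate(divide="ignore", invalid="ignore"):
            G = C / denom - 1.0
        # a pixel with zero mean has no normalizable fluctuation signal:
        # mark its pairs missing instead of letting inf/NaN poison averages
        dead = (ma <= 0) | (mb <= 0)
        if np.any(dead):
            G[dead, :] = np.nan
            G[:, dead] = np.nan
        lags.append(lag)
        mats.append(G)
    return np.asarray(lags), mats


def stics_correlate(
    trace: IntensityTrace,
    m: int = DEFAULT_M,
    chunk_length: float = DEFAULT_CHUNK,
    max_lag: float = 2e-3,
    include_excluded: bool = False,
    grid: PixelGrid | None = None,
) -> ShiftCorrelationSeries:
    """Correlate all ordered pixel pairs and average by spatial shift class.

    For each multiple-tau lag up to ``max_lag`` the 625 ordered pair
    correlations are grouped by the shift (dx_j - dx_i, dy_j - dy_i) of pair
    (i, j), giving a 9x9 matrix per lag; forward and reverse pairs land in
    opposite shift classes and the matrix is then symmetrized under
    (xi, psi) -> (-xi, -psi), which is exact for drift-free stationary
    signals.  Excluded pixels reduce the per-shift pair counts; classes left
    empty are NaN.
    """
    grid = grid or PixelGrid()
    counts = trace.counts  # (n_bins, 25); converted per chunk to bound memory
    active = trace.active_pixels(include_excluded)
    off = grid.pixel_offsets

    # shift-class index of each ordered active pair
    ai = np.repeat(active, len(active))
    aj = np.tile(active, len(active))
    sx = off[aj, 0] - off[ai, 0] + 4
    sy = off[aj, 1] - off[ai, 1] + 4
    flat_shift = sy * 9 + sx
    pair_counts = np.bincount(flat_shift, minlength=81).reshape(9, 9)

    n_per = int(round(chunk_length / trace.bin_width))
    n_chunks = counts.shape[0] // n_per
    if n_chunks == 0:
        warnings.warn(
            "trace shorter than one chunk; falling back to a single whole-trace chunk",
            stacklevel=2,
        )
        chunk_slices = [slice(None)]
    else:
        chunk_slices = [
            slice(i * n_per, (i + 1) * n_per) for i in range(n_chunks)
        ]

    lags = None
    acc = None
    cnt = None
    for sl in chunk_slices:
        A = counts[sl][:, active].T.astype(np.float64)
        lags, mats = _stics_chunk(A, m, trace.bin_width, max_lag)
        if acc is None:
            acc = [np.zeros(81) for _ in lags]
            cnt = [np.zeros(81) for _ in lags]
        for li, Gfull in enumerate(mats):
            g = Gfull.ravel()
            ok = np.isfinite(g)
            acc[li] += np.bincount(
                flat_shift[ok], weights=g[ok], minlength=81
            )
            cnt[li] += np.bincount(flat_shift[ok], minlength=81)
    with np.errstate(divide="ignore", invalid="ignore"):
        mats9 = np.stack(
            [
                (a / np.where(c > 0, c, np.nan)).reshape(9, 9)
                for a, c in zip(acc, cnt)
            ]
        )
    # exact centro-symmetrization (xi, psi) -> (-xi, -psi)
    mats9 = 0.5 * (mats9 + mats9[:, ::-1, ::-1])
    return ShiftCorrelationSeries(
        lag_times=lags,
        matrices=mats9,
        pair_counts=pair_counts,
        n_chunks=len(chunk_slices),
    )
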