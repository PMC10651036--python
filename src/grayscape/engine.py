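"""Moving-window, global, and multi-scale (scalogram) analysis.

The moving-window analysis slides a square window across the map one
pixel at a time; the metric of each window is written at the window's
center, so the output map has the input's dimensions and resolution.
Windows overhanging the map edge shrink to their in-bounds part rather
than producing a nodata border.  The engine keeps the dense frequency
and adjacency count arrays up to date incrementally — when the window
moves one column, only the counts (and pairs) of the entering and
leaving columns change — and recomputes every derived statistic from the
integer counts at each position, so results are bit-identical to
rebuilding each window from scratch (``method="scratch"`` does exactly
that, as a cross-check).

Global analysis evaluates a metric once on the tabulation of the entire
map extent; the scalogram driver repeats a moving-window analysis over a
grid of window sizes and reduces each metric map to a summary value
(e.g. its maximum), producing the metric-versus-scale curve used to look
for scale domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricSpec, MetricValue, TargetParams, check_params, evaluate, get_metric
from .raster import INCLUDE_ZERO, MISSING, N_LEVELS, GrayLevelRaster, ZeroPolicy
from .tabulation import (
    AdjacencyTabulation,
    FrequencyTabulation,
    adjacency_counts,
    frequency_counts,
    tabulate_adjacency,
    tabulate_frequency,
)

#: Default scalogram window sizes: 5x5 to 45x45 in steps of 2 (21 scales).
DEFAULT_SCALES: tuple[int, ...] = tuple(range(5, 46, 2))


@dataclass(frozen=True)
class WindowSpec:
    """Square moving-window geometry; the side must be odd and >= 3."""

    side_length: int

    def __post_init__(self):
        s = self.side_length
        if s < 3 or s % 2 == 0:
            raise ValueError(f"window side must be an odd integer >= 3, got {s}")

    @property
    def half(self) -> int:
        return self.side_length // 2


@dataclass
class MetricMap:
    """A metric raster aligned to the input, with NaN as nodata.

    ``values`` is float64 during computation; the writers narrow it to
    float32 or scaled 8-bit on output.
    """

    values: np.ndarray
    metric: MetricSpec
    window: WindowSpec | str
    zero_policy: ZeroPolicy
    params: TargetParams
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def window_area_km2(side_length: int, resolution_m: float) -> float:
    """Ground area of a side x side window, in km^2, rounded to integer
    precision when it is large.

    E.g. at 2430 m resolution a 31x31 window covers (31 * 2.43 km)^2 =
    5674.7 km^2, reported as 5675.
    """
    area = (side_length * resolution_m / 1000.0) ** 2
    return float(round(area)) if area >= 1 else area


def map_gray_level_range(
    raster: GrayLevelRaster, zero_policy: ZeroPolicy = INCLUDE_ZERO
) -> int | None:
    """Map-wide gray-level range (max - min of levels present), or None
    when no pixel is included."""
    return tabulate_frequency(raster, None, zero_policy).level_range


# ---------------------------------------------------------------------------
# Incremental sliding-window counts
# ---------------------------------------------------------------------------

class _SlidingCounts:
    """Frequency + adjacency counts of a window sliding along one row band.

    The band (window row extent) is fixed; sliding the center one column
    to the right removes the columns that left the window (their pixel
    counts, their within-column vertical pairs, and the horizontal pairs
    whose *left* member left) and adds the entering columns symmetrically.
    """

    def __init__(self, grid: np.ndarray, mask: np.ndarray, r0: int, r1: int):
        self.grid = grid
        self.mask = mask
        self.r0 = r0
        self.r1 = r1
        self.freq = np.zeros(N_LEVELS, dtype=np.int64)
        self.adj = np.zeros((N_LEVELS, N_LEVELS), dtype=np.int64)
        self.c0 = 0
        self.c1 = 0  # current column extent [c0, c1)

    def _column(self, c: int, sign: int) -> None:
        """Add (sign=+1) or remove (sign=-1) one column's pixels and its
        vertical pairs."""
        g = self.grid[self.r0 : self.r1, c]
        m = self.mask[self.r0 : self.r1, c]
        np.add.at(self.freq, g[m], sign)
        if g.shape[0] > 1:
            ok = m[:-1] & m[1:]
            np.add.at(self.adj, (g[:-1][ok], g[1:][ok]), sign)

    def _horizontal(self, cl: int, sign: int) -> None:
        """Add/remove the horizontal pairs between columns cl and cl+1."""
        gl = self.grid[self.r0 : self.r1, cl]
        gr = self.grid[self.r0 : self.r1, cl + 1]
        ok = self.mask[self.r0 : self.r1, cl] & self.mask[self.r0 : self.r1, cl + 1]
        np.add.at(self.adj, (gl[ok], gr[ok]), sign)

    def reset(self, c0: int, c1: int) -> None:
        """Initialize to the column extent [c0, c1) from scratch."""
        self.freq[:] = 0
        self.adj[:] = 0
        for c in range(c0, c1):
            self._column(c, +1)
            if c > c0:
                self._horizontal(c - 1, +1)
        self.c0, self.c1 = c0, c1

    def slide_to(self, c0: int, c1: int) -> None:
        """Move the column extent from [self.c0, self.c1) to [c0, c1)."""
        for c in range(self.c0, c0):  # columns leaving on the left
            self._column(c, -1)
            self._horizontal(c, -1)  # pair (c, c+1): left member gone
        for c in range(self.c1, c1):  # columns entering on the right
            self._column(c, +1)
            self._horizontal(c - 1, +1)  # pair (c-1, c): right member new
        self.c0, self.c1 = c0, c1


def moving_window(
    raster: GrayLevelRaster,
    metric: int | MetricSpec,
    window: int | WindowSpec,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
    params: TargetParams | None = None,
    method: str = "incremental",
) -> MetricMap:
    """Map a metric over every window position of the raster.

    Parameters
    ----------
    metric
        Metric id (1-51) or its registry entry.
    window
        Odd side length >= 3, or a :class:`WindowSpec`.
    method
        ``"incremental"`` (default) slides the tabulations;
        ``"scratch"`` rebuilds every window independently.  Both produce
        bit-identical maps; the scratch path exists as a correctness
        cross-check and reference.
    """
    spec = metric if isinstance(metric, MetricSpec) else get_metric(metric)
    wspec = window if isinstance(window, WindowSpec) else WindowSpec(window)
    params = check_params(spec, params)
    if method not in ("incremental", "scratch"):
        raise ValueError(f"unknown method {method!r}")

    grid = raster.values
    mask = raster.valid_mask(zero_policy)
    n_rows, n_cols = grid.shape
    h = wspec.half
    global_range = map_gray_level_range(raster, zero_policy) if spec.needs_global_range else None
    out = np.full((n_rows, n_cols), np.nan)

    need_f, need_a = spec.needs_frequency, spec.needs_adjacency

    def _emit(r, c, fcounts, acounts):
        freq = FrequencyTabulation(fcounts, copy=False) if need_f else None
        adj = AdjacencyTabulation(acounts, copy=False) if need_a else None
        mv = evaluate(spec, freq, adj, params, global_range)
        if not mv.is_missing:
            out[r, c] = float(mv.value)

    if method == "scratch":
        for r in range(n_rows):
            r0, r1 = max(0, r - h), min(n_rows, r + h + 1)
            for c in range(n_cols):
                c0, c1 = max(0, c - h), min(n_cols, c + h + 1)
                region = (r0, r1, c0, c1)
                fc = frequency_counts(raster, region, zero_policy) if need_f else None
                ac = adjacency_counts(raster, region, zero_policy) if need_a else None
                _emit(r, c, fc, ac)
    else:
        for r in range(n_rows):
            r0, r1 = max(0, r - h), min(n_rows, r + h + 1)
            sc = _SlidingCounts(grid, mask, r0, r1)
            sc.reset(0, min(n_cols, h + 1))
            _emit(r, 0, sc.freq, sc.adj)
            for c in range(1, n_cols):
                sc.slide_to(max(0, c - h), min(n_cols, c + h + 1))
                _emit(r, c, sc.freq, sc.adj)

    return MetricMap(
        values=out,
        metric=spec,
        window=wspec,
        zero_policy=zero_policy,
        params=params,
        metadata=dict(raster.metadata),
    )


def global_analysis(
    raster: GrayLevelRaster,
    metric: int | MetricSpec,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
    params: TargetParams | None = None,
) -> tuple[MetricValue, str]:
    """Evaluate a metric on the whole map extent.

    Returns the metric value (missing when no data or a guard fails) and
    a plain-text report.  The value equals any pixel of a moving-window
    map whose window covers the entire map.
    """
    spec = metric if isinstance(metric, MetricSpec) else get_metric(metric)
    params = check_params(spec, params)
    freq = tabulate_frequency(raster, None, zero_policy) if spec.needs_frequency else None
    adj = tabulate_adjacency(raster, None, zero_policy) if spec.needs_adjacency else None
    global_range = map_gray_level_range(raster, zero_policy) if spec.needs_global_range else None
    mv = evaluate(spec, freq, adj, params, global_range)
    lines = [
        "global analysis",
        f"metric: {spec.id} {spec.short_name}",
        f"map size: {raster.n_rows} x {raster.n_cols} pixels",
        f"zero policy: {'exclude' if zero_policy.exclude_zero else 'include'} gray level 0",
    ]
    for name in spec.params_required:
        lines.append(f"{name}: {getattr(params, name)}")
    lines.append(f"value: {'missing' if mv.is_missing else mv.value}")
    return mv, "\n".join(lines) + "\n"


def scalogram(
    raster: GrayLevelRaster,
    metric: int | MetricSpec,
    side_lengths: tuple[int, ...] | list[int] = DEFAULT_SCALES,
    summary: str = "max",
    quantile: float | None = None,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
    params: TargetParams | None = None,
) -> list[tuple[int, float]]:
    """Metric summary versus window size (observation scale).

    Runs one moving-window analysis per side length and reduces each
    metric map over its non-nodata pixels with ``summary`` ("max",
    "mean", or "quantile" with ``quantile`` in [0, 1]).  The default
    scale grid is 5x5 to 45x45 in steps of 2 (21 scales).  Scales where
    every pixel is nodata yield NaN.
    """
    if not side_lengths:
        raise ValueError("side_lengths must be a non-empty list of odd integers")
    if summary not in ("max", "mean", "quantile"):
        raise ValueError(f"summary must be max, mean or quantile, got {summary!r}")
    if summary == "quantile":
        if quantile is None or not 0.0 <= quantile <= 1.0:
            raise ValueError("quantile summary requires quantile in [0, 1]")
    out = []
    for side in side_lengths:
        mmap = moving_window(raster, metric, side, zero_policy, params)
        vals = mmap.values[~mmap.nodata_mask]
        if vals.size == 0:
            out.append((side, float("nan")))
        elif summary == "max":
            out.append((side, float(vals.max())))
        elif summary == "mean":
            out.append((side, float(vals.mean())))
        else:
            out.append((side, float(np.quantile(vals, quantile))))
    return out
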