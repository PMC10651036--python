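"""Gray-level frequency and adjacency tabulations.

Every metric is a function of one or both of two statistical summaries of
an analysis region:

* the **frequency tabulation** — counts ``x(i)`` of each gray level
  ``i`` among included pixels, with derived proportions ``p(i)``, the
  number of levels present ``Ng``, mean, variance and range;
* the **adjacency tabulation** — the ordered co-occurrence matrix
  ``x(i, j)`` of neighboring pixel-value pairs under the 2-neighbor rule
  (each pixel paired with the pixel one below and the pixel one to the
  right, each adjacency counted once; ``i`` is the upper/left value,
  ``j`` the lower/right value), with the unordered collapse ``x'(i, j)``,
  joint and marginal proportions, and the difference ``p_{x-y}(k)`` and
  sum ``p_{x+y}(k)`` distributions.

A pair is counted only if both pixels lie in the region and both are
included under the zero policy; a pixel adjacent to a missing/excluded
pixel still counts in the frequency tabulation but contributes no pair.

Counts live in dense 101-slot arrays (101x101 for adjacencies) regardless
of how many levels are present, so the moving-window engine can update
them incrementally in O(1) per element; all derived statistics are
recomputed from the integer counts on demand, never accumulated in
floating point.
"""

from __future__ import annotations

import numpy as np

from .raster import INCLUDE_ZERO, MISSING, N_LEVELS, GrayLevelRaster, ZeroPolicy

Region = tuple[int, int, int, int]  # (row_start, row_stop, col_start, col_stop)

_LEVELS = np.arange(N_LEVELS, dtype=np.float64)


def _resolve_region(raster: GrayLevelRaster, region: Region | None) -> Region:
    if region is None:
        return (0, raster.n_rows, 0, raster.n_cols)
    r0, r1, c0, c1 = region
    if not (0 <= r0 <= r1 <= raster.n_rows and 0 <= c0 <= c1 <= raster.n_cols):
        raise ValueError(f"region {region} outside raster of shape {raster.shape}")
    return region


class FrequencyTabulation:
    """Counts ``x(i)`` of gray levels with lazily derived statistics."""

    __slots__ = ("counts", "_cache")

    def __init__(self, counts: np.ndarray, copy: bool = True):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(f"counts must have shape ({N_LEVELS},)")
        self.counts = counts.copy() if copy else counts
        self._cache: dict = {}

    @property
    def total(self) -> int:
        if "total" not in self._cache:
            self._cache["total"] = int(self.counts.sum())
        return self._cache["total"]

    @property
    def p(self) -> np.ndarray:
        """Proportions p(i) over the dense level axis (zeros where absent)."""
        if "p" not in self._cache:
            if self.total == 0:
                raise ZeroDivisionError("empty tabulation has no proportions")
            self._cache["p"] = self.counts / self.total
        return self._cache["p"]

    @property
    def levels(self) -> np.ndarray:
        """Sorted gray levels present (x(i) > 0)."""
        if "levels" not in self._cache:
            self._cache["levels"] = np.flatnonzero(self.counts)
        return self._cache["levels"]

    @property
    def n_levels(self) -> int:
        """Ng, the number of gray levels present."""
        return len(self.levels)

    @property
    def min_level(self) -> int | None:
        return int(self.levels[0]) if self.n_levels else None

    @property
    def max_level(self) -> int | None:
        return int(self.levels[-1]) if self.n_levels else None

    @property
    def level_range(self) -> int | None:
        """max(i) - min(i), or None when empty."""
        if not self.n_levels:
            return None
        return int(self.levels[-1] - self.levels[0])

    @property
    def mean(self) -> float:
        """mu = sum_i i * p(i)."""
        return float(_LEVELS @ self.p)

    @property
    def variance(self) -> float:
        """sigma^2 = sum_i (i - mu)^2 * p(i)."""
        mu = self.mean
        return float(((_LEVELS - mu) ** 2) @ self.p)

    def median(self) -> int:
        """Order-statistic median; even counts take the lower middle value."""
        if self.total == 0:
            raise ZeroDivisionError("empty tabulation has no median")
        target = (self.total - 1) // 2  # 0-based rank of the lower middle
        cum = np.cumsum(self.counts)
        return int(np.searchsorted(cum, target + 1))

    def majority(self) -> int:
        """Most frequent level; ties broken toward the smallest level."""
        if self.total == 0:
            raise ZeroDivisionError("empty tabulation has no majority")
        return int(np.argmax(self.counts))


class AdjacencyTabulation:
    """Ordered co-occurrence counts ``x(i, j)`` with derived distributions.

    ``x(i, j)`` counts pairs with upper/left value ``i`` and lower/right
    value ``j``.  The unordered form follows the symmetric-complete
    definition ``x'(i, j) = x(i, j) + x(j, i)`` for ``i != j`` and
    ``x'(i, i) = x(i, i)``; sums "over j >= i" in metric formulas use its
    upper triangle, so each unordered adjacency is counted once.
    """

    __slots__ = ("counts", "_cache")

    def __init__(self, counts: np.ndarray, copy: bool = True):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (N_LEVELS, N_LEVELS):
            raise ValueError(f"counts must have shape ({N_LEVELS}, {N_LEVELS})")
        self.counts = counts.copy() if copy else counts
        self._cache: dict = {}

    @property
    def total(self) -> int:
        if "total" not in self._cache:
            self._cache["total"] = int(self.counts.sum())
        return self._cache["total"]

    @property
    def p(self) -> np.ndarray:
        """Joint proportions p(i, j) of the ordered matrix."""
        if "p" not in self._cache:
            if self.total == 0:
                raise ZeroDivisionError("empty tabulation has no proportions")
            self._cache["p"] = self.counts / self.total
        return self._cache["p"]

    @property
    def unordered(self) -> np.ndarray:
        """Symmetric-complete unordered counts x'(i, j)."""
        if "unordered" not in self._cache:
            x = self.counts
            full = x + x.T
            np.fill_diagonal(full, np.diagonal(x))
            self._cache["unordered"] = full
        return self._cache["unordered"]

    @property
    def unordered_upper(self) -> np.ndarray:
        """Upper triangle (j >= i) of x'; total mass equals ``total``."""
        if "unordered_upper" not in self._cache:
            self._cache["unordered_upper"] = np.triu(self.unordered)
        return self._cache["unordered_upper"]

    @property
    def p_unordered_upper(self) -> np.ndarray:
        """p'(i, j) over the upper triangle."""
        return self.unordered_upper / self.total

    @property
    def px(self) -> np.ndarray:
        """Row marginal p_x(i) = sum_j p(i, j)."""
        if "px" not in self._cache:
            self._cache["px"] = self.p.sum(axis=1)
        return self._cache["px"]

    @property
    def py(self) -> np.ndarray:
        """Column marginal p_y(j) = sum_i p(i, j)."""
        if "py" not in self._cache:
            self._cache["py"] = self.p.sum(axis=0)
        return self._cache["py"]

    @property
    def mu_x(self) -> float:
        return float(_LEVELS @ self.px)

    @property
    def mu_y(self) -> float:
        return float(_LEVELS @ self.py)

    @property
    def var_x(self) -> float:
        return float(((_LEVELS - self.mu_x) ** 2) @ self.px)

    @property
    def var_y(self) -> float:
        return float(((_LEVELS - self.mu_y) ** 2) @ self.py)

    @property
    def levels(self) -> np.ndarray:
        """Gray levels present in the adjacency matrix (row or column)."""
        if "levels" not in self._cache:
            mass = self.counts.sum(axis=0) + self.counts.sum(axis=1)
            self._cache["levels"] = np.flatnonzero(mass)
        return self._cache["levels"]

    @property
    def n_levels(self) -> int:
        """Ng of the adjacency matrix."""
        return len(self.levels)

    @property
    def level_range(self) -> int | None:
        """R, the range of gray levels present in the matrix."""
        lv = self.levels
        if not len(lv):
            return None
        return int(lv[-1] - lv[0])

    @property
    def diff_dist(self) -> np.ndarray:
        """p_{x-y}(k) = sum over |i - j| = k of p(i, j); length 101."""
        if "diff" not in self._cache:
            out = np.zeros(N_LEVELS)
            ii, jj = np.nonzero(self.counts)
            np.add.at(out, np.abs(ii - jj), self.p[ii, jj])
            self._cache["diff"] = out
        return self._cache["diff"]

    @property
    def sum_dist(self) -> np.ndarray:
        """p_{x+y}(k) = sum over i + j = k of p(i, j); length 201."""
        if "sum" not in self._cache:
            out = np.zeros(2 * N_LEVELS - 1)
            ii, jj = np.nonzero(self.counts)
            np.add.at(out, ii + jj, self.p[ii, jj])
            self._cache["sum"] = out
        return self._cache["sum"]

    @property
    def n_k_diff(self) -> int:
        """Nk of the difference distribution (nonzero k levels)."""
        return int(np.count_nonzero(self.diff_dist))

    @property
    def n_k_sum(self) -> int:
        """Nk of the sum distribution (nonzero k levels)."""
        return int(np.count_nonzero(self.sum_dist))


def collapse_unordered(tab: AdjacencyTabulation) -> np.ndarray:
    """Upper-triangular unordered counts x'(i, j), j >= i.

    The collapse folds the ordered matrix across the main diagonal:
    off-diagonal mass moves into the upper triangle, the diagonal is kept,
    and the total mass is preserved.
    """
    return tab.unordered_upper.copy()


# ---------------------------------------------------------------------------
# Count builders (shared by the global path and the window engine's
# from-scratch rebuilds; the incremental engine maintains the same arrays).
# ---------------------------------------------------------------------------

def frequency_counts(
    raster: GrayLevelRaster,
    region: Region | None = None,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
) -> np.ndarray:
    """Dense 101-slot gray-level counts for a rectangular region."""
    r0, r1, c0, c1 = _resolve_region(raster, region)
    sub = raster.values[r0:r1, c0:c1]
    mask = sub != MISSING
    if zero_policy.exclude_zero:
        mask &= sub != 0
    vals = sub[mask]
    return np.bincount(vals, minlength=N_LEVELS)[:N_LEVELS].astype(np.int64)


def adjacency_counts(
    raster: GrayLevelRaster,
    region: Region | None = None,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
) -> np.ndarray:
    """Dense 101x101 ordered adjacency counts for a rectangular region.

    Pairs follow the 2-neighbor rule: (pixel, pixel below) and
    (pixel, pixel right), each counted once, both members required to be
    in the region and included under the zero policy.
    """
    r0, r1, c0, c1 = _resolve_region(raster, region)
    sub = raster.values[r0:r1, c0:c1]
    mask = sub != MISSING
    if zero_policy.exclude_zero:
        mask &= sub != 0
    out = np.zeros((N_LEVELS, N_LEVELS), dtype=np.int64)
    # vertical: i = upper, j = lower
    if sub.shape[0] > 1:
        ok = mask[:-1, :] & mask[1:, :]
        np.add.at(out, (sub[:-1, :][ok], sub[1:, :][ok]), 1)
    # horizontal: i = left, j = right
    if sub.shape[1] > 1:
        ok = mask[:, :-1] & mask[:, 1:]
        np.add.at(out, (sub[:, :-1][ok], sub[:, 1:][ok]), 1)
    return out


def tabulate_frequency(
    raster: GrayLevelRaster,
    region: Region | None = None,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
) -> FrequencyTabulation:
    """Frequency tabulation of a rectangular region (whole raster if None).

    An empty included set is legal and yields ``total == 0``, which every
    downstream metric maps to a missing value.
    """
    return FrequencyTabulation(frequency_counts(raster, region, zero_policy), copy=False)


def tabulate_adjacency(
    raster: GrayLevelRaster,
    region: Region | None = None,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
) -> AdjacencyTabulation:
    """Adjacency tabulation of a rectangular region (whole raster if None)."""
    return AdjacencyTabulation(adjacency_counts(raster, region, zero_policy), copy=False)
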