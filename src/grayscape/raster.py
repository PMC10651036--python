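"""Raster data model: gray-level grids, quantization, missing data.

All analyses operate on a single currency: a 2D grid of integer *gray
levels* in ``[0, 100]`` plus a reserved missing-data code.  Categorical
(nominal) maps use the levels directly as class codes; numeric maps must
first be quantized ("binned") onto the gray-level scale with
:func:`quantize`.  Quantization is always an explicit step — no function in
this package bins silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reserved missing-data code, outside the valid gray-level range [0, 100].
#: Fixed at 255 — the conventional byte nodata — so 8-bit I/O round-trips.
MISSING = 255

#: Inclusive gray-level bounds.
GRAY_MIN, GRAY_MAX = 0, 100

#: Number of gray-level slots (dense axis length used by all tabulations).
N_LEVELS = GRAY_MAX - GRAY_MIN + 1


@dataclass(frozen=True)
class ZeroPolicy:
    """Whether gray level 0 is treated as missing in all tabulations.

    Level 0 often encodes "no data" or background in quantized products
    (e.g. 0 % cover); excluding it drops those pixels from every frequency
    and adjacency count.
    """

    exclude_zero: bool = False

    def includes(self, value: int) -> bool:
        if value == MISSING:
            return False
        if self.exclude_zero and value == 0:
            return False
        return True


INCLUDE_ZERO = ZeroPolicy(exclude_zero=False)
EXCLUDE_ZERO = ZeroPolicy(exclude_zero=True)


class GrayLevelRaster:
    """A 2D grid of integer gray levels in [0, 100] with a missing code.

    Parameters
    ----------
    values
        2D integer array.  Every element must be in ``[0, 100]`` or equal
        ``missing_code``.  Stored internally as ``uint8`` with missing
        pixels set to :data:`MISSING` (255).
    missing_code
        The value in ``values`` marking missing pixels (default 255).
    metadata
        Opaque pass-through metadata (e.g. georeferencing tags) preserved
        by the raster writers.
    """

    __slots__ = ("values", "metadata")

    def __init__(self, values, missing_code: int = MISSING, metadata: dict | None = None):
        arr = np.asarray(values)
        if arr.ndim != 2:
            raise ValueError(f"raster must be 2D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("raster must have at least one row and one column")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(
                "raster values must be integer-typed; quantize() numeric data first"
            )
        missing = arr == missing_code
        bad = ~missing & ((arr < GRAY_MIN) | (arr > GRAY_MAX))
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"value {arr[r, c]} at cell ({r}, {c}) outside [0, 100] and not "
                f"the missing code {missing_code}"
            )
        out = arr.astype(np.uint8, copy=True)
        out[missing] = MISSING
        out.flags.writeable = False
        self.values = out
        self.metadata = dict(metadata or {})

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_code(self) -> int:
        return MISSING

    def valid_mask(self, zero_policy: ZeroPolicy = INCLUDE_ZERO) -> np.ndarray:
        """Boolean mask of pixels included under the given zero policy."""
        mask = self.values != MISSING
        if zero_policy.exclude_zero:
            mask &= self.values != 0
        return mask

    def __eq__(self, other) -> bool:
        return isinstance(other, GrayLevelRaster) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        return f"GrayLevelRaster(shape={self.shape}, missing={int(np.sum(self.values == MISSING))})"


@dataclass(frozen=True)
class ValidationReport:
    """Summary of a raster's content; never raises."""

    n_rows: int
    n_cols: int
    n_pixels: int
    n_valid: int
    n_missing: int
    min_level: int | None
    max_level: int | None
    missing_fraction: float = field(init=False)

    def __post_init__(self):
        frac = self.n_missing / self.n_pixels if self.n_pixels else 0.0
        object.__setattr__(self, "missing_fraction", frac)


def validate(raster: GrayLevelRaster) -> ValidationReport:
    """Report pixel counts and the gray-level range of a raster."""
    vals = raster.values
    valid = vals != MISSING
    n_valid = int(valid.sum())
    if n_valid:
        present = vals[valid]
        lo, hi = int(present.min()), int(present.max())
    else:
        lo = hi = None
    return ValidationReport(
        n_rows=raster.n_rows,
        n_cols=raster.n_cols,
        n_pixels=vals.size,
        n_valid=n_valid,
        n_missing=vals.size - n_valid,
        min_level=lo,
        max_level=hi,
    )


def quantize(
    numeric_raster,
    source_range: tuple[float, float],
    n_bins: int = N_LEVELS,
    missing_value: float | None = None,
) -> GrayLevelRaster:
    """Quantize a numeric raster onto integer gray levels.

    Equal-width binning of ``source_range`` into ``n_bins`` bins mapped to
    gray levels ``0 .. n_bins-1``; the top bin is closed, so a value equal
    to the range maximum falls in the highest bin.  The mapping is monotone
    non-decreasing, and already-quantized integer data in ``[0, 100]``
    passed with ``source_range=(0, 100)`` and ``n_bins=101`` are returned
    unchanged.

    Parameters
    ----------
    numeric_raster
        2D real-valued array.  NaN cells and cells equal to
        ``missing_value`` map to the missing code.
    source_range
        ``(low, high)`` with ``high > low``; every non-missing value must
        lie inside it.
    n_bins
        Number of gray levels to produce, ``2 <= n_bins <= 101``.
    """
    lo, hi = float(source_range[0]), float(source_range[1])
    if not hi > lo:
        raise ValueError(f"source_range must have positive width, got ({lo}, {hi})")
    if not 2 <= n_bins <= N_LEVELS:
        raise ValueError(f"n_bins must be in [2, {N_LEVELS}], got {n_bins}")
    arr = np.asarray(numeric_raster, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"raster must be 2D, got shape {arr.shape}")
    missing = np.isnan(arr)
    if missing_value is not None:
        missing |= arr == missing_value
    bad = ~missing & ((arr < lo) | (arr > hi))
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"value {arr[r, c]} at cell ({r}, {c}) outside source_range ({lo}, {hi})"
        )
    width = (hi - lo) / n_bins
    levels = np.floor((arr - lo) / width)
    levels = np.clip(levels, 0, n_bins - 1)  # closes the top bin at hi
    out = np.where(missing, MISSING, levels).astype(np.uint8)
    return GrayLevelRaster(out)
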