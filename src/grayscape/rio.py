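"""Raster readers and writers.

GeoTIFF (single band, 8-bit unsigned) is the primary dialect, handled
through :mod:`tifffile`; the georeferencing tags of the source
(ModelPixelScale, ModelTiepoint, ModelTransformation, the GeoKey
directories, and GDAL_NODATA) are carried through as opaque metadata so
output maps stay registered to the input.  A headerless flat binary
8-bit format with explicit dimensions is supported for minimal
workflows.

Metric maps are written as 32-bit float bands (nodata -9999, declared in
the GDAL_NODATA tag) or, for metrics whose outputs fit a byte, as scaled
8-bit: unit-interval metrics are stored as ``round(100 * v)``,
integer/[0,100]-valued metrics as ``round(v)``, and 255 marks nodata.
Unbounded metrics (and the [-1,1]-bounded correlation) refuse byte mode.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .engine import MetricMap
from .metrics import METRICS, MetricSpec
from .raster import GRAY_MAX, GRAY_MIN, MISSING, GrayLevelRaster

#: Nodata value declared for float32 output bands.
FLOAT_NODATA = -9999.0

#: TIFF tag codes preserved verbatim from input to output (GeoTIFF
#: georeferencing plus the GDAL metadata pair).
_GEO_TAGS = (33550, 33922, 34264, 34735, 34736, 34737, 42112, 42113)


def _collect_geotags(page) -> dict:
    tags = {}
    for code in _GEO_TAGS:
        tag = page.tags.get(code)
        if tag is not None:
            tags[code] = (tag.code, tag.dtype, tag.count, tag.value, True)
    return tags


def _extratags(metadata: dict, nodata) -> list:
    out = []
    for code, entry in metadata.items():
        if not isinstance(code, int):
            continue
        if code == 42113:  # GDAL_NODATA is rewritten for the output band
            continue
        out.append(entry)
    if nodata is not None:
        nd = str(int(nodata)) if float(nodata).is_integer() else str(nodata)
        out.append((42113, "s", len(nd) + 1, nd, True))
    return out


def read_raster(
    path,
    nodata: int | None = None,
    rows: int | None = None,
    cols: int | None = None,
) -> GrayLevelRaster:
    """Read a gray-level raster.

    TIFF paths must hold a single 8-bit (or integer) band with values in
    ``[0, 100]`` plus the nodata code; a float-typed band is rejected
    with a pointer to :func:`grayscape.raster.quantize`.  Any other path
    is read as headerless flat binary 8-bit, which requires explicit
    ``rows`` and ``cols``.

    ``nodata`` overrides the file's declared nodata (GDAL_NODATA tag for
    TIFF, 255 otherwise).
    """
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            metadata = _collect_geotags(page)
            if nodata is None:
                tag = page.tags.get(42113)
                if tag is not None:
                    try:
                        nodata = int(float(str(tag.value).strip("\x00 ")))
                    except ValueError:
                        nodata = None
        if arr.ndim == 3:
            if arr.shape[2] == 1 or arr.shape[0] == 1:
                arr = arr.reshape(arr.shape[:2] if arr.shape[2] == 1 else arr.shape[1:])
            else:
                raise ValueError(
                    f"{path}: multi-band rasters are not supported (shape {arr.shape})"
                )
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single 2D band, got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.floating):
            raise TypeError(
                f"{path}: float-typed band; quantize() the numeric data onto "
                "gray levels [0, 100] first"
            )
    else:
        if rows is None or cols is None:
            raise ValueError(
                f"{path}: headerless binary input requires explicit rows and cols"
            )
        arr = np.fromfile(path, dtype=np.uint8)
        if arr.size != rows * cols:
            raise ValueError(
                f"{path}: file holds {arr.size} bytes, expected {rows * cols} "
                f"({rows} x {cols})"
            )
        arr = arr.reshape(rows, cols)
        metadata = {}
    if nodata is None:
        nodata = MISSING
    bad = (arr != nodata) & ((arr < GRAY_MIN) | (arr > GRAY_MAX))
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: value {arr[r, c]} at cell ({r}, {c}) outside "
            f"[0, 100] and not the nodata code {nodata}"
        )
    return GrayLevelRaster(arr, missing_code=int(nodata), metadata=metadata)


def write_raster(raster: GrayLevelRaster, path) -> None:
    """Write a gray-level raster as single-band 8-bit TIFF (nodata 255)."""
    tifffile.imwrite(
        str(path),
        raster.values,
        extratags=_extratags(raster.metadata, MISSING),
    )


def byte_eligible(spec: MetricSpec) -> bool:
    """Whether a metric's output can be stored in the scaled 8-bit form."""
    return spec.byte_scale is not None


def write_metric_map(mmap: MetricMap, path, precision: str = "float32") -> None:
    """Write a metric map as float32 (default) or scaled 8-bit TIFF."""
    if precision == "float32":
        out = mmap.values.astype(np.float32)
        out[np.isnan(out)] = FLOAT_NODATA
        tifffile.imwrite(
            str(path), out, extratags=_extratags(mmap.metadata, FLOAT_NODATA)
        )
        return
    if precision != "byte":
        raise ValueError(f"precision must be 'float32' or 'byte', got {precision!r}")
    spec = mmap.metric
    if spec.byte_scale is None:
        valid = sorted(i for i, s in METRICS.items() if s.byte_scale is not None)
        raise ValueError(
            f"metric {spec.id} ({spec.short_name}) has no 8-bit representation; "
            f"byte output is available for metrics {valid}"
        )
    scaled = np.round(mmap.values * spec.byte_scale)
    out = np.where(np.isnan(scaled), MISSING, scaled).astype(np.uint8)
    tifffile.imwrite(str(path), out, extratags=_extratags(mmap.metadata, MISSING))


def read_metric_map(path) -> tuple[np.ndarray, float | None]:
    """Read a written metric map back as (array, nodata); round-trips only."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        tag = page.tags.get(42113)
        nodata = None
        if tag is not None:
            try:
                nodata = float(str(tag.value).strip("\x00 "))
            except ValueError:
                nodata = None
    return arr, nodata
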