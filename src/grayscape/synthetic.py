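"""Reproducible synthetic rasters for testing and demonstration.

Each recipe describes a small raster with known structure: constant
patches, checkerboards, gradients, random categorical maps, random
binned-numeric surfaces, and block mosaics with missing holes.  The same
recipe and seed always produce the identical raster, so every test
fixture is generated at run time rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import MISSING, GrayLevelRaster, quantize

KINDS = (
    "constant",
    "checkerboard",
    "gradient",
    "random-categorical",
    "random-binned-numeric",
    "blocks-with-missing",
)


@dataclass(frozen=True)
class FixtureRecipe:
    """Description of one synthetic raster.

    ``levels`` is the gray-level alphabet the kind draws from (the
    constant value for "constant", the two alternating values for
    "checkerboard", the categorical alphabet otherwise); ``missing_frac``
    pokes that fraction of random holes into the result.
    """

    kind: str
    shape: tuple[int, int] = (20, 20)
    levels: tuple[int, ...] = (0, 1, 2, 3)
    missing_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; valid: {KINDS}")
        if not 0.0 <= self.missing_frac <= 1.0:
            raise ValueError(f"missing_frac must be in [0, 1], got {self.missing_frac}")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError(f"shape must be positive, got {self.shape}")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        for v in self.levels:
            if not 0 <= v <= 100:
                raise ValueError(f"gray level {v} outside [0, 100]")


def generate(recipe: FixtureRecipe) -> GrayLevelRaster:
    """Build the raster a recipe describes (deterministic in the seed)."""
    rng = np.random.default_rng(recipe.seed)
    rows, cols = recipe.shape
    kind = recipe.kind
    if kind == "constant":
        grid = np.full(recipe.shape, recipe.levels[0], dtype=np.uint8)
    elif kind == "checkerboard":
        a, b = recipe.levels[0], recipe.levels[-1]
        rr, cc = np.indices(recipe.shape)
        grid = np.where((rr + cc) % 2 == 0, a, b).astype(np.uint8)
    elif kind == "gradient":
        # left-to-right ramp over the full gray-level scale
        ramp = np.linspace(0.0, 1.0, cols)
        surface = np.tile(ramp, (rows, 1))
        return _with_missing(quantize(surface, (0.0, 1.0), 101), recipe, rng)
    elif kind == "random-categorical":
        grid = rng.choice(np.asarray(recipe.levels, dtype=np.uint8), size=recipe.shape)
    elif kind == "random-binned-numeric":
        # spatially smooth noise binned onto the gray-level scale
        coarse = rng.random((max(2, rows // 4), max(2, cols // 4)))
        ri = np.linspace(0, coarse.shape[0] - 1, rows)
        ci = np.linspace(0, coarse.shape[1] - 1, cols)
        surface = _bilinear(coarse, ri, ci)
        return _with_missing(quantize(surface, (0.0, 1.0), 101), recipe, rng)
    elif kind == "blocks-with-missing":
        block = max(2, min(rows, cols) // 4)
        br = (np.arange(rows) // block)[:, None]
        bc = (np.arange(cols) // block)[None, :]
        alphabet = np.asarray(recipe.levels, dtype=np.uint8)
        n_blocks = (br.max() + 1) * (bc.max() + 1)
        codes = rng.choice(alphabet, size=int(n_blocks))
        grid = codes[(br * (bc.max() + 1) + bc).ravel()].reshape(recipe.shape)
    else:  # pragma: no cover - guarded in the recipe
        raise AssertionError(kind)
    return _with_missing(GrayLevelRaster(grid), recipe, rng)


def _bilinear(coarse: np.ndarray, ri: np.ndarray, ci: np.ndarray) -> np.ndarray:
    r0 = np.floor(ri).astype(int)
    c0 = np.floor(ci).astype(int)
    r1 = np.minimum(r0 + 1, coarse.shape[0] - 1)
    c1 = np.minimum(c0 + 1, coarse.shape[1] - 1)
    fr = (ri - r0)[:, None]
    fc = (ci - c0)[None, :]
    top = coarse[np.ix_(r0, c0)] * (1 - fc) + coarse[np.ix_(r0, c1)] * fc
    bot = coarse[np.ix_(r1, c0)] * (1 - fc) + coarse[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def _with_missing(
    raster: GrayLevelRaster, recipe: FixtureRecipe, rng: np.random.Generator
) -> GrayLevelRaster:
    if recipe.missing_frac == 0.0:
        return raster
    grid = raster.values.copy()
    holes = rng.random(grid.shape) < recipe.missing_frac
    grid.flags.writeable = True
    grid[holes] = MISSING
    return GrayLevelRaster(grid)
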