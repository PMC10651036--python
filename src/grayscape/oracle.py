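"""Slow brute-force reference evaluator for every metric.

This module deliberately shares no code with the tabulation and metric
engine: it enumerates the included pixels and neighbor pairs of a region
with explicit Python loops, builds plain-dict distributions, and
transcribes each metric formula literally.  It exists purely as an
independent oracle for the test suite (regions up to ~50x50), never as a
computation path.

The one exception is the landscape-mosaic simplex partition: the oracle
recomputes the (p1, p2, p3) composition by loops but classifies it with
the same partition function as the engine, because the partition is a
single deterministic definition that is validated separately by
exhaustive enumeration.
"""

from __future__ import annotations

import math

from . import mosaic as _mosaic
from .metrics import TargetParams, get_metric
from .raster import INCLUDE_ZERO, MISSING, GrayLevelRaster, ZeroPolicy

__all__ = ["enumerate_pixels", "enumerate_pairs", "oracle_metric"]


def enumerate_pixels(raster, region=None, zero_policy=INCLUDE_ZERO):
    """List of included gray levels in the region, in scan order."""
    r0, r1, c0, c1 = region or (0, raster.n_rows, 0, raster.n_cols)
    vals = []
    for r in range(r0, r1):
        for c in range(c0, c1):
            v = int(raster.values[r, c])
            if zero_policy.includes(v):
                vals.append(v)
    return vals


def enumerate_pairs(raster, region=None, zero_policy=INCLUDE_ZERO):
    """List of ordered adjacency pairs (upper/left, lower/right).

    Implements the 2-neighbor rule: each pixel is paired with the pixel
    one below and the pixel one to the right; a pair is kept only when
    both members are inside the region and included by the zero policy.
    """
    r0, r1, c0, c1 = region or (0, raster.n_rows, 0, raster.n_cols)
    pairs = []
    for r in range(r0, r1):
        for c in range(c0, c1):
            v = int(raster.values[r, c])
            if not zero_policy.includes(v):
                continue
            if r + 1 < r1:
                w = int(raster.values[r + 1, c])
                if zero_policy.includes(w):
                    pairs.append((v, w))
            if c + 1 < c1:
                w = int(raster.values[r, c + 1])
                if zero_policy.includes(w):
                    pairs.append((v, w))
    return pairs


def _freq_dist(values):
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    n = len(values)
    return {v: k / n for v, k in counts.items()}, counts


def _pair_dist(pairs):
    counts = {}
    for ij in pairs:
        counts[ij] = counts.get(ij, 0) + 1
    n = len(pairs)
    return {ij: k / n for ij, k in counts.items()}, counts


def _unordered_dist(pairs):
    """p'(i, j) keyed by (min, max): off-diagonal mass folded together."""
    counts = {}
    for i, j in pairs:
        key = (i, j) if i <= j else (j, i)
        counts[key] = counts.get(key, 0) + 1
    n = len(pairs)
    return {ij: k / n for ij, k in counts.items()}


def oracle_metric(
    raster: GrayLevelRaster,
    region=None,
    metric_id: int = 1,
    zero_policy: ZeroPolicy = INCLUDE_ZERO,
    params: TargetParams | None = None,
    global_range: int | None = None,
):
    """Evaluate one metric by direct formula transcription.

    Returns a number, or None for a missing value (same guard semantics
    as the engine).  ``global_range`` must be supplied for metric 35.
    """
    spec = get_metric(metric_id)
    params = params or TargetParams()
    for name in spec.params_required:
        if getattr(params, name) is None:
            raise ValueError(f"metric {metric_id} requires parameter {name}")

    values = enumerate_pixels(raster, region, zero_policy)
    pairs = enumerate_pairs(raster, region, zero_policy)
    if spec.needs_frequency and not values:
        return None
    if spec.needs_adjacency and not pairs:
        return None

    if spec.needs_frequency:
        p, counts = _freq_dist(values)
        levels = sorted(p)
        ng = len(levels)
        mu = sum(i * pi for i, pi in p.items())
        var = sum((i - mu) ** 2 * pi for i, pi in p.items())
    if spec.needs_adjacency:
        pj, pair_counts = _pair_dist(pairs)
        pu = _unordered_dist(pairs)
        adj_levels = sorted({i for ij in pj for i in ij})
        adj_ng = len(adj_levels)
        px = {}
        py = {}
        for (i, j), pij in pj.items():
            px[i] = px.get(i, 0.0) + pij
            py[j] = py.get(j, 0.0) + pij
        mu_x = sum(i * v for i, v in px.items())
        mu_y = sum(j * v for j, v in py.items())
        var_x = sum((i - mu_x) ** 2 * v for i, v in px.items())
        var_y = sum((j - mu_y) ** 2 * v for j, v in py.items())
        p_diff = {}
        p_sum = {}
        for (i, j), pij in pj.items():
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + pij
            p_sum[i + j] = p_sum.get(i + j, 0.0) + pij

    m = metric_id
    if m == 1:
        return mu
    if m == 2:
        if adj_ng <= 1:
            return None
        return oracle_metric(raster, region, 4, zero_policy, params, global_range) / (
            2.0 * math.log(adj_ng)
        )
    if m == 3:
        if adj_ng <= 1:
            return None
        h = oracle_metric(raster, region, 5, zero_policy, params, global_range)
        return h / (math.log(adj_ng**2 + adj_ng) - math.log(2.0))
    if m == 4:
        return -sum(v * math.log(v) for v in pj.values() if v > 0)
    if m == 5:
        return -sum(v * math.log(v) for v in pu.values() if v > 0)
    if m == 6:
        return sum(v for (i, j), v in pj.items() if i == j)
    if m == 7:
        return -sum(v * math.log(v) for v in p.values() if v > 0)
    if m == 8:
        if ng <= 1:
            return None
        return oracle_metric(raster, region, 7, zero_policy, params) / math.log(ng)
    if m == 9:
        ordered = sorted(values)
        return ordered[(len(ordered) - 1) // 2]
    if m == 10:
        return 1.0 - sum(v * v for v in p.values())
    if m == 11:
        if ng <= 1:
            return None
        return oracle_metric(raster, region, 10, zero_policy, params) / (1.0 - 1.0 / ng)
    if m == 12:
        if adj_ng <= 1:
            return None
        d = oracle_metric(raster, region, 14, zero_policy, params)
        return d / (1.0 - 1.0 / adj_ng**2)
    if m == 13:
        if adj_ng <= 1:
            return None
        d = oracle_metric(raster, region, 15, zero_policy, params)
        return d / (1.0 - 2.0 / (adj_ng**2 + adj_ng))
    if m == 14:
        return 1.0 - sum(v * v for v in pj.values())
    if m == 15:
        return 1.0 - sum(v * v for v in pu.values())
    if m == 16:
        best = max(counts.values())
        return min(i for i, k in counts.items() if k == best)
    if m in (17, 18):
        p1 = p.get(1, 0.0)
        p2 = p.get(2, 0.0)
        p3 = p.get(3, 0.0)
        return _mosaic.classify_mosaic(p1, p2, p3, 19 if m == 17 else 103)
    if m == 19:
        return ng
    if m == 20:
        return max(p.values())
    if m == 21:
        return p.get(params.t1, 0.0)
    if m == 22:
        t1 = params.t1
        inv = sum(k for (i, j), k in pair_counts.items() if i == t1 or j == t1)
        return inv / len(pairs)
    if m in (23, 24):
        t1, t2 = params.t1, params.t2
        if t1 == t2:
            num = pair_counts.get((t1, t1), 0)
        else:
            num = pair_counts.get((t1, t2), 0) + pair_counts.get((t2, t1), 0)
        if m == 23:
            return num / len(pairs)
        denom = sum(k for (i, j), k in pair_counts.items() if i == t1 or j == t1)
        if denom == 0:
            return None
        return num / denom
    if m == 25:
        return math.sqrt(var)
    if m == 26:
        if mu <= 0:
            return None
        return 100.0 * math.sqrt(var) / mu
    if m == 27:
        return max(levels) - min(levels)
    if m == 28:
        return sum(abs(i - j) * v for (i, j), v in pj.items())
    if m == 29:
        return sum((i - j) ** 2 * v for (i, j), v in pj.items())
    if m == 30:
        return sum(v * v for v in pj.values())
    if m == 31:
        return sum(v * v for v in pu.values())
    if m == 32:
        return sum(v / (1.0 + (i - j) ** 2) for (i, j), v in pj.items())
    if m == 33:
        return sum(v / (1.0 + abs(i - j)) for (i, j), v in pj.items())
    if m == 34:
        return 1.0 - sum(abs(i - j) * v for (i, j), v in pj.items()) / 100.0
    if m == 35:
        if global_range is None:
            raise ValueError("metric 35 requires global_range")
        if global_range == 0:
            return None
        return 1.0 - sum(abs(i - j) * v for (i, j), v in pj.items()) / global_range
    if m == 36:
        r = max(adj_levels) - min(adj_levels)
        if r == 0:
            return None
        return 1.0 - sum(abs(i - j) * v for (i, j), v in pj.items()) / r
    if m == 37:
        return max(pj.values())
    if m == 38:
        return max(pu.values())
    if m == 39:
        return -sum(v * math.log(v) for v in p_diff.values() if v > 0)
    if m == 40:
        nk = len([v for v in p_diff.values() if v > 0])
        if nk <= 1:
            return None
        return oracle_metric(raster, region, 39, zero_policy, params) / math.log(nk)
    if m == 41:
        return -sum(v * math.log(v) for v in p_sum.values() if v > 0)
    if m == 42:
        nk = len([v for v in p_sum.values() if v > 0])
        if nk <= 1:
            return None
        return oracle_metric(raster, region, 41, zero_policy, params) / math.log(nk)
    if m == 43:
        return sum(i * j * v for (i, j), v in pj.items())
    if m == 44:
        sx, sy = math.sqrt(var_x), math.sqrt(var_y)
        if sx <= 0 or sy <= 0:
            return None
        return sum(
            ((i - mu_x) / sx) * ((j - mu_y) / sy) * v for (i, j), v in pj.items()
        )
    if m == 45:
        return sum((i + j - mu_x - mu_y) ** 3 * v for (i, j), v in pj.items())
    if m == 46:
        return sum((i + j - mu_x - mu_y) ** 4 * v for (i, j), v in pj.items())
    if m == 47:
        return math.sqrt(sum(i * i * v for i, v in p.items()))
    if m == 48:
        return sum(abs(i - mu) * v for i, v in p.items())
    if m == 49:
        return sum(v for k, v in p_diff.items() if k <= params.k_star)
    if m == 50:
        if var <= 0:
            return None
        return sum((i - mu) ** 3 * v for i, v in p.items()) / var**1.5
    if m == 51:
        if var <= 0:
            return None
        return sum((i - mu) ** 4 * v for i, v in p.items()) / var**2
    raise KeyError(f"unknown metric id {metric_id}")
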