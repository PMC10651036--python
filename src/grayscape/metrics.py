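"""Registry and evaluators for the 51 gray-level pattern metrics.

First-order metrics are functions of the gray-level frequency
distribution of the analysis region (mean, diversity, evenness, order
statistics, moments); second-order metrics are functions of the
gray-level adjacency (co-occurrence) matrix (entropy, contagion,
contrast, correlation, texture similarity, difference/sum-distribution
metrics).  Each metric has a fixed id (1-51) and short name, a declared
input-data applicability (nominal, ordinal, or all), and, where defined,
an output bound.

Logarithms are natural throughout.  Guard conditions (``Ng > 1`` for
evenness/equitability, ``sigma > 0`` for skewness/kurtosis, ``mu > 0``
for the coefficient of variation, ``sigma_x * sigma_y > 0`` for
correlation, a window range of zero for range-normalized similarity,
and an empty tabulation for everything) yield a *missing* value, never
an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import mosaic as _mosaic
from .raster import N_LEVELS
from .tabulation import AdjacencyTabulation, FrequencyTabulation

__all__ = [
    "MetricSpec",
    "TargetParams",
    "MetricValue",
    "METRICS",
    "get_metric",
    "list_metrics",
    "evaluate",
]

_LV = np.arange(N_LEVELS, dtype=np.float64)


@dataclass(frozen=True)
class TargetParams:
    """User-selected target parameters.

    ``t1``/``t2`` are target gray levels for the focal metrics (21-24);
    ``k_star`` is the cutoff level of the difference distribution for
    k-contagion (49).
    """

    t1: int | None = None
    t2: int | None = None
    k_star: int | None = None

    def __post_init__(self):
        for name, hi in (("t1", 100), ("t2", 100), ("k_star", 100)):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= hi):
                raise ValueError(f"{name} must be in [0, {hi}], got {v}")


@dataclass(frozen=True)
class MetricValue:
    """A metric evaluation: a number, or missing when a guard failed."""

    value: float | int | None
    is_missing: bool = False

    def __float__(self) -> float:
        if self.is_missing:
            return float("nan")
        return float(self.value)


_MISSING = MetricValue(None, is_missing=True)


@dataclass(frozen=True)
class MetricSpec:
    """Registry entry for one metric.

    ``needs`` is a subset of {"frequency", "adjacency"}; ``applicability``
    is "A" (all input), "N" (nominal only) or "O" (ordinal only);
    ``bounds`` is an inclusive output interval or None when unbounded;
    ``output`` is "real", "integer" or "nominal"; ``byte_scale`` is 100
    for unit-interval metrics stored as round(100 v) in 8-bit output, 1
    for integer/[0,100]-valued metrics stored as round(v), or None when
    the metric cannot be represented in a byte.
    """

    id: int
    short_name: str
    description: str
    needs: frozenset[str]
    applicability: str
    output: str
    bounds: tuple[float, float] | None
    params_required: tuple[str, ...] = ()
    byte_scale: int | None = None

    @property
    def needs_frequency(self) -> bool:
        return "frequency" in self.needs

    @property
    def needs_adjacency(self) -> bool:
        return "adjacency" in self.needs

    @property
    def needs_global_range(self) -> bool:
        return self.id == 35


# ---------------------------------------------------------------------------
# Evaluation context: lazy shared sub-expressions over the two tabulations.
# ---------------------------------------------------------------------------

class _Ctx:
    __slots__ = ("freq", "adj", "params", "global_range")

    def __init__(self, freq, adj, params, global_range):
        self.freq = freq
        self.adj = adj
        self.params = params
        self.global_range = global_range


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _freq_entropy(c: _Ctx) -> float:
    return _entropy(c.freq.p)


def _ordered_entropy(c: _Ctx) -> float:
    return _entropy(c.adj.p.ravel())


def _unordered_entropy(c: _Ctx) -> float:
    return _entropy(c.adj.p_unordered_upper.ravel())


def _ordered_uniformity(c: _Ctx) -> float:
    p = c.adj.p
    return float((p * p).sum())


def _unordered_uniformity(c: _Ctx) -> float:
    p = c.adj.p_unordered_upper
    return float((p * p).sum())


def _dissimilarity(c: _Ctx) -> float:
    ii, jj = np.nonzero(c.adj.counts)
    return float((np.abs(ii - jj) * c.adj.p[ii, jj]).sum())


def _t1_row_mass(c: _Ctx) -> int:
    """Total adjacencies involving t1 (symmetric-complete row of x')."""
    return int(c.adj.unordered[c.params.t1, :].sum())


def _pair_mass(c: _Ctx) -> int:
    """x(t1,t2) + x(t2,t1), or x(t1,t1) when the targets coincide."""
    t1, t2 = c.params.t1, c.params.t2
    if t1 == t2:
        return int(c.adj.counts[t1, t1])
    return int(c.adj.counts[t1, t2] + c.adj.counts[t2, t1])


# -- metric functions; return a float/int, or None for missing --------------

def _m1(c):  # Mean
    return c.freq.mean


def _m2(c):  # EvennessOrderedAdj
    ng = c.adj.n_levels
    if ng <= 1:
        return None
    return _ordered_entropy(c) / (2.0 * math.log(ng))


def _m3(c):  # EvennessUnorderedAdj
    ng = c.adj.n_levels
    if ng <= 1:
        return None
    return _unordered_entropy(c) / (math.log(ng * ng + ng) - math.log(2.0))


def _m4(c):  # EntropyOrderedAdj
    return _ordered_entropy(c)


def _m5(c):  # EntropyUnorderedAdj
    return _unordered_entropy(c)


def _m6(c):  # DiagonalContagion
    return float(np.trace(c.adj.p))


def _m7(c):  # ShannonDiversity
    return _freq_entropy(c)


def _m8(c):  # ShannonEvenness
    ng = c.freq.n_levels
    if ng <= 1:
        return None
    return _freq_entropy(c) / math.log(ng)


def _m9(c):  # Median
    return c.freq.median()


def _m10(c):  # GSDiversity
    p = c.freq.p
    return float(1.0 - (p * p).sum())


def _m11(c):  # GSEvenness
    ng = c.freq.n_levels
    if ng <= 1:
        return None
    return _m10(c) / (1.0 - 1.0 / ng)


def _m12(c):  # EquitabilityOrderedAdj
    ng = c.adj.n_levels
    if ng <= 1:
        return None
    return (1.0 - _ordered_uniformity(c)) / (1.0 - 1.0 / ng**2)


def _m13(c):  # EquitabilityUnorderedAdj
    ng = c.adj.n_levels
    if ng <= 1:
        return None
    return (1.0 - _unordered_uniformity(c)) / (1.0 - 2.0 / (ng**2 + ng))


def _m14(c):  # DiversityOrderedAdj
    return 1.0 - _ordered_uniformity(c)


def _m15(c):  # DiversityUnorderedAdj
    return 1.0 - _unordered_uniformity(c)


def _m16(c):  # Majority
    return c.freq.majority()


def _mosaic_value(c, variant):
    p = c.freq.p
    code = _mosaic.classify_mosaic(float(p[1]), float(p[2]), float(p[3]), variant)
    return code  # None when levels outside {1,2,3} are present


def _m17(c):  # LandscapeMosaic19
    return _mosaic_value(c, 19)


def _m18(c):  # LandscapeMosaic103
    return _mosaic_value(c, 103)


def _m19(c):  # NumberGrayLevels
    return c.freq.n_levels


def _m20(c):  # MaxAreaDensity
    return float(c.freq.p.max())


def _m21(c):  # FocalAreaDensity
    return float(c.freq.p[c.params.t1])


def _m22(c):  # FocalAdjT1
    return _t1_row_mass(c) / c.adj.total


def _m23(c):  # FocalAdjT1andT2
    return _pair_mass(c) / c.adj.total


def _m24(c):  # FocalAdjT1givenT2
    denom = _t1_row_mass(c)
    if denom == 0:
        return None
    return _pair_mass(c) / denom


def _m25(c):  # StandardDeviation (population)
    return math.sqrt(c.freq.variance)


def _m26(c):  # CoefficientVariation
    mu = c.freq.mean
    if mu <= 0:
        return None
    return 100.0 * _m25(c) / mu


def _m27(c):  # Range
    return c.freq.level_range


def _m28(c):  # Dissimilarity
    return _dissimilarity(c)


def _m29(c):  # Contrast
    ii, jj = np.nonzero(c.adj.counts)
    return float((((ii - jj) ** 2) * c.adj.p[ii, jj]).sum())


def _m30(c):  # UniformityOrderedAdj
    return _ordered_uniformity(c)


def _m31(c):  # UniformityUnorderedAdj
    return _unordered_uniformity(c)


def _m32(c):  # Homogeneity
    ii, jj = np.nonzero(c.adj.counts)
    return float((c.adj.p[ii, jj] / (1.0 + (ii - jj) ** 2)).sum())


def _m33(c):  # InverseDifference
    ii, jj = np.nonzero(c.adj.counts)
    return float((c.adj.p[ii, jj] / (1.0 + np.abs(ii - jj))).sum())


def _m34(c):  # SimilarityRMax
    return 1.0 - _dissimilarity(c) / 100.0


def _m35(c):  # SimilarityRGlobal
    if c.global_range is None:
        raise ValueError("SimilarityRGlobal requires the map-wide gray-level range")
    if c.global_range == 0:
        return None
    return 1.0 - _dissimilarity(c) / c.global_range


def _m36(c):  # SimilarityRWindow
    r = c.adj.level_range
    if not r:
        return None
    return 1.0 - _dissimilarity(c) / r


def _m37(c):  # DominanceOrderedAdj
    return float(c.adj.p.max())


def _m38(c):  # DominanceUnorderedAdj
    return float(c.adj.p_unordered_upper.max())


def _m39(c):  # DifferenceEntropy
    return _entropy(c.adj.diff_dist)


def _m40(c):  # DifferenceEvenness
    nk = c.adj.n_k_diff
    if nk <= 1:
        return None
    return _m39(c) / math.log(nk)


def _m41(c):  # SumEntropy
    return _entropy(c.adj.sum_dist)


def _m42(c):  # SumEvenness
    nk = c.adj.n_k_sum
    if nk <= 1:
        return None
    return _m41(c) / math.log(nk)


def _m43(c):  # AutoCorrelation
    ii, jj = np.nonzero(c.adj.counts)
    return float(((ii * jj) * c.adj.p[ii, jj]).sum())


def _m44(c):  # Correlation
    sx = math.sqrt(c.adj.var_x)
    sy = math.sqrt(c.adj.var_y)
    if sx <= 0 or sy <= 0:
        return None
    ii, jj = np.nonzero(c.adj.counts)
    z = ((ii - c.adj.mu_x) / sx) * ((jj - c.adj.mu_y) / sy)
    return float((z * c.adj.p[ii, jj]).sum())


def _cluster_moment(c, power):
    ii, jj = np.nonzero(c.adj.counts)
    d = ii + jj - c.adj.mu_x - c.adj.mu_y
    return float(((d**power) * c.adj.p[ii, jj]).sum())


def _m45(c):  # ClusterShade
    return _cluster_moment(c, 3)


def _m46(c):  # ClusterProminence
    return _cluster_moment(c, 4)


def _m47(c):  # RootMeanSquare
    return math.sqrt(float((_LV**2) @ c.freq.p))


def _m48(c):  # AverageAbsDeviation
    return float(np.abs(_LV - c.freq.mean) @ c.freq.p)


def _m49(c):  # kContagion
    # accumulate integer counts so the value is exactly non-decreasing in k*
    ii, jj = np.nonzero(c.adj.counts)
    mass = int(c.adj.counts[ii, jj][np.abs(ii - jj) <= c.params.k_star].sum())
    return mass / c.adj.total


def _central_moment_ratio(c, power):
    mu = c.freq.mean
    sigma = math.sqrt(c.freq.variance)
    if sigma <= 0:
        return None
    m = float(((_LV - mu) ** power) @ c.freq.p)
    return m / sigma**power


def _m50(c):  # Skewness
    return _central_moment_ratio(c, 3)


def _m51(c):  # Kurtosis
    return _central_moment_ratio(c, 4)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_F = frozenset({"frequency"})
_A = frozenset({"adjacency"})

# (id, short_name, description, needs, applicability, output, bounds,
#  params, byte_scale, function)
_TABLE = [
    (1, "Mean", "mean gray level", _F, "O", "real", (0, 100), (), 1, _m1),
    (2, "EvennessOrderedAdj", "entropy of ordered adjacencies / 2 log Ng", _A, "A", "real", (0, 1), (), 100, _m2),
    (3, "EvennessUnorderedAdj", "entropy of unordered adjacencies / log((Ng^2+Ng)/2)", _A, "A", "real", (0, 1), (), 100, _m3),
    (4, "EntropyOrderedAdj", "Shannon entropy of the ordered adjacency matrix", _A, "A", "real", None, (), None, _m4),
    (5, "EntropyUnorderedAdj", "Shannon entropy of the unordered adjacency matrix", _A, "A", "real", None, (), None, _m5),
    (6, "DiagonalContagion", "proportion of like adjacencies (matrix trace)", _A, "A", "real", (0, 1), (), 100, _m6),
    (7, "ShannonDiversity", "Shannon entropy of gray-level frequencies", _F, "A", "real", None, (), None, _m7),
    (8, "ShannonEvenness", "Shannon diversity / log Ng", _F, "A", "real", (0, 1), (), 100, _m8),
    (9, "Median", "median gray level (lower middle on even counts)", _F, "O", "integer", (0, 100), (), 1, _m9),
    (10, "GSDiversity", "Gini-Simpson diversity of gray levels", _F, "A", "real", (0, 1), (), 100, _m10),
    (11, "GSEvenness", "Gini-Simpson diversity / (1 - 1/Ng)", _F, "A", "real", (0, 1), (), 100, _m11),
    (12, "EquitabilityOrderedAdj", "ordered-adjacency diversity / (1 - 1/Ng^2)", _A, "A", "real", (0, 1), (), 100, _m12),
    (13, "EquitabilityUnorderedAdj", "unordered-adjacency diversity / (1 - 2/(Ng^2+Ng))", _A, "A", "real", (0, 1), (), 100, _m13),
    (14, "DiversityOrderedAdj", "Gini-Simpson diversity of ordered adjacencies", _A, "A", "real", (0, 1), (), 100, _m14),
    (15, "DiversityUnorderedAdj", "Gini-Simpson diversity of unordered adjacencies", _A, "A", "real", (0, 1), (), 100, _m15),
    (16, "Majority", "most frequent gray level (smallest on ties)", _F, "A", "integer", (0, 100), (), 1, _m16),
    (17, "LandscapeMosaic19", "ternary 19-class mosaic of p(1),p(2),p(3)", _F, "N", "nominal", (1, 19), (), 1, _m17),
    (18, "LandscapeMosaic103", "ternary 103-class mosaic of p(1),p(2),p(3)", _F, "N", "nominal", (1, 103), (), 1, _m18),
    (19, "NumberGrayLevels", "number of gray levels present (Ng)", _F, "A", "integer", (1, 100), (), 1, _m19),
    (20, "MaxAreaDensity", "maximum frequency proportion", _F, "A", "real", (0, 1), (), 100, _m20),
    (21, "FocalAreaDensity", "proportion of target level t1", _F, "A", "real", (0, 1), ("t1",), 100, _m21),
    (22, "FocalAdjT1", "proportion of adjacencies involving t1", _A, "A", "real", (0, 1), ("t1",), 100, _m22),
    (23, "FocalAdjT1andT2", "proportion of adjacencies between t1 and t2", _A, "A", "real", (0, 1), ("t1", "t2"), 100, _m23),
    (24, "FocalAdjT1givenT2", "t1-t2 adjacencies among adjacencies involving t1", _A, "A", "real", (0, 1), ("t1", "t2"), 100, _m24),
    (25, "StandardDeviation", "population standard deviation of gray levels", _F, "O", "real", (0, 100), (), 1, _m25),
    (26, "CoefficientVariation", "100 * standard deviation / mean", _F, "O", "real", None, (), None, _m26),
    (27, "Range", "max - min gray level", _F, "O", "integer", (0, 100), (), 1, _m27),
    (28, "Dissimilarity", "mean absolute gray-level difference of adjacencies", _A, "O", "real", None, (), None, _m28),
    (29, "Contrast", "mean squared gray-level difference of adjacencies", _A, "O", "real", None, (), None, _m29),
    (30, "UniformityOrderedAdj", "angular second moment, ordered adjacencies", _A, "A", "real", (0, 1), (), 100, _m30),
    (31, "UniformityUnorderedAdj", "angular second moment, unordered adjacencies", _A, "A", "real", (0, 1), (), 100, _m31),
    (32, "Homogeneity", "inverse difference moment", _A, "O", "real", (0, 1), (), 100, _m32),
    (33, "InverseDifference", "inverse absolute difference", _A, "O", "real", (0, 1), (), 100, _m33),
    (34, "SimilarityRMax", "1 - dissimilarity / 100", _A, "O", "real", (0, 1), (), 100, _m34),
    (35, "SimilarityRGlobal", "1 - dissimilarity / global gray-level range", _A, "O", "real", (0, 1), (), 100, _m35),
    (36, "SimilarityRWindow", "1 - dissimilarity / window gray-level range", _A, "O", "real", (0, 1), (), 100, _m36),
    (37, "DominanceOrderedAdj", "maximum ordered adjacency proportion", _A, "A", "real", (0, 1), (), 100, _m37),
    (38, "DominanceUnorderedAdj", "maximum unordered adjacency proportion", _A, "A", "real", (0, 1), (), 100, _m38),
    (39, "DifferenceEntropy", "entropy of the difference distribution", _A, "O", "real", None, (), None, _m39),
    (40, "DifferenceEvenness", "difference entropy / log Nk", _A, "O", "real", (0, 1), (), 100, _m40),
    (41, "SumEntropy", "entropy of the sum distribution", _A, "O", "real", None, (), None, _m41),
    (42, "SumEvenness", "sum entropy / log Nk", _A, "O", "real", (0, 1), (), 100, _m42),
    (43, "AutoCorrelation", "mean product of adjacent gray levels", _A, "O", "real", None, (), None, _m43),
    (44, "Correlation", "Pearson correlation of adjacent gray levels", _A, "O", "real", (-1, 1), (), None, _m44),
    (45, "ClusterShade", "third central cluster moment", _A, "O", "real", None, (), None, _m45),
    (46, "ClusterProminence", "fourth central cluster moment", _A, "O", "real", None, (), None, _m46),
    (47, "RootMeanSquare", "root mean square gray level", _F, "O", "real", None, (), None, _m47),
    (48, "AverageAbsDeviation", "mean absolute deviation from the mean", _F, "O", "real", None, (), None, _m48),
    (49, "kContagion", "difference-distribution mass at or below k*", _A, "O", "real", (0, 1), ("k_star",), 100, _m49),
    (50, "Skewness", "standardized third central moment", _F, "O", "real", None, (), None, _m50),
    (51, "Kurtosis", "standardized fourth central moment", _F, "O", "real", None, (), None, _m51),
]

METRICS: dict[int, MetricSpec] = {}
_FUNCS: dict[int, object] = {}
for _id, _name, _desc, _needs, _app, _out, _bounds, _params, _scale, _fn in _TABLE:
    METRICS[_id] = MetricSpec(
        id=_id,
        short_name=_name,
        description=_desc,
        needs=_needs,
        applicability=_app,
        output=_out,
        bounds=_bounds,
        params_required=_params,
        byte_scale=_scale,
    )
    _FUNCS[_id] = _fn
del _id, _name, _desc, _needs, _app, _out, _bounds, _params, _scale, _fn


def get_metric(metric_id: int) -> MetricSpec:
    try:
        return METRICS[metric_id]
    except KeyError:
        raise KeyError(f"unknown metric id {metric_id}; valid ids are 1..51") from None


def list_metrics() -> list[MetricSpec]:
    """The full catalogue, ordered by metric id."""
    return [METRICS[i] for i in sorted(METRICS)]


def check_params(spec: MetricSpec, params: TargetParams | None) -> TargetParams:
    """Validate that the metric's required target parameters are present."""
    params = params or TargetParams()
    for name in spec.params_required:
        if getattr(params, name) is None:
            raise ValueError(
                f"metric {spec.id} ({spec.short_name}) requires parameter {name}"
            )
    return params


def evaluate(
    metric: int | MetricSpec,
    freq: FrequencyTabulation | None = None,
    adj: AdjacencyTabulation | None = None,
    params: TargetParams | None = None,
    global_range: int | None = None,
) -> MetricValue:
    """Evaluate one metric on pre-built tabulations.

    Supply the tabulation(s) the metric needs (``spec.needs``); an empty
    required tabulation — or any formula guard — yields a missing value.
    ``global_range`` is the map-wide gray-level range required by metric
    35 only.
    """
    spec = metric if isinstance(metric, MetricSpec) else get_metric(metric)
    params = check_params(spec, params)
    if spec.needs_frequency:
        if freq is None:
            raise ValueError(f"metric {spec.id} requires a frequency tabulation")
        if freq.total == 0:
            return _MISSING
    if spec.needs_adjacency:
        if adj is None:
            raise ValueError(f"metric {spec.id} requires an adjacency tabulation")
        if adj.total == 0:
            return _MISSING
    out = _FUNCS[spec.id](_Ctx(freq, adj, params, global_range))
    if out is None:
        return _MISSING
    return MetricValue(out)
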