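"""Metric registry, closed-form cases, guards, bounds, and identities."""

import math

import numpy as np
import pytest

from grayscape import (
    EXCLUDE_ZERO,
    INCLUDE_ZERO,
    GrayLevelRaster,
    TargetParams,
    evaluate,
    get_metric,
    list_metrics,
    tabulate_adjacency,
    tabulate_frequency,
)
from grayscape.metrics import METRICS
from grayscape.tabulation import AdjacencyTabulation
from tests.conftest import random_fixture


def _tabs(raster, policy=INCLUDE_ZERO, region=None):
    return (
        tabulate_frequency(raster, region, policy),
        tabulate_adjacency(raster, region, policy),
    )


def _value(metric_id, raster, policy=INCLUDE_ZERO, **kw):
    ft, at = _tabs(raster, policy)
    params = TargetParams(
        t1=kw.pop("t1", None), t2=kw.pop("t2", None), k_star=kw.pop("k_star", None)
    )
    return evaluate(metric_id, ft, at, params, **kw)


class TestRegistry:
    def test_catalogue_has_51_uniquely_numbered_metrics(self):
        cat = list_metrics()
        assert len(cat) == 51
        assert [m.id for m in cat] == list(range(1, 52))

    @pytest.mark.parametrize(
        "mid,name",
        [
            (1, "Mean"), (2, "EvennessOrderedAdj"), (3, "EvennessUnorderedAdj"),
            (4, "EntropyOrderedAdj"), (9, "Median"), (10, "GSDiversity"),
            (16, "Majority"), (17, "LandscapeMosaic19"), (18, "LandscapeMosaic103"),
            (19, "NumberGrayLevels"), (25, "StandardDeviation"), (29, "Contrast"),
            (32, "Homogeneity"), (44, "Correlation"), (49, "kContagion"),
            (51, "Kurtosis"),
        ],
    )
    def test_short_names(self, mid, name):
        assert get_metric(mid).short_name == name

    def test_needs_declared_per_metric_family(self):
        assert get_metric(2).needs_adjacency and not get_metric(2).needs_frequency
        assert get_metric(3).needs_adjacency
        assert get_metric(7).needs_frequency and not get_metric(7).needs_adjacency

    def test_unknown_id_is_an_error(self):
        with pytest.raises(KeyError):
            get_metric(52)

    def test_missing_required_target_parameter_is_an_error(self, demo_4x4):
        with pytest.raises(ValueError, match="t1"):
            _value(21, demo_4x4)
        with pytest.raises(ValueError, match="k_star"):
            _value(49, demo_4x4)


class TestClosedFormCases:
    """Hand-derivable values on degenerate and symmetric windows."""

    def test_constant_window(self, constant_40):
        assert _value(1, constant_40).value == 40.0
        assert _value(6, constant_40).value == 1.0  # all adjacencies on diagonal
        assert _value(29, constant_40).value == 0.0
        assert _value(32, constant_40).value == 1.0
        assert _value(34, constant_40).value == 1.0
        assert _value(9, constant_40).value == 40
        assert _value(23, constant_40, t1=40, t2=40).value == 1.0

    def test_two_equal_levels_gini_simpson(self):
        grid = np.repeat([[10] * 5 + [20] * 5], 4, axis=0).astype(np.uint8)
        r = GrayLevelRaster(grid)
        assert _value(10, r).value == pytest.approx(0.5)  # 1 - 2 * 0.5^2

    def test_equal_frequencies_maximize_shannon_evenness(self):
        grid = np.array([[i] * 4 for i in (5, 9, 33, 70)], dtype=np.uint8)
        assert _value(8, GrayLevelRaster(grid)).value == pytest.approx(1.0)

    def test_number_of_gray_levels(self):
        grid = np.array([[3, 7], [9, 3]], dtype=np.uint8)
        assert _value(19, GrayLevelRaster(grid)).value == 3

    def test_full_difference_mass_gives_unit_k_contagion(self, demo_4x4):
        assert _value(49, demo_4x4, k_star=100).value == pytest.approx(1.0)

    def test_symmetric_frequency_distribution_has_zero_skewness(self):
        grid = np.array([[10, 20, 30, 20, 10, 30]], dtype=np.uint8)
        assert _value(50, GrayLevelRaster(grid)).value == pytest.approx(0.0)

    def test_median_even_count_takes_lower_middle(self):
        r = GrayLevelRaster(np.array([[1, 2, 3, 4]], dtype=np.uint8))
        assert _value(9, r).value == 2

    def test_majority_tie_breaks_to_smallest_level(self):
        r = GrayLevelRaster(np.array([[9, 9, 4, 4, 7]], dtype=np.uint8))
        assert _value(16, r).value == 4

    def test_checkerboard_focal_adjacency(self):
        rr, cc = np.indices((6, 6))
        r = GrayLevelRaster(np.where((rr + cc) % 2 == 0, 10, 90).astype(np.uint8))
        assert _value(22, r, t1=10).value == 1.0  # every pair involves 10
        assert _value(23, r, t1=10, t2=90).value == 1.0
        assert _value(24, r, t1=10, t2=90).value == 1.0


class TestGuards:
    """Guard conditions produce missing values, never exceptions."""

    def test_single_level_evenness_guards(self, constant_40):
        for mid in (2, 3, 8, 11, 12, 13, 40, 42):
            assert _value(mid, constant_40).is_missing

    def test_zero_variance_moment_guards(self, constant_40):
        assert _value(50, constant_40).is_missing
        assert _value(51, constant_40).is_missing
        assert _value(44, constant_40).is_missing

    def test_zero_mean_cv_guard(self):
        r = GrayLevelRaster(np.zeros((4, 4), dtype=np.uint8))
        assert _value(26, r).is_missing

    def test_zero_window_range_similarity_guard(self, constant_40):
        assert _value(36, constant_40).is_missing

    def test_empty_tabulation_is_missing_for_every_metric(self):
        r = GrayLevelRaster(np.zeros((4, 4), dtype=np.uint8))
        params = TargetParams(t1=1, t2=2, k_star=10)
        ft, at = _tabs(r, EXCLUDE_ZERO)
        assert ft.total == 0 and at.total == 0
        for spec in list_metrics():
            assert evaluate(spec, ft, at, params, global_range=5).is_missing

    def test_focal_denominator_guard(self, demo_4x4):
        # t1 = 9 never occurs: metric 24's denominator is zero
        assert _value(24, demo_4x4, t1=9, t2=1).is_missing

    def test_mosaic_missing_when_levels_outside_1_to_3(self, demo_4x4):
        r = GrayLevelRaster(np.array([[1, 2], [3, 4]], dtype=np.uint8))
        assert _value(17, r).is_missing
        assert _value(17, demo_4x4).value is not None  # levels {1,2,3} only


BOUNDED_IDS = sorted(i for i, s in METRICS.items() if s.bounds is not None)


@pytest.mark.parametrize("seed", range(6))
def test_bounds_hold_on_random_windows(seed):
    """Every bounded metric stays inside its declared output interval."""
    r = random_fixture(seed, shape=(12, 12), levels=(0, 1, 2, 3, 25, 60, 100))
    policy = EXCLUDE_ZERO if seed % 2 else INCLUDE_ZERO
    ft, at = _tabs(r, policy)
    params = TargetParams(t1=2, t2=60, k_star=40)
    for mid in BOUNDED_IDS:
        spec = METRICS[mid]
        mv = evaluate(spec, ft, at, params, global_range=100)
        if mv.is_missing:
            continue
        lo, hi = spec.bounds
        assert lo - 1e-9 <= float(mv.value) <= hi + 1e-9, (mid, mv.value)


@pytest.mark.parametrize("seed", range(4))
def test_compositional_identities(seed):
    """Evenness metrics equal their entropy/diversity parents, normalized."""
    r = random_fixture(seed, shape=(12, 12))
    ft, at = _tabs(r)
    def v(mid):
        return float(evaluate(mid, ft, at))
    assert v(2) == pytest.approx(v(4) / (2 * math.log(at.n_levels)), rel=1e-12)
    assert v(3) == pytest.approx(
        v(5) / (math.log(at.n_levels**2 + at.n_levels) - math.log(2)), rel=1e-12
    )
    assert v(8) == pytest.approx(v(7) / math.log(ft.n_levels), rel=1e-12)
    assert v(11) == pytest.approx(v(10) / (1 - 1 / ft.n_levels), rel=1e-12)
    assert v(14) == pytest.approx(1 - v(30), rel=1e-12)
    assert v(15) == pytest.approx(1 - v(31), rel=1e-12)
    assert v(40) == pytest.approx(v(39) / math.log(at.n_k_diff), rel=1e-12)
    assert v(42) == pytest.approx(v(41) / math.log(at.n_k_sum), rel=1e-12)


def test_symmetric_matrix_entropy_relation():
    """For a symmetric ordered matrix, H_unordered = H_ordered - p_offdiag * log 2."""
    rng = np.random.default_rng(5)
    counts = np.zeros((101, 101), dtype=np.int64)
    block = rng.integers(0, 30, (8, 8))
    counts[:8, :8] = block + block.T  # symmetric by construction
    at = AdjacencyTabulation(counts)
    h_ord = float(evaluate(4, adj=at))
    h_unord = float(evaluate(5, adj=at))
    p_offdiag = 1.0 - float(evaluate(6, adj=at))
    assert h_unord == pytest.approx(h_ord - p_offdiag * math.log(2), rel=1e-12)


def test_k_contagion_monotone_in_k_star(demo_4x4):
    ft, at = _tabs(demo_4x4)
    vals = [float(evaluate(49, ft, at, TargetParams(k_star=k))) for k in range(101)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert vals[-1] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(4))
def test_similarity_ordering_by_normalizing_range(seed):
    """Similarity grows with the normalizing range: R_max >= R_global >= R_window."""
    r = random_fixture(seed, shape=(10, 10), levels=(5, 20, 40, 70), missing=0.05)
    ft, at = _tabs(r)
    window_range = at.level_range
    global_range = ft.level_range
    s_max = float(evaluate(34, adj=at))
    s_glob = float(evaluate(35, adj=at, global_range=global_range))
    s_win = float(evaluate(36, adj=at))
    assert window_range <= global_range <= 100
    assert s_max >= s_glob >= s_win - 1e-12


def test_correlation_matches_direct_pair_summation():
    """Independent check of metric 44 by summation over the raw pair list."""
    from grayscape.oracle import enumerate_pairs

    r = random_fixture(11, shape=(15, 15), levels=(3, 17, 42, 88), missing=0.1)
    pairs = enumerate_pairs(r)
    n = len(pairs)
    mu_x = sum(a for a, _ in pairs) / n
    mu_y = sum(b for _, b in pairs) / n
    sx = math.sqrt(sum((a - mu_x) ** 2 for a, _ in pairs) / n)
    sy = math.sqrt(sum((b - mu_y) ** 2 for _, b in pairs) / n)
    expected = sum(((a - mu_x) / sx) * ((b - mu_y) / sy) for a, b in pairs) / n
    assert float(_value(44, r)) == pytest.approx(expected, rel=1e-9)
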