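"""Frequency and adjacency tabulations and their derived distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from grayscape import (
    EXCLUDE_ZERO,
    INCLUDE_ZERO,
    MISSING,
    AdjacencyTabulation,
    GrayLevelRaster,
    collapse_unordered,
    tabulate_adjacency,
    tabulate_frequency,
)
from grayscape.oracle import enumerate_pairs, enumerate_pixels
from tests.conftest import random_fixture


class TestFrequency:
    def test_full_4x4_counts_16_pixels(self, demo_4x4):
        assert tabulate_frequency(demo_4x4).total == 16

    def test_constant_region(self):
        r = GrayLevelRaster(np.full((3, 3), 7))
        ft = tabulate_frequency(r)
        assert ft.counts[7] == 9
        assert (ft.n_levels, ft.mean, ft.variance) == (1, 7.0, 0.0)

    def test_zero_exclusion_drops_only_zeros(self):
        grid = np.zeros((10, 10), dtype=np.uint8)
        grid[5:, :] = 100
        ft = tabulate_frequency(GrayLevelRaster(grid), None, EXCLUDE_ZERO)
        assert (ft.total, ft.n_levels) == (50, 1)

    def test_empty_region_totals_zero(self):
        r = GrayLevelRaster(np.full((4, 4), MISSING))
        assert tabulate_frequency(r).total == 0


class TestAdjacency:
    def test_full_4x4_counts_24_adjacencies(self, demo_4x4):
        assert tabulate_adjacency(demo_4x4).total == 24

    def test_single_pixel_has_no_pairs(self, demo_4x4):
        assert tabulate_adjacency(demo_4x4, (0, 1, 0, 1)).total == 0

    def test_constant_3x3_region(self):
        r = GrayLevelRaster(np.full((3, 3), 5))
        at = tabulate_adjacency(r)
        assert at.total == 12  # 2 * n * (n - 1) for n = 3
        assert at.p[5, 5] == 1.0

    def test_pair_dropped_when_either_member_missing(self):
        grid = np.array([[1, MISSING], [2, 3]], dtype=np.uint8)
        at = tabulate_adjacency(GrayLevelRaster(grid))
        # surviving pairs: (1,2) vertical and (2,3) horizontal
        assert at.total == 2
        assert at.counts[1, 2] == 1 and at.counts[2, 3] == 1

    def test_orientation_upper_left_is_row_index(self):
        grid = np.array([[2, 5]], dtype=np.uint8)
        at = tabulate_adjacency(GrayLevelRaster(grid))
        assert at.counts[2, 5] == 1 and at.counts[5, 2] == 0


class TestCollapse:
    def test_definitional_sum(self):
        counts = np.zeros((101, 101), dtype=np.int64)
        counts[2, 5] = 3
        counts[5, 2] = 4
        x = collapse_unordered(AdjacencyTabulation(counts))
        assert x[2, 5] == 7 and x[5, 2] == 0

    def test_diagonal_only_matrix_unchanged(self):
        counts = np.zeros((101, 101), dtype=np.int64)
        np.fill_diagonal(counts[:10, :10], np.arange(10))
        assert np.array_equal(collapse_unordered(AdjacencyTabulation(counts)), counts)

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(42)
        counts = np.zeros((101, 101), dtype=np.int64)
        counts[:10, :10] = rng.integers(0, 20, (10, 10))
        x = collapse_unordered(AdjacencyTabulation(counts))
        for i in range(101):
            for j in range(101):
                if j > i:
                    assert x[i, j] == counts[i, j] + counts[j, i]
                elif j == i:
                    assert x[i, j] == counts[i, i]
                else:
                    assert x[i, j] == 0


class TestDerivedDistributions:
    def test_constant_window(self):
        at = tabulate_adjacency(GrayLevelRaster(np.full((4, 4), 30)))
        assert at.diff_dist[0] == 1.0
        assert at.sum_dist[60] == 1.0

    def test_checkerboard_concentrates_difference_mass(self):
        rr, cc = np.indices((8, 8))
        grid = np.where((rr + cc) % 2 == 0, 10, 90).astype(np.uint8)
        at = tabulate_adjacency(GrayLevelRaster(grid))
        assert at.diff_dist[80] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_marginals_and_distributions_match_pair_enumeration(self, seed):
        r = random_fixture(seed, shape=(20, 20))
        at = tabulate_adjacency(r)
        pairs = enumerate_pairs(r)
        n = len(pairs)
        assert at.total == n
        for i in range(101):
            assert at.px[i] == pytest.approx(
                sum(1 for a, _ in pairs if a == i) / n, abs=1e-12
            )
            assert at.py[i] == pytest.approx(
                sum(1 for _, b in pairs if b == i) / n, abs=1e-12
            )
        for k in range(101):
            assert at.diff_dist[k] == pytest.approx(
                sum(1 for a, b in pairs if abs(a - b) == k) / n, abs=1e-12
            )
        for k in range(201):
            assert at.sum_dist[k] == pytest.approx(
                sum(1 for a, b in pairs if a + b == k) / n, abs=1e-12
            )

    def test_zero_exclusion_bounds_k_ranges(self):
        r = random_fixture(7, levels=(0, 1, 2, 99, 100), missing=0.0)
        at = tabulate_adjacency(r, None, EXCLUDE_ZERO)
        assert at.diff_dist[100] == 0.0  # |i-j| = 100 needs level 0
        assert at.sum_dist[0] == at.sum_dist[1] == 0.0  # i+j >= 2 without zeros


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    arrays(
        np.uint8,
        st.tuples(st.integers(1, 12), st.integers(1, 12)),
        elements=st.sampled_from([0, 1, 2, 3, 50, 100, MISSING]),
    ),
    st.booleans(),
)
def test_tabulation_invariants(grid, exclude_zero):
    """Totals, normalizations, and ordered/unordered mass agreement."""
    r = GrayLevelRaster(grid)
    policy = EXCLUDE_ZERO if exclude_zero else INCLUDE_ZERO
    ft = tabulate_frequency(r, None, policy)
    at = tabulate_adjacency(r, None, policy)
    assert ft.total == len(enumerate_pixels(r, None, policy))
    assert at.total == len(enumerate_pairs(r, None, policy))
    if not exclude_zero and not np.any(grid == MISSING):
        rows, cols = grid.shape
        assert at.total == rows * (cols - 1) + cols * (rows - 1)
    if ft.total:
        assert ft.p.sum() == pytest.approx(1.0, abs=1e-9)
    if at.total:
        assert at.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert at.p_unordered_upper.sum() == pytest.approx(1.0, abs=1e-9)
        assert at.diff_dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert at.sum_dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert at.px.sum() == pytest.approx(1.0, abs=1e-9)
        assert at.py.sum() == pytest.approx(1.0, abs=1e-9)
        assert at.unordered_upper.sum() == at.total
        assert np.array_equal(np.diag(at.unordered), np.diag(at.counts))
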