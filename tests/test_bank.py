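import itertools

import numpy as np
import pytest

from octad.backbone import RegionGrid
from octad.bank import (
    CoresetConfig,
    KnnConfig,
    NominalBank,
    build_bank,
    greedy_coreset,
    knn_avg_distance,
    score_regions_aligned,
    score_regions_global,
)
from octad.errors import ConfigurationError, InputError

from conftest import brute_knn_mean, make_bank, make_grid


class TestBuildBank:
    def test_counts_and_positions(self, rng):
        grids = [make_grid(rng, 4, 4, 3) for _ in range(3)]
        bank = build_bank(grids)
        assert bank.size == 48
        # independent per-position tally
        for r in range(4):
            for c in range(4):
                assert len(bank.position_slice(r, c)) == 3

    def test_single_cell_grid(self, rng):
        bank = build_bank([make_grid(rng, 1, 1, 5)])
        assert bank.size == 1
        assert tuple(bank.positions[0]) == (0, 0)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            build_bank([make_grid(rng, 2, 2, 3), make_grid(rng, 2, 2, 4)])


class TestKnnAvgDistance:
    def test_zero_for_duplicated_query(self):
        q = np.array([1.0, 2.0])
        bank = NominalBank(np.tile(q, (5, 1)), np.zeros((5, 2), int), (1, 1))
        assert knn_avg_distance(q, bank, KnnConfig(k=5)) == 0.0

    def test_one_dimensional_exhaustive_case(self):
        bank = NominalBank(np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [10.0]]),
                           np.zeros((6, 2), int), (1, 1))
        assert knn_avg_distance(np.array([0.0]), bank, KnnConfig(k=5)) == 2.0

    def test_default_k_is_five(self):
        assert KnnConfig().k == 5

    def test_k_exceeding_bank_rejected(self, small_bank):
        with pytest.raises(ConfigurationError):
            knn_avg_distance(np.zeros(4), small_bank, KnnConfig(k=51))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            bank = make_bank(rng, n=int(rng.integers(6, 40)), d=3)
            q = rng.normal(size=3)
            k = int(rng.integers(1, 6))
            got = knn_avg_distance(q, bank, KnnConfig(k=k))
            assert got == pytest.approx(brute_knn_mean(q, bank.vectors, k))


class TestGreedyCoreset:
    def test_full_budget_preserves_vector_set(self, rng):
        bank = make_bank(rng, n=20, d=3)
        out = greedy_coreset(bank, CoresetConfig(fraction=1.0, seed=0))
        assert out.is_coreset
        got = {tuple(v) for v in out.vectors}
        want = {tuple(v) for v in bank.vectors}
        assert got == want

    def test_three_point_line_achieves_optimal_radius(self):
        # brute force over all 2-subsets of {0,1,10}: optimal min-max radius is 1
        bank = NominalBank(np.array([[0.0], [1.0], [10.0]]), np.zeros((3, 2), int), (1, 1))
        out = greedy_coreset(bank, CoresetConfig(fraction=2 / 3, seed=0))
        assert out.size == 2
        radius = max(
            min(abs(v - s) for s in out.vectors.ravel()) for v in bank.vectors.ravel()
        )
        assert radius == 1.0

    def test_deterministic_given_seed(self, rng):
        bank = make_bank(rng, n=30, d=4)
        a = greedy_coreset(bank, CoresetConfig(fraction=0.3, seed=5))
        b = greedy_coreset(bank, CoresetConfig(fraction=0.3, seed=5))
        assert np.array_equal(a.vectors, b.vectors)

    def test_default_fraction_is_one_percent(self):
        assert CoresetConfig().fraction == 0.01

    def test_two_approximation_of_kcenter_optimum(self, rng):
        # greedy farthest-point is a classical 2-approximation; verify
        # against the brute-force optimum on small instances
        for trial in range(15):
            n = int(rng.integers(5, 12))
            budget = int(rng.integers(1, 5))
            pts = rng.normal(size=(n, 2))
            bank = NominalBank(pts, np.zeros((n, 2), int), (1, 1))
            out = greedy_coreset(bank, CoresetConfig(fraction=budget / n + 1e-9, seed=trial))
            assert out.size == budget
            dmat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            sel = [np.flatnonzero(np.isclose(pts, v).all(axis=1))[0]
                   for v in out.vectors]
            greedy_radius = dmat[:, sel].min(axis=1).max()
            opt = min(
                dmat[:, list(sub)].min(axis=1).max()
                for sub in itertools.combinations(range(n), budget)
            )
            assert greedy_radius <= 2 * opt + 1e-12

    def test_coreset_scores_dominate_full_bank_scores(self, rng):
        bank = make_bank(rng, n=60, d=3)
        core = greedy_coreset(bank, CoresetConfig(fraction=0.2, seed=1))
        for _ in range(10):
            q = rng.normal(size=3)
            assert knn_avg_distance(q, core, KnnConfig(k=3)) >= knn_avg_distance(
                q, bank, KnnConfig(k=3)
            ) - 1e-12


class TestRegionScoring:
    def test_global_scores_match_exhaustive_oracle(self, rng):
        bank = make_bank(rng, n=50, d=4)
        grid = make_grid(rng, 3, 3, 4)
        out = score_regions_global(grid, bank, KnnConfig(k=5))
        for r in range(3):
            for c in range(3):
                assert out.grid[r, c] == pytest.approx(
                    brute_knn_mean(grid.grid[r, c], bank.vectors, 5)
                )

    def test_bank_members_score_zero(self, rng):
        grid = make_grid(rng, 2, 2, 3)
        bank = build_bank([grid] * 5)
        out = score_regions_global(grid, bank, KnnConfig(k=5))
        assert np.allclose(out.grid, 0.0)

    def test_aligned_matches_position_restricted_oracle(self, rng):
        grids = [make_grid(rng, 3, 3, 4) for _ in range(8)]
        bank = build_bank(grids)
        query = make_grid(rng, 3, 3, 4)
        out = score_regions_aligned(query, bank, KnnConfig(k=5))
        for r in range(3):
            for c in range(3):
                slice_vecs = bank.vectors[bank.position_slice(r, c)]
                assert out.grid[r, c] == pytest.approx(
                    brute_knn_mean(query.grid[r, c], slice_vecs, 5)
                )

    def test_aligned_training_grid_scores_zero(self, rng):
        grids = [make_grid(rng, 2, 2, 3, source_id=str(i)) for i in range(3)]
        bank = build_bank(grids * 2)  # every aligned slice has 6 >= k members
        out = score_regions_aligned(grids[0], bank, KnnConfig(k=2))
        assert np.allclose(out.grid, 0.0)

    def test_global_never_exceeds_aligned(self, rng):
        # the k smallest distances over a superset are pointwise <= those
        # over any subset, so global scores are bounded by aligned scores
        grids = [make_grid(rng, 3, 3, 4) for _ in range(7)]
        bank = build_bank(grids)
        query = make_grid(rng, 3, 3, 4)
        g = score_regions_global(query, bank, KnnConfig(k=5)).grid
        a = score_regions_aligned(query, bank, KnnConfig(k=5)).grid
        assert np.all(g <= a + 1e-12)

    def test_aligned_slice_smaller_than_k_rejected(self, rng):
        bank = build_bank([make_grid(rng, 2, 2, 3) for _ in range(3)])
        with pytest.raises(ConfigurationError, match=r"\(0, 0\)"):
            score_regions_aligned(make_grid(rng, 2, 2, 3), bank, KnnConfig(k=5))
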