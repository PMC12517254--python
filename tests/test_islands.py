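import numpy as np
import pandas as pd
import pytest

from dynatile.errors import InsufficientDataError
from dynatile.fixtures import FixtureSpec, make_toy_domain, plant_fe_sites
from dynatile.islands import (
    FilterParams,
    IslandTileMatrix,
    build_tile_matrix,
    convergence_length,
    cys_fe_filter,
    ligating_cysteines,
    segment_islands,
)
from dynatile.structure_io import FeSite
from dynatile.weights import WeightVector

EQUAL = WeightVector(1 / 3, 1 / 3, 1 / 3)


def table_row(length, t_center, s_cos=0.9, s_frob=0.6, s_sw=30.0, q_start=1):
    return {
        "length": length, "q_start": q_start, "q_center": q_start + (length - 1) // 2,
        "t_start": t_center - (length - 1) // 2, "t_center": t_center,
        "s_cosine": s_cos, "d_frobenius": 0.1, "s_frobenius": s_frob, "s_sw": s_sw,
    }


class TestBuildTileMatrix:
    def test_single_row_single_cell(self):
        df = pd.DataFrame([table_row(6, 10)])
        matrix = build_tile_matrix(df, EQUAL, target_n=20)
        assert matrix.mask.sum() == 1
        value = matrix.values[0, 9]
        assert value == pytest.approx((0.9 + 0.6 + 0.3) / 3)

    def test_max_aggregation_over_query_tiles(self):
        df = pd.DataFrame(
            [table_row(6, 10, s_cos=0.2, s_frob=0.2, s_sw=20.0, q_start=1),
             table_row(6, 10, s_cos=0.8, s_frob=0.8, s_sw=80.0, q_start=2)]
        )
        matrix = build_tile_matrix(df, EQUAL, target_n=20)
        assert matrix.values[0, 9] == pytest.approx(0.8)

    def test_cell_count_per_row(self, helix_structure, helix_corr):
        from dynatile.tiling import build_score_table

        table = build_score_table(
            helix_corr, helix_corr, helix_structure, helix_structure, l_min=6, l_max=9
        )
        n = helix_structure.n_residues
        matrix = build_tile_matrix(table.df, EQUAL, target_n=n)
        for i, length in enumerate(matrix.lengths):
            assert matrix.mask[i].sum() == n - length + 1

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_tile_matrix(pd.DataFrame(columns=["length", "t_center"]), EQUAL, 10)


class TestCysFeFilter:
    @pytest.fixture
    def cys_structure(self):
        structure, _ = make_toy_domain(
            FixtureSpec(domain_length=30, fold="helix", seed=2, cys_positions=(15,))
        )
        return structure

    def _matrix(self, n, lengths=(6,)):
        lengths = np.asarray(lengths)
        centers = np.arange(1, n + 1)
        values = np.full((len(lengths), n), 0.5)
        mask = np.zeros_like(values, dtype=bool)
        for i, length in enumerate(lengths):
            half = (length - 1) // 2
            for start in range(1, n - length + 2):
                mask[i, start + half - 1] = True
        values[~mask] = np.nan
        return IslandTileMatrix(lengths=lengths, centers=centers, values=values, mask=mask)

    def test_boundary_distances_inclusive(self, cys_structure):
        sg = cys_structure.sg_xyz[14]
        for r, expected in ((2.18, True), (2.35, True), (2.17, False), (2.36, False)):
            fe = [FeSite((sg[0] + r, sg[1], sg[2]), "SF4", "x")]
            assert ligating_cysteines(cys_structure, fe)[14] == expected

    def test_tiles_without_cysteine_masked(self, cys_structure):
        fe = plant_fe_sites(cys_structure)
        matrix = self._matrix(cys_structure.n_residues, lengths=(6,))
        filtered = cys_fe_filter(matrix, cys_structure, fe)
        surviving_centers = filtered.centers[filtered.mask[0]]
        # tiles of length 6 centered c cover [c-2, c+3]; they contain Cys15
        # iff 12 <= c <= 17
        assert list(surviving_centers) == [12, 13, 14, 15, 16, 17]

    def test_no_fe_masks_everything(self, cys_structure):
        matrix = self._matrix(cys_structure.n_residues)
        filtered = cys_fe_filter(matrix, cys_structure, [])
        assert filtered.mask.sum() == 0

    def test_monotone_in_fe_sites(self, cys_structure):
        matrix = self._matrix(cys_structure.n_residues)
        fe = plant_fe_sites(cys_structure)
        far = [FeSite((500.0, 0.0, 0.0), "FES", "far")]
        few = cys_fe_filter(matrix, cys_structure, far)
        more = cys_fe_filter(matrix, cys_structure, far + fe)
        assert np.all(more.mask >= few.mask)

    def test_survival_ignores_cell_value(self, cys_structure):
        fe = plant_fe_sites(cys_structure)
        matrix = self._matrix(cys_structure.n_residues)
        matrix.values[matrix.mask] = np.linspace(-5, 5, matrix.mask.sum())
        filtered = cys_fe_filter(matrix, cys_structure, fe)
        low = cys_fe_filter(matrix, cys_structure, fe)
        assert np.array_equal(filtered.mask, low.mask)
        assert filtered.mask.sum() > 0


class TestSegmentIslands:
    def _matrix_from_mask(self, mask_row):
        mask = np.asarray(mask_row, dtype=bool)[None, :]
        values = np.where(mask, 1.0, np.nan)
        return IslandTileMatrix(
            lengths=np.array([6]), centers=np.arange(1, mask.shape[1] + 1),
            values=values, mask=mask,
        )

    def test_fully_masked_matrix_has_no_islands(self):
        assert segment_islands(self._matrix_from_mask([0, 0, 0, 0])) == []

    def test_single_block_single_island(self):
        islands = segment_islands(self._matrix_from_mask([0, 1, 1, 1, 0]))
        assert len(islands) == 1
        assert islands[0].island_id == "A"
        assert islands[0].center_range == (2, 4)

    def test_islands_partition_surviving_columns(self):
        matrix = self._matrix_from_mask([1, 1, 0, 0, 1, 0, 1, 1, 1])
        islands = segment_islands(matrix)
        assert [i.island_id for i in islands] == ["A", "B", "C"]
        covered = np.zeros(9, dtype=int)
        for isl in islands:
            covered += isl.member_mask.astype(int)
        alive = matrix.mask.any(axis=0)
        assert np.array_equal(covered > 0, alive)
        assert covered.max() == 1  # no column in two islands

    def test_two_planted_copies_give_two_islands(self):
        from dynatile.fixtures import make_embedded_fixture
        from dynatile.tiling import Tile

        spec = FixtureSpec(seed=4)
        emb = make_embedded_fixture(spec)
        n = emb.structure.n_residues
        lengths = np.arange(6, spec.domain_length // 2 + 1)
        centers = np.arange(1, n + 1)
        mask = np.zeros((len(lengths), n), dtype=bool)
        for i, length in enumerate(lengths):
            for start in range(1, n - length + 2):
                mask[i, Tile(length=int(length), start=start).center - 1] = True
        matrix = IslandTileMatrix(
            lengths=lengths, centers=centers,
            values=np.where(mask, 1.0, np.nan), mask=mask,
        )
        filtered = cys_fe_filter(matrix, emb.structure, emb.fe_sites)
        islands = segment_islands(filtered)
        assert len(islands) == spec.n_copies
        for isl, (lo, hi) in zip(islands, emb.ground_truth):
            assert isl.center_range[0] < hi and isl.center_range[1] > lo


class TestConvergenceLength:
    def test_constant_series_converges_at_minimum(self):
        lengths = np.arange(6, 30)
        l_opt, converged = convergence_length(lengths, np.full(len(lengths), 0.8))
        assert converged and l_opt == 6

    def test_saturating_curve_matches_numeric_oracle(self):
        lengths = np.arange(6, 56)
        s = 1.0 - np.exp(-lengths / 10.0)
        l_opt, converged = convergence_length(lengths, s, eps=0.005)
        assert converged
        # independent numeric derivative oracle on the analytic curve
        deriv = np.gradient(s, lengths)
        oracle = lengths[np.argmax(np.abs(deriv) < 0.005)]
        assert abs(l_opt - oracle) <= 2

    def test_steep_linear_series_falls_back(self):
        lengths = np.arange(6, 30)
        s = 0.05 * lengths
        l_opt, converged = convergence_length(lengths, s, eps=0.005)
        assert not converged and l_opt == lengths[-1]

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            convergence_length([6, 7, 8], [0.1, 0.2, 0.3])
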