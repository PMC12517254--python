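"""Dynamic-programming optimal tile path through an island.

Rows of the DP are the island's surviving tile lengths in ascending order;
columns are its tile-center indices.  Row 0 of the DP matrix copies the
island values (the defined starting state); every later cell adds its own
value to the best predecessor within two columns on either side,

    DPM[i, j] = value[i, j] + max(DPM[i-1, j-2 .. j+2]),

with masked or out-of-range predecessors at −∞.  The traceback matrix
records the argmax column; the optimal path is read from the maximum of
the deepest reachable row back to row 0.  All ties break toward the
smallest column index so the result is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .islands import Island, IslandTileMatrix

logger = logging.getLogger(__name__)

STEP_REACH = 2  # columns visible on each side of j in the previous row


@dataclass
class DPMatrix:
    """DP score matrix, predecessor (traceback) matrix, and row/column
    labels (tile lengths and center indices)."""

    dpm: np.ndarray
    tm: np.ndarray  # predecessor column index, -1 where none
    lengths: np.ndarray
    centers: np.ndarray


@dataclass
class OptimalPath:
    """Ordered (tile_length, tile_center) steps and their cumulative weight."""

    steps: list[tuple[int, int]]
    total_weight: float


def fill_dp(values: np.ndarray, lengths=None, centers=None) -> DPMatrix:
    """Fill the DP and traceback matrices for one island's value grid.

    ``values`` holds the island's weighted sums with NaN (or −inf) at
    masked cells.  A row none of whose cells is reachable leaves all its
    cells at −∞; the traceback then stops at the deepest reachable row.
    """
    grid = np.asarray(values, dtype=float)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("island value grid must be a non-empty 2-D array")
    n_rows, n_cols = grid.shape
    cell = np.where(np.isfinite(grid), grid, -np.inf)
    if not np.any(np.isfinite(cell[0])):
        raise ValueError("row 0 has no unmasked cell")

    dpm = np.full_like(cell, -np.inf)
    tm = np.full(cell.shape, -1, dtype=int)
    dpm[0] = cell[0]
    for i in range(1, n_rows):
        prev = dpm[i - 1]
        for j in range(n_cols):
            if cell[i, j] == -np.inf:
                continue
            lo = max(0, j - STEP_REACH)
            hi = min(n_cols, j + STEP_REACH + 1)
            window = prev[lo:hi]
            k = int(np.argmax(window))  # first (smallest-column) argmax
            if window[k] == -np.inf:
                continue
            dpm[i, j] = cell[i, j] + window[k]
            tm[i, j] = lo + k
        if not np.any(np.isfinite(dpm[i])):
            logger.info("DP row %d unreachable; path will terminate earlier", i)

    lengths = np.arange(n_rows) if lengths is None else np.asarray(lengths, dtype=int)
    centers = np.arange(n_cols) if centers is None else np.asarray(centers, dtype=int)
    return DPMatrix(dpm=dpm, tm=tm, lengths=lengths, centers=centers)


def traceback(dp: DPMatrix) -> OptimalPath:
    """Read the optimal path from the deepest reachable row back to row 0."""
    finite_rows = [i for i in range(dp.dpm.shape[0]) if np.any(np.isfinite(dp.dpm[i]))]
    if not finite_rows:
        raise ValueError("DP matrix has no reachable cell")
    last = finite_rows[-1]
    row = dp.dpm[last]
    j = int(np.flatnonzero(row == row.max())[0])  # tie -> smallest column
    total = float(row[j])
    steps: list[tuple[int, int]] = []
    i = last
    while i >= 0:
        steps.append((int(dp.lengths[i]), int(dp.centers[j])))
        j_prev = dp.tm[i, j]
        if i > 0 and j_prev < 0:
            break
        j = int(j_prev) if i > 0 else j
        i -= 1
    steps.reverse()
    return OptimalPath(steps=steps, total_weight=total)


def optimal_path_for_island(matrix: IslandTileMatrix, island: Island) -> OptimalPath:
    """DP + traceback over the island's columns and surviving lengths."""
    cols = np.flatnonzero(island.member_mask)
    sub_mask = matrix.mask[:, cols]
    rows = np.flatnonzero(sub_mask.any(axis=1))  # skip fully-masked lengths
    if rows.size == 0:
        raise ValueError(f"island {island.island_id} has no surviving cells")
    values = np.where(sub_mask[rows], matrix.values[np.ix_(rows, cols)], np.nan)
    dp = fill_dp(values, lengths=matrix.lengths[rows], centers=matrix.centers[cols])
    return traceback(dp)


def path_table(path: OptimalPath, matrix: IslandTileMatrix, island: Island):
    """Per-step (length, center, cell value, cumulative) rows for export."""
    import pandas as pd

    l_index = {int(length): i for i, length in enumerate(matrix.lengths)}
    c_index = {int(center): j for j, center in enumerate(matrix.centers)}
    rows = []
    cum = 0.0
    for length, center in path.steps:
        val = float(matrix.values[l_index[length], c_index[center]])
        cum += val
        rows.append(
            {
                "island_id": island.island_id,
                "length": length,
                "center": center,
                "value": val,
                "cumulative": cum,
            }
        )
    return pd.DataFrame(rows)
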