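"""Weighted-sum landscape, cysteine-iron filtering, island segmentation.

The landscape ("island tile matrix") has one row per tile length and one
column per target tile-center index; each cell holds the best weighted
similarity over all query tiles for the target tile at that (length,
center).  Cells near the termini have no valid tile, producing the
sawtooth envelope.  A geometric filter then keeps only tiles containing
at least one cysteine whose SG sulfur sits within Fe-S bonding distance
(2.18-2.35 Å) of an iron atom; maximal runs of surviving center columns
are the "islands" (labelled A, B, ... left to right) within which the
optimal-path search is confined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import InsufficientDataError
from .structure_io import CaStructure, FeSite
from .weights import WeightVector, weighted_column

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Cys SG - Fe distance window for plausible Fe-S coordination, Å."""

    r_min: float = 2.18
    r_max: float = 2.35
    #: absolute tolerance so the inclusive bounds are robust to float rounding
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ValueError("need 0 < r_min < r_max")


@dataclass
class IslandTileMatrix:
    """Tile-length × tile-center landscape of best weighted sums."""

    lengths: np.ndarray  # ascending tile lengths, one per row
    centers: np.ndarray  # target seq_index centers, one per column
    values: np.ndarray  # (n_lengths, n_centers), NaN where masked
    mask: np.ndarray  # True where a surviving tile exists

    def copy(self) -> "IslandTileMatrix":
        return IslandTileMatrix(
            self.lengths.copy(), self.centers.copy(), self.values.copy(), self.mask.copy()
        )

    def to_long_frame(self, islands: list["Island"] | None = None) -> pd.DataFrame:
        """Plot-ready long format (length, center, value, island_id)."""
        li, ci = np.nonzero(self.mask)
        frame = pd.DataFrame(
            {
                "length": self.lengths[li],
                "center": self.centers[ci],
                "value": self.values[li, ci],
                "island_id": "",
            }
        )
        for isl in islands or []:
            lo, hi = isl.center_range
            frame.loc[(frame["center"] >= lo) & (frame["center"] <= hi), "island_id"] = isl.island_id
        return frame


@dataclass
class Island:
    """A maximal contiguous run of surviving tile-center columns."""

    island_id: str
    center_range: tuple[int, int]
    member_mask: np.ndarray  # boolean over the matrix's center columns


def build_tile_matrix(
    table, weights: WeightVector, target_n: int
) -> IslandTileMatrix:
    """Aggregate a score table into the landscape: cell (L, j) is the max
    S_weighted over query tiles for target tiles of length L centered at j."""
    df = table.df if hasattr(table, "df") else table
    if len(df) == 0:
        raise InsufficientDataError("empty score table")
    work = df[["length", "t_center"]].copy()
    work["s_weighted"] = weighted_column(df, weights)
    best = work.groupby(["length", "t_center"])["s_weighted"].max()

    lengths = np.asarray(sorted(df["length"].unique()), dtype=int)
    centers = np.arange(1, target_n + 1)
    values = np.full((len(lengths), len(centers)), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    l_index = {length: i for i, length in enumerate(lengths)}
    for (length, center), val in best.items():
        i, j = l_index[int(length)], int(center) - 1
        if 0 <= j < len(centers):
            values[i, j] = val
            mask[i, j] = True
    return IslandTileMatrix(lengths=lengths, centers=centers, values=values, mask=mask)


def ligating_cysteines(
    target: CaStructure, fe_sites: list[FeSite], params: FilterParams | None = None
) -> np.ndarray:
    """Boolean per residue: is it a cysteine whose SG lies within the Fe-S
    bonding window of any iron?  (Inclusive on both bounds.)"""
    params = params or FilterParams()
    out = np.zeros(target.n_residues, dtype=bool)
    if not fe_sites:
        return out
    fe = np.array([s.fe_xyz for s in fe_sites], dtype=float)
    for i in range(target.n_residues):
        sg = target.sg_xyz[i]
        if target.aa[i] != "C" or not np.all(np.isfinite(sg)):
            continue  # disordered side chain fails the filter
        dist = np.linalg.norm(fe - sg[None, :], axis=1)
        out[i] = bool(
            np.any((dist >= params.r_min - params.tol) & (dist <= params.r_max + params.tol))
        )
    return out


def cys_fe_filter(
    matrix: IslandTileMatrix,
    target: CaStructure,
    fe_sites: list[FeSite],
    params: FilterParams | None = None,
) -> IslandTileMatrix:
    """Mask every tile lacking a coordinating cysteine (geometry only; the
    tile's weighted-sum value plays no role)."""
    params = params or FilterParams()
    lig = ligating_cysteines(target, fe_sites, params)
    cum = np.concatenate([[0], np.cumsum(lig)])
    out = matrix.copy()
    n = target.n_residues
    for i, length in enumerate(out.lengths):
        half = (int(length) - 1) // 2
        for j, center in enumerate(out.centers):
            if not out.mask[i, j]:
                continue
            start = int(center) - half
            end = start + int(length) - 1
            start, end = max(1, start), min(n, end)
            if cum[end] - cum[start - 1] == 0:
                out.mask[i, j] = False
                out.values[i, j] = np.nan
    return out


def segment_islands(matrix: IslandTileMatrix) -> list[Island]:
    """Maximal runs of center columns with ≥1 surviving cell, labelled
    A, B, ... in ascending center order."""
    col_alive = matrix.mask.any(axis=0)
    islands: list[Island] = []
    in_run = False
    start = 0
    for j, alive in enumerate(np.append(col_alive, False)):
        if alive and not in_run:
            in_run, start = True, j
        elif not alive and in_run:
            in_run = False
            member = np.zeros_like(col_alive)
            member[start:j] = True
            label = _island_label(len(islands))
            islands.append(
                Island(
                    island_id=label,
                    center_range=(int(matrix.centers[start]), int(matrix.centers[j - 1])),
                    member_mask=member,
                )
            )
    return islands


def _island_label(index: int) -> str:
    label = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def island_residue_span(matrix: IslandTileMatrix, island: Island) -> tuple[int, int]:
    """Residue extent covered by the island's surviving tiles."""
    li, ci = np.nonzero(matrix.mask & island.member_mask[None, :])
    if li.size == 0:
        raise InsufficientDataError(f"island {island.island_id} has no surviving cells")
    lengths = matrix.lengths[li]
    centers = matrix.centers[ci]
    starts = centers - (lengths - 1) // 2
    ends = starts + lengths - 1
    return int(starts.min()), int(ends.max())


def convergence_length(
    lengths,
    s_of_l,
    smooth_sigma: float = 2.0,
    window: int = 5,
    eps: float = 0.005,
    degree: int = 5,
) -> tuple[int, bool]:
    """Smallest tile length where the smoothed derivative of S(L) vanishes.

    Fits a polynomial to S(L), differentiates, Gaussian-smooths the
    derivative (sigma in units of L), applies a rolling average, and
    returns the smallest L with |S'| < eps.  Falls back to the largest L
    (logged, converged=False) when the derivative never settles.
    """
    lengths = np.asarray(lengths, dtype=float)
    s_of_l = np.asarray(s_of_l, dtype=float)
    if len(lengths) < 5 or len(lengths) != len(s_of_l):
        raise InsufficientDataError("need >= 5 (L, S) points")
    order = np.argsort(lengths)
    lengths, s_of_l = lengths[order], s_of_l[order]
    deg = min(degree, len(lengths) - 1)
    poly = np.polynomial.Polynomial.fit(lengths, s_of_l, deg)
    deriv = poly.deriv()(lengths)
    smoothed = gaussian_filter1d(deriv, sigma=smooth_sigma, mode="nearest")
    if window > 1:
        smoothed = (
            pd.Series(smoothed).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
    hits = np.flatnonzero(np.abs(smoothed) < eps)
    if hits.size == 0:
        logger.info("S(L) derivative never fell below eps=%g; falling back to max L", eps)
        return int(lengths[-1]), False
    return int(lengths[hits[0]]), True
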