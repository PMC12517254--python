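"""Composite ranking, threshold filtering, match assembly and exports.

Within each tile-length class, every pair is ranked best-first on each of
the three similarity metrics; the rank-sum is the composite score (small =
better).  Pairs with cosine similarity below 0.5 or sequence similarity
below 50% are discarded, only lengths 6..⌊N_query/2⌋ take part, and the
best 20% by composite are kept per length class.  Final matches place one
converged tile per island (length from the per-path convergence analysis,
center from the optimal path) and map it back to chain + author numbering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .islands import Island, IslandTileMatrix, convergence_length
from .paths import OptimalPath
from .structure_io import CaStructure, MatchRecord
from .tiling import MIN_TILE_LENGTH

logger = logging.getLogger(__name__)

COSINE_CUTOFF = 0.5
SW_CUTOFF = 50.0
TOP_FRACTION = 0.2


def composite_rank(rows) -> pd.DataFrame:
    """Add per-metric dense ranks (1 = most similar) and their sum.

    Ranks are computed within each tile-length class; identical rows get
    identical composites.
    """
    df = (rows.df if hasattr(rows, "df") else rows).copy()
    if len(df) == 0:
        raise ValueError("empty score table")
    for col in ("s_cosine", "s_frobenius", "s_sw"):
        df[f"rank_{col}"] = (
            df.groupby("length")[col].rank(method="dense", ascending=False).astype(int)
        )
    df["composite"] = df["rank_s_cosine"] + df["rank_s_frobenius"] + df["rank_s_sw"]
    return df


def threshold_filter(ranked: pd.DataFrame, n_query: int) -> pd.DataFrame:
    """§-style selection: cutoffs, length window, per-class top 20%.

    Drops pairs with s_cosine < 0.5 or s_sw < 50%, restricts to lengths
    6..⌊n_query/2⌋, then keeps the best 20% by composite rank (ceil, so a
    non-empty class keeps at least one pair).  The output is marked as
    already-selected, so re-applying the filter is the identity on the
    percentile step (the cutoffs themselves are naturally idempotent).
    """
    l_max = n_query // 2
    df = ranked[
        (ranked["length"] >= MIN_TILE_LENGTH)
        & (ranked["length"] <= l_max)
        & (ranked["s_cosine"] >= COSINE_CUTOFF)
        & (ranked["s_sw"] >= SW_CUTOFF)
    ]
    if len(df) == 0:
        logger.warning("threshold_filter: no tiles survive the cutoffs")
        return df.copy()
    if ranked.attrs.get("top_fraction_applied"):
        out = df.copy()
        out.attrs["top_fraction_applied"] = True
        return out
    kept = []
    for _, group in df.groupby("length"):
        n_keep = math.ceil(TOP_FRACTION * len(group))
        kept.append(group.nsmallest(n_keep, "composite", keep="all").head(n_keep))
    out = pd.concat(kept).sort_index()
    out.attrs["top_fraction_applied"] = True
    return out


def assemble_matches(
    paths: dict[str, OptimalPath],
    islands: list[Island],
    matrix: IslandTileMatrix,
    target: CaStructure,
    smooth_sigma: float = 2.0,
    window: int = 5,
    eps: float = 0.005,
    score_lookup: pd.DataFrame | None = None,
) -> list[MatchRecord]:
    """One converged match per island.

    The tile length is the smallest L at which the path's weighted sum
    S(L) stops improving (per-path convergence); its center is the path
    step at that length.  ``score_lookup`` (a score table with an
    s_weighted column) supplies the per-metric scores of the best query
    tile for the chosen cell.
    """
    l_index = {int(length): i for i, length in enumerate(matrix.lengths)}
    c_index = {int(center): j for j, center in enumerate(matrix.centers)}
    matches: list[MatchRecord] = []
    for island in islands:
        path = paths.get(island.island_id)
        if path is None or not path.steps:
            continue
        lengths = [step[0] for step in path.steps]
        s_values = [
            float(matrix.values[l_index[length], c_index[center]])
            for length, center in path.steps
        ]
        if len(lengths) >= 5:
            l_opt, converged = convergence_length(
                lengths, s_values, smooth_sigma=smooth_sigma, window=window, eps=eps
            )
        else:
            l_opt, converged = max(lengths), False
            logger.info(
                "island %s: path too short for convergence analysis; using max L",
                island.island_id,
            )
        step = next(s for s in path.steps if s[0] == l_opt)
        length, center = step
        start = center - (length - 1) // 2
        end = start + length - 1
        start = max(1, start)
        end = min(target.n_residues, end)
        scores = {
            "s_weighted": float(matrix.values[l_index[length], c_index[center]])
        }
        if score_lookup is not None:
            hit = score_lookup[
                (score_lookup["length"] == length) & (score_lookup["t_center"] == center)
            ]
            if len(hit):
                best = hit.loc[hit["s_weighted"].idxmax()]
                scores.update(
                    {
                        "s_cosine": float(best["s_cosine"]),
                        "s_frobenius": float(best["s_frobenius"]),
                        "s_sw": float(best["s_sw"]),
                        "s_weighted": float(best["s_weighted"]),
                    }
                )
        matches.append(
            MatchRecord(
                island_id=island.island_id,
                tile_length=int(length),
                tile_center=int(center),
                residue_range=(int(start), int(end)),
                chain=target.chain_id[start - 1],
                auth_range=(
                    int(target.auth_resnum[start - 1]),
                    int(target.auth_resnum[end - 1]),
                ),
                scores=scores,
                converged=converged,
            )
        )
    return matches


def export_dynamics_vs_structure(table, length: int = 30, target_id: str | None = None) -> pd.DataFrame:
    """Paired (s_frobenius, s_cosine) rows for all tile pairs at one length.

    The default length of 30 residues matches the structure-vs-dynamics
    comparison across tile centers; the export is plot-ready and applies
    no curve fitting.
    """
    df = table.df if hasattr(table, "df") else table
    sel = df[df["length"] == length]
    if len(sel) == 0:
        logger.warning("no tile pairs of length %d; empty export", length)
        return pd.DataFrame(columns=["s_frobenius", "s_cosine", "target_id"])
    out = sel[["s_frobenius", "s_cosine"]].copy()
    out["target_id"] = target_id if target_id is not None else getattr(table, "target_id", "")
    return out.reset_index(drop=True)
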