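"""Sliding-window tiles and the three pairwise similarity metrics.

A tile is a contiguous window of L residues (L ≥ 6, the shortest window
that still captures a β-strand or a small helix).  For a protein of N
residues there are N − L + 1 tiles per length, hence

    N_t = Σ_{L=6..N} (N − L + 1)

tiles in total.  Each tile's unit of dynamical comparison is the L×L
diagonal block of its own protein's cross-correlation matrix; query and
target blocks are compared by (i) cosine similarity of the flattened
blocks, (ii) a Frobenius-distance-derived similarity obtained through the
continuous Gower mapping s = 1 − d/d_max (d_max taken per tile length over
all pairs of the run, since d scales with matrix size), and (iii) local
Smith-Waterman sequence similarity with BLOSUM62, normalized by the mean
of the two tiles' self-alignment scores and expressed in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .anm import CrossCorrelationMatrix
from .errors import BoundError, UndefinedSimilarityError
from .structure_io import CaStructure

logger = logging.getLogger(__name__)

MIN_TILE_LENGTH = 6

#: named gap-penalty presets (open, extend); "default" keeps the aligner's own
GAP_PRESETS = {"zero": (0.0, 0.0), "blast": (-11.0, -1.0)}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Tile:
    """A contiguous window: 1-based start, length L, floor-convention center."""

    length: int
    start: int

    @property
    def center(self) -> int:
        return self.start + (self.length - 1) // 2

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def residue_ids(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length)


def enumerate_tiles(n_residues: int, l_min: int = MIN_TILE_LENGTH, l_max: int | None = None) -> list[Tile]:
    """All tiles with l_min ≤ L ≤ l_max for a protein of ``n_residues``."""
    l_max = n_residues if l_max is None else l_max
    if l_min < MIN_TILE_LENGTH:
        raise BoundError(f"minimum tile length is {MIN_TILE_LENGTH}, got {l_min}")
    if not l_min <= l_max <= n_residues:
        raise BoundError(f"need {l_min} <= l_max <= N, got l_max={l_max}, N={n_residues}")
    return [
        Tile(length=length, start=start)
        for length in range(l_min, l_max + 1)
        for start in range(1, n_residues - length + 2)
    ]


def tile_submatrix(corr: CrossCorrelationMatrix | np.ndarray, tile: Tile) -> np.ndarray:
    """The tile's L×L diagonal block of the cross-correlation matrix."""
    values = corr.values if isinstance(corr, CrossCorrelationMatrix) else np.asarray(corr)
    n = values.shape[0]
    if tile.start < 1 or tile.end > n:
        raise IndexError(f"tile {tile.start}..{tile.end} outside 1..{n}")
    lo = tile.start - 1
    return values[lo : lo + tile.length, lo : lo + tile.length]


def cosine_similarity(sub_q: np.ndarray, sub_t: np.ndarray) -> float:
    """Cosine of the flattened blocks; -1 (opposite) .. 1 (identical)."""
    u = np.asarray(sub_q, dtype=float).ravel()
    v = np.asarray(sub_t, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("submatrices must have equal shape")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero block")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def frobenius_distance(sub_q: np.ndarray, sub_t: np.ndarray) -> float:
    """Element-wise Euclidean distance of the two equal-size blocks (no
    superposition: correlation blocks are already rigid-motion invariant)."""
    q = np.asarray(sub_q, dtype=float)
    t = np.asarray(sub_t, dtype=float)
    if q.shape != t.shape:
        raise ValueError("submatrices must have equal shape")
    return float(np.linalg.norm(q - t))


def frobenius_similarity(sub_q: np.ndarray, sub_t: np.ndarray, d_max: float) -> tuple[float, float]:
    """(d, s) with the Gower mapping s = 1 − d/d_max; clamps s at 0 when d
    exceeds a d_max that was estimated on a subset."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    d = frobenius_distance(sub_q, sub_t)
    s = 1.0 - d / d_max
    if s < 0.0:
        logger.warning("Frobenius distance %.4g exceeds d_max %.4g; clamping s to 0", d, d_max)
        s = 0.0
    return d, s


def make_aligner(gap_scores: str | tuple[float, float] | None = None) -> PairwiseAligner:
    """Local BLOSUM62 aligner.  ``gap_scores`` is None (the library default),
    a preset name from GAP_PRESETS, or an (open, extend) pair."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    if gap_scores is not None:
        if isinstance(gap_scores, str):
            gap_scores = GAP_PRESETS[gap_scores]
        aligner.open_gap_score, aligner.extend_gap_score = gap_scores
    return aligner


def _sanitize(seq: str) -> str:
    if set(seq) <= _STANDARD_AA:
        return seq
    logger.warning("non-standard letters in %r mapped to X", seq)
    return "".join(c if c in _STANDARD_AA else "X" for c in seq)


def sequence_similarity(seq_q: str, seq_t: str, aligner: PairwiseAligner | None = None) -> float:
    """Smith-Waterman score normalized by the mean self-alignment score, %."""
    if not seq_q or not seq_t:
        raise ValueError("sequences must be non-empty")
    aligner = aligner or make_aligner()
    seq_q, seq_t = _sanitize(seq_q), _sanitize(seq_t)
    self_q = aligner.score(seq_q, seq_q)
    self_t = aligner.score(seq_t, seq_t)
    denom = (self_q + self_t) / 2.0
    if denom <= 0:
        logger.warning("non-positive self-alignment score; similarity set to 0")
        return 0.0
    return float(np.clip(100.0 * aligner.score(seq_q, seq_t) / denom, 0.0, 100.0))


@dataclass
class ScoreTable:
    """Per tile-pair similarity rows plus the per-length maximum Frobenius
    distance used by the Gower mapping.

    Columns of ``df``: length, q_start, q_center, t_start, t_center,
    s_cosine, d_frobenius, s_frobenius, s_sw (percent).
    """

    df: pd.DataFrame
    d_max_per_length: dict[int, float] = field(default_factory=dict)
    query_id: str = ""
    target_id: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, query_id: str = "", target_id: str = "") -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        d_max = (
            df.groupby("length")["d_frobenius"].max().to_dict() if len(df) else {}
        )
        return cls(df=df, d_max_per_length=d_max, query_id=query_id, target_id=target_id)


def _block_rows(values: np.ndarray, length: int) -> np.ndarray:
    """All diagonal L×L blocks, flattened: shape (N-L+1, L*L)."""
    n = values.shape[0]
    n_tiles = n - length + 1
    out = np.empty((n_tiles, length * length))
    for s in range(n_tiles):
        out[s] = values[s : s + length, s : s + length].ravel()
    return out


def score_all_pairs(
    corr_q: CrossCorrelationMatrix,
    corr_t: CrossCorrelationMatrix,
    structure_q: CaStructure,
    structure_t: CaStructure,
    length: int,
    aligner: PairwiseAligner | None = None,
) -> pd.DataFrame:
    """Score every (query tile, target tile) pair at one tile length.

    Returns one row per pair; ``s_frobenius`` uses d_max observed over all
    pairs of this length.
    """
    aligner = aligner or make_aligner()
    nq, nt = corr_q.n_residues, corr_t.n_residues
    q_blocks = _block_rows(corr_q.values, length)
    t_blocks = _block_rows(corr_t.values, length)
    n_qt, n_tt = q_blocks.shape[0], t_blocks.shape[0]

    q_norm = np.linalg.norm(q_blocks, axis=1)
    t_norm = np.linalg.norm(t_blocks, axis=1)
    if np.any(q_norm == 0) or np.any(t_norm == 0):
        raise UndefinedSimilarityError("zero correlation block encountered")
    dot = q_blocks @ t_blocks.T
    s_cos = np.clip(dot / np.outer(q_norm, t_norm), -1.0, 1.0)
    d2 = q_norm[:, None] ** 2 + t_norm[None, :] ** 2 - 2.0 * dot
    d = np.sqrt(np.clip(d2, 0.0, None))
    d_max = float(d.max())
    s_frob = 1.0 - d / d_max if d_max > 0 else np.ones_like(d)

    q_seqs = [structure_q.subsequence(s + 1, s + length) for s in range(n_qt)]
    t_seqs = [structure_t.subsequence(s + 1, s + length) for s in range(n_tt)]
    q_self = np.array([aligner.score(s, s) for s in map(_sanitize, q_seqs)])
    t_self = np.array([aligner.score(s, s) for s in map(_sanitize, t_seqs)])
    s_sw = np.empty((n_qt, n_tt))
    for i, qs in enumerate(q_seqs):
        qs = _sanitize(qs)
        for j, ts in enumerate(t_seqs):
            denom = (q_self[i] + t_self[j]) / 2.0
            s_sw[i, j] = (
                np.clip(100.0 * aligner.score(qs, _sanitize(ts)) / denom, 0.0, 100.0)
                if denom > 0
                else 0.0
            )

    qi, ti = np.meshgrid(np.arange(n_qt), np.arange(n_tt), indexing="ij")
    half = (length - 1) // 2
    return pd.DataFrame(
        {
            "length": length,
            "q_start": qi.ravel() + 1,
            "q_center": qi.ravel() + 1 + half,
            "t_start": ti.ravel() + 1,
            "t_center": ti.ravel() + 1 + half,
            "s_cosine": s_cos.ravel(),
            "d_frobenius": d.ravel(),
            "s_frobenius": s_frob.ravel(),
            "s_sw": s_sw.ravel(),
        }
    )


def build_score_table(
    corr_q: CrossCorrelationMatrix,
    corr_t: CrossCorrelationMatrix,
    structure_q: CaStructure,
    structure_t: CaStructure,
    l_min: int = MIN_TILE_LENGTH,
    l_max: int | None = None,
    aligner: PairwiseAligner | None = None,
) -> ScoreTable:
    """Score all pairs for every length l_min..l_max (default: query length)."""
    l_max = min(corr_q.n_residues, corr_t.n_residues) if l_max is None else l_max
    if l_min < MIN_TILE_LENGTH:
        raise BoundError(f"minimum tile length is {MIN_TILE_LENGTH}")
    aligner = aligner or make_aligner()
    frames = []
    d_max: dict[int, float] = {}
    for length in range(l_min, l_max + 1):
        frame = score_all_pairs(corr_q, corr_t, structure_q, structure_t, length, aligner)
        d_max[length] = float(frame["d_frobenius"].max())
        frames.append(frame)
    return ScoreTable(
        df=pd.concat(frames, ignore_index=True),
        d_max_per_length=d_max,
        query_id=structure_q.source_id,
        target_id=structure_t.source_id,
    )
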