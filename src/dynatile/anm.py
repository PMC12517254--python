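"""Anisotropic network model: Hessian, normal modes, cross-correlations.

Each Cα is a node of a uniform mass-spring network; pairs closer than the
cutoff r_c are joined by springs of constant γ.  Diagonalizing the 3N×3N
Hessian yields normal modes; the six zero-frequency rigid-body modes are
discarded and the lowest non-trivial modes (default 10) are used to build
the N×N normalized residue cross-correlation matrix

    C_ij = cov_ij / sqrt(cov_ii · cov_jj),
    cov_ij = Σ_k (1/λ_k) u_k,i · u_k,j

where u_k,i is mode k's 3-vector at residue i.  The 1/λ weighting follows
the standard ANM pseudo-inverse covariance over retained modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, DegenerateMobilityError, ModeCountError
from .structure_io import CaStructure

logger = logging.getLogger(__name__)


@dataclass
class AnmParams:
    """ANM parameters: spring constant γ [kcal/(mol·Å²)], cutoff r_c [Å],
    number of retained non-trivial modes, rigid-body tolerance factor and
    the size above which the sparse eigensolver is used."""

    gamma: float = 1.0
    cutoff: float = 15.0
    n_modes: int = 10
    rigid_tol_factor: float = 1e-8
    dense_limit: int = 500

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cutoff <= 0 or self.n_modes < 1:
            raise ValueError("gamma > 0, cutoff > 0 and n_modes >= 1 required")

    def cache_key(self) -> str:
        return f"g{self.gamma:g}_c{self.cutoff:g}_m{self.n_modes}"


@dataclass
class ModeSet:
    """Non-trivial normal modes: ascending positive eigenvalues and unit
    eigenvectors of shape (n_modes, 3N)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_residues: int


@dataclass
class CrossCorrelationMatrix:
    """Normalized N×N residue cross-correlation (symmetric, unit diagonal,
    entries in [-1, 1])."""

    values: np.ndarray
    n_modes_used: int

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def _coords(structure) -> np.ndarray:
    if isinstance(structure, CaStructure):
        return structure.ca_xyz
    return np.asarray(structure, dtype=float)


def build_hessian(structure, params: AnmParams | None = None):
    """Build the 3N×3N ANM Hessian (dense ndarray, or CSR above dense_limit).

    The off-diagonal 3×3 super-element for a connected pair (i, j) is
    -γ (d ⊗ d)/|d|² with d = x_j - x_i; diagonal blocks are the negative
    sums of the row's off-diagonal blocks, so all row-block sums vanish
    (translational invariance).
    """
    params = params or AnmParams()
    xyz = _coords(structure)
    n = xyz.shape[0]
    if n < 2:
        raise ValueError("need at least two residues")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite coordinates")

    pairs = cKDTree(xyz).query_pairs(params.cutoff, output_type="ndarray")
    if pairs.size:
        d = xyz[pairs[:, 1]] - xyz[pairs[:, 0]]
        dist2 = np.einsum("ij,ij->i", d, d)
        if np.any(dist2 < 1e-12):
            raise DegenerateGeometryError("coincident nodes within the cutoff")
        # per-pair 3x3 super-element  γ (d⊗d)/|d|²
        blocks = params.gamma * np.einsum("ni,nj->nij", d, d) / dist2[:, None, None]
    else:
        blocks = np.zeros((0, 3, 3))

    use_sparse = n >= params.dense_limit
    if not use_sparse:
        h = np.zeros((3 * n, 3 * n))
        for (i, j), b in zip(pairs, blocks):
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = -b
            h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = -b
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += b
            h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += b
        return h

    rows, cols, vals = [], [], []
    off = np.repeat(np.arange(3), 3)  # block-local row index pattern
    ocl = np.tile(np.arange(3), 3)
    for (i, j), b in zip(pairs, blocks):
        flat = b.ravel()
        for bi, bj, sgn in ((i, j, -1.0), (j, i, -1.0), (i, i, 1.0), (j, j, 1.0)):
            rows.append(3 * bi + off)
            cols.append(3 * bj + ocl)
            vals.append(sgn * flat)
    h = scipy.sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    return h


def compute_modes(hessian, params: AnmParams | None = None) -> ModeSet:
    """Diagonalize the Hessian and return the lowest non-trivial modes.

    Eigenvalues with |λ| below rigid_tol_factor × λ_max are treated as
    rigid-body modes and discarded.  A connected 3-D network has exactly
    six; any other count is logged as a warning (a disconnected network
    has more).  The next n_modes smallest eigenpairs are returned in
    ascending order.
    """
    params = params or AnmParams()
    sparse = scipy.sparse.issparse(hessian)
    dim = hessian.shape[0]
    n_res = dim // 3

    if not sparse:
        evals, evecs = scipy.linalg.eigh(hessian)
    else:
        lam_max = scipy.sparse.linalg.eigsh(
            hessian, k=1, which="LA", return_eigenvectors=False
        )[0]
        k = min(params.n_modes + 6, dim - 1)
        while True:
            evals, evecs = scipy.sparse.linalg.eigsh(hessian, k=k, sigma=-1e-2, which="LM")
            tol = params.rigid_tol_factor * max(abs(lam_max), 1.0)
            if np.sum(np.abs(evals) >= tol) >= params.n_modes or k >= dim - 1:
                break
            k = min(2 * k, dim - 1)
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]

    lam_max = float(np.max(np.abs(evals))) if not sparse else float(abs(lam_max))
    tol = params.rigid_tol_factor * max(lam_max, 1.0)
    rigid = np.abs(evals) < tol
    n_rigid = int(np.sum(rigid))
    if n_rigid != 6:
        logger.warning(
            "expected 6 rigid-body modes, found %d (disconnected network?)", n_rigid
        )
    keep = np.flatnonzero(~rigid)
    if keep.size < params.n_modes:
        raise ModeCountError(
            f"only {keep.size} non-trivial modes available, {params.n_modes} requested"
        )
    keep = keep[: params.n_modes]
    vecs = evecs[:, keep].T.copy()
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return ModeSet(eigenvalues=evals[keep].copy(), eigenvectors=vecs, n_residues=n_res)


def cross_correlation(modes: ModeSet) -> CrossCorrelationMatrix:
    """Normalized cross-correlation matrix from the retained modes."""
    n = modes.n_residues
    v = modes.eigenvectors.reshape(len(modes.eigenvalues), n, 3)
    w = 1.0 / modes.eigenvalues
    cov = np.einsum("k,kia,kja->ij", w, v, v, optimize=True)
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        raise DegenerateMobilityError("zero mean-square fluctuation for some residue")
    c = cov / np.sqrt(np.outer(diag, diag))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CrossCorrelationMatrix(values=c, n_modes_used=len(modes.eigenvalues))


def compute_cross_correlation(
    structure, params: AnmParams | None = None
) -> CrossCorrelationMatrix:
    """Convenience: Hessian → modes → cross-correlation in one call."""
    params = params or AnmParams()
    return cross_correlation(compute_modes(build_hessian(structure, params), params))
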