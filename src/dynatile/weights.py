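"""Metric weights by Gaussian-process Bayesian optimization.

The weighted similarity of a tile pair is

    S_weighted = w_cos·s_cos + w_frob·s_frob + w_sw·s_sw

with all three scores on the unit scale (the Smith-Waterman percentage is
divided by 100 before mixing) and the weights on the probability simplex.
The objective O(w) is the mean Pearson correlation of S_weighted with each
individual metric column; it is maximized over the simplex with a 115-call
budget: 15 uniformly random simplex points, then 100 points chosen by
expected improvement under a zero-mean Gaussian process with a squared
exponential kernel whose (σ², ℓ) are refit by maximum likelihood at every
guided iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.stats import norm

from .errors import UndefinedCorrelationError
from .tiling import ScoreTable

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("s_cosine", "s_frobenius", "s_sw")


@dataclass(frozen=True)
class WeightVector:
    """Normalized non-negative weights for the three similarity metrics."""

    w_cosine: float
    w_frobenius: float
    w_sw: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12):
            raise ValueError("weights must be non-negative")
        total = arr.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"weights must sum to 1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_cosine, self.w_frobenius, self.w_sw])

    @classmethod
    def from_array(cls, arr) -> "WeightVector":
        arr = np.asarray(arr, dtype=float)
        arr = arr / arr.sum()
        return cls(*arr)


def weighted_similarity(scores, weights: WeightVector):
    """Weighted sum of the three scores (all already on the unit scale)."""
    s = np.asarray(scores, dtype=float)
    return s @ weights.as_array() if s.ndim > 1 else float(s @ weights.as_array())


def weighted_column(table: ScoreTable | pd.DataFrame, weights: WeightVector) -> np.ndarray:
    """S_weighted for every row of a score table (rescales s_sw to [0,1])."""
    df = table.df if isinstance(table, ScoreTable) else table
    stacked = np.column_stack(
        [df["s_cosine"].to_numpy(), df["s_frobenius"].to_numpy(), df["s_sw"].to_numpy() / 100.0]
    )
    return stacked @ weights.as_array()


def objective(weights: WeightVector, table: ScoreTable | pd.DataFrame):
    """(O, C_cosine, C_frobenius, C_sw): Pearson correlations of S_weighted
    against each metric column, and their mean."""
    df = table.df if isinstance(table, ScoreTable) else table
    if len(df) < 3:
        raise ValueError("need at least 3 rows to correlate")
    s = weighted_column(df, weights)
    corrs = []
    for col in METRIC_COLUMNS:
        x = df[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise UndefinedCorrelationError(f"metric column {col} is constant")
        if np.std(s) == 0:
            raise UndefinedCorrelationError("weighted score is constant")
        corrs.append(float(np.corrcoef(s, x)[0, 1]))
    return (float(np.mean(corrs)), *corrs)


class GaussianProcess:
    """Noise-free GP regression with zero prior mean and SE kernel
    k(x,x') = σ² exp(−‖x−x'‖²/(2ℓ²)); a 1e-10 jitter keeps the Cholesky
    factorization stable."""

    def __init__(self, sigma2: float = 1.0, length_scale: float = 0.2, jitter: float = 1e-10):
        if length_scale <= 0 or sigma2 <= 0:
            raise ValueError("sigma2 and length_scale must be positive")
        self.sigma2 = sigma2
        self.length_scale = length_scale
        self.jitter = jitter
        self.x_obs: np.ndarray | None = None
        self.y_obs: np.ndarray | None = None
        self._chol = None

    def _kernel(self, a: np.ndarray, b: np.ndarray, sigma2=None, length_scale=None) -> np.ndarray:
        sigma2 = self.sigma2 if sigma2 is None else sigma2
        length_scale = self.length_scale if length_scale is None else length_scale
        d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
        return sigma2 * np.exp(-d2 / (2.0 * length_scale**2))

    def fit(self, x_obs, y_obs) -> "GaussianProcess":
        self.x_obs = np.atleast_2d(np.asarray(x_obs, dtype=float))
        self.y_obs = np.asarray(y_obs, dtype=float)
        if len(self.x_obs) != len(self.y_obs) or len(self.y_obs) == 0:
            raise ValueError("observations must be non-empty and consistent")
        k = self._kernel(self.x_obs, self.x_obs)
        jitter = self.jitter
        while True:
            try:
                self._chol = scipy.linalg.cholesky(
                    k + jitter * np.eye(len(k)), lower=True
                )
                break
            except scipy.linalg.LinAlgError:
                jitter *= 10.0
                logger.info("kernel matrix singular; jitter raised to %g", jitter)
                if jitter > 1e-2:
                    raise
        return self

    def _neg_log_marginal_likelihood(self, log_params: np.ndarray) -> float:
        sigma2, length_scale = np.exp(log_params)
        k = self._kernel(self.x_obs, self.x_obs, sigma2, length_scale)
        k += self.jitter * np.eye(len(k))
        try:
            chol = scipy.linalg.cholesky(k, lower=True)
        except scipy.linalg.LinAlgError:
            return 1e10
        alpha = scipy.linalg.cho_solve((chol, True), self.y_obs)
        return float(
            0.5 * self.y_obs @ alpha
            + np.sum(np.log(np.diag(chol)))
            + 0.5 * len(self.y_obs) * np.log(2 * np.pi)
        )

    def fit_hyperparameters(self) -> "GaussianProcess":
        """Maximum-likelihood (σ², ℓ) on the current observations."""
        if self.x_obs is None:
            raise ValueError("fit observations first")
        res = scipy.optimize.minimize(
            self._neg_log_marginal_likelihood,
            x0=np.log([self.sigma2, self.length_scale]),
            method="L-BFGS-B",
            bounds=[(np.log(1e-6), np.log(1e3)), (np.log(1e-3), np.log(1e2))],
        )
        self.sigma2, self.length_scale = np.exp(res.x)
        return self.fit(self.x_obs, self.y_obs)

    def predict(self, x_new):
        """Posterior (mean, variance) at x_new (row per point)."""
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if self._chol is None:
            raise ValueError("GP not fitted")
        k_star = self._kernel(self.x_obs, x_new)
        alpha = scipy.linalg.cho_solve((self._chol, True), self.y_obs)
        mean = k_star.T @ alpha
        v = scipy.linalg.solve_triangular(self._chol, k_star, lower=True)
        var = np.clip(self.sigma2 - np.sum(v**2, axis=0), 0.0, None)
        return mean, var


def expected_improvement(mean, variance, f_best: float) -> np.ndarray:
    """Closed-form EI for maximization; 0 where variance is 0 and mean does
    not exceed the incumbent."""
    mean = np.asarray(mean, dtype=float)
    sd = np.sqrt(np.clip(np.asarray(variance, dtype=float), 0.0, None))
    improve = mean - f_best
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, improve / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(sd > 0, improve * norm.cdf(z) + sd * norm.pdf(z), np.maximum(improve, 0.0))
    return np.clip(ei, 0.0, None)


@dataclass
class OptimizationTrace:
    """Per-iteration record of the Bayesian optimization run."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def best_so_far(self) -> np.ndarray:
        return self.records["best_so_far"].to_numpy()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _sample_simplex(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.dirichlet(np.ones(3), size=size)


def optimize_weights(
    table: ScoreTable | pd.DataFrame,
    n_random: int = 15,
    n_guided: int = 100,
    seed: int | None = None,
    candidate_pool: int = 2000,
) -> tuple[WeightVector, OptimizationTrace]:
    """Maximize O(w) over the weight simplex with the 15 + 100 call budget.

    Fully reproducible given ``seed``; returns the best observed weights
    (normalized) and the iteration trace.
    """
    rng = np.random.default_rng(seed)
    df = table.df if isinstance(table, ScoreTable) else table

    xs: list[np.ndarray] = []
    ys: list[float] = []
    rows: list[dict] = []

    def evaluate(w_arr: np.ndarray, phase: str) -> None:
        wv = WeightVector.from_array(w_arr)
        o, c_cos, c_frob, c_sw = objective(wv, df)
        xs.append(wv.as_array())
        ys.append(o)
        rows.append(
            {
                "iteration": len(rows) + 1,
                "phase": phase,
                "w_cosine": wv.w_cosine,
                "w_frobenius": wv.w_frobenius,
                "w_sw": wv.w_sw,
                "objective": o,
                "c_cosine": c_cos,
                "c_frobenius": c_frob,
                "c_sw": c_sw,
                "best_so_far": max(o, rows[-1]["best_so_far"]) if rows else o,
            }
        )

    for w in _sample_simplex(rng, n_random):
        evaluate(w, "random")

    gp = GaussianProcess(sigma2=1.0, length_scale=0.2)
    for _ in range(n_guided):
        gp.fit(np.vstack(xs), np.asarray(ys)).fit_hyperparameters()
        candidates = _sample_simplex(rng, candidate_pool)
        mean, var = gp.predict(candidates)
        ei = expected_improvement(mean, var, max(ys))
        evaluate(candidates[int(np.argmax(ei))], "guided")

    best = int(np.argmax(ys))
    trace = OptimizationTrace(records=pd.DataFrame(rows))
    return WeightVector.from_array(xs[best]), trace
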