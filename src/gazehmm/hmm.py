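"""Hidden Markov models with bivariate Gaussian emissions.

The hidden states play the role of data-driven regions of interest (ROIs):
each state emits fixation coordinates from its own 2-D Gaussian, the prior
gives the probability that a fixation sequence starts in each ROI, and the
transition matrix carries the temporal structure of the scan path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import EmptySequenceError, GazeHmmError

_SIMPLEX_ATOL = 1e-9


def gaussian_logpdf(xy: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at each row of ``xy`` (shape (n, 2))."""
    xy = np.atleast_2d(xy)
    d = xy.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = xy - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def is_spd(mat: np.ndarray, atol: float = 1e-10) -> bool:
    if not np.allclose(mat, mat.T, atol=atol):
        return False
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        return False
    return True


def nearest_spd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetrize and floor eigenvalues so the matrix is usable as a covariance."""
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


@dataclass
class HiddenMarkovModel:
    """Prior, transition matrix and K Gaussian ROIs.

    Parameters
    ----------
    prior : (K,) probability vector over starting states.
    transition : (K, K) row-stochastic matrix.
    means : (K, 2) ROI centres in degrees of visual angle.
    covariances : (K, 2, 2) symmetric positive-definite ROI covariances (deg^2).
    """

    prior: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float).reshape(len(self.prior), -1)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.validate()

    @property
    def K(self) -> int:
        return len(self.prior)

    @property
    def n_dim(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        K = self.K
        if self.transition.shape != (K, K):
            raise GazeHmmError(f"transition must be {K}x{K}")
        if self.covariances.shape != (K, self.n_dim, self.n_dim):
            raise GazeHmmError("covariance stack has wrong shape")
        if not np.isclose(self.prior.sum(), 1.0, atol=_SIMPLEX_ATOL) or np.any(self.prior < -_SIMPLEX_ATOL):
            raise GazeHmmError("prior is not a probability vector")
        rows = self.transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_SIMPLEX_ATOL) or np.any(self.transition < -_SIMPLEX_ATOL):
            raise GazeHmmError("transition matrix is not row-stochastic")
        for k in range(K):
            if not is_spd(self.covariances[k]):
                raise GazeHmmError(f"covariance of state {k} is not SPD")

    # ------------------------------------------------------------------ #
    def emission_logpdf(self, xy: np.ndarray) -> np.ndarray:
        """(n, K) matrix of per-state Gaussian log densities."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.empty((xy.shape[0], self.K))
        for k in range(self.K):
            out[:, k] = gaussian_logpdf(xy, self.means[k], self.covariances[k])
        return out

    def log_likelihood(self, xy: np.ndarray) -> float:
        """Marginal log-likelihood of one fixation sequence (forward algorithm).

        Uses the scaled forward recursion, so it stays finite for long
        sequences and SPD covariances.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if xy.shape[0] == 0:
            raise EmptySequenceError("cannot score an empty fixation sequence")
        logb = self.emission_logpdf(xy)
        shift = logb.max(axis=1)
        b = np.exp(logb - shift[:, None])
        alpha = self.prior * b[0]
        c = alpha.sum()
        loglik = np.log(c) + shift[0]
        alpha /= c
        for t in range(1, xy.shape[0]):
            alpha = (alpha @ self.transition) * b[t]
            c = alpha.sum()
            loglik += np.log(c) + shift[t]
            alpha /= c
        return float(loglik)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the transition chain (left eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition.T)
        idx = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()

    def dispersion(self) -> float:
        """Spread statistic used to tell centralized from distributed patterns.

        Stationary-weighted mean covariance trace plus the stationary-weighted
        variance of the ROI means around their weighted centroid. Small values
        mean gaze concentrated in one tight region.
        """
        w = self.stationary_distribution()
        mean_trace = float(np.sum(w * np.trace(self.covariances, axis1=1, axis2=2)))
        centroid = w @ self.means
        spread = float(np.sum(w * np.sum((self.means - centroid) ** 2, axis=1)))
        return mean_trace + spread

    def permute(self, order: Iterable[int]) -> "HiddenMarkovModel":
        """Return an equivalent model with states relabelled by ``order``."""
        order = np.asarray(list(order), dtype=int)
        return HiddenMarkovModel(
            prior=self.prior[order],
            transition=self.transition[np.ix_(order, order)],
            means=self.means[order],
            covariances=self.covariances[order],
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "prior": self.prior.tolist(),
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HiddenMarkovModel":
        return cls(
            prior=np.array(d["prior"], dtype=float),
            transition=np.array(d["transition"], dtype=float),
            means=np.array(d["means"], dtype=float),
            covariances=np.array(d["covariances"], dtype=float),
            meta=dict(d.get("meta", {})),
        )
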