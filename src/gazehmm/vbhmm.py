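"""Variational Bayesian EM for Gaussian-emission HMMs.

Each participant's fixation sequences (one chain per 10-s window, the chain
resets at window boundaries) are modelled by an HMM whose hidden states are
data-driven ROIs. Conjugate priors are placed on every parameter — Dirichlet
on the prior vector and on each transition row, Normal–Wishart on each ROI's
Gaussian — and a factorized variational posterior is optimized by alternating
a forward–backward E-step under expected log-parameters with conjugate
posterior updates. The number of states K is selected by refitting over a
range (3..6 by default) and keeping the solution with the highest variational
lower bound (the quantity VBEM maximizes; it penalizes K implicitly).

The returned point model uses posterior means: normalized Dirichlet weights,
Normal–Wishart mean vectors, and inverse-Wishart mean covariances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import digamma, gammaln
from sklearn.cluster import KMeans

from .errors import FitError
from .fixations import FixationSequence
from .hmm import HiddenMarkovModel, nearest_spd

logger = logging.getLogger(__name__)

_D = 2  # observation dimension: fixation x, y


def _det2(M: np.ndarray) -> np.ndarray:
    """Determinant of stacked 2x2 matrices."""
    return M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]


def _inv2(M: np.ndarray) -> np.ndarray:
    """Inverse of stacked 2x2 matrices."""
    det = _det2(M)
    out = np.empty_like(M)
    out[..., 0, 0] = M[..., 1, 1]
    out[..., 1, 1] = M[..., 0, 0]
    out[..., 0, 1] = -M[..., 0, 1]
    out[..., 1, 0] = -M[..., 1, 0]
    return out / det[..., None, None]

#: screen bounds used for the default prior scale (deg, half-extent)
SCREEN_HALF_EXTENT = (16.0, 10.0)


def _default_nw_scale() -> np.ndarray:
    # prior ROI SD targeted at ~1/16 of the screen diagonal
    diag = 2.0 * np.hypot(*SCREEN_HALF_EXTENT)
    return np.eye(_D) * (diag / 16.0) ** 2 * (5.0 - 3.0)


@dataclass
class VBPriors:
    """Hyperparameters of the conjugate priors.

    ``nw_scale`` is the inverse-Wishart scale on the emission covariance, so
    the prior mean covariance is ``nw_scale / (nw_dof - 3)`` (d = 2).
    """

    dirichlet_concentration: float = 1.0
    nw_mean: np.ndarray = field(default_factory=lambda: np.zeros(_D))
    nw_beta: float = 1.0
    nw_scale: np.ndarray = field(default_factory=_default_nw_scale)
    nw_dof: float = 5.0

    def __post_init__(self) -> None:
        self.nw_mean = np.asarray(self.nw_mean, dtype=float)
        self.nw_scale = np.asarray(self.nw_scale, dtype=float)
        if self.dirichlet_concentration <= 0 or self.nw_beta <= 0:
            raise FitError("concentration and nw_beta must be positive")
        if self.nw_dof <= _D - 1:
            raise FitError("nw_dof must exceed d - 1")
        if not np.allclose(self.nw_scale, self.nw_scale.T):
            raise FitError("nw_scale must be symmetric")


@dataclass
class FitResult:
    """One fitted HMM plus the evidence trail of the fit."""

    model: HiddenMarkovModel
    lower_bound: float
    n_iterations: int
    converged: bool
    K_candidates: Dict[int, float] = field(default_factory=dict)
    lower_bound_trace: List[float] = field(default_factory=list)
    log_likelihood: Optional[float] = None


# --------------------------------------------------------------------------- #
#  batching
# --------------------------------------------------------------------------- #

def _stack_sequences(sequences: Sequence[Union[FixationSequence, np.ndarray]]
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Pad sequences into (N, Tmax, 2) with a boolean validity mask."""
    arrays = []
    for s in sequences:
        a = s.xy if isinstance(s, FixationSequence) else np.atleast_2d(np.asarray(s, float))
        if a.shape[0] >= 1:
            arrays.append(a)
    if not arrays:
        raise FitError("no non-empty sequences to fit")
    tmax = max(a.shape[0] for a in arrays)
    X = np.zeros((len(arrays), tmax, _D))
    mask = np.zeros((len(arrays), tmax), dtype=bool)
    for i, a in enumerate(arrays):
        X[i, : a.shape[0]] = a
        mask[i, : a.shape[0]] = True
    return X, mask


def _fb_core_py(b: np.ndarray, lengths: np.ndarray, pi: np.ndarray, A: np.ndarray):
    """Per-sequence scaled forward–backward (explicit loops; numba-compiled)."""
    N, T, K = b.shape
    loglik = np.zeros(N)
    gamma = np.zeros((N, T, K))
    xi = np.zeros((K, K))
    ginit = np.zeros(K)
    alpha = np.zeros((T, K))
    beta = np.zeros((T, K))
    c = np.zeros(T)
    for n in range(N):
        Tn = int(lengths[n])
        c0 = 0.0
        for k in range(K):
            alpha[0, k] = pi[k] * b[n, 0, k]
            c0 += alpha[0, k]
        c[0] = c0
        loglik[n] += np.log(c0)
        for k in range(K):
            alpha[0, k] /= c0
        for t in range(1, Tn):
            ct = 0.0
            for k in range(K):
                acc = 0.0
                for j in range(K):
                    acc += alpha[t - 1, j] * A[j, k]
                v = acc * b[n, t, k]
                alpha[t, k] = v
                ct += v
            c[t] = ct
            loglik[n] += np.log(ct)
            for k in range(K):
                alpha[t, k] /= ct
        for k in range(K):
            beta[Tn - 1, k] = 1.0
        for t in range(Tn - 2, -1, -1):
            for k in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[k, j] * b[n, t + 1, j] * beta[t + 1, j]
                beta[t, k] = acc / c[t + 1]
            for k in range(K):
                w = alpha[t, k] / c[t + 1]
                for j in range(K):
                    xi[k, j] += w * A[k, j] * b[n, t + 1, j] * beta[t + 1, j]
        for t in range(Tn):
            norm = 0.0
            for k in range(K):
                g = alpha[t, k] * beta[t, k]
                gamma[n, t, k] = g
                norm += g
            for k in range(K):
                gamma[n, t, k] /= norm
        for k in range(K):
            ginit[k] += gamma[n, 0, k]
    return loglik, gamma, xi, ginit


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _fb_core = njit(cache=False)(_fb_core_py)
except Exception:  # pragma: no cover
    _fb_core = _fb_core_py


def _forward_backward(log_b: np.ndarray, mask: np.ndarray,
                      log_pi: np.ndarray, log_A: np.ndarray):
    """Scaled forward–backward over a padded batch.

    ``log_pi`` / ``log_A`` may be expected log-parameters (sub-normalized).
    Padded steps are skipped entirely, so each sequence's likelihood and
    posteriors use only its own observations. Returns (loglik per sequence,
    gamma, xi_sum, gamma_init).
    """
    shift = np.where(mask, log_b.max(axis=2), 0.0)
    b = np.exp(log_b - shift[:, :, None])
    lengths = mask.sum(axis=1).astype(np.int64)
    loglik, gamma, xi_sum, ginit = _fb_core(
        np.ascontiguousarray(b), lengths, np.exp(log_pi), np.exp(log_A)
    )
    loglik = loglik + shift.sum(axis=1)
    return loglik, gamma, xi_sum, ginit


# --------------------------------------------------------------------------- #
#  posterior bookkeeping
# --------------------------------------------------------------------------- #

class _Posterior:
    """Variational posterior: Dirichlets + Normal–Wisharts for K states."""

    def __init__(self, K: int, priors: VBPriors):
        self.K = K
        self.priors = priors
        self.W0inv = priors.nw_scale            # inverse-Wishart scale on covariance
        self.W0 = np.linalg.inv(self.W0inv)     # Wishart scale on precision
        self.alpha_pi = np.full(K, priors.dirichlet_concentration)
        self.alpha_A = np.full((K, K), priors.dirichlet_concentration)
        self.beta = np.full(K, priors.nw_beta)
        self.m = np.tile(priors.nw_mean, (K, 1))
        self.W = np.tile(self.W0, (K, 1, 1))
        self.nu = np.full(K, priors.nw_dof)

    # -- M-step ------------------------------------------------------- #
    def update(self, X: np.ndarray, mask: np.ndarray,
               gamma: np.ndarray, xi_sum: np.ndarray, gamma_init: np.ndarray) -> None:
        p = self.priors
        self.alpha_pi = p.dirichlet_concentration + gamma_init
        self.alpha_A = p.dirichlet_concentration + xi_sum
        flatX = X.reshape(-1, _D)
        flatG = gamma.reshape(-1, self.K)
        Nk = flatG.sum(axis=0)                       # (K,)
        safe = np.maximum(Nk, 1e-12)
        xbar = (flatG.T @ flatX) / safe[:, None]     # (K, 2)
        self.beta = p.nw_beta + Nk
        self.nu = p.nw_dof + Nk
        self.m = (p.nw_beta * p.nw_mean + Nk[:, None] * xbar) / self.beta[:, None]
        # scatter via second moments: S_k = E[xx^T] - N_k xbar xbar^T
        x, y = flatX[:, 0], flatX[:, 1]
        S2 = np.empty((self.K, _D, _D))
        S2[:, 0, 0] = flatG.T @ (x * x)
        S2[:, 0, 1] = S2[:, 1, 0] = flatG.T @ (x * y)
        S2[:, 1, 1] = flatG.T @ (y * y)
        Sk = S2 - Nk[:, None, None] * np.einsum("ki,kj->kij", xbar, xbar)
        dm = xbar - p.nw_mean
        psi = (self.W0inv[None] + Sk
               + (p.nw_beta * Nk / self.beta)[:, None, None]
               * np.einsum("ki,kj->kij", dm, dm))
        nearly_empty = Nk < 2.0
        if nearly_empty.any():
            psi[nearly_empty] += 1e-6 * np.eye(_D)
            logger.debug("%d nearly-empty states; ridge added", nearly_empty.sum())
        self.W = _inv2(psi)
        self._Nk = Nk

    # -- expected log-parameters for the E-step ------------------------ #
    def expected_log_pi(self) -> np.ndarray:
        return digamma(self.alpha_pi) - digamma(self.alpha_pi.sum())

    def expected_log_A(self) -> np.ndarray:
        return digamma(self.alpha_A) - digamma(self.alpha_A.sum(axis=1))[:, None]

    def expected_logdet_precision(self) -> np.ndarray:
        return (digamma(0.5 * self.nu) + digamma(0.5 * (self.nu - 1))
                + _D * np.log(2.0) + np.log(_det2(self.W)))

    def expected_log_emission(self, X: np.ndarray) -> np.ndarray:
        """(N, T, K) expected Gaussian log density under the NW posterior."""
        N, T, _ = X.shape
        elogdet = self.expected_logdet_precision()
        flat = X.reshape(-1, _D)
        dx = flat[:, 0][:, None] - self.m[:, 0][None, :]        # (n, K)
        dy = flat[:, 1][:, None] - self.m[:, 1][None, :]
        quad = (self.W[:, 0, 0][None] * dx * dx
                + 2.0 * self.W[:, 0, 1][None] * dx * dy
                + self.W[:, 1, 1][None] * dy * dy)
        val = 0.5 * (elogdet[None, :] - _D / self.beta[None, :]
                     - self.nu[None, :] * quad - _D * np.log(2 * np.pi))
        return val.reshape(N, T, self.K)

    # -- KL terms of the lower bound ----------------------------------- #
    def kl(self) -> float:
        p = self.priors
        rows = np.vstack([self.alpha_pi[None, :], self.alpha_A])   # (K+1, K)
        a0 = np.full(self.K, p.dirichlet_concentration)
        sa = rows.sum(axis=1)
        kl_dir = float(
            np.sum(gammaln(sa) - gammaln(a0.sum())
                   - (gammaln(rows) - gammaln(a0)[None, :]).sum(axis=1)
                   + ((rows - a0) * (digamma(rows) - digamma(sa)[:, None])).sum(axis=1))
        )
        # Normal part, expectation over the Wishart precision
        dm = self.m - p.nw_mean
        quad = np.einsum("ki,kij,kj->k", dm, self.W, dm)
        kl_gauss = 0.5 * np.sum(
            _D * np.log(self.beta / p.nw_beta) + _D * p.nw_beta / self.beta - _D
            + p.nw_beta * self.nu * quad
        )
        # Wishart part
        logdetW = np.log(_det2(self.W))
        elogdet = self.expected_logdet_precision()
        kl_wish = np.sum(
            _log_wishart_B(self.W, self.nu, logdetW)
            - _log_wishart_B(self.W0, p.nw_dof)
            + 0.5 * (self.nu - p.nw_dof) * elogdet
            - 0.5 * self.nu * _D
            + 0.5 * self.nu * np.einsum("ij,kji->k", self.W0inv, self.W)
        )
        return kl_dir + float(kl_gauss + kl_wish)

    # -- point estimate ------------------------------------------------ #
    def mean_model(self) -> HiddenMarkovModel:
        prior = self.alpha_pi / self.alpha_pi.sum()
        trans = self.alpha_A / self.alpha_A.sum(axis=1, keepdims=True)
        denom = np.maximum(self.nu - _D - 1.0, 1e-6)
        covs = _inv2(self.W) / denom[:, None, None]
        covs = np.stack([nearest_spd(c) for c in covs])
        return HiddenMarkovModel(prior=prior, transition=trans,
                                 means=self.m.copy(), covariances=covs)


def _log_wishart_B(W: np.ndarray, nu, logdet=None):
    """Log normalizer of the Wishart distribution (vectorized over a stack)."""
    if logdet is None:
        logdet = np.log(_det2(W))
    return (
        -0.5 * nu * logdet - 0.5 * nu * _D * np.log(2.0)
        - 0.25 * _D * (_D - 1) * np.log(np.pi)
        - gammaln(0.5 * nu) - gammaln(0.5 * (nu - 1))
    )


# --------------------------------------------------------------------------- #
#  fitting
# --------------------------------------------------------------------------- #

def _init_responsibilities(X, mask, K, rng) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means split of pooled fixations, one-hot softened, restart-jittered."""
    pts = X[mask]
    if len(np.unique(pts, axis=0)) >= K:
        km = KMeans(n_clusters=K, n_init=1,
                    random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(pts)
    else:
        labels = rng.integers(K, size=len(pts))
    gamma = np.zeros((len(pts), K))
    gamma[np.arange(len(pts)), labels] = 1.0
    gamma = 0.85 * gamma + 0.15 * rng.dirichlet(np.ones(K), size=len(pts))
    full = np.zeros((X.shape[0], X.shape[1], K))
    full[mask] = gamma
    # transition pseudo-counts from consecutive soft labels
    xi = np.zeros((K, K))
    for n in range(X.shape[0]):
        T_n = int(mask[n].sum())
        g = full[n, :T_n]
        if T_n > 1:
            xi += g[:-1].T @ g[1:]
    return full, xi, full[:, 0, :].sum(axis=0)


def fit_vbhmm(
    sequences: Sequence[Union[FixationSequence, np.ndarray]],
    K: int,
    priors: Optional[VBPriors] = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> FitResult:
    """Fit a K-state Gaussian HMM by VBEM; best of ``n_restarts`` by lower bound.

    The variational lower bound is non-decreasing over iterations within each
    restart; convergence is declared when its relative increase drops below
    ``tol``.
    """
    if K < 1:
        raise FitError("K must be >= 1")
    priors = priors or VBPriors()
    X, mask = _stack_sequences(sequences)
    root = np.random.default_rng(seed)
    best: Optional[Tuple[float, _Posterior, List[float], bool]] = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31))
        post = _Posterior(K, priors)
        gamma, xi, ginit = _init_responsibilities(X, mask, K, rng)
        post.update(X, mask, gamma, xi, ginit)
        trace: List[float] = []
        converged = False
        for _ in range(max_iter):
            log_b = post.expected_log_emission(X)
            loglik, gamma, xi, ginit = _forward_backward(
                log_b, mask, post.expected_log_pi(), post.expected_log_A()
            )
            elbo = float(loglik.sum()) - post.kl()
            trace.append(elbo)
            if len(trace) > 1:
                delta = trace[-1] - trace[-2]
                if abs(delta) < tol * abs(trace[-1]):
                    converged = True
                    break
            post.update(X, mask, gamma, xi, ginit)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], post, trace, converged)
    elbo, post, trace, converged = best
    model = post.mean_model()
    ll = float(sum(model.log_likelihood(X[n, : mask[n].sum()])
                   for n in range(X.shape[0])))
    return FitResult(model=model, lower_bound=elbo, n_iterations=len(trace),
                     converged=converged, K_candidates={K: elbo},
                     lower_bound_trace=trace, log_likelihood=ll)


def select_model(
    sequences: Sequence[Union[FixationSequence, np.ndarray]],
    K_min: int = 3,
    K_max: int = 6,
    priors: Optional[VBPriors] = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
    criterion: str = "lower_bound",
) -> FitResult:
    """Fit every K in [K_min, K_max] and keep the best one.

    ``criterion`` selects by the variational lower bound (default; the
    quantity VBEM maximizes) or by the raw data log-likelihood of the
    posterior-mean model (``"log_likelihood"``).
    """
    if K_min > K_max or K_min < 1:
        raise FitError("need 1 <= K_min <= K_max")
    if criterion not in ("lower_bound", "log_likelihood"):
        raise FitError(f"unknown selection criterion {criterion!r}")
    fits: Dict[int, FitResult] = {}
    for K in range(K_min, K_max + 1):
        fits[K] = fit_vbhmm(sequences, K, priors=priors, n_restarts=n_restarts,
                            seed=seed + K, tol=tol, max_iter=max_iter)
    score = (lambda f: f.lower_bound) if criterion == "lower_bound" \
        else (lambda f: f.log_likelihood)
    best_K = max(fits, key=lambda K: score(fits[K]))
    result = fits[best_K]
    result.K_candidates = {K: score(fits[K]) for K in fits}
    return result


def log_likelihood(model: HiddenMarkovModel,
                   seq: Union[FixationSequence, np.ndarray]) -> float:
    """Forward-algorithm log-likelihood of one fixation sequence."""
    xy = seq.xy if isinstance(seq, FixationSequence) else np.asarray(seq, float)
    return model.log_likelihood(xy)
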