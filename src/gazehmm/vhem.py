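"""Clustering HMMs by variational hierarchical EM (VHEM).

Groups the per-participant HMMs into clusters (two, in this analysis) and
produces one representative HMM per cluster, using only the parameters of the
input models — no fixation data is revisited. Expectations are taken over
*virtual* observation sequences of a fixed length drawn from each input HMM:
the E-step computes a variational lower bound on the expected log-likelihood
of each representative with respect to each input via a log-sum-exp backward
recursion over paired (input-state, representative-state) chains, inputs are
then (re)assigned to their most similar representative, and the M-step
updates representative parameters from the expected co-occupancy statistics.
The best of many random restarts (100 by default) by total expected
log-likelihood is returned.

Representatives get K equal to the median K of the input models (lower median
on ties). The two representatives are labelled *centralized* / *distributed*
by their gaze dispersion statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ClusteringError, LabelingError
from .hmm import HiddenMarkovModel, nearest_spd

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    """Cluster assignments, representatives and diagnostics."""

    assignments: Dict[str, int]
    representatives: List[HiddenMarkovModel]
    expected_log_likelihood: float
    n_roi_representative: int
    labels: Dict[int, str] = field(default_factory=dict)
    similarity: Optional[np.ndarray] = None  # (n_models, n_clusters)
    objective_trace: List[float] = field(default_factory=list)

    def representative(self, label: str) -> HiddenMarkovModel:
        """Representative HMM by its 'centralized'/'distributed' label."""
        for cluster, lab in self.labels.items():
            if lab == label:
                return self.representatives[cluster]
        raise LabelingError(f"no representative labelled {label!r}")

    def to_dict(self) -> dict:
        return {
            "assignments": dict(self.assignments),
            "representatives": [m.to_dict() for m in self.representatives],
            "expected_log_likelihood": self.expected_log_likelihood,
            "n_roi_representative": self.n_roi_representative,
            "labels": {str(k): v for k, v in self.labels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusteringResult":
        return cls(
            assignments={k: int(v) for k, v in d["assignments"].items()},
            representatives=[HiddenMarkovModel.from_dict(m) for m in d["representatives"]],
            expected_log_likelihood=float(d["expected_log_likelihood"]),
            n_roi_representative=int(d["n_roi_representative"]),
            labels={int(k): v for k, v in d.get("labels", {}).items()},
        )


def median_k(models: Sequence[HiddenMarkovModel]) -> int:
    """Median state count over models; even count takes the lower median."""
    ks = sorted(m.K for m in models)
    return ks[(len(ks) - 1) // 2]


# --------------------------------------------------------------------------- #
#  pairwise expected log-likelihood machinery
# --------------------------------------------------------------------------- #

def _lse_last(x: np.ndarray) -> np.ndarray:
    """Log-sum-exp over the last axis (fast path, no scipy dispatch)."""
    m = x.max(axis=-1, keepdims=True)
    return (m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True)))[..., 0]


def _rep_context(rep: HiddenMarkovModel):
    """Per-representative quantities reused across every base model."""
    inv = np.linalg.inv(rep.covariances)                 # (Kr, d, d)
    sign, logdet = np.linalg.slogdet(rep.covariances)
    return rep.means, inv, logdet


def _gauss_cross_loglik(base: HiddenMarkovModel, rep: HiddenMarkovModel,
                        ctx=None) -> np.ndarray:
    """l[b, r] = E_{x ~ N_b(base)}[log N_r(rep)(x)], closed form for Gaussians."""
    means_r, inv_r, logdet_r = ctx if ctx is not None else _rep_context(rep)
    d = base.n_dim
    dm = base.means[:, None, :] - means_r[None, :, :]          # (Kb, Kr, d)
    tr = np.einsum("bij,rji->br", base.covariances, inv_r)
    maha = np.einsum("bri,rij,brj->br", dm, inv_r, dm)
    return -0.5 * (d * np.log(2 * np.pi) + logdet_r[None, :] + tr + maha)


def expected_log_likelihood(base: HiddenMarkovModel, rep: HiddenMarkovModel,
                            virtual_length: int = 20) -> float:
    """Variational lower bound on E_base[log p(virtual sequence | rep)]."""
    val, _ = _pair_bound(base, rep, virtual_length)
    return val


def _pair_bound(base: HiddenMarkovModel, rep: HiddenMarkovModel,
                tau: int) -> Tuple[float, List[np.ndarray]]:
    """Backward log-sum-exp recursion.

    Returns the bound and the time-indexed variational assignments
    ``phi[0]`` of shape (Kb, Kr) — softmax over representative start states
    per base start state — and ``phi[t]`` (t >= 1) of shape (Kr, Kb, Kr):
    softmax over the representative's next state given its current state and
    the base's next state.
    """
    l = _gauss_cross_loglik(base, rep)
    log_a_i = np.log(np.maximum(base.transition, 1e-300))
    log_a_j = np.log(np.maximum(rep.transition, 1e-300))
    log_pi_j = np.log(np.maximum(rep.prior, 1e-300))

    G = l.copy()                       # G_tau(b, r)
    phis: List[np.ndarray] = [None] * tau
    for t in range(tau - 1, 0, -1):
        # scores[r, b', r'] = log a_j[r, r'] + G_{t+1}(b', r')
        scores = log_a_j[:, None, :] + G[None, :, :]
        lse = _lse_last(scores)                    # (Kr, Kb)
        phis[t] = np.exp(scores - lse[:, :, None])  # (Kr, Kb', Kr')
        # G_t(b, r) = l(b, r) + sum_{b'} a_i[b, b'] * lse[r, b']
        G = l + base.transition @ lse.T
    start_scores = log_pi_j[None, :] + G           # (Kb, Kr)
    start_lse = _lse_last(start_scores)            # (Kb,)
    phis[0] = np.exp(start_scores - start_lse[:, None])
    bound = float(base.prior @ start_lse)
    return bound, phis


def _bounds_matrix(models: Sequence[HiddenMarkovModel],
                   reps: Sequence[HiddenMarkovModel], tau: int) -> np.ndarray:
    """L[i, j] = variational expected log-likelihood bound, batched.

    Models are grouped by their state count so the whole backward recursion
    runs as a few stacked array operations instead of one Python loop per
    (model, representative) pair. Identical in value to :func:`_pair_bound`.
    """
    Kr = reps[0].K
    log_a_j = np.stack([np.log(np.maximum(r.transition, 1e-300)) for r in reps])
    log_pi_j = np.stack([np.log(np.maximum(r.prior, 1e-300)) for r in reps])
    L = np.empty((len(models), len(reps)))
    groups: Dict[int, List[int]] = {}
    for i, m in enumerate(models):
        groups.setdefault(m.K, []).append(i)
    ctxs = [_rep_context(r) for r in reps]
    for Kb, idx in groups.items():
        sub = [models[i] for i in idx]
        a_i = np.stack([m.transition for m in sub])                 # (n, Kb, Kb)
        pri = np.stack([m.prior for m in sub])                      # (n, Kb)
        l = np.stack([
            np.stack([_gauss_cross_loglik(m, r, ctx)                # (m, Kb, Kr)
                      for r, ctx in zip(reps, ctxs)])
            for m in sub
        ])                                                          # (n, m, Kb, Kr)
        G = l.copy()
        for _ in range(tau - 1):
            scores = log_a_j[None, :, :, None, :] + G[:, :, None, :, :]
            lse = _lse_last(scores)                                 # (n, m, Kr, Kb)
            G = l + np.einsum("nbc,nmrc->nmbr", a_i, lse)
        start = _lse_last(log_pi_j[None, :, None, :] + G)           # (n, m, Kb)
        L[idx, :] = np.einsum("nb,nmb->nm", pri, start)
    return L


def _pair_statistics(base: HiddenMarkovModel, phis: List[np.ndarray], tau: int):
    """Expected co-occupancy statistics of (base-state, rep-state) chains.

    Returns (nu1[r], Xi[r, r'], M[b, r]) where nu1 is the expected start
    occupancy of the representative's states, Xi the expected transition
    counts, and M the total expected pairing mass between base and
    representative states over the virtual sequence.
    """
    Kb, Kr = phis[0].shape
    nu = base.prior[:, None] * phis[0]             # (b, r)
    nu1 = nu.sum(axis=0)
    M = nu.copy()
    Xi = np.zeros((Kr, Kr))
    for t in range(1, tau):
        # flow[c, r, s]: next base state c, current rep state r, next rep state s
        flow = np.einsum("br,bc,rcs->crs", nu, base.transition, phis[t])
        Xi += flow.sum(axis=0)
        nu = flow.sum(axis=1)  # (next base, next rep)
        M += nu
    return nu1, Xi, M


def _batch_statistics(sub: Sequence[HiddenMarkovModel], rep: HiddenMarkovModel,
                      tau: int, ctx=None):
    """Expected co-occupancy statistics for same-K base models, batched.

    Returns (nu1, Xi, mass, mean_acc, second_acc) already summed over the
    batch: expected representative start occupancy, transition counts, total
    pairing mass per representative state, and mass-weighted first/second
    moments of the base emissions (second moment = cov + mean meanT).
    """
    Kr = rep.K
    d = rep.n_dim
    log_a_j = np.log(np.maximum(rep.transition, 1e-300))
    log_pi_j = np.log(np.maximum(rep.prior, 1e-300))
    a_i = np.stack([m.transition for m in sub])                  # (n, Kb, Kb)
    pri = np.stack([m.prior for m in sub])                       # (n, Kb)
    l = np.stack([_gauss_cross_loglik(m, rep, ctx) for m in sub])  # (n, Kb, Kr)
    G = l.copy()
    phis = [None] * tau
    for t in range(tau - 1, 0, -1):
        scores = log_a_j[None, :, None, :] + G[:, None, :, :]    # (n, Kr, Kb, Kr)
        lse = _lse_last(scores)
        phis[t] = np.exp(scores - lse[..., None])
        G = l + np.einsum("nbc,nrc->nbr", a_i, lse)
    start_scores = log_pi_j[None, None, :] + G                   # (n, Kb, Kr)
    phis[0] = np.exp(start_scores - _lse_last(start_scores)[..., None])

    nu = pri[:, :, None] * phis[0]                               # (n, b, r)
    nu1 = nu.sum(axis=1)
    M = nu.copy()
    Xi = np.zeros((len(sub), Kr, Kr))
    for t in range(1, tau):
        flow = np.einsum("nbr,nbc,nrcs->ncrs", nu, a_i, phis[t])
        Xi += flow.sum(axis=1)
        nu = flow.sum(axis=2)
        M += nu
    means_b = np.stack([m.means for m in sub])                   # (n, Kb, d)
    second_b = np.stack([
        m.covariances + np.einsum("bi,bj->bij", m.means, m.means) for m in sub
    ])                                                           # (n, Kb, d, d)
    mass = M.sum(axis=(0, 1))                                    # (Kr,)
    mean_acc = np.einsum("nbr,nbd->rd", M, means_b)
    second_acc = np.einsum("nbr,nbij->rij", M, second_b)
    return nu1.sum(axis=0), Xi.sum(axis=0), mass, mean_acc, second_acc


def _mstep_representative(members: Sequence[HiddenMarkovModel],
                          rep: HiddenMarkovModel, tau: int) -> HiddenMarkovModel:
    """M-step: pool expected statistics of the assigned input models."""
    Kr, d = rep.K, rep.n_dim
    nu1 = np.zeros(Kr)
    Xi = np.zeros((Kr, Kr))
    mass = np.zeros(Kr)
    mean_acc = np.zeros((Kr, d))
    second_acc = np.zeros((Kr, d, d))
    ctx = _rep_context(rep)
    groups: Dict[int, List[HiddenMarkovModel]] = {}
    for m in members:
        groups.setdefault(m.K, []).append(m)
    for sub in groups.values():
        n1, xi, ms, ma, sa = _batch_statistics(sub, rep, tau, ctx)
        nu1 += n1
        Xi += xi
        mass += ms
        mean_acc += ma
        second_acc += sa
    prior = nu1 / nu1.sum()
    trans = np.empty_like(Xi)
    means = np.empty((Kr, d))
    covs = np.empty((Kr, d, d))
    for r in range(Kr):
        row = Xi[r]
        trans[r] = row / row.sum() if row.sum() > 1e-12 else rep.transition[r]
        if mass[r] > 1e-12:
            means[r] = mean_acc[r] / mass[r]
            cov = second_acc[r] / mass[r] - np.outer(means[r], means[r])
            covs[r] = nearest_spd(cov)
        else:
            means[r] = rep.means[r]
            covs[r] = rep.covariances[r]
    return HiddenMarkovModel(prior=prior, transition=trans,
                             means=means, covariances=covs)


def _init_representative(models: Sequence[HiddenMarkovModel], K_rep: int,
                         rng: np.random.Generator) -> HiddenMarkovModel:
    """Seed a representative from a random input HMM with K >= K_rep,
    keeping its K_rep highest-stationary-mass states."""
    candidates = [m for m in models if m.K >= K_rep]
    src = candidates[int(rng.integers(len(candidates)))]
    if src.K == K_rep:
        keep = np.arange(K_rep)
    else:
        keep = np.argsort(src.stationary_distribution())[::-1][:K_rep]
        keep = np.sort(keep)
    prior = src.prior[keep]
    prior = prior / prior.sum()
    trans = src.transition[np.ix_(keep, keep)]
    trans = trans / trans.sum(axis=1, keepdims=True)
    # small jitter so duplicate inputs in different restarts break symmetry
    means = src.means[keep] + rng.normal(0.0, 1e-3, size=(K_rep, src.n_dim))
    return HiddenMarkovModel(prior=prior, transition=trans, means=means,
                             covariances=src.covariances[keep].copy())


def cluster_hmms(
    models: Sequence[HiddenMarkovModel],
    n_clusters: int = 2,
    n_restarts: int = 100,
    seed: int = 0,
    virtual_length: int = 20,
    max_iter: int = 30,
    tol: float = 1e-5,
    names: Optional[Sequence[str]] = None,
) -> ClusteringResult:
    """Cluster HMMs and build representative HMMs; best restart wins.

    ``virtual_length`` is the length of the virtual observation sequences the
    expectations are taken over (about the number of fixations in one 10-s
    window at typical fixation rates). Ties in similarity assign to cluster 0.
    """
    models = list(models)
    if len(models) < n_clusters:
        raise ClusteringError(
            f"need at least {n_clusters} models, got {len(models)}"
        )
    if names is None:
        names = [str(i) for i in range(len(models))]
    K_rep = median_k(models)
    root = np.random.default_rng(seed)
    best: Optional[Tuple[float, List[HiddenMarkovModel], np.ndarray]] = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31))
        reps = [_init_representative(models, K_rep, rng) for _ in range(n_clusters)]
        prev_obj = -np.inf
        trace: List[float] = []
        for _ in range(max_iter):
            L = _bounds_matrix(models, reps, virtual_length)
            assign = L.argmax(axis=1)
            obj = float(L[np.arange(len(models)), assign].sum())
            trace.append(obj)
            if obj - prev_obj < tol * max(1.0, abs(obj)) and prev_obj > -np.inf:
                break
            prev_obj = obj
            for j in range(n_clusters):
                member_idx = np.flatnonzero(assign == j)
                if len(member_idx) == 0:
                    continue  # keep the previous representative
                members = [models[i] for i in member_idx]
                reps[j] = _mstep_representative(members, reps[j], virtual_length)
        if best is None or obj > best[0]:
            best = (obj, reps, L, trace)
    obj, reps, L, trace = best
    assign = L.argmax(axis=1)
    assignments = {names[i]: int(assign[i]) for i in range(len(models))}
    result = ClusteringResult(
        assignments=assignments,
        representatives=reps,
        expected_log_likelihood=obj,
        n_roi_representative=K_rep,
        similarity=L,
        objective_trace=trace,
    )
    return label_representatives(result)


def label_representatives(result: ClusteringResult) -> ClusteringResult:
    """Attach 'centralized'/'distributed' labels by the dispersion statistic.

    Dispersion is the stationary-weighted mean covariance trace plus the
    stationary-weighted variance of ROI means around their weighted centroid;
    the larger-dispersion representative is the distributed one. A tie within
    1e-9 is refused (the patterns cannot be told apart automatically).
    """
    if len(result.representatives) != 2:
        raise LabelingError("labelling requires exactly two representatives")
    disp = [m.dispersion() for m in result.representatives]
    if abs(disp[0] - disp[1]) < 1e-9:
        raise LabelingError("representatives have identical dispersion; inspect manually")
    hi = int(np.argmax(disp))
    result.labels = {hi: "distributed", 1 - hi: "centralized"}
    return result
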