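"""Mind-wandering measures and group statistics.

Objective measure: signal-detection sensitivity d' towards the No-go target
(withholding to the target is a *hit*; responding to it a *miss*; failing to
respond to a Go letter a *false alarm*; responding to a Go letter a *correct
rejection*). Subjective measure: each block-end thought probe is labelled
focused attention (FA), mind-wandering (MW) or excluded from its content
option (1-5) and focus rating (1-7). Eye-movement measure: the D-C scale

    dc = (D_MLL - C_MLL) / (|D_MLL| + |C_MLL|)

where D_MLL / C_MLL are the participant's mean log-likelihoods under the
distributed / centralized representative HMMs; positive dc means more
distributed-like viewing. Trial-level coupling between gaze pattern and
attentional state is tested with the likelihood-ratio G² test on a 2x2
contingency table plus its odds ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError
from .fixations import FixationSequence
from .hmm import HiddenMarkovModel
from .vbhmm import log_likelihood

logger = logging.getLogger(__name__)

FA, MW, EXCLUDED = "FA", "MW", "excluded"


@dataclass(frozen=True)
class SartRecord:
    """One trial of the SART behavioral log."""

    participant: str
    block: int
    trial_index: int          # 1-based within block
    letter: str
    is_target: bool
    responded: bool
    rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.is_target and self.letter != "C":
            raise AnalysisError("No-go target must be the letter C")
        if self.responded and self.rt_ms is None:
            raise AnalysisError("responded trials need an RT")
        if not self.responded and self.rt_ms is not None and not np.isnan(self.rt_ms):
            raise AnalysisError("unresponded trials cannot carry an RT")


@dataclass(frozen=True)
class ProbeResponse:
    """One block-end thought probe: content option 1-5 and focus rating 1-7."""

    participant: str
    block: int
    option: int
    rating: int

    def __post_init__(self) -> None:
        if not 1 <= self.option <= 5:
            raise AnalysisError(f"probe option {self.option} out of range 1-5")
        if not 1 <= self.rating <= 7:
            raise AnalysisError(f"focus rating {self.rating} out of range 1-7")


@dataclass(frozen=True)
class SdtCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_nogo(self) -> int:
        return self.hits + self.misses

    @property
    def n_go(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class DCScore:
    """Distributed-vs-centralized placement of one participant."""

    participant: str
    d_mll: float
    c_mll: float
    dc: float


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = pattern (centralized, distributed), cols = (FA, MW)."""

    centralized_fa: int
    centralized_mw: int
    distributed_fa: int
    distributed_mw: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.centralized_fa, self.centralized_mw],
             [self.distributed_fa, self.distributed_mw]],
            dtype=float,
        )


# --------------------------------------------------------------------------- #
#  SDT scoring
# --------------------------------------------------------------------------- #

def score_sdt(records: Sequence[SartRecord]) -> SdtCounts:
    """Tally hits / misses / false alarms / correct rejections."""
    h = m = fa = cr = 0
    for r in records:
        if r.is_target:
            if r.responded:
                m += 1
            else:
                h += 1
        else:
            if r.responded:
                cr += 1
            else:
                fa += 1
    return SdtCounts(hits=h, misses=m, false_alarms=fa, correct_rejections=cr)


def dprime(counts: SdtCounts, correction: str = "log_linear") -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate).

    The log-linear correction (0.5 added to each cell, 1 to each denominator)
    is applied unconditionally so extreme rates stay finite.
    """
    if counts.n_nogo == 0 or counts.n_go == 0:
        raise AnalysisError("need at least one trial of each class for d'")
    if correction == "log_linear":
        hit_rate = (counts.hits + 0.5) / (counts.n_nogo + 1.0)
        fa_rate = (counts.false_alarms + 0.5) / (counts.n_go + 1.0)
    elif correction == "none":
        hit_rate = counts.hits / counts.n_nogo
        fa_rate = counts.false_alarms / counts.n_go
    else:
        raise AnalysisError(f"unknown correction {correction!r}")
    return float(sps.norm.ppf(hit_rate) - sps.norm.ppf(fa_rate))


def windowed_records(records: Sequence[SartRecord], window_trials: int = 5
                     ) -> List[SartRecord]:
    """Restrict Go trials to those inside the pre-target windows.

    Keeps every No-go trial plus the ``window_trials`` Go trials immediately
    preceding it within the same block (5 trials x 2 s = the 10-s window).
    """
    by_block: Dict[Tuple[str, int], List[SartRecord]] = {}
    for r in records:
        by_block.setdefault((r.participant, r.block), []).append(r)
    out: List[SartRecord] = []
    for recs in by_block.values():
        targets = [r for r in recs if r.is_target]
        if not targets:
            continue
        tpos = targets[0].trial_index
        for r in recs:
            if r.is_target or tpos - window_trials <= r.trial_index < tpos:
                out.append(r)
    return out


# --------------------------------------------------------------------------- #
#  labelling
# --------------------------------------------------------------------------- #

def label_objective(record: SartRecord) -> str:
    """FA if the No-go target was withheld, MW if a commission error."""
    if not record.is_target:
        raise AnalysisError("objective labelling needs the No-go target trial")
    return MW if record.responded else FA


def label_subjective(probe: ProbeResponse) -> str:
    """FA / MW / excluded from the probe's content option and focus rating.

    Options 1-2 with rating 5-7 are FA; options 3-4 with rating 1-3 are MW;
    option 5 ("nothing in particular") follows the rating alone; rating 4 is
    the ambiguous state and is excluded; incongruent pairs (task-focused
    content with a low rating, or off-task content with a high rating) are
    excluded as well.
    """
    if probe.rating == 4:
        return EXCLUDED
    focused = probe.rating >= 5
    if probe.option in (1, 2):
        return FA if focused else EXCLUDED
    if probe.option in (3, 4):
        return EXCLUDED if focused else MW
    return FA if focused else MW  # option 5 resolved by the rating


def proportion_fa(labels: Iterable[str]) -> float:
    """Fraction of probes labelled FA, out of *all* probes (excluded included)."""
    labels = list(labels)
    if not labels:
        raise AnalysisError("need at least one probe")
    return sum(1 for l in labels if l == FA) / len(labels)


# --------------------------------------------------------------------------- #
#  D-C scale and trial classification
# --------------------------------------------------------------------------- #

def dc_score(
    seqs: Sequence[FixationSequence],
    distributed_rep: HiddenMarkovModel,
    centralized_rep: HiddenMarkovModel,
    participant: str = "",
    per_fixation: bool = False,
) -> DCScore:
    """Mean log-likelihood under both representatives and the D-C scale.

    ``per_fixation`` normalizes each sequence's log-likelihood by its length
    before averaging (off by default; 10-s windows have near-equal lengths).
    """
    seqs = [s for s in seqs if len(s) > 0]
    if not seqs:
        raise AnalysisError("dc_score needs at least one non-empty sequence")
    norm = (lambda s: len(s)) if per_fixation else (lambda s: 1.0)
    d_mll = float(np.mean([log_likelihood(distributed_rep, s) / norm(s) for s in seqs]))
    c_mll = float(np.mean([log_likelihood(centralized_rep, s) / norm(s) for s in seqs]))
    denom = abs(d_mll) + abs(c_mll)
    if denom == 0.0:
        raise AnalysisError("both mean log-likelihoods are zero; dc undefined")
    return DCScore(participant=participant, d_mll=d_mll, c_mll=c_mll,
                   dc=(d_mll - c_mll) / denom)


def classify_trial(
    seq: FixationSequence,
    distributed_rep: HiddenMarkovModel,
    centralized_rep: HiddenMarkovModel,
) -> str:
    """'centralized' or 'distributed', whichever representative scores higher.

    Exact ties go to 'centralized' (and are logged); with continuous
    emissions they have measure zero.
    """
    if len(seq) == 0:
        raise AnalysisError("cannot classify an empty sequence")
    ll_d = log_likelihood(distributed_rep, seq)
    ll_c = log_likelihood(centralized_rep, seq)
    if ll_d == ll_c:
        logger.info("trial likelihood tie; assigning centralized")
        return "centralized"
    return "distributed" if ll_d > ll_c else "centralized"


# --------------------------------------------------------------------------- #
#  G² test and group statistics
# --------------------------------------------------------------------------- #

def g2_test(table: ContingencyTable) -> Tuple[float, float, float]:
    """Likelihood-ratio chi-squared test and odds ratio for a 2x2 table.

    G² = 2 Σ O ln(O/E) with expecteds from the independence margins (empty
    cells contribute zero); p from chi² with 1 df; OR = ad/bc with the
    Haldane–Anscombe 0.5 correction when a cell is empty (OR only).
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise AnalysisError("G² needs positive row and column margins")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g2 = float(2.0 * terms.sum())
    p = float(sps.chi2.sf(g2, df=1))
    a, b = obs[0]
    c, d = obs[1]
    if min(a, b, c, d) == 0:
        logger.info("empty cell; Haldane–Anscombe correction applied to the OR")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = float((a * d) / (b * c))
    return g2, p, odds_ratio


@dataclass(frozen=True)
class GroupStats:
    """Two-sample, paired and correlation statistics for one comparison."""

    t_ind: Optional[float] = None
    p_ind: Optional[float] = None
    df_ind: Optional[float] = None
    cohen_d: Optional[float] = None
    t_paired: Optional[float] = None
    p_paired: Optional[float] = None
    df_paired: Optional[float] = None
    pearson_r: Optional[float] = None
    p_r: Optional[float] = None


def group_stats(
    group_a: Optional[Sequence[float]] = None,
    group_b: Optional[Sequence[float]] = None,
    paired_pairs: Optional[Sequence[Tuple[float, float]]] = None,
    xy_pairs: Optional[Sequence[Tuple[float, float]]] = None,
) -> GroupStats:
    """Independent / paired t statistics, pooled-SD Cohen's d and Pearson r."""
    out: Dict[str, float] = {}
    if group_a is not None and group_b is not None:
        a = np.asarray(group_a, float)
        b = np.asarray(group_b, float)
        if len(a) < 2 or len(b) < 2:
            raise AnalysisError("need >= 2 values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise AnalysisError("degenerate variance in both groups")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        out.update(
            t_ind=float(t), p_ind=float(p), df_ind=float(len(a) + len(b) - 2),
            cohen_d=float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0,
        )
    if paired_pairs is not None:
        arr = np.asarray(paired_pairs, float)
        if arr.shape[0] < 2:
            raise AnalysisError("need >= 2 pairs for a paired t-test")
        diffs = arr[:, 0] - arr[:, 1]
        if diffs.std(ddof=1) == 0:
            raise AnalysisError("degenerate variance of paired differences")
        t, p = sps.ttest_rel(arr[:, 0], arr[:, 1])
        out.update(t_paired=float(t), p_paired=float(p),
                   df_paired=float(arr.shape[0] - 1))
    if xy_pairs is not None:
        arr = np.asarray(xy_pairs, float)
        if arr.shape[0] < 3:
            raise AnalysisError("need >= 3 pairs for Pearson r")
        if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
            raise AnalysisError("degenerate variance for correlation")
        r, p = sps.pearsonr(arr[:, 0], arr[:, 1])
        out.update(pearson_r=float(r), p_r=float(p))
    return GroupStats(**out)
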