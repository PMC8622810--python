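"""Synthetic SART cohort generator.

Emulates the study design the analysis assumes: a sustained attention to
response task of 40 blocks x 25 two-second letter trials with one No-go
target (the letter C) per block at positions 6-15, a thought probe at each
block end (5 content options plus a 1-7 focus rating), and gaze driven by a
latent attentional state per block. The latent state (focused attention, FA,
vs mind-wandering, MW) jointly selects which gaze archetype generates the
block's fixations, the probability of a commission error on the No-go trial,
and the probe answer - so every downstream stage of the pipeline has ground
truth to recover.

Two gaze archetypes are shipped: a *centralized* pattern with tight ROIs near
the screen centre and a *distributed* pattern with wide, spread-out ROIs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import ArchetypeLabelError, ConfigError, EmptySequenceError
from .fixations import FixationSequence, GazeSample, sequences_to_frame
from .hmm import HiddenMarkovModel

ARCHETYPE_LABELS = ("centralized", "distributed")

#: letters shown in the task: A-Y (25 letters, Z excluded); C is the No-go target.
LETTERS = [c for c in string.ascii_uppercase[:25]]
TARGET_LETTER = "C"
GO_LETTERS = [c for c in LETTERS if c != TARGET_LETTER]

MIN_FIX_DURATION_MS = 60.0
#: fixation durations: log-normal, median 250 ms, sigma_log 0.4, floored at 60 ms
FIX_DURATION_MEDIAN_MS = 250.0
FIX_DURATION_SIGMA_LOG = 0.4
SACCADE_GAP_MS = 30.0


@dataclass
class ArchetypeSpec:
    """A generative gaze pattern: an HMM plus its archetype label."""

    label: str
    hmm: HiddenMarkovModel

    def __post_init__(self) -> None:
        if self.label not in ARCHETYPE_LABELS:
            raise ArchetypeLabelError(f"unknown archetype label {self.label!r}")

    # convenience views matching the published parameterization
    @property
    def n_rois(self) -> int:
        return self.hmm.K

    @property
    def roi_means(self) -> np.ndarray:
        return self.hmm.means

    @property
    def roi_covariances(self) -> np.ndarray:
        return self.hmm.covariances

    @property
    def prior(self) -> np.ndarray:
        return self.hmm.prior

    @property
    def transition(self) -> np.ndarray:
        return self.hmm.transition

    def dispersion(self) -> float:
        """Unweighted spread: mean covariance trace + variance of ROI means."""
        mean_trace = float(np.mean(np.trace(self.roi_covariances, axis1=1, axis2=2)))
        centroid = self.roi_means.mean(axis=0)
        spread = float(np.mean(np.sum((self.roi_means - centroid) ** 2, axis=1)))
        return mean_trace + spread


def make_archetype(label: str, seed: int) -> ArchetypeSpec:
    """Build one of the two shipped gaze archetypes, deterministically.

    ``centralized``: three ROIs hugging the screen centre, small covariances,
    strong return transitions to the central ROI. ``distributed``: three ROIs
    spread across (and beyond) the stimulus region with wide covariances and a
    well-mixing chain. The seed jitters ROI placement slightly so cohorts are
    not all identical; the jitter is small enough that the centralized
    archetype always has the smaller dispersion statistic.
    """
    if label not in ARCHETYPE_LABELS:
        raise ArchetypeLabelError(f"unknown archetype label {label!r}")
    rng = np.random.default_rng(seed)
    if label == "centralized":
        means = np.array([[0.0, 0.0], [-1.8, 0.5], [1.8, 0.5]])
        means = means + rng.normal(0.0, 0.2, size=means.shape)
        covs = np.stack(
            [
                np.diag([0.6**2, 0.6**2]),
                np.diag([0.9**2, 0.7**2]),
                np.diag([0.9**2, 0.7**2]),
            ]
        )
        prior = np.array([0.7, 0.15, 0.15])
        transition = np.array(
            [
                [0.85, 0.075, 0.075],
                [0.60, 0.30, 0.10],
                [0.60, 0.10, 0.30],
            ]
        )
    else:
        means = np.array([[0.0, 0.0], [-10.0, -5.0], [10.0, 5.0]])
        means = means + rng.normal(0.0, 0.8, size=means.shape)
        covs = np.stack(
            [
                np.diag([2.5**2, 2.0**2]),
                np.diag([3.0**2, 2.5**2]),
                np.diag([3.0**2, 2.5**2]),
            ]
        )
        prior = np.array([0.4, 0.3, 0.3])
        transition = np.array(
            [
                [0.50, 0.25, 0.25],
                [0.30, 0.50, 0.20],
                [0.30, 0.20, 0.50],
            ]
        )
    hmm = HiddenMarkovModel(prior=prior, transition=transition, means=means,
                            covariances=covs, meta={"archetype": label})
    return ArchetypeSpec(label=label, hmm=hmm)


def sample_fixation_sequence(
    spec: ArchetypeSpec,
    n_fixations: int,
    rng: np.random.Generator,
    participant: str = "",
    window_type: str = "raw",
    window_id: int = 0,
) -> FixationSequence:
    """Simulate the hidden ROI chain and emit one fixation per step.

    Onsets accumulate fixation durations (log-normal, floored at 60 ms) plus a
    fixed saccade gap, so onsets are strictly increasing and non-overlapping.
    """
    if n_fixations < 1:
        raise EmptySequenceError("n_fixations must be >= 1")
    hmm = spec.hmm
    states = np.empty(n_fixations, dtype=int)
    states[0] = rng.choice(hmm.K, p=hmm.prior)
    for t in range(1, n_fixations):
        states[t] = rng.choice(hmm.K, p=hmm.transition[states[t - 1]])
    xy = np.empty((n_fixations, 2))
    for k in range(hmm.K):
        mask = states == k
        n_k = int(mask.sum())
        if n_k:
            xy[mask] = rng.multivariate_normal(hmm.means[k], hmm.covariances[k], size=n_k)
    durations = FIX_DURATION_MEDIAN_MS * np.exp(
        rng.normal(0.0, FIX_DURATION_SIGMA_LOG, size=n_fixations)
    )
    durations = np.maximum(durations, MIN_FIX_DURATION_MS)
    onsets = np.concatenate(
        [[0.0], np.cumsum(durations[:-1] + SACCADE_GAP_MS)]
    )
    seq = FixationSequence(
        xy=xy, onset=onsets, duration=durations,
        participant=participant, window_type=window_type, window_id=window_id,
        meta={"states": states},
    )
    return seq


def render_gaze_samples(
    seq: FixationSequence,
    rate_hz: float = 100.0,
    saccade_velocity_degps: float = 300.0,
    jitter_deg: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> List[GazeSample]:
    """Render a fixation sequence back into a raw gaze-sample trace.

    The trace is stationary at each fixation's position (plus optional
    Gaussian jitter) for its duration, then moves in a straight line at
    ``saccade_velocity_degps`` toward the next fixation, holding there until
    that fixation's onset. Round-tripping through fixation detection recovers
    the fixation count and centroids.
    """
    if rate_hz <= 0:
        raise ConfigError("rate_hz must be positive")
    if saccade_velocity_degps <= 100.0:
        raise ConfigError("saccade velocity must exceed the 100 deg/s threshold")
    if len(seq) == 0:
        return []
    if jitter_deg > 0 and rng is None:
        rng = np.random.default_rng(0)
    step = 1000.0 / rate_hz
    t0 = seq.onset[0]
    t_end = seq.onset[-1] + seq.duration[-1]
    times = np.arange(t0, t_end - 1e-9, step)
    pos = np.empty((len(times), 2))
    pos[:] = seq.xy[0]
    for i in range(len(seq)):
        start, dur = seq.onset[i], seq.duration[i]
        in_fix = (times >= start - 1e-9) & (times < start + dur - 1e-9)
        pos[in_fix] = seq.xy[i]
        if i + 1 < len(seq):
            p0, p1 = seq.xy[i], seq.xy[i + 1]
            dist = float(np.linalg.norm(p1 - p0))
            transit_ms = dist / saccade_velocity_degps * 1000.0
            t_leave = start + dur
            in_transit = (times >= t_leave - 1e-9) & (times < t_leave + transit_ms - 1e-9)
            if in_transit.any():
                frac = (times[in_transit] - t_leave) / max(transit_ms, 1e-9)
                pos[in_transit] = p0 + frac[:, None] * (p1 - p0)
            after = times >= t_leave + transit_ms - 1e-9
            pos[after] = p1
    if jitter_deg > 0:
        pos = pos + rng.normal(0.0, jitter_deg, size=pos.shape)
    return [GazeSample(t=float(t), x=float(p[0]), y=float(p[1])) for t, p in zip(times, pos)]


# --------------------------------------------------------------------------- #
#  Cohort simulation
# --------------------------------------------------------------------------- #

def _default_mw_rates() -> Dict[str, float]:
    return {"centralized": 0.10, "distributed": 0.75}


@dataclass
class CohortConfig:
    """Study-design parameters for one simulated cohort.

    Defaults mirror the task structure the analysis expects: 40 blocks of 25
    two-second trials, one No-go target per block at positions 6-15, a probe
    per block. ``mw_base_rate`` maps participant group to the per-block
    probability of the latent mind-wandering state; commission probabilities
    give the chance of failing to withhold on the No-go trial in each latent
    state.
    """

    n_participants_per_group: int = 8
    n_blocks: int = 40
    trials_per_block: int = 25
    trial_duration: float = 2.0          # seconds, ITI included
    mw_base_rate: Dict[str, float] = field(default_factory=_default_mw_rates)
    commission_prob_fa: float = 0.20
    commission_prob_mw: float = 0.65
    go_miss_prob: float = 0.05
    fixation_rate: float = 2.0           # mean fixations per second
    contamination: float = 0.10          # probe answer disagrees with latent state
    window_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.commission_prob_fa, self.commission_prob_mw,
                 self.go_miss_prob, self.contamination, *self.mw_base_rate.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.n_participants_per_group < 1 or self.n_blocks < 1 or self.trials_per_block < 10:
            raise ConfigError("cohort dimensions out of range")
        if set(self.mw_base_rate) != set(ARCHETYPE_LABELS):
            raise ConfigError("mw_base_rate must map both archetype groups")


@dataclass
class Cohort:
    """One simulated cohort: fixation windows, behavioral log, probes, truth."""

    config: CohortConfig
    archetypes: Dict[str, ArchetypeSpec]
    sequences: List[FixationSequence]
    sart: pd.DataFrame
    probes: pd.DataFrame
    latent: pd.DataFrame
    groups: Dict[str, str]

    @property
    def participants(self) -> List[str]:
        return sorted(self.groups)

    def sequences_for(self, participant: Optional[str] = None,
                      window_type: Optional[str] = None) -> List[FixationSequence]:
        out = self.sequences
        if participant is not None:
            out = [s for s in out if s.participant == participant]
        if window_type is not None:
            out = [s for s in out if s.window_type == window_type]
        return out

    def to_files(self, outdir: str | Path, include_gaze: bool = False,
                 rate_hz: float = 100.0, saccade_velocity_degps: float = 300.0) -> Dict[str, Path]:
        """Write the delimited outputs; ground truth goes to its own file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fixations": outdir / "fixations.csv",
            "behavior": outdir / "behavior.csv",
            "latent": outdir / "latent_states.csv",
        }
        sequences_to_frame(self.sequences).to_csv(paths["fixations"], index=False)
        self.sart.to_csv(paths["behavior"], index=False)
        self.latent.to_csv(paths["latent"], index=False)
        if include_gaze:
            rows = []
            for seq in self.sequences:
                for s in render_gaze_samples(seq, rate_hz=rate_hz,
                                             saccade_velocity_degps=saccade_velocity_degps):
                    rows.append({"participant": seq.participant, "block": seq.window_id,
                                 "t_ms": s.t, "x_deg": s.x, "y_deg": s.y})
            paths["gaze"] = outdir / "gaze.csv"
            pd.DataFrame(rows, columns=["participant", "block", "t_ms", "x_deg", "y_deg"]
                         ).to_csv(paths["gaze"], index=False)
        return paths


def _draw_probe(latent: str, rng: np.random.Generator, contamination: float):
    """Probe option and focus rating, consistent with the latent state unless
    contaminated (in which case the opposite state's distribution is used)."""
    state = latent
    if rng.random() < contamination:
        state = "MW" if latent == "FA" else "FA"
    if state == "FA":
        option = int(rng.choice([1, 2, 5]))
        rating = int(rng.integers(5, 8))
    else:
        option = int(rng.choice([3, 4, 5]))
        rating = int(rng.integers(1, 4))
    return option, rating


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort. Identical configs (same seed) give identical cohorts."""
    rng = np.random.default_rng(config.seed)
    archetypes = {
        label: make_archetype(label, seed=int(rng.integers(2**31)))
        for label in ARCHETYPE_LABELS
    }
    trial_ms = config.trial_duration * 1000.0
    mean_fix = config.fixation_rate * config.window_s

    sequences: List[FixationSequence] = []
    sart_rows, probe_rows, latent_rows = [], [], []
    groups: Dict[str, str] = {}

    for group in ARCHETYPE_LABELS:
        for i in range(config.n_participants_per_group):
            pid = f"{group[0]}{i + 1:02d}"
            groups[pid] = group
            for block in range(config.n_blocks):
                latent = "MW" if rng.random() < config.mw_base_rate[group] else "FA"
                latent_rows.append({"participant": pid, "block": block,
                                    "state": latent, "group": group})
                spec = archetypes["distributed" if latent == "MW" else "centralized"]
                target_pos = int(rng.integers(6, 16))  # 1-based trial index, 6..15
                p_commit = (config.commission_prob_mw if latent == "MW"
                            else config.commission_prob_fa)
                for trial in range(1, config.trials_per_block + 1):
                    is_target = trial == target_pos
                    if is_target:
                        letter = TARGET_LETTER
                        responded = bool(rng.random() < p_commit)
                    else:
                        letter = GO_LETTERS[int(rng.integers(len(GO_LETTERS)))]
                        responded = bool(rng.random() >= config.go_miss_prob)
                    rt = float(rng.uniform(250.0, 600.0)) if responded else np.nan
                    sart_rows.append({
                        "participant": pid, "block": block, "trial": trial,
                        "letter": letter, "is_target": is_target,
                        "responded": responded, "rt_ms": rt,
                    })
                option, rating = _draw_probe(latent, rng, config.contamination)
                probe_rows.append({"participant": pid, "block": block,
                                   "option": option, "rating": rating})
                for wtype in ("pre_target", "pre_probe"):
                    n_fix = max(2, int(rng.poisson(mean_fix)))
                    seq = sample_fixation_sequence(
                        spec, n_fix, rng, participant=pid,
                        window_type=wtype, window_id=block,
                    )
                    keep = seq.onset < config.window_s * 1000.0
                    keep[0] = True
                    seq = seq.subset(keep)
                    seq.meta["latent"] = latent
                    seq.meta["target_pos"] = target_pos
                    sequences.append(seq)

    sart = pd.DataFrame(sart_rows)
    probes = pd.DataFrame(probe_rows)
    # behavioral log carries the block's probe answer on every trial row
    sart = sart.merge(probes.rename(columns={"option": "probe_option",
                                             "rating": "probe_rating"}),
                      on=["participant", "block"], how="left")
    latent = pd.DataFrame(latent_rows)
    return Cohort(config=config, archetypes=archetypes, sequences=sequences,
                  sart=sart, probes=probes, latent=latent, groups=groups)
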