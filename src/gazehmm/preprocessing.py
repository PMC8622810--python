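"""Raw gaze to analysis-ready fixation sequences.

Implements a velocity-threshold fixation detector (saccade when point-to-point
velocity exceeds 100 deg/s, fixation when velocity stays below it for at least
60 ms), the per-participant 3-SD fixation-duration exclusion, and extraction
of the 10-s pre-target / pre-probe analysis windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .errors import WindowError
from .fixations import AnalysisEvent, FixationSequence, GazeSample

logger = logging.getLogger(__name__)

VELOCITY_THRESHOLD_DEGPS = 100.0
MIN_FIX_DURATION_MS = 60.0


def detect_fixations(
    samples: Sequence[GazeSample],
    velocity_threshold_degps: float = VELOCITY_THRESHOLD_DEGPS,
    min_duration_ms: float = MIN_FIX_DURATION_MS,
    participant: str = "",
    max_gap_factor: float = 2.0,
) -> FixationSequence:
    """Group gaze samples into fixations by the velocity-threshold rule.

    Velocity between consecutive valid samples is the Euclidean displacement
    divided by the sample interval (two-point estimate, no smoothing). Maximal
    runs whose internal velocities all stay below the threshold, whose samples
    are valid, and whose gaps do not exceed ``max_gap_factor`` times the median
    sample interval become candidate fixations; runs spanning less than
    ``min_duration_ms`` are discarded. Fixation position is the centroid of
    the run's samples; duration is the run's time span.
    """
    valid = [s for s in samples if s.valid]
    empty = FixationSequence(
        xy=np.empty((0, 2)), onset=np.empty(0), duration=np.empty(0),
        participant=participant, window_type="raw",
    )
    if len(valid) < 2:
        logger.warning("fewer than 2 valid gaze samples; returning empty sequence")
        return empty
    t = np.array([s.t for s in valid])
    xy = np.array([[s.x, s.y] for s in valid])
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise WindowError("gaze timestamps must be strictly increasing")
    vel = np.linalg.norm(np.diff(xy, axis=0), axis=1) / (dt / 1000.0)
    max_gap = max_gap_factor * float(np.median(dt))
    # link i -> i+1 is "smooth" when below threshold and not across a gap
    smooth = (vel < velocity_threshold_degps) & (dt <= max_gap + 1e-9)

    fixations: List[Tuple[np.ndarray, float, float]] = []
    run_start = 0
    for i in range(len(valid)):
        is_last = i == len(valid) - 1
        if is_last or not smooth[i]:
            span = t[i] - t[run_start]
            if span >= min_duration_ms - 1e-9:
                centroid = xy[run_start : i + 1].mean(axis=0)
                fixations.append((centroid, t[run_start], span))
            run_start = i + 1
    if not fixations:
        return empty
    return FixationSequence(
        xy=np.array([f[0] for f in fixations]),
        onset=np.array([f[1] for f in fixations]),
        duration=np.array([f[2] for f in fixations]),
        participant=participant,
        window_type="raw",
    )


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for the 3-SD duration exclusion of one participant."""

    n_total: int
    n_removed: int
    threshold_ms: float

    @property
    def fraction_removed(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 1.0 - (self.n_total - self.n_removed) / self.n_total


def exclude_outlier_fixations(
    sequences: Iterable[FixationSequence],
) -> Tuple[List[FixationSequence], ExclusionReport]:
    """Drop fixations whose duration exceeds the participant mean + 3 SD.

    Mean and (sample) SD are pooled over all of the participant's fixations in
    the given session; the inequality is strict, so with zero SD nothing is
    removed. Order and all other fixation fields are untouched.
    """
    seqs = list(sequences)
    durations = np.concatenate([s.duration for s in seqs]) if seqs else np.empty(0)
    n_total = len(durations)
    if n_total < 2:
        return seqs, ExclusionReport(n_total=n_total, n_removed=0, threshold_ms=np.inf)
    mean = float(durations.mean())
    sd = float(durations.std(ddof=1))
    threshold = mean + 3.0 * sd
    out = []
    n_removed = 0
    for seq in seqs:
        mask = seq.duration <= threshold
        n_removed += int((~mask).sum())
        out.append(seq.subset(mask) if not mask.all() else seq)
    if n_removed:
        logger.info("excluded %d/%d fixations above %.1f ms", n_removed, n_total, threshold)
    return out, ExclusionReport(n_total=n_total, n_removed=n_removed, threshold_ms=threshold)


def extract_window(
    seq: FixationSequence,
    event: AnalysisEvent,
    window_s: float = 10.0,
) -> FixationSequence:
    """Cut the fixations whose onset falls in [event.onset - window, event.onset).

    The window is half-open at the event: a fixation beginning exactly at the
    event is excluded. Events earlier than one window length into the
    recording yield a truncated window, flagged via ``truncated``. Fixation
    fields are never altered, only membership.
    """
    if len(seq) > 0:
        span_end = float(np.max(seq.onset + seq.duration))
        if event.onset < 0 or event.onset > span_end + window_s * 1000.0:
            raise WindowError(
                f"event at {event.onset} ms lies outside the recording span"
            )
    window_ms = window_s * 1000.0
    start = event.onset - window_ms
    mask = (seq.onset >= start) & (seq.onset < event.onset)
    return seq.subset(
        mask,
        window_type=event.window_type,
        window_id=event.block,
        truncated=bool(start < 0),
    )
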