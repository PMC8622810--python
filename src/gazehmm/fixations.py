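"""Core gaze data containers: raw samples, fixation sequences, analysis events.

Coordinate convention used throughout the package: degrees of visual angle,
origin at screen centre, x rightward, y downward, screen bounds roughly
±16 deg horizontally and ±10 deg vertically. Times are milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List

import numpy as np
import pandas as pd

from .errors import GazeHmmError

WINDOW_TYPES = ("raw", "pre_target", "pre_probe")


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze coordinate from the eye-tracker stream."""

    t: float          # ms
    x: float          # deg
    y: float          # deg
    valid: bool = True


@dataclass(frozen=True)
class AnalysisEvent:
    """A No-go target onset or a thought-probe onset within one block."""

    kind: str         # "no_go_target" | "probe"
    block: int
    onset: float      # ms

    def __post_init__(self) -> None:
        if self.kind not in ("no_go_target", "probe"):
            raise GazeHmmError(f"unknown event kind {self.kind!r}")

    @property
    def window_type(self) -> str:
        return "pre_target" if self.kind == "no_go_target" else "pre_probe"


@dataclass
class FixationSequence:
    """Ordered fixations within one recording or one 10-s analysis window.

    ``xy`` has shape (n, 2) in degrees; ``onset`` and ``duration`` are in ms.
    Invariants: durations >= 60 ms, onsets strictly increasing, and fixation i
    ends no later than fixation i+1 begins.
    """

    xy: np.ndarray
    onset: np.ndarray
    duration: np.ndarray
    participant: str = ""
    window_type: str = "raw"
    window_id: int = 0
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.onset = np.asarray(self.onset, dtype=float).reshape(-1)
        self.duration = np.asarray(self.duration, dtype=float).reshape(-1)
        if not (len(self.xy) == len(self.onset) == len(self.duration)):
            raise GazeHmmError("xy, onset and duration must have equal length")
        if self.window_type not in WINDOW_TYPES:
            raise GazeHmmError(f"unknown window_type {self.window_type!r}")

    def __len__(self) -> int:
        return len(self.onset)

    def validate(self, min_duration_ms: float = 60.0) -> None:
        if np.any(self.duration < min_duration_ms - 1e-9):
            raise GazeHmmError("fixation shorter than the minimum duration")
        if len(self) > 1:
            if np.any(np.diff(self.onset) <= 0):
                raise GazeHmmError("fixation onsets must be strictly increasing")
            if np.any(self.onset[:-1] + self.duration[:-1] > self.onset[1:] + 1e-9):
                raise GazeHmmError("fixations overlap")

    def subset(self, mask: np.ndarray, **changes) -> "FixationSequence":
        """A new sequence keeping rows where ``mask`` is true; fields untouched."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            xy=self.xy[mask],
            onset=self.onset[mask],
            duration=self.duration[mask],
            meta=dict(self.meta),
            **changes,
        )


def sequences_to_frame(seqs: Iterable[FixationSequence]) -> pd.DataFrame:
    """Flatten sequences into the package's delimited fixation table."""
    rows = []
    for seq in seqs:
        for i in range(len(seq)):
            rows.append(
                {
                    "participant": seq.participant,
                    "window_type": seq.window_type,
                    "window_id": seq.window_id,
                    "fix_index": i,
                    "x_deg": seq.xy[i, 0],
                    "y_deg": seq.xy[i, 1],
                    "onset_ms": seq.onset[i],
                    "duration_ms": seq.duration[i],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "window_type", "window_id", "fix_index",
            "x_deg", "y_deg", "onset_ms", "duration_ms",
        ],
    )


def frame_to_sequences(df: pd.DataFrame) -> List[FixationSequence]:
    """Inverse of :func:`sequences_to_frame`, grouped by participant/window."""
    seqs = []
    for (pid, wtype, wid), g in df.groupby(
        ["participant", "window_type", "window_id"], sort=True
    ):
        g = g.sort_values("fix_index")
        seqs.append(
            FixationSequence(
                xy=g[["x_deg", "y_deg"]].to_numpy(),
                onset=g["onset_ms"].to_numpy(),
                duration=g["duration_ms"].to_numpy(),
                participant=str(pid),
                window_type=str(wtype),
                window_id=int(wid),
            )
        )
    return seqs
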