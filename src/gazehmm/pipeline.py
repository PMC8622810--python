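"""End-to-end pipeline: simulate -> preprocess -> fit -> cluster -> analyze.

One `PipelineConfig` drives every stage; every random operation derives its
seed from the single root seed, so identical configs reproduce identical
outputs. Each stage writes delimited/JSON outputs plus a manifest with a
config hash and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from .errors import ConfigError, InputValidationError
from .fixations import FixationSequence, frame_to_sequences, sequences_to_frame
from .hmm import HiddenMarkovModel
from .preprocessing import exclude_outlier_fixations
from .synthetic import Cohort, CohortConfig, simulate_cohort
from .vbhmm import FitResult, VBPriors, select_model
from .vhem import ClusteringResult, cluster_hmms

logger = logging.getLogger(__name__)

WINDOW_TYPES = ("pre_target", "pre_probe")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study's stated values as defaults."""

    out_dir: str = "gazehmm_out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # preprocessing
    velocity_threshold_degps: float = 100.0
    min_fix_duration_ms: float = 60.0
    window_s: float = 10.0
    # fitting
    K_min: int = 3
    K_max: int = 6
    n_restarts_fit: int = 5
    selection_criterion: str = "lower_bound"
    # clustering
    n_clusters: int = 2
    n_restarts_cluster: int = 100
    virtual_length: int = 20
    # analysis
    dprime_scope: str = "windowed"   # "windowed" | "all"

    def __post_init__(self) -> None:
        if self.K_min > self.K_max:
            raise ConfigError("K_max must be >= K_min")
        if self.dprime_scope not in ("windowed", "all"):
            raise ConfigError(f"unknown dprime_scope {self.dprime_scope!r}")
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)

    # -- serialization -------------------------------------------------- #
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# --------------------------------------------------------------------------- #
#  stages as library functions
# --------------------------------------------------------------------------- #

def preprocess_sequences(
    sequences: Sequence[FixationSequence],
) -> Tuple[List[FixationSequence], Dict[str, float]]:
    """Per-participant 3-SD duration exclusion, pooled over both window types."""
    by_pid: Dict[str, List[FixationSequence]] = {}
    for s in sequences:
        by_pid.setdefault(s.participant, []).append(s)
    out: List[FixationSequence] = []
    fractions: Dict[str, float] = {}
    for pid in sorted(by_pid):
        kept, report = exclude_outlier_fixations(by_pid[pid])
        out.extend(kept)
        fractions[pid] = report.fraction_removed
    return out, fractions


def fit_participant_models(
    sequences: Sequence[FixationSequence],
    window_type: str,
    config: PipelineConfig,
    priors: Optional[VBPriors] = None,
) -> Dict[str, FitResult]:
    """One selected HMM per participant for the given window type."""
    by_pid: Dict[str, List[FixationSequence]] = {}
    for s in sequences:
        if s.window_type == window_type and len(s) > 0:
            by_pid.setdefault(s.participant, []).append(s)
    fits: Dict[str, FitResult] = {}
    base = _stage_seed(config.seed, f"fit:{window_type}")
    for i, pid in enumerate(sorted(by_pid)):
        fits[pid] = select_model(
            by_pid[pid],
            K_min=config.K_min,
            K_max=config.K_max,
            priors=priors,
            n_restarts=config.n_restarts_fit,
            seed=(base + 97 * i) % (2**31),
            criterion=config.selection_criterion,
        )
    return fits


def cluster_participant_models(
    fits: Dict[str, FitResult],
    config: PipelineConfig,
    window_type: str,
) -> ClusteringResult:
    pids = sorted(fits)
    return cluster_hmms(
        [fits[p].model for p in pids],
        n_clusters=config.n_clusters,
        n_restarts=config.n_restarts_cluster,
        seed=_stage_seed(config.seed, f"cluster:{window_type}"),
        virtual_length=config.virtual_length,
        names=pids,
    )


@dataclass
class AnalysisBundle:
    """Everything the analysis stage computes, for both window types."""

    participants: pd.DataFrame          # dc, mll, d', proportion FA, groups
    trials: pd.DataFrame                # per-window classification + outcome
    contingency: Dict[str, an.ContingencyTable]
    g2: Dict[str, Tuple[float, float, float]]          # window -> (G2, p, OR)
    stats: Dict[str, an.GroupStats]

    def to_json_dict(self) -> dict:
        return {
            "contingency": {w: t.as_array().tolist() for w, t in self.contingency.items()},
            "g2": {w: {"G2": v[0], "p": v[1], "odds_ratio": v[2]}
                   for w, v in self.g2.items()},
            "stats": {k: dataclasses.asdict(v) for k, v in self.stats.items()},
        }


def _sart_records(df: pd.DataFrame) -> Dict[str, List[an.SartRecord]]:
    recs: Dict[str, List[an.SartRecord]] = {}
    for row in df.itertuples(index=False):
        rt = getattr(row, "rt_ms", None)
        rt = None if rt is None or (isinstance(rt, float) and np.isnan(rt)) else float(rt)
        recs.setdefault(str(row.participant), []).append(
            an.SartRecord(
                participant=str(row.participant),
                block=int(row.block),
                trial_index=int(row.trial),
                letter=str(row.letter),
                is_target=bool(row.is_target),
                responded=bool(row.responded),
                rt_ms=rt,
            )
        )
    return recs


def analyze_cohort(
    sequences: Sequence[FixationSequence],
    sart: pd.DataFrame,
    probes: pd.DataFrame,
    clusterings: Dict[str, ClusteringResult],
    config: PipelineConfig,
) -> AnalysisBundle:
    """Compute the full results bundle from fitted/clustered material.

    Per participant: the D-C scale for each window type (group assignment by
    its sign), d' over the pre-target-window trials (or all trials per
    ``dprime_scope``), and the proportion of probes rated FA. Per trial: the
    gaze-pattern classification of each 10-s window against its objective
    (target withheld vs commission) or subjective (probe FA vs MW) outcome,
    pooled into a 2x2 G² test per window type.
    """
    records = _sart_records(sart)
    pids = sorted(records)

    probe_labels: Dict[str, List[str]] = {p: [] for p in pids}
    probe_label_by_block: Dict[Tuple[str, int], str] = {}
    for row in probes.itertuples(index=False):
        pr = an.ProbeResponse(str(row.participant), int(row.block),
                              int(row.option), int(row.rating))
        lab = an.label_subjective(pr)
        probe_labels[str(row.participant)].append(lab)
        probe_label_by_block[(str(row.participant), int(row.block))] = lab

    target_by_block: Dict[Tuple[str, int], an.SartRecord] = {}
    for pid, recs in records.items():
        for r in recs:
            if r.is_target:
                target_by_block[(pid, r.block)] = r

    rows = []
    for pid in pids:
        recs = records[pid]
        scored = an.windowed_records(recs) if config.dprime_scope == "windowed" else recs
        dp = an.dprime(an.score_sdt(scored))
        row = {"participant": pid, "dprime": dp,
               "proportion_fa": an.proportion_fa(probe_labels[pid])}
        for wtype in WINDOW_TYPES:
            if wtype not in clusterings:
                continue
            cl = clusterings[wtype]
            rep_d = cl.representative("distributed")
            rep_c = cl.representative("centralized")
            seqs = [s for s in sequences
                    if s.participant == pid and s.window_type == wtype and len(s) > 0]
            sc = an.dc_score(seqs, rep_d, rep_c, participant=pid)
            group = "distributed" if sc.dc > 0 else "centralized"
            row.update({
                f"dc_{wtype}": sc.dc,
                f"d_mll_{wtype}": sc.d_mll,
                f"c_mll_{wtype}": sc.c_mll,
                f"group_{wtype}": group,
            })
        rows.append(row)
    per_participant = pd.DataFrame(rows)

    trial_rows = []
    contingency: Dict[str, an.ContingencyTable] = {}
    g2: Dict[str, Tuple[float, float, float]] = {}
    for wtype in WINDOW_TYPES:
        if wtype not in clusterings:
            continue
        cl = clusterings[wtype]
        rep_d = cl.representative("distributed")
        rep_c = cl.representative("centralized")
        counts = {("centralized", an.FA): 0, ("centralized", an.MW): 0,
                  ("distributed", an.FA): 0, ("distributed", an.MW): 0}
        for seq in sequences:
            if seq.window_type != wtype or len(seq) == 0:
                continue
            key = (seq.participant, seq.window_id)
            if wtype == "pre_target":
                target = target_by_block.get(key)
                if target is None:
                    continue
                outcome = an.label_objective(target)
            else:
                outcome = probe_label_by_block.get(key, an.EXCLUDED)
                if outcome == an.EXCLUDED:
                    continue
            pattern = an.classify_trial(seq, rep_d, rep_c)
            counts[(pattern, outcome)] += 1
            trial_rows.append({"participant": seq.participant, "block": seq.window_id,
                               "window_type": wtype, "pattern": pattern,
                               "outcome": outcome})
        table = an.ContingencyTable(
            centralized_fa=counts[("centralized", an.FA)],
            centralized_mw=counts[("centralized", an.MW)],
            distributed_fa=counts[("distributed", an.FA)],
            distributed_mw=counts[("distributed", an.MW)],
        )
        contingency[wtype] = table
        g2[wtype] = an.g2_test(table)
    trials = pd.DataFrame(trial_rows,
                          columns=["participant", "block", "window_type",
                                   "pattern", "outcome"])

    stats: Dict[str, an.GroupStats] = {}
    if "pre_target" in clusterings:
        cen = per_participant[per_participant["group_pre_target"] == "centralized"]
        dis = per_participant[per_participant["group_pre_target"] == "distributed"]
        if len(cen) >= 2 and len(dis) >= 2:
            stats["dprime_by_group"] = an.group_stats(
                group_a=dis["dprime"], group_b=cen["dprime"]
            )
        stats["dc_vs_dprime"] = an.group_stats(
            xy_pairs=list(zip(per_participant["dc_pre_target"],
                              per_participant["dprime"]))
        )
    if "pre_probe" in clusterings:
        cen = per_participant[per_participant["group_pre_probe"] == "centralized"]
        dis = per_participant[per_participant["group_pre_probe"] == "distributed"]
        if len(cen) >= 2 and len(dis) >= 2:
            stats["proportion_fa_by_group"] = an.group_stats(
                group_a=dis["proportion_fa"], group_b=cen["proportion_fa"]
            )
        stats["dc_vs_proportion_fa"] = an.group_stats(
            xy_pairs=list(zip(per_participant["dc_pre_probe"],
                              per_participant["proportion_fa"]))
        )
    return AnalysisBundle(participants=per_participant, trials=trials,
                          contingency=contingency, g2=g2, stats=stats)


# --------------------------------------------------------------------------- #
#  full pipeline with file outputs
# --------------------------------------------------------------------------- #

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, make_plots: bool = False) -> AnalysisBundle:
    """Run every stage, writing versioned outputs and a manifest.

    Re-running with an identical config reproduces byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    # simulate ---------------------------------------------------------- #
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=_stage_seed(config.seed, "simulate")
    )
    cohort = simulate_cohort(cohort_cfg)
    paths = cohort.to_files(out)
    written.extend(paths.values())
    logger.info("simulate: %d participants, %d sequences",
                len(cohort.participants), len(cohort.sequences))

    # preprocess -------------------------------------------------------- #
    sequences, fractions = preprocess_sequences(cohort.sequences)
    prep_path = out / "fixations_clean.csv"
    sequences_to_frame(sequences).to_csv(prep_path, index=False)
    written.append(prep_path)
    excl_path = out / "exclusion_report.json"
    excl_path.write_text(json.dumps(fractions, indent=2, sort_keys=True))
    written.append(excl_path)

    # fit + cluster per window type ------------------------------------- #
    clusterings: Dict[str, ClusteringResult] = {}
    for wtype in WINDOW_TYPES:
        fits = fit_participant_models(sequences, wtype, config)
        models_path = out / f"models_{wtype}.json"
        models_path.write_text(json.dumps(
            {pid: {"model": f.model.to_dict(),
                   "lower_bound": f.lower_bound,
                   "K_candidates": {str(k): v for k, v in f.K_candidates.items()}}
             for pid, f in fits.items()}, indent=2, sort_keys=True))
        written.append(models_path)
        cl = cluster_participant_models(fits, config, wtype)
        clusterings[wtype] = cl
        cl_path = out / f"clusters_{wtype}.json"
        cl_path.write_text(json.dumps(cl.to_dict(), indent=2, sort_keys=True))
        written.append(cl_path)

    # analyze ----------------------------------------------------------- #
    bundle = analyze_cohort(sequences, cohort.sart, cohort.probes,
                            clusterings, config)
    part_path = out / "participants.csv"
    bundle.participants.to_csv(part_path, index=False, float_format="%.10g")
    trial_path = out / "trials.csv"
    bundle.trials.to_csv(trial_path, index=False)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(bundle.to_json_dict(), indent=2, sort_keys=True))
    written.extend([part_path, trial_path, summary_path])

    if make_plots:
        from .report import render_report
        written.extend(render_report(bundle, clusterings, out))

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "files": {p.name: _checksum(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return bundle


# --------------------------------------------------------------------------- #
#  input validation
# --------------------------------------------------------------------------- #

_FIXATION_COLS = ["participant", "window_type", "window_id", "fix_index",
                  "x_deg", "y_deg", "onset_ms", "duration_ms"]
_BEHAVIOR_COLS = ["participant", "block", "trial", "letter", "is_target",
                  "responded", "rt_ms", "probe_option", "probe_rating"]
_GAZE_COLS = ["participant", "block", "t_ms", "x_deg", "y_deg"]


def validate_inputs(files: Dict[str, str | Path]) -> List[str]:
    """Schema-check the delimited inputs; returns a list of error strings.

    ``files`` maps kind ('fixations' | 'behavior' | 'gaze') to a path. Line
    numbers refer to the data rows of the file (header = line 1).
    """
    errors: List[str] = []
    for kind, path in files.items():
        path = Path(path)
        if not path.exists():
            raise InputValidationError(f"{path} does not exist")
        df = pd.read_csv(path)
        expected = {"fixations": _FIXATION_COLS, "behavior": _BEHAVIOR_COLS,
                    "gaze": _GAZE_COLS}.get(kind)
        if expected is None:
            raise InputValidationError(f"unknown input kind {kind!r}")
        missing = [c for c in expected if c not in df.columns]
        if missing:
            errors.append(f"{path.name}: missing columns {missing}")
            continue
        if kind == "behavior":
            for idx, row in df.iterrows():
                line = idx + 2
                if not (1 <= row["probe_option"] <= 5):
                    errors.append(f"{path.name}:{line}: probe_option out of range 1-5")
                if not (1 <= row["probe_rating"] <= 7):
                    errors.append(f"{path.name}:{line}: probe_rating out of range 1-7")
                if not (1 <= row["trial"]):
                    errors.append(f"{path.name}:{line}: trial index must be >= 1")
        elif kind == "fixations":
            if (df["duration_ms"] < 0).any():
                bad = df.index[df["duration_ms"] < 0][0] + 2
                errors.append(f"{path.name}:{bad}: negative fixation duration")
            for key, g in df.groupby(["participant", "window_type", "window_id"]):
                onsets = g.sort_values("fix_index")["onset_ms"].to_numpy()
                if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
                    errors.append(
                        f"{path.name}: non-increasing onsets for {key}"
                    )
        elif kind == "gaze":
            for key, g in df.groupby(["participant", "block"]):
                t = g["t_ms"].to_numpy()
                if len(t) > 1 and not np.all(np.diff(t) > 0):
                    errors.append(
                        f"{path.name}: non-monotone timestamps for participant/block {key}"
                    )
    return errors
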