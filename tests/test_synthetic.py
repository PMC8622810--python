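"""Synthetic cohort generator: archetypes, sampling, rendering, task structure."""

import numpy as np
import pandas as pd
import pytest

import gazehmm as gz
from gazehmm.errors import ArchetypeLabelError, ConfigError, EmptySequenceError
from gazehmm.synthetic import _default_mw_rates


# --------------------------------------------------------------------- #
#  archetypes
# --------------------------------------------------------------------- #

@pytest.mark.parametrize("label", ["centralized", "distributed"])
@pytest.mark.parametrize("seed", [0, 1, 7])
def test_archetype_is_valid_and_deterministic(label, seed):
    spec = gz.make_archetype(label, seed)
    again = gz.make_archetype(label, seed)
    assert np.array_equal(spec.roi_means, again.roi_means)
    assert spec.prior.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(spec.transition.sum(axis=1), 1.0, atol=1e-9)
    for cov in spec.roi_covariances:
        np.linalg.cholesky(cov)  # SPD


@pytest.mark.parametrize("seed", range(5))
def test_centralized_tighter_than_distributed(seed):
    c = gz.make_archetype("centralized", seed)
    d = gz.make_archetype("distributed", seed)
    assert c.dispersion() < d.dispersion()


def test_unknown_archetype_label_rejected():
    with pytest.raises(ArchetypeLabelError):
        gz.make_archetype("diffuse", 0)


# --------------------------------------------------------------------- #
#  fixation sequence sampling
# --------------------------------------------------------------------- #

def test_degenerate_emission_pins_fixations(rng):
    spec = gz.ArchetypeSpec("centralized", gz.HiddenMarkovModel(
        prior=[1.0], transition=[[1.0]], means=[[0.0, 0.0]],
        covariances=[1e-12 * np.eye(2)],
    ))
    seq = gz.sample_fixation_sequence(spec, 50, rng)
    assert np.all(np.abs(seq.xy) < 1e-4)
    seq.validate()


def test_identity_transition_freezes_state(rng):
    spec = gz.ArchetypeSpec("distributed", gz.HiddenMarkovModel(
        prior=[0.5, 0.5], transition=np.eye(2),
        means=[[-10.0, 0.0], [10.0, 0.0]],
        covariances=[0.01 * np.eye(2)] * 2,
    ))
    for _ in range(5):
        seq = gz.sample_fixation_sequence(spec, 30, rng)
        signs = np.sign(seq.xy[:, 0])
        assert np.all(signs == signs[0])


def test_occupancy_matches_stationary_distribution():
    """Empirical state frequencies converge to the chain's stationary
    distribution (eigen-decomposition oracle)."""
    spec = gz.make_archetype("distributed", 3)
    # oracle: left eigenvector of the transition matrix
    vals, vecs = np.linalg.eig(spec.transition.T)
    stat = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    stat = np.abs(stat) / np.abs(stat).sum()
    rng = np.random.default_rng(42)
    seq = gz.sample_fixation_sequence(spec, 10_000, rng)
    freqs = np.bincount(seq.meta["states"], minlength=spec.n_rois) / 10_000
    assert np.all(np.abs(freqs - stat) < 0.02)


def test_sampling_needs_at_least_one_fixation(rng):
    spec = gz.make_archetype("centralized", 0)
    with pytest.raises(EmptySequenceError):
        gz.sample_fixation_sequence(spec, 0, rng)


# --------------------------------------------------------------------- #
#  gaze rendering
# --------------------------------------------------------------------- #

def test_render_single_fixation_sample_count():
    seq = gz.FixationSequence(xy=[[1.0, 2.0]], onset=[0.0], duration=[500.0])
    samples = gz.render_gaze_samples(seq, rate_hz=100)
    assert len(samples) == 50
    assert all(s.x == 1.0 and s.y == 2.0 for s in samples)


def test_render_transit_duration_matches_arithmetic():
    """5 deg apart at 200 deg/s: the transit lasts 25 ms."""
    seq = gz.FixationSequence(xy=[[0.0, 0.0], [5.0, 0.0]],
                              onset=[0.0, 500.0], duration=[300.0, 300.0])
    samples = gz.render_gaze_samples(seq, rate_hz=1000, saccade_velocity_degps=200)
    ts = np.array([s.t for s in samples])
    xs = np.array([s.x for s in samples])
    moving = (xs > 1e-9) & (xs < 5.0 - 1e-9)
    assert ts[moving].min() >= 300.0
    assert ts[moving].max() <= 325.0
    assert moving.sum() == pytest.approx(25, abs=1)


def test_render_empty_sequence():
    seq = gz.FixationSequence(xy=np.empty((0, 2)), onset=[], duration=[])
    assert gz.render_gaze_samples(seq) == []


def test_render_rejects_slow_saccade():
    seq = gz.FixationSequence(xy=[[0.0, 0.0]], onset=[0.0], duration=[100.0])
    with pytest.raises(ConfigError):
        gz.render_gaze_samples(seq, saccade_velocity_degps=90.0)


def test_render_detect_round_trip(rng):
    """Jitter-free rendering recovers fixation count and centroids."""
    spec = gz.make_archetype("distributed", 1)
    seq = gz.sample_fixation_sequence(spec, 12, rng)
    samples = gz.render_gaze_samples(seq, rate_hz=100, saccade_velocity_degps=300)
    detected = gz.detect_fixations(samples)
    assert len(detected) == len(seq)
    assert np.all(np.linalg.norm(detected.xy - seq.xy, axis=1) < 0.1)


# --------------------------------------------------------------------- #
#  cohort simulation
# --------------------------------------------------------------------- #

def test_cohort_task_structure(small_cohort):
    """Each participant sees n_blocks x 25 trials with one No-go per block at
    positions 6-15."""
    cfg = small_cohort.config
    for pid, g in small_cohort.sart.groupby("participant"):
        assert len(g) == cfg.n_blocks * cfg.trials_per_block
        targets = g[g["is_target"]]
        assert len(targets) == cfg.n_blocks
        assert targets["trial"].between(6, 15).all()
        assert (targets["letter"] == "C").all()
        assert not (g[~g["is_target"]]["letter"] == "C").any()


def test_no_error_sources_means_all_withheld():
    cfg = gz.CohortConfig(
        n_participants_per_group=1, n_blocks=5, seed=1,
        mw_base_rate={"centralized": 0.0, "distributed": 0.0},
        commission_prob_fa=0.0,
    )
    cohort = gz.simulate_cohort(cfg)
    targets = cohort.sart[cohort.sart["is_target"]]
    assert not targets["responded"].any()


def test_cohort_determinism():
    a = gz.simulate_cohort(gz.CohortConfig(n_participants_per_group=2,
                                           n_blocks=4, seed=9))
    b = gz.simulate_cohort(gz.CohortConfig(n_participants_per_group=2,
                                           n_blocks=4, seed=9))
    pd.testing.assert_frame_equal(a.sart, b.sart)
    pd.testing.assert_frame_equal(a.probes, b.probes)
    assert len(a.sequences) == len(b.sequences)
    for sa, sb in zip(a.sequences, b.sequences):
        assert np.array_equal(sa.xy, sb.xy)
        assert np.array_equal(sa.onset, sb.onset)


def test_commission_rate_higher_in_mw_blocks():
    """Commission errors on No-go trials track the latent state (>= 1000
    No-go trials)."""
    cfg = gz.CohortConfig(n_participants_per_group=13, n_blocks=40, seed=11)
    cohort = gz.simulate_cohort(cfg)
    targets = cohort.sart[cohort.sart["is_target"]]
    merged = targets.merge(cohort.latent, on=["participant", "block"])
    assert len(merged) >= 1000
    rate_mw = merged.loc[merged["state"] == "MW", "responded"].mean()
    rate_fa = merged.loc[merged["state"] == "FA", "responded"].mean()
    assert rate_mw > rate_fa


def test_group_gaze_dispersion_separates():
    """Pooled fixation spread is larger for the distributed group in every
    cohort of >= 5 participants per group."""
    for seed in range(3):
        cohort = gz.simulate_cohort(
            gz.CohortConfig(n_participants_per_group=5, n_blocks=10, seed=seed)
        )
        disp = {}
        for group in ("centralized", "distributed"):
            pids = [p for p, g in cohort.groups.items() if g == group]
            xy = np.vstack([s.xy for s in cohort.sequences
                            if s.participant in pids])
            disp[group] = float(np.var(xy, axis=0).sum())
        assert disp["distributed"] > disp["centralized"]


def test_probe_answers_follow_latent_state():
    cfg = gz.CohortConfig(n_participants_per_group=4, n_blocks=20,
                          contamination=0.0, seed=5)
    cohort = gz.simulate_cohort(cfg)
    merged = cohort.probes.merge(cohort.latent, on=["participant", "block"])
    fa = merged[merged["state"] == "FA"]
    mw = merged[merged["state"] == "MW"]
    assert fa["option"].isin([1, 2, 5]).all() and fa["rating"].between(5, 7).all()
    assert mw["option"].isin([3, 4, 5]).all() and mw["rating"].between(1, 3).all()


def test_bad_probabilities_rejected():
    with pytest.raises(ConfigError):
        gz.CohortConfig(commission_prob_fa=1.4)
    with pytest.raises(ConfigError):
        gz.CohortConfig(mw_base_rate={"centralized": -0.1, "distributed": 0.5})


def test_shipped_defaults_are_consistent():
    cfg = gz.CohortConfig()
    assert cfg.commission_prob_mw > cfg.commission_prob_fa
    assert set(_default_mw_rates()) == {"centralized", "distributed"}


def test_cohort_file_round_trip(tmp_path, small_cohort):
    from gazehmm.fixations import frame_to_sequences
    paths = small_cohort.to_files(tmp_path)
    df = pd.read_csv(paths["fixations"])
    seqs = frame_to_sequences(df)
    assert len(seqs) == len(small_cohort.sequences)
    total_in = sum(len(s) for s in small_cohort.sequences)
    total_out = sum(len(s) for s in seqs)
    assert total_in == total_out
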