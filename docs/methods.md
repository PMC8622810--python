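# Methods

`gazehmm` implements an eye-movement-pattern analysis of sustained attention:
per-participant hidden Markov models over fixation coordinates, clustering of
those models into two representative gaze patterns, and the statistics that
relate a participant's position on the resulting distributed–centralized
scale to objective and subjective markers of mind-wandering. This note
records the models, the defaults and why they were chosen, what the bundled
synthetic cohort does and does not emulate, and the numerical choices a
replicator would need.

## The task and its measures

The paradigm is a sustained attention to response task (SART): 40 blocks of
25 letter trials of 2 s each, with one No-go target (the letter C) per block
at a uniformly random position between trials 6 and 15, and a thought probe
at each block end. The probe asks for thought content (five options) and a
1–7 focus rating.

Three measures are computed per participant:

- **Objective (d′).** Withholding to the No-go target is a *hit*, responding
  to it a *miss*; failing to respond to a Go letter is a *false alarm*,
  responding a *correct rejection*. d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm
  rate). The log-linear correction (add 0.5 to each count, 1 to each
  denominator) is applied unconditionally so extreme rates stay finite and
  there is no discontinuity between "corrected" and "uncorrected"
  participants. By default d′ is scored over the trials falling inside the
  10-s pre-target windows (the No-go trial plus the five preceding Go
  trials); a flag scores all trials instead.
- **Subjective (proportion FA).** Probe answers are labelled focused
  attention (options 1–2 with rating 5–7), mind-wandering (options 3–4 with
  rating 1–3), or excluded (rating 4, the ambiguous midpoint). Option 5
  ("nothing in particular") is resolved by the rating alone. Incongruent
  pairs — task-focused content with a low rating or off-task content with a
  high rating — are excluded, since only the congruent combinations are
  defined. The proportion of FA labels is taken out of *all* probes
  (excluded ones stay in the denominator).
- **Eye movements (the D-C scale).** After clustering (below), each
  participant's mean per-window log-likelihood under the distributed
  (D_MLL) and centralized (C_MLL) representative HMMs gives

      dc = (D_MLL − C_MLL) / (|D_MLL| + |C_MLL|),

  a dimensionless score in [−1, 1]; positive values mean more
  distributed-like viewing. Per-window log-likelihoods enter unnormalized:
  the 10-s windows contain near-equal fixation counts by construction, and
  the scale is sensitive to MLL magnitude, so a `per_fixation`
  normalization flag exists but is off by default. Participants are
  assigned to the distributed group when dc > 0, else centralized.

## Gaze preprocessing

Fixations are detected from 100-Hz gaze samples with a velocity threshold:
point-to-point velocity is displacement over the sample interval (two-point
estimate, no smoothing), saccades are velocities above 100 deg/s, and a
fixation is a maximal below-threshold run spanning at least 60 ms. Its
position is the run centroid, its duration the run's time span. Invalid
samples (tracking loss) split runs; a fixation cannot bridge a gap longer
than twice the median sample interval.

Per participant, fixations whose duration exceeds the participant's mean
plus three (sample) standard deviations are excluded; the inequality is
strict, so a zero-variance participant loses nothing. The mean is pooled
over all the participant's fixations in the session.

Analysis windows cover the 10 s before each No-go target and before each
probe. Membership is by fixation onset and the interval is half-open at the
event, [t − 10 s, t): a fixation starting exactly at the event is excluded.
Early events yield truncated windows, flagged as such. Coordinates
everywhere are degrees of visual angle, origin at screen centre, x
rightward, y downward, screen approximately ±16 × ±10 deg.

## Per-participant HMMs (VBEM)

Each 10-s window is one observation sequence of fixation (x, y) pairs; the
chain resets at window boundaries. The HMM's hidden states act as
data-driven regions of interest (ROIs): each state emits from its own
bivariate Gaussian. Conjugate priors — symmetric Dirichlet (concentration
1.0) on the prior vector and each transition row, Normal–Wishart on each
Gaussian — are updated by variational Bayesian EM: the E-step runs a scaled
forward–backward pass under the expected log-parameters, the M-step applies
the standard conjugate updates, and the variational lower bound (data terms
from the forward normalizers minus the KL of every posterior factor) is
non-decreasing across iterations. Convergence is a relative lower-bound
change below 1e-5, capped at 200 iterations; the best of 5 restarts wins,
each restart initialized from a k-means split of the pooled fixations with
restart-specific softening.

Normal–Wishart defaults: prior mean at screen centre, β = 1, ν = 5, and an
inverse-Wishart scale of I·(screen diagonal / 16)²·(ν − 3), which puts the
prior mean ROI standard deviation at about 1/16 of the screen diagonal
(≈ 2.4 deg). These hyperpriors are the main replication knob and are fully
configurable. A 1e-6·I ridge is added to a state's scale matrix when its
responsibility mass falls below two effective points.

The state count K is selected by refitting at K = 3…6 and keeping the
highest variational lower bound — the quantity VBEM maximizes, which
penalizes extra states implicitly. Selection by the posterior-mean model's
raw data log-likelihood is available behind a flag. The returned point model
uses posterior means (normalized Dirichlet weights, NW means,
inverse-Wishart mean covariances, ν − 3 in the denominator for d = 2).

## Clustering HMMs (VHEM)

The individual HMMs are clustered into two groups using only their
parameters. For a virtual sequence length τ (default 20, about the number
of fixations in a 10-s window at 2 fixations/s), the expected
log-likelihood of a representative with respect to an input HMM is lower-
bounded by a variational backward recursion: the Gaussian-vs-Gaussian
expected log-density has a closed form, and at each virtual time step a
log-sum-exp over the representative's states gives the optimal soft pairing
between input states and representative states. The E-step evaluates this
bound for every (input, representative) pair; inputs are assigned to their
best representative (ties to cluster 0); the M-step updates each
representative from the expected co-occupancy statistics of its members
(start occupancies, transition flows, and mass-weighted first and second
moments of the input Gaussians). The objective — the summed bound over
assigned pairs — is non-decreasing across iterations; iteration stops at a
relative change below 1e-5 or 30 iterations. The procedure restarts 100
times from representatives seeded by randomly chosen input models, and the
restart with the highest expected log-likelihood wins.

The representatives' state count is the median K of the inputs (lower
median on even counts). When the seeding input has more states than that,
the states with the largest stationary mass are kept. Labels are assigned by
a dispersion statistic — the stationary-weighted mean covariance trace plus
the stationary-weighted variance of ROI means around their weighted
centroid — with the larger-dispersion representative called *distributed*;
a tie within 1e-9 raises an error rather than guessing.

The batched E/M implementations are cross-checked in the test suite against
independent per-pair reference recursions.

## Trial-level analysis

Each 10-s window is classified centralized or distributed by which
representative assigns it the higher log-likelihood (exact ties, which have
measure zero under continuous emissions, go to centralized and are logged).
Pattern-by-outcome counts — withheld vs commission for pre-target windows,
probe-FA vs probe-MW for pre-probe windows — form 2×2 tables tested with
the likelihood-ratio statistic G² = 2 Σ O ln(O/E) against χ²(1), with the
odds ratio ad/bc (Haldane–Anscombe 0.5 correction when a cell is empty,
applied to the OR only). Tables are pooled across participants;
within-participant dependence of trials is a known caveat of the pooled
test. Group comparisons use pooled-variance two-sample t-tests, paired
t-tests and pooled-SD Cohen's d; associations use Pearson r.

## The synthetic cohort

The generator produces the statistical structure the analysis assumes, so
the whole pipeline is testable without any recorded data. Each participant
belongs to a *trait* group (centralized or distributed). Per block, a latent
attentional state (FA or MW) is drawn with a group-specific probability;
the state selects which gaze archetype generates both of the block's
windows, sets the commission probability on the No-go trial, and drives the
probe answer (FA states draw options {1,2,5} with ratings 5–7, MW states
options {3,4,5} with ratings 1–3, with a 10% contamination rate drawing
from the opposite state's distribution so recovery is non-trivial).

Shipped defaults, chosen once as realistic values for this paradigm:

| parameter | default | rationale |
| --- | --- | --- |
| participants per group | 8 | small-cohort scale typical of eye-tracking studies |
| blocks × trials | 40 × 25, 2-s trials | the task layout |
| MW rate per block | 0.10 (centralized) / 0.75 (distributed) | trait groups must differ in their dominant state; cohort mean ≈ 43% MW is in the usual probe-study range |
| commission probability | 0.20 (FA) / 0.65 (MW) | commission errors on SART targets are frequent, and much more so when mind-wandering |
| Go miss probability | 0.05 | occasional lapses on Go trials |
| fixation rate | 2.0 /s | ≈ 20 fixations per 10-s window |
| fixation durations | log-normal, median 250 ms, σ_log 0.4, floored at 60 ms | typical fixation-duration distribution above the detector's floor |
| reaction times | uniform 250–600 ms | only used to fill the behavioral log |

The two archetypes are 3-ROI HMMs. The centralized one concentrates near
the screen centre (ROIs at (0,0) and (±1.8, 0.5), SDs 0.6–0.9 deg, strong
return transitions to the central ROI). The distributed one spreads across
the screen (ROIs at (0,0) and (±10, ±5), SDs 2–2.5 deg, a well-mixing
chain). The distributed ROIs are deliberately distinct regions
(separation ≈ 4 SDs): regions of interest that overlap almost completely
are not meaningful ROIs, and under the VHEM bound such mixtures are better
summarized by a single broad component, which would defeat the
dispersion-based labeling (see limitations). A seed-dependent jitter on ROI
positions keeps cohorts from being identical while preserving every
archetype invariant.

What the generator does **not** emulate: eye-tracker noise beyond optional
Gaussian jitter in the gaze renderer, blinks, pupil size, head movement,
calibration error, letter-dependent gaze behavior, response-time dynamics,
or drift in attentional state over the session (block states are i.i.d.
given the group). Passing end-to-end tests therefore shows that the
pipeline recovers the planted structure under clean, well-specified
conditions — not that it would do so at any effect size in recorded data.

## Numerical choices

- Forward passes use per-step scaling (not log-space), accumulating log
  normalizers; likelihoods are exact to ~1e-8 against path enumeration.
- The VBEM forward–backward kernel is numba-compiled with a pure-python
  fallback; VHEM E/M steps are batched across models grouped by state
  count.
- Covariances returned to users are symmetrized with an eigenvalue floor of
  1e-8 (`nearest_spd`) before validation.
- Ties: equidistant inputs in VHEM go to cluster 0; trial-classification
  ties go to centralized; dc = 0 assigns the centralized group. All are
  logged.
- Degenerate inputs: fewer than 2 valid gaze samples yield an empty
  sequence with a warning; a zero-variance duration distribution excludes
  nothing; zero-margin contingency tables are rejected; empty-cluster
  M-steps keep the previous representative.
- Every random operation derives its seed from one root seed via SHA-256,
  keeping derived seeds below 2³¹.

## Problem sizes

The test suite and the reproduction script run the full pipeline at the
generator's default scale (16 participants × 40 blocks, both window types,
K = 3…6 with 5 fitting restarts, 100 clustering restarts), about 40 s per
cohort on one CPU; replicate-based checks use 10 seeded cohorts. The
planted-recovery checks use 5 + 5 participants with K = 3 fits and the
model-selection study uses 50 sequences × 20 fixations per replicate.

## Known limitations

- The VHEM variational bound rewards soft hedging across representative
  states. When input ROIs overlap heavily (e.g. flank ROIs 1.8 deg from a
  0.6-deg-SD centre), the optimal representative shrinks minor ROIs toward
  the dominant one rather than copying the input exactly; with
  well-separated ROIs the fixed point matches the input to ~0.01 deg. This
  does not affect two-cluster discrimination or labeling in any tested
  regime, but representative ROI geometry should be read qualitatively.
- With all-identical inputs, one cluster takes every model and the other
  representative is vestigial.
- The pooled trial-level G² ignores within-participant dependence.
- The D-C scale's zero crossing (used for group assignment) is meaningful
  only when the two representatives are comparably good density models of
  their own patterns; extremely unbalanced cohorts can push the crossing
  off-centre.
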