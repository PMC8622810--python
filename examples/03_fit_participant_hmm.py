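"""Fit one participant's gaze HMM by variational Bayesian EM.

Draws 10-s windows' worth of fixations from a known 2-ROI generator and
refits the model, showing that the ROI means, self-transitions and the
automatically selected state count match the generator.
"""

import numpy as np

import gazehmm as gz

truth = gz.HiddenMarkovModel(
    prior=[0.5, 0.5],
    transition=[[0.8, 0.2], [0.2, 0.8]],
    means=[[-8.0, 0.0], [8.0, 0.0]],
    covariances=[np.eye(2), np.eye(2)],
)
rng = np.random.default_rng(0)
spec = gz.ArchetypeSpec("distributed", truth)
windows = [gz.sample_fixation_sequence(spec, 20, rng) for _ in range(50)]

fit = gz.fit_vbhmm(windows, K=2, seed=0)
print("recovered ROI means:")
print(fit.model.means.round(2))
print("recovered self-transitions:", np.diag(fit.model.transition).round(2))
print(f"lower bound {fit.lower_bound:.1f} nats after {fit.n_iterations} "
      f"iterations (converged={fit.converged})")
# The means should be within ~0.5 deg of (-8, 0) / (8, 0) and the
# self-transitions near the generating 0.8.

selected = gz.select_model(windows, K_min=1, K_max=4, seed=0, n_restarts=3)
print("state-count selection by lower bound:",
      {k: round(v, 1) for k, v in selected.K_candidates.items()})
print("selected K =", selected.model.K)
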