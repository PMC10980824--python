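"""Simulate Markov-switching envelope data and recover its hidden states.

Generates 5 subjects of 8-state amplitude-envelope data with known
spatial patterns, runs the standardize -> concatenate -> PCA -> HMM ->
Viterbi pipeline, and compares decoded fractional occupancies against
the generative truth after Hungarian state matching.
"""

import numpy as np

import restdyn as rd
from restdyn.state_metrics import state_power_maps

cfg = rd.SimulationConfig(
    n_subjects=5, n_sessions=1, n_nodes=20, n_states=8,
    samples_per_session=8000, noise_sd=0.3, seed=42,
)
paths = rd.simulate_state_paths(cfg)
dataset = rd.simulate_envelopes(paths, cfg)

concat = rd.prewhiten_pca(rd.standardize_concatenate(dataset), n_components=10)
model = rd.fit_hmm(concat.Z, K=8, n_restarts=2, seed=0,
                   boundaries=concat.boundaries, covariance_type="diag")
seq = rd.viterbi_decode(model, concat.Z, boundaries=concat.boundaries)

true_concat = np.concatenate([paths[k] for k in sorted(paths)])
perm = rd.match_states(
    state_power_maps(true_concat, concat.X, K=8),
    state_power_maps(seq.path, concat.X, K=8),
)

print(f"winning restart: {model.restart_index}  (negative log-likelihood "
      f"{model.score:.0f}; lower is better)")
errs = []
for key in sorted(paths):
    true_fo = np.bincount(paths[key], minlength=8) / cfg.samples_per_session
    est_fo = np.array([np.mean(seq.split()[key] == perm[k]) for k in range(8)])
    errs.append(np.abs(est_fo - true_fo).mean())
print(f"mean absolute FO error across recordings: {np.mean(errs):.4f}")
print("matched self-transition probabilities:",
      np.round([model.transmat[perm[k], perm[k]] for k in range(8)], 3))
print("(generative value 0.85 -> mean state lifetime ~167 ms at 40 Hz; a small"
      " FO error and self-transitions near 0.85 mean the fast state dynamics"
      " were recovered.)")
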