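"""Concurrent model fitting and comparison on a mixed synthetic group.

Simulates 10 reinforcement-learning and 30 Kalman-filter agents playing a
two-armed bandit, fits both models to all subjects with HBI, and prints
model frequencies, protected exceedance probabilities and the per-subject
attribution accuracy.  The model frequency estimates the fraction of the
population expressing each model; the protected exceedance probability is
the probability that a model is the most frequent one, discounted by the
chance hypothesis that evidence differences are spurious.
"""

import numpy as np

import hbinfer as hb

cfg = hb.make_scenario("same_complexity", counts=(10, 30),
                       n_replications=1, seed=7, T=100)
data, truth = hb.generate_group_dataset(cfg, 0)
models = [hb.get_model(m) for m in cfg.model_space]

fit = hb.run_hbi(data, models, options=hb.HBIOptions(seed=7))

print(f"{'model':<10} {'frequency':>10} {'xp':>8} {'pxp':>8}")
for k, m in enumerate(models):
    print(f"{m.name:<10} {fit.model_frequency[k]:>10.3f} "
          f"{fit.xp[k]:>8.3f} {fit.pxp[k]:>8.3f}")
print(f"P0 (chance hypothesis) = {fit.P0:.3g}")

assigned = np.argmax(fit.subjects.r, axis=0)
acc = np.mean(assigned == truth["model_index"])
print(f"subject-level attribution accuracy: {100 * acc:.1f}% "
      f"(true mix: 25% RL / 75% Kalman)")
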