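"""Group-level inference on a model parameter with the HBI t-test.

Simulates go/no-go agents whose Pavlovian bias parameter b has a true
group mean of 1.0 (positive bias: "go" for appetitive cues), fits the
biased-RL model hierarchically and tests whether the group-level bias
differs from zero.  The hierarchical error plays the role of a standard
error whose degrees of freedom are driven by the responsibility-weighted
subject count, not the raw N.
"""

import hbinfer as hb

cfg = hb.make_scenario("gonogo_bias", counts=(20,), n_replications=1,
                       seed=11, effect=1.0)
data, truth = hb.generate_group_dataset(cfg, 0)
model = hb.get_model("biased_rl")

fit = hb.run_hbi(data, [model],
                 options=hb.HBIOptions(seed=11, compute_pxp=False))
res = hb.hbi_ttest(fit, "biased_rl", "bias", null_value=0.0)

print(f"group mean bias a = {res.a:.3f}  (generating mean 1.0)")
print(f"hierarchical error = {res.hierarchical_error:.3f}, "
      f"dof = {res.dof:.1f}")
print(f"t = {res.t:.2f}, two-sided p = {res.p:.4f}")
lo, hi = res.credible_interval
print(f"95% credible interval: [{lo:.3f}, {hi:.3f}]")
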