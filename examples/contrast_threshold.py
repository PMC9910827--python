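"""Contrast-threshold estimation for a simulated 2AFC observer.

Simulates the six-level, 75-trial constant-stimuli design for an
observer with threshold 0.05 and slope 3, fits the Quick function by
maximum likelihood, attaches a 500-replicate parametric bootstrap SE,
and derives the sensitivity change metrics.
"""

import numpy as np

import eyepatch as ep
from eyepatch.synthetic import gen_constant_stimuli

levels = np.array([0.015, 0.025, 0.04, 0.06, 0.09, 0.13])
observer = ep.PsychoObserverParams(true_alpha=0.05, true_beta=3.0, seed=11)
data = gen_constant_stimuli(observer, levels, n_per_level=75)

fit = ep.fit_quick(data)
fit = ep.bootstrap_quick(fit, data, n_boot=500, seed=11)

print("level   trials  correct  fitted P")
for lev, n, k in zip(data.levels, data.n_trials, data.n_correct):
    p = ep.quick_probability(lev, fit.alpha, fit.beta)
    print(f"{lev:5.3f} {n:8d} {k:8d} {p:9.3f}")

print(f"\nthreshold alpha : {fit.alpha:.4f} +- {fit.alpha_se:.4f} "
      f"(true 0.0500; 81.6% correct point)")
print(f"slope beta      : {fit.beta:.2f} (true 3.00)")
print(f"95% CI          : [{fit.alpha_ci[0]:.4f}, {fit.alpha_ci[1]:.4f}]")

cs = 1.0 / fit.alpha
print(f"contrast sensitivity = 1/alpha = {cs:.1f}")

# change metrics, using the kind of pre/post sensitivities the patching
# experiment produces
pre, post = 103.086, 70.017
print(f"\npre {pre} -> post {post}:")
print(f"  dB change            : {ep.cs_change_db(pre, post):+.2f} dB")
print(f"  percent decrease     : {-ep.relative_effect(pre, post) * 100:.1f} %")
print(f"  sensitivity ratio UPE/PE (e.g. {post}/{pre/2:.1f}) : "
      f"{ep.cs_ratio(post, pre / 2):.3f}")
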