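"""Profile the normal-mixture objective and compute MR power.

Left: with 40% invalid instruments the pi0 profile still peaks sharply at
the generating effect (majority-valid regime).  Right: the approximate power
of an IVW-style test for a binary outcome at a COVID-hospitalization-sized
outcome GWAS (n ~ 10,908, ~22% cases).
"""

import numpy as np

from mrkit import SimConfig, harmonize, mr_power, mrmix, simulate, standardize_pairs

cfg = SimConfig(m=200, theta_true=0.4, sigma_gamma=0.3,
                pleio_fraction=0.4, pleio_sd=0.05, seed=4)
exposure, outcome, _, truth = simulate(cfg)
std = standardize_pairs(harmonize(exposure[0], outcome[0]))
est, curve = mrmix(std, n_boot=200, seed=4)

print(f"mixture profile argmax: theta = {est.theta:.2f} "
      f"(truth {truth.theta_true}), bootstrap SE = {est.se:.4f}")
print(f"fitted null proportion pi0 = {est.pi0:.2f} (60% of instruments are valid)")
peak = curve.objective[np.abs(curve.thetas - est.theta) <= 0.05]
print(f"profile is sharp: pi0 drops {curve.objective.max() - np.median(curve.objective):.2f} "
      "from peak to median across the grid\n")

print(f"{'theta':>6s} {'OR':>5s} {'power':>7s}")
for theta in (0.1, 0.25, 0.5, 0.75):
    res = mr_power(theta, r2_instrument=0.02, n_outcome=10_908,
                   case_fraction=2430 / 10_908, alpha=0.05)
    print(f"{theta:6.2f} {np.exp(theta):5.2f} {res.power:7.1%}")

# Small outcome GWAS keep power low for modest odds ratios: detecting
# OR ~ 1.3 reliably needs either stronger instruments or more cases.
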