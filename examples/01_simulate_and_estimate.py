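"""Simulate a two-sample MR study and compare all four causal estimators.

Generates summary statistics for 129 instruments with a true causal effect
of theta = 0.5 (odds ratio ~1.65) where 10% of instruments carry directional
horizontal pleiotropy, then estimates theta with IVW, MR-Egger, IMRP and the
normal-mixture profile.
"""

from mrkit import SimConfig, egger, harmonize, imrp, ivw, mrmix, simulate, standardize_pairs

cfg = SimConfig(
    m=129, theta_true=0.5, sigma_gamma=0.05,
    pleio_fraction=0.10, pleio_mode="directional", pleio_mean=0.02, pleio_sd=0.02,
    seed=1,
)
exposure, outcome, _, truth = simulate(cfg)
pairs = harmonize(exposure[0], outcome[0])
std = standardize_pairs(pairs)

print(f"true theta = {truth.theta_true}  ({len(truth.invalid_ids)} invalid instruments)\n")
print(f"{'method':8s} {'theta':>8s} {'SE':>8s} {'OR':>6s} {'95% CI':>16s} {'used':>5s}")
for est in (ivw(std), egger(std), imrp(std)[0], mrmix(std, seed=1)[0]):
    ci = f"({est.ci_low:.2f}, {est.ci_high:.2f})"
    print(f"{est.method:8s} {est.theta:8.4f} {est.se:8.4f} "
          f"{est.odds_ratio:6.2f} {ci:>16s} {est.n_snps_used:5d}")

# The estimators disagree in characteristic ways: IVW folds the planted
# directional pleiotropy into its slope, IMRP excludes the flagged
# instruments (here 129 -> 107) and discounts it, and MR-Egger's extra
# intercept buys robustness at the cost of a wider confidence interval.
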