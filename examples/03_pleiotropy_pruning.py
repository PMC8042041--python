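"""Detect and prune horizontally pleiotropic instruments with IMRP.

Plants 10 of 100 instruments with direct outcome effects ten times the
sampling noise SD, then shows the iterative test-and-exclude loop recovering
exactly the planted set and an unbiased causal effect.
"""

from mrkit import SimConfig, harmonize, imrp, ivw, simulate, standardize_pairs

noise_sd = SimConfig().n_outcome ** -0.5
cfg = SimConfig(m=100, theta_true=0.3, sigma_gamma=0.05,
                pleio_fraction=0.10, pleio_mode="directional",
                pleio_mean=10 * noise_sd, pleio_sd=1e-4, seed=3)
exposure, outcome, _, truth = simulate(cfg)
std = standardize_pairs(harmonize(exposure[0], outcome[0]))

naive = ivw(std)
pruned, pleio = imrp(std, alpha_pleio=0.05)

planted = set(truth.invalid_ids)
excluded = set(pruned.excluded_snps)
print(f"planted pleiotropic instruments: {len(planted)}")
print(f"IMRP excluded {len(excluded)} in {pruned.iterations} iterations; "
      f"recall = {len(planted & excluded) / len(planted):.0%}, "
      f"false exclusions = {len(excluded - planted)}")
print(f"\nIVW on all instruments:   theta = {naive.theta:.4f} (truth {truth.theta_true})")
print(f"IMRP after pruning:       theta = {pruned.theta:.4f} +- {pruned.se:.4f}")
print(f"Bonferroni-flagged SNPs:  {int(pleio['flagged_bonferroni'].sum())} "
      f"(line at 0.05/{len(std)})")

# The naive IVW estimate is dragged upward by the planted direct effects;
# after exclusion the estimate re-centers on the generating value.
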