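"""Distinguish a peptide isomer pair from replicate runs by direct infusion.

Simulates 100-scan MS/MS acquisitions of one analyte (replicates) and of a
planted isomer, builds the hypothesized mean from five replicate pairs
(mean + 3 SD of their observed means), and tests both comparisons.
"""

from specdiff import (
    hypothesized_mean_from_replicates,
    nonparametric_test,
    observed_mean_between,
    one_sample_test,
    simulate,
)
from specdiff.io import average_scans


def observed(seed: int, isomer: bool):
    cfg = simulate.SyntheticConfig(seed=seed)
    if isomer:
        a, b, _, _ = simulate.isomer_pair(cfg)
    else:
        a, b = simulate.replicate_pair(cfg)
    return observed_mean_between(average_scans(a), average_scans(b))


# hypothesized mean from five independent replicate run pairs
replicate_means = [observed(seed, isomer=False).observed_mean for seed in range(5)]
mu0 = hypothesized_mean_from_replicates(replicate_means)
print(f"replicate observed means : {[round(m, 5) for m in replicate_means]}")
print(f"hypothesized mean (mean+3SD): {mu0.value:.5f}")

for name, seed, isomer in [("fresh replicate pair", 10, False), ("isomer pair", 11, True)]:
    diffs = observed(seed, isomer)
    result = one_sample_test(diffs, mu0)
    p_w = nonparametric_test(diffs, mu0)
    print(
        f"\n{name}: observed mean {diffs.observed_mean:.5f} over "
        f"{diffs.n_channels} fragment channels"
    )
    print(
        f"  one-tailed t-test vs mu0: t={result.t_statistic:.3f}, "
        f"p={result.p_value_t:.4g} {result.stars!r} -> {result.verdict}"
    )
    print(f"  Wilcoxon signed-rank p={p_w:.4g}")

print(
    "\nAn observed mean at the replicate floor (~1e-3) stays below the"
    "\nhypothesized mean; the isomer comparison sits orders of magnitude"
    "\nabove it because abundance moved between fragmentation channels."
    "\nNote the Wilcoxon p-value: the default generator concentrates the"
    "\nisomer effect on 4 of 20 channels, and a rank test discounts a"
    "\nshift carried by few channels (see docs/methods.md)."
)
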