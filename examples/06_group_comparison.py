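"""Normality-gated two-group comparison with Bonferroni-corrected stars."""

import numpy as np

from tpsd import compare_groups

rng = np.random.default_rng(0)
# e.g. final-session false-alarm rates of two 8-mouse groups
wt_fa = rng.normal(0.24, 0.05, 8).clip(0, 1)
ko_fa = rng.normal(0.55, 0.12, 8).clip(0, 1)

res = compare_groups(wt_fa, ko_fa, alpha=0.05, n_comparisons=1)
print(f"test: {res.test_name}")
print(f"statistic = {res.statistic:.3f}, p = {res.p_value:.2e}, stars = {res.stars}")

res14 = compare_groups(wt_fa, ko_fa, n_comparisons=14)
print(f"with 14 planned comparisons: effective alpha = {res14.alpha_effective:.4f}, "
      f"stars = {res14.stars}")
print("-> each group is screened with a Lilliefors normality test; a t-test is")
print("   used only if both pass, otherwise a rank test. Stars: * p<a, ** p<a/10,")
print("   *** p<a/100 on the Bonferroni-corrected alpha.")
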