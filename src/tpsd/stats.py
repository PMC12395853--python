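"""Two-group comparison layer with a normality gate and Bonferroni stars.

Each group is screened with a Lilliefors test at 0.05; if both groups are
consistent with normality a Student t-test (paired or unpaired) is used,
otherwise the Wilcoxon signed-rank (paired) or rank-sum / Mann-Whitney
(unpaired) test.  With multiple planned comparisons the working alpha is
Bonferroni-corrected (alpha / n_comparisons), and significance stars follow
the convention * p < alpha, ** p < alpha/10, *** p < alpha/100 (strict
inequalities throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = ["ComparisonResult", "compare_groups", "annotate_stars", "long_format_dprime"]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison."""

    test_name: str
    statistic: float
    p_value: float
    alpha_effective: float
    stars: str
    paired: bool
    n_per_group: tuple[int, int]


def annotate_stars(p: float, alpha_effective: float) -> str:
    """Significance stars: *** p < a/100, ** p < a/10, * p < a, else ns."""
    if not 0.0 <= p <= 1.0 or not 0.0 < alpha_effective <= 1.0:
        raise ValueError("p and alpha_effective must be valid probabilities")
    if p < alpha_effective / 100:
        return "***"
    if p < alpha_effective / 10:
        return "**"
    if p < alpha_effective:
        return "*"
    return "ns"


def _is_normalish(x: np.ndarray) -> bool:
    # Lilliefors tables need n >= 4; with n == 3 be conservative and route to
    # the non-parametric branch.  Zero-variance samples are trivially
    # non-normal for this purpose.
    if x.size < 4 or np.ptp(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm")
    return p > NORMALITY_ALPHA


def compare_groups(
    a,
    b,
    paired: bool = False,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> ComparisonResult:
    """Compare two samples with the normality-gated test battery.

    Parametric only if *both* groups pass the Lilliefors screen.  Ties in the
    rank tests are handled by the scipy implementations' standard corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 observations")
    if paired and a.size != b.size:
        raise ValueError("paired groups must have equal length")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")

    normal = _is_normalish(a) and _is_normalish(b)
    if normal:
        if paired:
            res = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = sps.ttest_ind(a, b)
            name = "unpaired t-test"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            if np.all(a == b):
                stat, p = 0.0, 1.0
            else:
                res = sps.wilcoxon(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
            name = "Wilcoxon signed-rank"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            name = "Wilcoxon rank-sum (Mann-Whitney)"
    alpha_eff = alpha / n_comparisons
    return ComparisonResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        alpha_effective=alpha_eff,
        stars=annotate_stars(p, alpha_eff),
        paired=paired,
        n_per_group=(int(a.size), int(b.size)),
    )


def long_format_dprime(performance: pd.DataFrame) -> pd.DataFrame:
    """Long-format export (mouse_id, genotype, session, d_prime) for external
    mixed-model fitting."""
    out = performance[["mouse_id", "genotype", "session", "d_prime_best"]].copy()
    return out.rename(columns={"d_prime_best": "d_prime"})
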