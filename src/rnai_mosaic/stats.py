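"""Supporting statistics: Wilson score intervals, t-tests, two-way ANOVA.

Proportion confidence intervals use the Wilson score method with a
continuity correction — the small-sample-safe interval recommended for
single binomial proportions — and differences between two proportions use
the Newcombe square-and-add construction built from the two Wilson
intervals.  The two-way ANOVA handles the balanced, replicated two-factor
layout used to test for interaction between experimental factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ProportionCI",
    "AnovaTable",
    "wilson_ci",
    "diff_proportions_test",
    "t_test_two_tailed",
    "anova_two_way",
]


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    alpha: float
    lower: float
    upper: float
    continuity: bool

    @property
    def estimate(self) -> float:
        return self.k / self.n

    @property
    def width(self) -> float:
        return self.upper - self.lower


def wilson_ci(
    k: int, n: int, alpha: float = 0.05, continuity: bool = True
) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    With ``continuity=True`` this is the continuity-corrected Wilson
    interval: the bounds solve ``(|p_hat - p| - 1/(2n))^2 = z^2 p(1-p)/n``,
    in closed form.  Boundary cases are forced: k=0 gives lower=0 and k=n
    gives upper=1.  Bounds are clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    q = 1.0 - p
    z2 = z * z
    if continuity:
        lower = (
            2 * n * p + z2 - 1.0 - z * np.sqrt(z2 - 2.0 - 1.0 / n + 4 * p * (n * q + 1.0))
        ) / (2 * (n + z2))
        upper = (
            2 * n * p + z2 + 1.0 + z * np.sqrt(z2 + 2.0 - 1.0 / n + 4 * p * (n * q - 1.0))
        ) / (2 * (n + z2))
    else:
        half = z * np.sqrt(p * q / n + z2 / (4 * n * n))
        lower = (p + z2 / (2 * n) - half) / (1.0 + z2 / n)
        upper = (p + z2 / (2 * n) + half) / (1.0 + z2 / n)
    if k == 0:
        lower = 0.0
    if k == n:
        upper = 1.0
    lower = float(min(max(lower, 0.0), p))
    upper = float(max(min(upper, 1.0), p))
    return ProportionCI(k=k, n=n, alpha=alpha, lower=lower, upper=upper, continuity=continuity)


def diff_proportions_test(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05, continuity: bool = True
) -> tuple[tuple[float, float], bool]:
    """Newcombe square-and-add interval for a difference of proportions.

    The interval for ``p1 - p2`` is assembled from the two single-sample
    Wilson intervals (l1, u1) and (l2, u2):

        lower = (p1 - p2) - sqrt((p1 - l1)^2 + (u2 - p2)^2)
        upper = (p1 - p2) + sqrt((u1 - p1)^2 + (p2 - l2)^2)

    The difference is declared significant when the interval excludes 0.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    ci1 = wilson_ci(k1, n1, alpha, continuity)
    ci2 = wilson_ci(k2, n2, alpha, continuity)
    p1, p2 = k1 / n1, k2 / n2
    d = p1 - p2
    lower = d - float(np.hypot(p1 - ci1.lower, ci2.upper - p2))
    upper = d + float(np.hypot(ci1.upper - p1, p2 - ci2.lower))
    significant = lower > 0.0 or upper < 0.0
    return (lower, upper), significant


def t_test_two_tailed(
    sample_a, sample_b, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample, two-tailed t-test.

    Defaults to the classical equal-variance Student test; set
    ``equal_var=False`` for the Welch variant.  Raises on degenerate input
    (fewer than 2 observations per sample or zero pooled variance).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            # identical constants: no evidence of difference
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass(frozen=True)
class AnovaTable:
    """Decomposition of a balanced replicated two-factor layout."""

    ss: dict[str, float]      # keys: factor_a, factor_b, interaction, residual
    df: dict[str, int]
    ms: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    alpha: float

    @property
    def ss_total(self) -> float:
        return sum(self.ss.values())

    @property
    def interaction_significant(self) -> bool:
        return self.p["interaction"] < self.alpha


def anova_two_way(data: np.ndarray, alpha: float = 0.05) -> AnovaTable:
    """Two-way ANOVA with replication on a balanced layout.

    ``data`` has shape (levels_a, levels_b, replicates) with >= 2 replicates
    per cell (a ragged/unbalanced layout is rejected).  Returns the standard
    decomposition with an interaction term:

        SS_total = SS_A + SS_B + SS_AB + SS_residual
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError(
            "data must be a (levels_a, levels_b, replicates) array; "
            "unbalanced designs are not supported"
        )
    a_lv, b_lv, r = arr.shape
    if a_lv < 2 or b_lv < 2:
        raise ValueError("each factor needs >= 2 levels")
    if r < 2:
        raise ValueError("replication requires >= 2 observations per cell")

    grand = arr.mean()
    mean_a = arr.mean(axis=(1, 2))
    mean_b = arr.mean(axis=(0, 2))
    mean_ab = arr.mean(axis=2)

    ss_a = b_lv * r * float(((mean_a - grand) ** 2).sum())
    ss_b = a_lv * r * float(((mean_b - grand) ** 2).sum())
    ss_ab = r * float(
        ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_resid = float(((arr - mean_ab[:, :, None]) ** 2).sum())

    df_a = a_lv - 1
    df_b = b_lv - 1
    df_ab = df_a * df_b
    df_resid = a_lv * b_lv * (r - 1)

    ms = {
        "factor_a": ss_a / df_a,
        "factor_b": ss_b / df_b,
        "interaction": ss_ab / df_ab,
        "residual": ss_resid / df_resid,
    }
    f = {key: ms[key] / ms["residual"] for key in ("factor_a", "factor_b", "interaction")}
    p = {
        "factor_a": float(sps.f.sf(f["factor_a"], df_a, df_resid)),
        "factor_b": float(sps.f.sf(f["factor_b"], df_b, df_resid)),
        "interaction": float(sps.f.sf(f["interaction"], df_ab, df_resid)),
    }
    return AnovaTable(
        ss={
            "factor_a": ss_a,
            "factor_b": ss_b,
            "interaction": ss_ab,
            "residual": ss_resid,
        },
        df={
            "factor_a": df_a,
            "factor_b": df_b,
            "interaction": df_ab,
            "residual": df_resid,
        },
        ms=ms,
        f=f,
        p=p,
        alpha=alpha,
    )
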