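"""One-way ANOVA with Bonferroni post-hoc pairwise comparisons.

Built from the standard sums of squares rather than delegating the test to
a stats library: F = MS_between / MS_within, with the upper F tail obtained
from the regularized incomplete beta function. The post-hoc t statistics
use the ANOVA within-group mean square as the pooled variance with
df_within degrees of freedom — the convention of classic ANOVA software —
and Bonferroni adjustment multiplies each raw p by the number of pairs.

Frames of an MD distance series are treated as independent observations
here (n = 5000 per complex in the reference analysis). They are not:
successive frames are autocorrelated, so p-values are anti-conservative.
This mirrors the upstream analysis convention and is documented as a
caveat rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import betainc

__all__ = ["AnovaResult", "PairwiseComparison", "one_way_anova", "bonferroni_pairwise"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    group_ns: tuple[int, ...]
    ms_within: float
    degenerate_variance: bool = False

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: int
    group_b: int
    mean_difference: float
    t: float
    p_raw: float
    p_adjusted: float  # min(1, p_raw * n_pairs)
    significant: bool

    def __post_init__(self) -> None:
        if self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p must not be below raw p")


def f_sf(f: float, d1: int, d2: int) -> float:
    """Upper tail P(F > f) of the F(d1, d2) distribution.

    Via the regularized incomplete beta function:
    P(F > f) = I_{d2/(d2 + d1 f)}(d2/2, d1/2).
    """
    if f <= 0:
        return 1.0
    if not np.isfinite(f):
        return 0.0
    x = d2 / (d2 + d1 * f)
    return float(betainc(d2 / 2.0, d1 / 2.0, x))


def _validated_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA across k groups of values.

    Degenerate case: zero within-group variance everywhere with unequal
    means gives p = 0 and ``degenerate_variance=True``; with equal means
    the data carry no evidence and F = 0, p = 1.
    """
    gs = _validated_groups(groups)
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(gs, means)))
    df_between = k - 1
    df_within = n_total - k
    sds = tuple(float(g.std(ddof=1)) for g in gs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            f_stat, p, degen = 0.0, 1.0, False
        else:
            f_stat, p, degen = float("inf"), 0.0, True
    else:
        ms_between = ss_between / df_between
        ms_within = ss_within / df_within
        f_stat = ms_between / ms_within
        p = f_sf(f_stat, df_between, df_within)
        degen = False
    return AnovaResult(
        F=f_stat if np.isfinite(f_stat) else float("inf"),
        df_between=df_between,
        df_within=df_within,
        p=p,
        group_means=tuple(float(m) for m in means),
        group_sds=sds,
        group_ns=tuple(int(n) for n in ns),
        ms_within=(ss_within / df_within) if df_within > 0 else 0.0,
        degenerate_variance=degen,
    )


def bonferroni_pairwise(groups, alpha: float = 0.05) -> list[PairwiseComparison]:
    """All k(k-1)/2 pooled-variance pairwise t tests, Bonferroni adjusted.

    The pooled variance is the within-group mean square of the full ANOVA
    with df_within degrees of freedom. Raw two-sided p comes from
    t^2 ~ F(1, df_within), reusing the same beta-function tail.
    """
    gs = _validated_groups(groups)
    anova = one_way_anova(gs)
    m = len(gs) * (len(gs) - 1) // 2
    out: list[PairwiseComparison] = []
    for a, b in combinations(range(len(gs)), 2):
        diff = anova.group_means[a] - anova.group_means[b]
        if anova.ms_within == 0.0:
            t_stat = float("inf") if diff != 0 else 0.0
            p_raw = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(
                anova.ms_within * (1.0 / anova.group_ns[a] + 1.0 / anova.group_ns[b])
            )
            t_stat = diff / se
            p_raw = f_sf(t_stat**2, 1, anova.df_within)
        p_adj = min(1.0, p_raw * m)
        out.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                mean_difference=float(diff),
                t=float(t_stat),
                p_raw=float(p_raw),
                p_adjusted=float(p_adj),
                significant=bool(p_adj < alpha),
            )
        )
    return out
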