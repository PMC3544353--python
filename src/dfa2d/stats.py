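"""Group comparison of scaling exponents: one-way ANOVA + Tukey pairwise tests.

Input is a mapping from group label to the exponent values of its images
(e.g. alpha1 per image).  Output bundles per-group mean +/- SD (sample SD,
n-1 denominator), the ANOVA F statistic with degrees of freedom and
p-value, and Tukey HSD adjusted p-values for all pairwise comparisons.
Unequal group sizes are handled by the Tukey-Kramer form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core2d import ConfigurationError

__all__ = [
    "GroupSummary",
    "PairwiseResult",
    "ComparisonReport",
    "summarize",
    "anova_tukey",
    "format_report",
]

DEFAULT_ALPHA_LEVEL = 0.05


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float  # NaN when n == 1 (sample SD undefined)


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class ComparisonReport:
    summaries: list[GroupSummary]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    alpha_level: float
    pairwise: list[PairwiseResult]

    def to_dict(self) -> dict:
        return {
            "groups": [vars(s) | {"sd": None if math.isnan(s.sd) else s.sd}
                       for s in self.summaries],
            "anova": {
                "F": self.f_statistic,
                "df_between": self.df_between,
                "df_within": self.df_within,
                "p_value": self.p_value,
            },
            "alpha_level": self.alpha_level,
            "tukey": [vars(p) for p in self.pairwise],
        }


def _validate(groups: dict) -> dict[str, np.ndarray]:
    clean = {}
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=np.float64)
        if arr.size == 0:
            raise ConfigurationError(f"group {name!r} is empty")
        if not np.isfinite(arr).all():
            raise ConfigurationError(f"group {name!r} contains non-finite values")
        clean[str(name)] = arr
    return clean


def summarize(groups: dict) -> list[GroupSummary]:
    """Per-group sample mean and SD (n-1 denominator); SD is NaN for n = 1."""
    clean = _validate(groups)
    out = []
    for name, arr in clean.items():
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
        out.append(GroupSummary(name=name, n=int(arr.size), mean=float(arr.mean()), sd=sd))
    return out


def anova_tukey(groups: dict, alpha_level: float = DEFAULT_ALPHA_LEVEL) -> ComparisonReport:
    """One-way ANOVA across >= 2 groups plus Tukey HSD pairwise comparisons.

    Degenerate case: zero within-group variance everywhere with unequal
    means yields an infinite F (p = 0) with a warning; identical groups
    yield F = 0, p = 1.
    """
    clean = _validate(groups)
    names = list(clean)
    G = len(names)
    if G < 2:
        raise ConfigurationError(f"need >= 2 groups, got {G}")
    n_total = sum(a.size for a in clean.values())
    if n_total <= G:
        raise ConfigurationError(
            f"total sample size {n_total} must exceed the number of groups {G}"
        )

    arrays = [clean[name] for name in names]
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between, df_within = G - 1, n_total - G

    if ss_within <= 0.0:
        if ss_between <= 0.0:
            f_stat, p_value = 0.0, 1.0
        else:
            warnings.warn("zero within-group variance with unequal means: F is infinite",
                          stacklevel=2)
            f_stat, p_value = math.inf, 0.0
    elif ss_between <= 0.0:
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = sps.f_oneway(*arrays)
        f_stat, p_value = float(f_stat), float(p_value)

    pairwise = _tukey_pairwise(clean, names, alpha_level)
    return ComparisonReport(
        summaries=summarize(clean),
        f_statistic=f_stat,
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        alpha_level=alpha_level,
        pairwise=pairwise,
    )


def _tukey_pairwise(clean, names, alpha_level) -> list[PairwiseResult]:
    endog = np.concatenate([clean[n] for n in names])
    labels = np.concatenate([[n] * clean[n].size for n in names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pairwise_tukeyhsd(endog, labels, alpha=alpha_level)
    pairs = list(combinations(res.groupsunique, 2))
    out = []
    for (a, b), diff, p_adj, reject in zip(pairs, res.meandiffs, res.pvalues, res.reject):
        out.append(PairwiseResult(
            group_a=str(a), group_b=str(b),
            mean_diff=float(diff),
            p_adjusted=float(p_adj),
            significant=bool(reject) if not math.isnan(p_adj) else float(p_adj) < alpha_level,
        ))
    return out


def format_report(report: ComparisonReport, value_name: str = "alpha1") -> str:
    """Readable text table: mean +/- SD per group, ANOVA line, Tukey pairs."""
    lines = [f"{'group':<12}{'n':>4}  {value_name} (mean +/- SD)"]
    for s in report.summaries:
        sd = "n/a" if math.isnan(s.sd) else f"{s.sd:.3f}"
        lines.append(f"{s.name:<12}{s.n:>4}  {s.mean:.3f} +/- {sd}")
    p = f"{report.p_value:.3g}" if report.p_value >= 0.001 else "<0.001"
    lines.append(
        f"ANOVA: F({report.df_between}, {report.df_within}) = "
        f"{report.f_statistic:.3f}, P = {p}"
    )
    for pr in report.pairwise:
        mark = "*" if pr.significant else " "
        lines.append(
            f"  {pr.group_a} vs {pr.group_b}: diff = {pr.mean_diff:+.3f}, "
            f"P_adj = {pr.p_adjusted:.3g} {mark}"
        )
    lines.append(f"(* significant at P < {report.alpha_level:g}, Tukey-adjusted)")
    return "\n".join(lines)
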