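"""Rank-based statistical battery for the interspecific comparisons.

The centerpiece is the Scheirer–Ray–Hare (SRH) test: a two-way ANOVA
computed on mid-ranks of the pooled responses, with each effect's
statistic ``H = SS_effect / MS_total`` referred to a chi-square
distribution (``MS_total = SS_total / (N - 1)`` is the variance of the
ranks).  Alongside the canonical H statistic, the ordinary rank-ANOVA F
with its denominator degrees of freedom is reported, since published
analyses of this design often state F rather than H.

Pairwise post-hoc comparisons use two-sided Wilcoxon rank-sum tests with
Bonferroni adjustment.  Exact null distributions are used for small
samples (full enumeration when ties are present), normal approximation
with tie correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError

__all__ = [
    "FactorialDataset",
    "EffectResult",
    "SRHResult",
    "PairwiseComparison",
    "MannWhitneyResult",
    "scheirer_ray_hare",
    "pairwise_wilcoxon",
    "wilcoxon_mann_whitney",
    "shapiro",
    "levene",
    "t_test",
    "spearman",
    "significance_stars",
]


@dataclass(frozen=True)
class FactorialDataset:
    """One response with two fully crossed categorical factors."""

    response: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        a = np.asarray(self.factor_a)
        b = np.asarray(self.factor_b)
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "factor_a", a)
        object.__setattr__(self, "factor_b", b)
        if not (len(y) == len(a) == len(b)):
            raise DataError("response and factor arrays differ in length")
        if np.any(~np.isfinite(y)):
            raise DataError("missing or non-finite responses")
        if len(self.levels_a) < 2 or len(self.levels_b) < 2:
            raise DataError("each factor needs at least 2 levels")
        for la in self.levels_a:
            for lb in self.levels_b:
                if not np.any((a == la) & (b == lb)):
                    raise DataError(f"empty design cell ({la!r}, {lb!r})")

    @property
    def levels_a(self) -> tuple:
        return tuple(dict.fromkeys(self.factor_a.tolist()))

    @property
    def levels_b(self) -> tuple:
        return tuple(dict.fromkeys(self.factor_b.tolist()))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, response: str, factors: Sequence[str]
    ) -> "FactorialDataset":
        if len(factors) != 2:
            raise ConfigError("exactly two factors are required")
        for col in (response, *factors):
            if col not in df.columns:
                raise DataError(f"column {col!r} not in table")
        return cls(
            response=df[response].to_numpy(dtype=float),
            factor_a=df[factors[0]].to_numpy(),
            factor_b=df[factors[1]].to_numpy(),
            name_a=factors[0],
            name_b=factors[1],
        )


@dataclass(frozen=True)
class EffectResult:
    """One SRH effect: rank sum of squares, H (chi-square) and rank F."""

    ss: float
    df: int
    H: float
    p_chi2: float
    F: float
    df_denom: int
    p_F: float


@dataclass(frozen=True)
class SRHResult:
    effects: Mapping[str, EffectResult]  # keys "A", "B", "AB"
    ss_within: float
    ss_total: float
    n: int
    degenerate: bool = False  # constant response: H := 0, p := 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append({
                "effect": name, "SS_ranks": e.ss, "df": e.df, "H": e.H,
                "p_chi2": e.p_chi2, "F": e.F, "df_denom": e.df_denom,
                "p_F": e.p_F, "stars": significance_stars(e.p_chi2),
            })
        return pd.DataFrame(rows)


def _rank_anova_ss(data: FactorialDataset, ranks: np.ndarray):
    """Sums of squares of the two-way layout on ranks.

    Balanced designs use the closed-form cell-mean decomposition;
    unbalanced designs fall back to type-II sums of squares via an OLS
    fit (statsmodels).
    """
    a, b = data.factor_a, data.factor_b
    la, lb = data.levels_a, data.levels_b
    counts = np.array([[np.sum((a == x) & (b == y)) for y in lb] for x in la])
    grand = ranks.mean()

    if np.all(counts == counts.flat[0]):
        ss_a = sum(
            np.sum(a == x) * (ranks[a == x].mean() - grand) ** 2 for x in la
        )
        ss_b = sum(
            np.sum(b == y) * (ranks[b == y].mean() - grand) ** 2 for y in lb
        )
        ss_cells = sum(
            np.sum(m) * (ranks[m].mean() - grand) ** 2
            for x in la for y in lb
            for m in [(a == x) & (b == y)]
        )
        return float(ss_a), float(ss_b), float(ss_cells - ss_a - ss_b)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"r": ranks, "fa": a.astype(str), "fb": b.astype(str)})
    model = smf.ols("r ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return (
        float(table.loc["C(fa)", "sum_sq"]),
        float(table.loc["C(fb)", "sum_sq"]),
        float(table.loc["C(fa):C(fb)", "sum_sq"]),
    )


def scheirer_ray_hare(data: FactorialDataset) -> SRHResult:
    """Two-way ANOVA on mid-ranks with chi-square-referred H statistics."""
    n = len(data.response)
    ranks = sps.rankdata(data.response)
    n_a, n_b = len(data.levels_a), len(data.levels_b)
    dfs = {"A": n_a - 1, "B": n_b - 1, "AB": (n_a - 1) * (n_b - 1)}
    df_within = n - n_a * n_b
    if df_within <= 0:
        raise DataError("no residual degrees of freedom (one obs per cell)")

    ss_total = float(np.sum((ranks - ranks.mean()) ** 2))
    if ss_total == 0.0:  # constant response: every rank equal
        effects = {
            k: EffectResult(0.0, d, 0.0, 1.0, 0.0, df_within, 1.0)
            for k, d in dfs.items()
        }
        return SRHResult(effects=effects, ss_within=0.0, ss_total=0.0,
                         n=n, degenerate=True)

    ss_a, ss_b, ss_ab = _rank_anova_ss(data, ranks)
    ss_within = ss_total - ss_a - ss_b - ss_ab
    ms_total = ss_total / (n - 1)
    ms_within = ss_within / df_within

    effects = {}
    for key, ss in (("A", ss_a), ("B", ss_b), ("AB", ss_ab)):
        d = dfs[key]
        H = ss / ms_total
        if ms_within > 0:
            F = (ss / d) / ms_within
            p_F = float(sps.f.sf(F, d, df_within))
        else:
            F, p_F = math.inf, 0.0
        effects[key] = EffectResult(
            ss=ss, df=d, H=float(H), p_chi2=float(sps.chi2.sf(H, d)),
            F=float(F), df_denom=df_within, p_F=p_F,
        )
    return SRHResult(effects=effects, ss_within=float(ss_within),
                     ss_total=ss_total, n=n)


# ---------------------------------------------------------------------------
# rank-sum tests

@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # rank sum of the first sample minus its minimum
    p: float
    method: str  # "exact", "exact-ties", "asymptotic"


def _exact_ties_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group labelings.

    Mid-ranks are fixed by the pooled data, so the permutation null is
    over which ``len(x)`` of the pooled values carry the first label.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Wilcoxon rank-sum / Mann–Whitney test.

    The reported statistic is U of the first sample (its rank sum minus
    ``n1(n1+1)/2``).  Small samples (both n <= 12) use the exact null —
    full enumeration when ties are present — larger ones the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both samples must be non-empty")
    small = len(x) <= 12 and len(y) <= 12
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    u1 = float(sps.rankdata(np.concatenate([x, y]))[: len(x)].sum()
               - len(x) * (len(x) + 1) / 2.0)
    if small and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(U=u1, p=float(res.pvalue), method="exact")
    if small and math.comb(len(x) + len(y), len(x)) <= 200_000:
        return MannWhitneyResult(U=u1, p=_exact_ties_p(x, y),
                                 method="exact-ties")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return MannWhitneyResult(U=u1, p=float(res.pvalue), method="asymptotic")


@dataclass(frozen=True)
class PairwiseComparison:
    group_1: str
    group_2: str
    U: float
    p_raw: float
    p_adjusted: float
    method: str

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> list[PairwiseComparison]:
    """All pairwise two-sided rank-sum tests with p-value adjustment.

    ``adjust="bonferroni"`` multiplies each raw p by the number of
    comparisons (capped at 1); ``adjust="none"`` reports raw p twice.
    """
    if adjust not in ("bonferroni", "none"):
        raise ConfigError(f"unknown adjustment {adjust!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise DataError("need at least two groups")
    for lab in labels:
        if len(np.asarray(groups[lab])) == 0:
            raise DataError(f"group {lab!r} has no observations")
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    out = []
    for g1, g2 in pairs:
        res = wilcoxon_mann_whitney(groups[g1], groups[g2])
        p_adj = min(1.0, m * res.p) if adjust == "bonferroni" else res.p
        out.append(PairwiseComparison(
            group_1=g1, group_2=g2, U=res.U, p_raw=res.p,
            p_adjusted=p_adj, method=res.method,
        ))
    return out


# ---------------------------------------------------------------------------
# auxiliary classical tests (thin scipy wrappers, kept behind one surface)

def shapiro(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise DataError("Shapiro–Wilk needs at least 3 observations")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def levene(*groups: Sequence[float], center: str = "median") -> tuple[float, float]:
    """Levene's homoscedasticity test (median-centered by default)."""
    if len(groups) < 2:
        raise DataError("Levene's test needs at least two groups")
    res = sps.levene(*[np.asarray(g, dtype=float) for g in groups],
                     center=center)
    return float(res.statistic), float(res.pvalue)


def t_test(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Two-sample t test, unpaired (Welch-free, pooled) or paired."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise DataError("paired t test needs equal-length samples")
        if np.all(x == y):  # zero differences: no evidence against the null
            return 0.0, 1.0
        res = sps.ttest_rel(x, y)
    else:
        res = sps.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t test."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                        equal_var=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank-order correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("Spearman correlation needs equal-length samples")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Significance bands: ns (> 0.05), * (<= 0.05), ** (<= 0.01),
    *** (<= 0.001); boundaries inclusive."""
    if not (0.0 <= p <= 1.0):
        raise DataError(f"p-value {p} outside [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
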