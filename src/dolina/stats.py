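"""Diversity indices, group comparisons, and the volume-prediction models.

Diversity follows the standard plot-survey indices: Shannon H' = -sum p_i
ln p_i (nats) and Simpson D = 1 - sum p_i**2, with p_i the cover proportion
of species i.

Group comparisons follow the variance-gated protocol common in vegetation
studies: Levene's test decides homogeneity of variances; homogeneous pairs
are compared with a pooled-variance Student's t-test, heterogeneous data
(or >2 groups with heterogeneous variance) with a Kruskal-Wallis test
followed by the Siegel-Castellan multiple-comparison procedure on mean
ranks, summarised as a compact letter display.

The volume model suite regresses ln(S_vol) on ln(S_depth) (M1), ln(S_area)
(M2) and both (M3) by OLS; models are compared by partial F-tests and
AIC = n*ln(RSS/n) + 2*(k+1).  Only AIC differences are meaningful — the
additive constant is convention-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "DiversityResult",
    "ComparisonReport",
    "ModelFit",
    "shannon_index",
    "simpson_index",
    "diversity",
    "compare_groups",
    "kruskal_multicomp",
    "fit_volume_models",
    "BRAUN_BLANQUET_MIDPOINTS",
]

#: Optional Braun-Blanquet cover-class -> midpoint-proportion translation.
BRAUN_BLANQUET_MIDPOINTS = {
    "r": 0.001, "+": 0.005, "1": 0.025, "2": 0.15, "3": 0.375,
    "4": 0.625, "5": 0.875,
}


@dataclass
class DiversityResult:
    richness: int
    H_prime: float
    D: float


def _clean_proportions(abundances, renormalise: bool) -> np.ndarray:
    if isinstance(abundances, dict):
        p = np.asarray(list(abundances.values()), dtype=float)
    else:
        p = np.asarray(abundances, dtype=float)
    if p.size == 0:
        raise ValueError("no abundances given")
    if np.any(p <= 0):
        raise ValueError("all proportions must be positive")
    if renormalise:
        p = p / p.sum()
    return p


def shannon_index(abundances, renormalise: bool = False) -> float:
    """Shannon diversity H' = -sum p_i ln(p_i), in nats."""
    p = _clean_proportions(abundances, renormalise)
    return float(-(p * np.log(p)).sum())


def simpson_index(abundances, renormalise: bool = False) -> float:
    """Simpson diversity D = 1 - sum p_i**2."""
    p = _clean_proportions(abundances, renormalise)
    return float(1.0 - (p ** 2).sum())


def diversity(abundances, renormalise: bool = False) -> DiversityResult:
    p = _clean_proportions(abundances, renormalise)
    return DiversityResult(richness=p.size,
                           H_prime=shannon_index(p),
                           D=simpson_index(p))


@dataclass
class ComparisonReport:
    """Result of a variance-gated group comparison."""

    test: str                    # "t" | "kruskal"
    statistic: float
    p_value: float
    levene_statistic: float
    levene_p: float
    group_means: list[float]
    letters: list[str] = field(default_factory=list)


def compare_groups(*groups: Sequence[float], alpha: float = 0.05) -> ComparisonReport:
    """Compare two or more samples with the variance-gated protocol.

    Two groups: Levene's test (mean-centred), then a pooled t-test if
    variances are homogeneous (Levene p > alpha) or Kruskal-Wallis if not.
    More than two groups: one-way ANOVA when homogeneous, otherwise
    Kruskal-Wallis plus the Siegel-Castellan multiple comparison with a
    compact letter display.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    lev_stat, lev_p = sps.levene(*arrays, center="mean")
    if np.isnan(lev_stat):  # all values identical in every group
        lev_stat, lev_p = 0.0, 1.0
    means = [float(a.mean()) for a in arrays]
    homogeneous = lev_p > alpha
    if len(arrays) == 2:
        if homogeneous:
            if np.allclose(np.concatenate(arrays), arrays[0][0]):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=True)
            letters = ["a", "a"] if p > alpha else ["a", "b"]
            return ComparisonReport("t", float(stat), float(p), float(lev_stat),
                                    float(lev_p), means, letters)
        stat, p = sps.kruskal(*arrays)
        letters = ["a", "a"] if p > alpha else ["a", "b"]
        return ComparisonReport("kruskal", float(stat), float(p),
                                float(lev_stat), float(lev_p), means, letters)
    if homogeneous:
        stat, p = sps.f_oneway(*arrays)
        letters = ["a"] * len(arrays) if p > alpha else _letters_from_pairs(
            len(arrays), _pairwise_t(arrays, alpha))
        return ComparisonReport("anova", float(stat), float(p), float(lev_stat),
                                float(lev_p), means, letters)
    stat, p = sps.kruskal(*arrays)
    sig = kruskal_multicomp(arrays, alpha=alpha) if p <= alpha else set()
    letters = _letters_from_pairs(len(arrays), sig)
    return ComparisonReport("kruskal", float(stat), float(p), float(lev_stat),
                            float(lev_p), means, letters)


def _pairwise_t(arrays: list[np.ndarray], alpha: float) -> set[tuple[int, int]]:
    k = len(arrays)
    m = k * (k - 1) / 2
    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            _, p = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
            if p <= alpha / m:  # Bonferroni within the ANOVA branch
                sig.add((i, j))
    return sig


def kruskal_multicomp(arrays: list[np.ndarray], alpha: float = 0.05
                      ) -> set[tuple[int, int]]:
    """Siegel-Castellan multiple comparison after Kruskal-Wallis.

    Pair (i, j) is significantly different when the absolute difference of
    mean ranks exceeds  z_{1 - alpha/(k(k-1))} * sqrt(N(N+1)/12 * (1/n_i +
    1/n_j)), two-sided at family level alpha.
    """
    k = len(arrays)
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    big_n = pooled.size
    crit_z = sps.norm.ppf(1 - alpha / (k * (k - 1)))
    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(big_n * (big_n + 1) / 12.0
                           * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if abs(mean_ranks[i] - mean_ranks[j]) > crit_z * se:
                sig.add((i, j))
    return sig


def _letters_from_pairs(k: int, sig: set[tuple[int, int]]) -> list[str]:
    """Compact letter display by the insert-and-absorb algorithm: groups not
    significantly different share at least one letter."""
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # letter sets: start with one set containing everyone, split on conflicts
    sets: list[set[int]] = [set(range(k))]
    for (i, j) in sorted(sig):
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {j})
                new_sets.append(s - {i})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: min(s))
    letters = ["" for _ in range(k)]
    for idx, s in enumerate(sets):
        for g in sorted(s):
            letters[g] += alphabet[idx % len(alphabet)]
    return letters


@dataclass
class ModelFit:
    """One OLS fit of the ln-volume model suite."""

    model_id: str
    predictors: list[str]
    coefficients: dict[str, float]
    residual_se: float
    adj_r2: float
    aic: float
    rss: float
    n: int


@dataclass
class PartialFReport:
    full: str
    reduced: str
    f_statistic: float
    p_value: float


def _aic(rss: float, n: int, k: int) -> float:
    return n * math.log(rss / n) + 2 * (k + 1)


def fit_volume_models(table: pd.DataFrame) -> tuple[list[ModelFit], list[PartialFReport]]:
    """Fit M1 (ln depth), M2 (ln area) and M3 (both) for ln volume by OLS.

    The input table needs positive columns S_depth, S_area, S_vol.  Returns
    the three fits (coefficients, residual SE, adjusted R**2, AIC) and the
    partial F comparisons of M3 against each nested model.
    """
    for col in ("S_depth", "S_area", "S_vol"):
        if col not in table.columns:
            raise ValueError(f"missing column {col}")
        bad = table.index[table[col] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive {col} for records {bad[:10]}")
    n = len(table)
    if n <= 4:
        raise ValueError("need more than 4 observations")
    ln_d = np.log(table["S_depth"].to_numpy(dtype=float))
    ln_a = np.log(table["S_area"].to_numpy(dtype=float))
    ln_v = np.log(table["S_vol"].to_numpy(dtype=float))
    designs = {
        "M1": {"ln_S_depth": ln_d},
        "M2": {"ln_S_area": ln_a},
        "M3": {"ln_S_depth": ln_d, "ln_S_area": ln_a},
    }
    fits: list[ModelFit] = []
    results = {}
    for mid, cols in designs.items():
        X = sm.add_constant(pd.DataFrame(cols))
        res = sm.OLS(ln_v, X).fit()
        rss = float(res.ssr)
        k = len(cols)
        fits.append(ModelFit(
            model_id=mid,
            predictors=list(cols),
            coefficients={name: float(v) for name, v in res.params.items()},
            residual_se=float(math.sqrt(rss / (n - k - 1))),
            adj_r2=float(res.rsquared_adj),
            aic=_aic(rss, n, k),
            rss=rss,
            n=n,
        ))
        results[mid] = res
    reports: list[PartialFReport] = []
    full = results["M3"]
    for mid in ("M1", "M2"):
        red = results[mid]
        df_num = red.df_resid - full.df_resid
        f_stat = ((red.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
        p = float(sps.f.sf(f_stat, df_num, full.df_resid))
        reports.append(PartialFReport("M3", mid, float(f_stat), p))
    return fits, reports
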