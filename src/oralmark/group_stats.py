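"""Nonparametric group comparisons for gut-barrier markers and clinical
variables across the three dysbiosis groups.

Continuous variables are summarised as median with a distribution-free 95%
confidence interval (order-statistic/binomial method) and compared with
Kruskal-Wallis omnibus tests followed by pairwise Mann-Whitney tests with
Bonferroni correction; categorical variables with Pearson chi-square;
pairwise associations with Spearman rank correlation.

The default pairwise scheme follows the three contrasts used for barrier
markers: (a) PPI with dysbiosis vs no PPI, (b) PPI without dysbiosis vs
no PPI, (c) PPI with vs without dysbiosis — multiplier 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biomarker_discovery import NO_PPI, PPI_DYSBIOSIS, PPI_NO_DYSBIOSIS

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "pairwise_mw_bonferroni",
    "spearman",
    "chi_square",
    "median_ci",
    "compare_groups",
    "DEFAULT_CONTRASTS",
]

DEFAULT_CONTRASTS = [
    ("a", PPI_DYSBIOSIS, NO_PPI),
    ("b", PPI_NO_DYSBIOSIS, NO_PPI),
    ("c", PPI_DYSBIOSIS, PPI_NO_DYSBIOSIS),
]


@dataclass
class GroupComparison:
    variable: str
    per_group: pd.DataFrame        # group, n, median, ci_low, ci_high
    omnibus_h: float
    omnibus_p: float
    contrasts: pd.DataFrame        # label, group1, group2, p_raw, p_adj, skipped


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    All-tied data yields H = 0, p = 1 rather than an error.
    """
    v = np.asarray(list(values), dtype=float)
    g = np.asarray(list(groups))
    uniq = pd.unique(g)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [v[g == u] for u in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.ptp(v) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def pairwise_mw_bonferroni(
    values, groups, contrasts=DEFAULT_CONTRASTS
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests with Bonferroni correction.

    Adjusted p = raw p x number of contrasts, capped at 1 (tables report the
    cap as "> 0.999"). Contrasts with an empty group are skipped and flagged.
    """
    v = np.asarray(list(values), dtype=float)
    g = np.asarray(list(groups))
    m = len(contrasts)
    rows = []
    for label, g1, g2 in contrasts:
        a, b = v[g == g1], v[g == g2]
        if len(a) == 0 or len(b) == 0:
            rows.append({"label": label, "group1": g1, "group2": g2,
                         "p_raw": np.nan, "p_adj": np.nan, "skipped": True})
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            p_raw = 1.0
        else:
            p_raw = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
        rows.append({"label": label, "group1": g1, "group2": g2,
                     "p_raw": p_raw, "p_adj": min(1.0, p_raw * m),
                     "skipped": False})
    return pd.DataFrame(rows)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Uses exact permutation p for n <= 9 and the t approximation otherwise.
    Constant input yields (nan, nan) — undefined, flagged by NaN.
    """
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if len(xv) < 3 or len(xv) != len(yv):
        raise ValueError("need >=3 paired observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(xv, yv)
    rho = float(res.statistic)
    if len(xv) <= 9:
        return rho, _spearman_exact_p(xv, yv, rho)
    return rho, float(res.pvalue)


def _spearman_exact_p(xv: np.ndarray, yv: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho by full enumeration."""
    from itertools import permutations

    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.linalg.norm(rx_c) * np.linalg.norm(ry_c)
    perms = np.array(list(permutations(rx_c)))
    rhos = perms @ ry_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2-way count table.

    Warns when any expected count is below 5; zero-margin rows/columns are
    an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("need a 2-way table of non-negative counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero-margin row or column")
    stat, p, _, expected = stats.chi2_contingency(obs, correction=False)
    if np.any(expected < 5):
        import warnings

        warnings.warn("expected counts below 5; chi-square may be unreliable",
                      stacklevel=2)
    return float(stat), float(p)


def median_ci(values, level: float = 0.95) -> tuple[float, float, float, bool]:
    """Median and distribution-free CI from order statistics.

    Returns (median, low, high, exact_flag). The bounds are the order
    statistics x_(l), x_(u) with l the largest integer such that
    P(Binom(n, 1/2) < l) <= (1-level)/2 and u = n + 1 - l. For n < 6 no such
    interval exists at 95%; the full range is reported with exact_flag False.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    n = len(v)
    if n < 1:
        raise ValueError("need at least one observation")
    med = float(np.median(v))
    if n < 6:
        return med, float(v[0]), float(v[-1]), False
    alpha = (1 - level) / 2
    # largest l with P(X <= l-1) <= alpha, X ~ Binom(n, 0.5)
    cdf = stats.binom.cdf(np.arange(n + 1), n, 0.5)
    l_candidates = np.flatnonzero(cdf <= alpha)
    l = int(l_candidates[-1]) + 1 if len(l_candidates) else 1
    u = n + 1 - l
    return med, float(v[l - 1]), float(v[u - 1]), True


def compare_groups(
    records: pd.DataFrame,
    variables,
    group_col: str = "dysbiosis_group",
    contrasts=DEFAULT_CONTRASTS,
) -> list[GroupComparison]:
    """Barrier-marker-style comparison of variables across dysbiosis groups."""
    out = []
    for var in variables:
        sub = records[[group_col, var]].dropna()
        v = sub[var].to_numpy(float)
        g = sub[group_col].to_numpy()
        per_rows = []
        for grp in pd.unique(g):
            vals = v[g == grp]
            med, lo, hi, exact = median_ci(vals)
            per_rows.append({"group": grp, "n": len(vals), "median": med,
                             "ci_low": lo, "ci_high": hi, "ci_exact": exact})
        h, p = kruskal_wallis(v, g)
        contr = pairwise_mw_bonferroni(v, g, contrasts=contrasts)
        out.append(
            GroupComparison(
                variable=var,
                per_group=pd.DataFrame(per_rows),
                omnibus_h=h,
                omnibus_p=p,
                contrasts=contr,
            )
        )
    return out
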