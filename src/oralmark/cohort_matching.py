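"""Propensity-score matching of PPI users to non-users on liver severity.

PPI prescription in cirrhosis is confounded with disease severity, so
exposed subjects are matched to unexposed controls by nearest-neighbour
propensity-score matching *with replacement* (a control may serve several
cases). The propensity model is a main-effects logistic regression of
exposure on Child-Pugh and MELD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PropensityFit",
    "MatchedCohort",
    "fit_propensity",
    "match_nearest",
    "balance_diagnostics",
]

DEFAULT_COVARIATES = ("child_pugh", "meld")


@dataclass
class PropensityFit:
    scores: pd.Series              # P(exposure | covariates), indexed by sample
    params: pd.Series
    penalized: bool                # True when the MLE was separated/unstable


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame            # case_id, control_id, case_ps, control_ps, pair_cv
    reuse_counts: pd.Series        # matches per control actually used
    unmatched_controls: list[str]

    @property
    def median_pair_cv(self) -> float:
        return float(self.pairs["pair_cv"].median())


def fit_propensity(
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    exposure_col: str = "ppi_use",
) -> PropensityFit:
    """Logistic-regression propensity scores for exposure.

    Falls back to an L2-penalized fit (flagged) when the MLE separates or
    fails to converge, so scores stay strictly inside (0, 1).
    """
    df = records
    y = df[exposure_col].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("both exposure groups must be present")
    X = df[list(covariates)].astype(float)
    if X.isna().any().any():
        raise ValueError("covariates must be complete (no missing values)")
    Xc = sm.add_constant(X, has_constant="add")
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, Xc).fit(disp=0)
        params = fit.params
        scores = np.asarray(fit.predict(Xc))
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise RuntimeError("unstable MLE")
    except Exception:
        penalized = True
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        lr.fit(X.to_numpy(), y)
        params = pd.Series(
            np.concatenate(([lr.intercept_[0]], lr.coef_[0])), index=Xc.columns
        )
        scores = lr.predict_proba(X.to_numpy())[:, 1]
    eps = 1e-12
    scores = np.clip(scores, eps, 1 - eps)
    return PropensityFit(
        scores=pd.Series(scores, index=df["sample_id"].astype(str).to_numpy()),
        params=pd.Series(np.asarray(params), index=Xc.columns),
        penalized=penalized,
    )


def _pair_cv(a: float, b: float) -> float:
    """Coefficient of variation (%) of a pair of propensity scores, sample sd."""
    m = (a + b) / 2
    if m == 0:
        return 0.0
    sd = abs(a - b) / np.sqrt(2)
    return float(sd / m * 100)


def match_nearest(
    scores: pd.Series,
    exposure: pd.Series,
) -> MatchedCohort:
    """Nearest-neighbour matching with replacement on the propensity score.

    Cases are processed in descending score order (order is irrelevant to the
    optimum under replacement but fixed for determinism); score ties among
    controls break by control-id order. Controls never matched are excluded.
    """
    scores = scores.astype(float)
    exp = exposure.astype(bool)
    exp = exp.reindex(scores.index)
    case_ids = [i for i in scores.index if exp[i]]
    control_ids = [i for i in scores.index if not exp[i]]
    if not control_ids:
        raise ValueError("no controls available for matching")
    case_ids.sort(key=lambda i: -scores[i])
    ctrl_scores = scores[control_ids].to_numpy()
    rows = []
    use = {c: 0 for c in control_ids}
    for cid in case_ids:
        diffs = np.abs(ctrl_scores - scores[cid])
        j = int(np.argmin(diffs))  # argmin takes the first = control-id order
        ctrl = control_ids[j]
        use[ctrl] += 1
        rows.append(
            {
                "case_id": cid,
                "control_id": ctrl,
                "case_ps": scores[cid],
                "control_ps": scores[ctrl],
                "pair_cv": _pair_cv(scores[cid], scores[ctrl]),
            }
        )
    pairs = pd.DataFrame(rows)
    reuse = pd.Series({c: n for c, n in use.items() if n > 0}, dtype=int)
    unmatched = [c for c, n in use.items() if n == 0]
    return MatchedCohort(pairs=pairs, reuse_counts=reuse, unmatched_controls=unmatched)


def balance_diagnostics(
    records: pd.DataFrame,
    matched: MatchedCohort,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    exposure_col: str = "ppi_use",
) -> pd.DataFrame:
    """Standardized mean differences before and after matching.

    SMD = (mean_case - mean_control) / pooled sd, with the pooled sd taken
    from the unmatched groups for both columns so the scale is comparable.
    Constant covariates are reported as 0 with a flag.
    """
    df = records.set_index(records["sample_id"].astype(str))
    exp = df[exposure_col].astype(bool)
    rows = []
    for cov in covariates:
        v = df[cov].astype(float)
        case_v, ctrl_v = v[exp], v[~exp]
        pooled = np.sqrt((case_v.var(ddof=1) + ctrl_v.var(ddof=1)) / 2)
        flagged = not np.isfinite(pooled) or pooled == 0
        if flagged:
            rows.append({"covariate": cov, "smd_pre": 0.0, "smd_post": 0.0,
                         "zero_variance": True})
            continue
        smd_pre = (case_v.mean() - ctrl_v.mean()) / pooled
        mc = v[matched.pairs["case_id"]].to_numpy()
        mt = v[matched.pairs["control_id"]].to_numpy()
        smd_post = (mc.mean() - mt.mean()) / pooled
        rows.append({"covariate": cov, "smd_pre": float(smd_pre),
                     "smd_post": float(smd_post), "zero_variance": False})
    return pd.DataFrame(rows)
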