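"""Kaplan-Meier and Cox proportional-hazards analysis of liver-related
three-year mortality by dysbiosis group.

Follow-up is administratively truncated at 36 months; liver-unrelated
deaths, transplantation and loss to follow-up are censored. The headline
model is a forced-entry Cox regression with two dysbiosis indicators
(PPI with dysbiosis, PPI without dysbiosis; reference: no PPI use) plus
Child-Pugh and MELD as confounders. Estimation is delegated to lifelines
(Efron tie handling); monotone-likelihood instability with few events is
surfaced via a convergence flag rather than silently reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from .biomarker_discovery import NO_PPI, PPI_DYSBIOSIS, PPI_NO_DYSBIOSIS

__all__ = [
    "KMCurve",
    "CoxFit",
    "ThreeGroupResult",
    "truncate_followup",
    "km_fit",
    "cox_fit",
    "three_group_model",
]

HORIZON_MONTHS = 36.0


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    group: str
    event_times: np.ndarray        # distinct times where S drops
    survival: np.ndarray           # S(t) just after each event time
    at_risk: np.ndarray            # n at risk just before each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return float(s)

    def at_risk_at(self, t: float) -> int:
        """Number at risk just before time t (for at-risk tables)."""
        n = len(self._all_times)
        return int(np.sum(self._all_times >= t))

    _all_times: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    log_likelihood: float
    converged: bool
    dropped_covariates: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hazard_ratio": self.hazard_ratio,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "p": self.wald_p,
            },
            index=self.covariates,
        )


def truncate_followup(
    times: np.ndarray, events: np.ndarray, horizon: float = HORIZON_MONTHS
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at the observation horizon (months)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t < 0):
        raise ValueError("negative follow-up times")
    over = t > horizon
    t = np.minimum(t, horizon)
    e = e & ~over
    return t, e


def km_fit(
    times, events, groups=None
) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit estimate per group.

    At equal times censorings are taken to occur after events (the standard
    convention). ``groups=None`` fits a single pooled curve keyed "all".
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t < 0):
        raise ValueError("negative follow-up times")
    g = np.asarray(["all"] * len(t)) if groups is None else np.asarray(list(groups))
    out: dict[str, KMCurve] = {}
    for grp in pd.unique(g):
        mask = g == grp
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        sf = kmf.survival_function_.iloc[:, 0]
        ev = kmf.event_table
        drop_times = ev.index[ev["observed"] > 0].to_numpy(float)
        surv = np.array([sf.loc[dt] for dt in drop_times])
        at_risk = ev.loc[drop_times, "at_risk"].to_numpy(float)
        censor_times = np.repeat(
            ev.index.to_numpy(float), ev["censored"].to_numpy(int)
        )
        curve = KMCurve(
            group=str(grp),
            event_times=drop_times,
            survival=surv,
            at_risk=at_risk,
            censor_times=censor_times,
        )
        curve._all_times = t[mask]
        out[str(grp)] = curve
    return out


def cox_fit(times, events, covariates: pd.DataFrame) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald inference).

    Constant covariates are dropped with a warning before fitting; monotone
    partial likelihood (complete separation) is reported through
    ``converged=False`` instead of an exception.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    X = covariates.astype(float).reset_index(drop=True)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no non-constant covariates to fit")
    df = X.copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cph.fit(df, duration_col="_time", event_col="_event")
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged = False
        except ConvergenceError:
            # monotone likelihood: refit with a tiny ridge penalty, flag it
            converged = False
            cph = CoxPHFitter(penalizer=1e-6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    beta = s["coef"].to_numpy()
    se = s["se(coef)"].to_numpy()
    with np.errstate(over="ignore"):  # very wide Wald CIs overflow to inf
        return CoxFit(
        covariates=list(s.index),
        beta=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci95_low=np.exp(beta - 1.96 * se),
        ci95_high=np.exp(beta + 1.96 * se),
        wald_p=s["p"].to_numpy(),
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        dropped_covariates=dropped,
    )


@dataclass
class ThreeGroupResult:
    adjusted: CoxFit               # dysbiosis indicators + Child-Pugh + MELD
    univariate: CoxFit             # dysbiosis indicators only
    km: dict[str, KMCurve]


def three_group_model(
    records: pd.DataFrame,
    group_col: str = "dysbiosis_group",
    horizon: float = HORIZON_MONTHS,
) -> ThreeGroupResult:
    """Survival linkage of the three-level dysbiosis classification.

    Fits (a) the forced-entry adjusted model with indicators for
    ``ppi_dysbiosis`` and ``ppi_no_dysbiosis`` (reference ``no_ppi``) plus
    Child-Pugh and MELD, and (b) the univariate two-indicator model, along
    with per-group Kaplan-Meier curves. Degenerate indicator columns (e.g.
    every PPI user dysbiotic) are dropped by :func:`cox_fit` with a warning.
    """
    df = records.copy()
    if (df[group_col] == NO_PPI).sum() == 0:
        raise ValueError("reference group (no PPI use) is empty")
    t, e = truncate_followup(
        df["followup_months"].to_numpy(float),
        (df["event"] == "liver_death").to_numpy()
        if df["event"].dtype == object
        else df["event"].to_numpy(bool),
        horizon=horizon,
    )
    X = pd.DataFrame(
        {
            PPI_DYSBIOSIS: (df[group_col] == PPI_DYSBIOSIS).astype(float).to_numpy(),
            PPI_NO_DYSBIOSIS: (df[group_col] == PPI_NO_DYSBIOSIS)
            .astype(float)
            .to_numpy(),
            "child_pugh": df["child_pugh"].to_numpy(float),
            "meld": df["meld"].to_numpy(float),
        }
    )
    adjusted = cox_fit(t, e, X)
    univariate = cox_fit(t, e, X[[PPI_DYSBIOSIS, PPI_NO_DYSBIOSIS]])
    km = km_fit(t, e, df[group_col].to_numpy())
    return ThreeGroupResult(adjusted=adjusted, univariate=univariate, km=km)
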