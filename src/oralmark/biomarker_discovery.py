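"""Single-taxon biomarker discovery for PPI-associated dysbiosis.

The cascade mirrors how such biomarkers are established in practice:

1. univariate screening — Mann-Whitney U per taxon, PPI users vs non-users,
   Benjamini-Hochberg adjusted;
2. random-forest ranking by mean decrease in accuracy (out-of-bag
   permutation importance);
3. candidate selection — taxa in the top 5% of the importance ranking that
   are also significant after adjustment, plus any literature-prior taxa;
4. threshold calibration — AUROC with Mann-Whitney significance, then the
   cut-point maximising the Youden index J = sensitivity + specificity - 1;
5. a validation gate — the frozen threshold must reach >= 70% accuracy in
   an independent validation cohort;
6. three-group dysbiosis classification (no PPI / PPI without dysbiosis /
   PPI with dysbiosis) driven by one gated biomarker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CandidateBiomarker",
    "BiomarkerModel",
    "DysbiosisLabel",
    "mann_whitney_screen",
    "bh_adjust",
    "rf_rank",
    "select_candidates",
    "auroc",
    "youden_calibrate",
    "validate_gate",
    "predict_dysbiotic",
    "classify_dysbiosis",
    "run_cascade",
]

NO_PPI = "no_ppi"
PPI_NO_DYSBIOSIS = "ppi_no_dysbiosis"
PPI_DYSBIOSIS = "ppi_dysbiosis"


@dataclass
class CandidateBiomarker:
    taxon_id: str
    rank_level: str
    p_raw: float
    q_bh: float
    rf_importance: float | None
    in_top5: bool
    source: Literal["data_driven", "literature_prior"]

    def __post_init__(self) -> None:
        if not (0 <= self.p_raw <= 1 and 0 <= self.q_bh <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.q_bh < self.p_raw - 1e-12:
            raise ValueError("BH-adjusted q cannot be below raw p")


@dataclass
class BiomarkerModel:
    """One taxon's calibrated decision rule and its performance."""

    taxon_id: str
    threshold: float                      # relative abundance at screening depth
    direction: Literal["high_predicts_ppi", "low_predicts_ppi"]
    auroc: float
    auroc_p: float
    sensitivity: float
    specificity: float
    youden_j: float
    threshold_count: float | None = None  # count-equivalent at screening depth
    accuracy_validation: float | None = None
    balanced_accuracy_validation: float | None = None
    passed_gate: bool | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.youden_j <= 1 + 1e-9:
            raise ValueError("Youden J must lie in [-1, 1]")


@dataclass
class DysbiosisLabel:
    sample_id: str
    taxon_id: str
    group: Literal["no_ppi", "ppi_no_dysbiosis", "ppi_dysbiosis"]


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(bool)
    return y


def mann_whitney_screen(abundances: np.ndarray, labels: Sequence) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per taxon between PPI users and non-users.

    ``abundances`` is taxa x samples; ``labels`` is the per-sample exposure
    flag. Exact enumeration is used for small tie-free groups (n <= 8 each),
    otherwise the tie-corrected normal approximation. Taxa that are constant
    across all samples get p = 1 with a degenerate flag.
    """
    X = np.atleast_2d(np.asarray(abundances, dtype=float))
    y = _as_bool_labels(labels)
    if X.shape[1] != len(y):
        raise ValueError("abundance columns and labels must align")
    if y.all() or not y.any():
        raise ValueError("both exposure groups must be nonempty")
    pos, neg = X[:, y], X[:, ~y]
    small = pos.shape[1] <= 8 and neg.shape[1] <= 8
    rows = []
    for i in range(X.shape[0]):
        a, b = pos[i], neg[i]
        if np.ptp(X[i]) == 0:
            rows.append((np.nan, 1.0, True))
            continue
        has_ties = len(np.unique(X[i])) < len(X[i])
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append((float(res.statistic), float(res.pvalue), False))
    return pd.DataFrame(rows, columns=["U", "p_raw", "degenerate"])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rf_rank(
    abundances: np.ndarray,
    labels: Sequence,
    n_trees: int = 1000,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean decrease in out-of-bag accuracy under per-taxon permutation.

    A random forest (sqrt-feature subsampling) is fit on samples x taxa; the
    importance of taxon j is the average, over trees and ``n_repeats``
    permutations, of the drop in that tree's out-of-bag accuracy when column
    j is shuffled. Deterministic given ``seed``.
    """
    X = np.ascontiguousarray(np.asarray(abundances, dtype=np.float32).T)
    y = _as_bool_labels(labels).astype(np.int64)
    n, m = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if np.bincount(y).min() < 2:
        raise ValueError("need >=2 samples per class")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    n_boot = _get_n_samples_bootstrap(n, rf.max_samples, None)
    oob_idx = [
        _generate_unsampled_indices(t.random_state, n, n_boot, None)
        for t in rf.estimators_
    ]
    classes = rf.classes_
    base_acc = np.empty(len(rf.estimators_))
    tree_structs = [t.tree_ for t in rf.estimators_]
    for k, (tr, idx) in enumerate(zip(tree_structs, oob_idx)):
        if len(idx) == 0:
            base_acc[k] = np.nan
            continue
        pred = classes[np.argmax(tr.predict(X[idx]), axis=-1).ravel()]
        base_acc[k] = np.mean(pred == y[idx])
    rng = np.random.default_rng(seed)
    drops = np.zeros(m)
    valid = ~np.isnan(base_acc)
    for _ in range(n_repeats):
        for j in range(m):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            acc_sum, cnt = 0.0, 0
            for k, (tr, idx) in enumerate(zip(tree_structs, oob_idx)):
                if not valid[k]:
                    continue
                pred = classes[np.argmax(tr.predict(Xp[idx]), axis=-1).ravel()]
                acc_sum += base_acc[k] - np.mean(pred == y[idx])
                cnt += 1
            drops[j] += acc_sum / max(cnt, 1)
    return drops / n_repeats


def select_candidates(
    taxon_ids: Sequence[str],
    p_raw: Sequence[float],
    q_bh: Sequence[float],
    rf_importance: Sequence[float],
    literature_taxa: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    top_frac: float = 0.05,
    rank_level: str = "otu",
) -> list[CandidateBiomarker]:
    """Data-driven candidates (top-5% RF importance AND q < alpha) plus
    literature-prior taxa appended unconditionally.

    ``literature_taxa`` is a list of (taxon_id, rank_level) pairs; the caller
    aggregates the table to each stated rank before scoring them. The top-x%
    count uses the ceiling rule with a minimum of one taxon.
    """
    ids = list(taxon_ids)
    p = np.asarray(list(p_raw), dtype=float)
    q = np.asarray(list(q_bh), dtype=float)
    imp = np.asarray(list(rf_importance), dtype=float)
    if not (len(ids) == len(p) == len(q) == len(imp)):
        raise ValueError("screening and ranking inputs must cover the same taxa")
    m = len(ids)
    k = max(1, math.ceil(top_frac * m))
    # rank by importance, descending; stable order breaks ties by input position
    order = np.argsort(-imp, kind="stable")
    top_set = set(order[:k].tolist())
    out: list[CandidateBiomarker] = []
    for i in range(m):
        in_top = i in top_set
        if in_top and q[i] < alpha:
            out.append(
                CandidateBiomarker(
                    taxon_id=ids[i], rank_level=rank_level, p_raw=float(p[i]),
                    q_bh=float(q[i]), rf_importance=float(imp[i]),
                    in_top5=True, source="data_driven",
                )
            )
    selected = {c.taxon_id for c in out}
    for tid, level in literature_taxa or []:
        if tid in selected:
            continue
        if tid in ids:
            i = ids.index(tid)
            pr, qb, im = float(p[i]), float(q[i]), float(imp[i])
            in_top = i in top_set
        else:
            pr, qb, im, in_top = 1.0, 1.0, None, False
        out.append(
            CandidateBiomarker(
                taxon_id=tid, rank_level=level, p_raw=pr, q_bh=qb,
                rf_importance=im, in_top5=in_top, source="literature_prior",
            )
        )
    return out


@dataclass
class AurocResult:
    auc: float
    p_value: float


def auroc(scores: Sequence[float], labels: Sequence) -> AurocResult:
    """AUROC with ties counted half, and its Mann-Whitney significance.

    AUROC = (concordant + 0.5 * tied pairs) / (n1 * n0) = U / (n1 * n0).
    """
    s = np.asarray(list(scores), dtype=float)
    y = _as_bool_labels(labels)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    if np.ptp(s) == 0:
        return AurocResult(0.5, 1.0)
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return AurocResult(auc, float(res.pvalue))


def _confusion_rates(s: np.ndarray, y: np.ndarray, thr: float, high: bool):
    pred = s >= thr if high else s <= thr
    sens = np.mean(pred[y]) if y.any() else np.nan
    spec = np.mean(~pred[~y]) if (~y).any() else np.nan
    return float(sens), float(spec)


def youden_calibrate(
    scores: Sequence[float],
    labels: Sequence,
    taxon_id: str = "",
    screening_depth: int | None = None,
) -> BiomarkerModel:
    """Pick the cut-point maximising J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive distinct
    scores plus sentinels below/above every score; both decision directions
    are enumerated. Ties in J are broken toward the direction agreeing with
    the AUROC (>= 0.5: high scores predict PPI), then toward higher
    specificity, then toward the larger threshold (the biomarkers this
    models are specificity-leaning).
    """
    s = np.asarray(list(scores), dtype=float)
    y = _as_bool_labels(labels)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    roc = auroc(s, y)
    if np.ptp(s) == 0:
        return BiomarkerModel(
            taxon_id=taxon_id, threshold=float(s[0]), direction="high_predicts_ppi",
            auroc=0.5, auroc_p=1.0, sensitivity=1.0, specificity=0.0,
            youden_j=0.0, degenerate=True,
            threshold_count=(s[0] * screening_depth if screening_depth else None),
        )
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2
    span = uniq[-1] - uniq[0]
    cands = np.concatenate(
        ([uniq[0] - 0.5 * span - 1], mids, [uniq[-1] + 0.5 * span + 1])
    )
    preferred_high = roc.auc >= 0.5
    best = None
    for high in (True, False):
        for thr in cands:
            sens, spec = _confusion_rates(s, y, thr, high)
            j = sens + spec - 1
            key = (round(j, 12), high == preferred_high, round(spec, 12), thr)
            if best is None or key > best[0]:
                best = (key, thr, sens, spec, j, high)
    _, thr, sens, spec, j, high = best
    return BiomarkerModel(
        taxon_id=taxon_id,
        threshold=float(thr),
        direction="high_predicts_ppi" if high else "low_predicts_ppi",
        auroc=roc.auc,
        auroc_p=roc.p_value,
        sensitivity=sens,
        specificity=spec,
        youden_j=float(j),
        threshold_count=(float(thr) * screening_depth if screening_depth else None),
    )


def predict_dysbiotic(model: BiomarkerModel, scores: Sequence[float]) -> np.ndarray:
    """Apply the frozen decision rule: predicted-positive on the >= side."""
    s = np.asarray(list(scores), dtype=float)
    if model.direction == "high_predicts_ppi":
        return s >= model.threshold
    return s <= model.threshold


def validate_gate(
    model: BiomarkerModel,
    scores: Sequence[float],
    labels: Sequence,
    gate: float = 0.70,
) -> BiomarkerModel:
    """Score the frozen threshold on the validation cohort.

    The threshold and direction are never re-estimated here; the gate is
    inclusive (accuracy of exactly 70% passes). Balanced accuracy is
    reported alongside raw accuracy.
    """
    s = np.asarray(list(scores), dtype=float)
    y = _as_bool_labels(labels)
    if len(s) == 0:
        raise ValueError("validation set is empty")
    pred = predict_dysbiotic(model, s)
    acc = float(np.mean(pred == y))
    if y.any() and (~y).any():
        bal = float((np.mean(pred[y]) + np.mean(~pred[~y])) / 2)
    else:
        bal = np.nan
    return replace(
        model,
        accuracy_validation=acc,
        balanced_accuracy_validation=bal,
        passed_gate=acc >= gate,
    )


def classify_dysbiosis(
    sample_ids: Sequence[str],
    ppi_use: Sequence[bool],
    scores: Sequence[float],
    model: BiomarkerModel,
    allow_unvalidated: bool = False,
) -> list[DysbiosisLabel]:
    """Three-group classification driven by one gated biomarker.

    no PPI -> ``no_ppi``; PPI user predicted positive -> ``ppi_dysbiosis``
    (true positives); PPI user predicted negative -> ``ppi_no_dysbiosis``
    (false negatives).
    """
    if model.passed_gate is not True:
        if not allow_unvalidated:
            raise ValueError(
                f"biomarker {model.taxon_id!r} has not passed the validation gate"
            )
        warnings.warn(
            f"classifying with unvalidated biomarker {model.taxon_id!r}",
            stacklevel=2,
        )
    s = np.asarray(list(scores), dtype=float)
    if np.any(np.isnan(s)):
        bad = [sid for sid, v in zip(sample_ids, s) if np.isnan(v)]
        raise ValueError(f"missing biomarker abundance for samples: {bad}")
    pred = predict_dysbiotic(model, s)
    out = []
    for sid, ppi, pos in zip(sample_ids, np.asarray(list(ppi_use), dtype=bool), pred):
        if not ppi:
            group = NO_PPI
        elif pos:
            group = PPI_DYSBIOSIS
        else:
            group = PPI_NO_DYSBIOSIS
        out.append(DysbiosisLabel(sample_id=str(sid), taxon_id=model.taxon_id,
                                  group=group))
    return out


@dataclass
class CascadeResult:
    candidates: list[CandidateBiomarker]
    models: list[BiomarkerModel]          # calibrated + gated, one per candidate
    screen: pd.DataFrame                  # taxon_id, U, p_raw, q_bh, rf_importance


def run_cascade(
    discovery_abund: np.ndarray,
    discovery_labels: Sequence[bool],
    validation_abund: np.ndarray,
    validation_labels: Sequence[bool],
    taxon_ids: Sequence[str],
    literature_taxa: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    top_frac: float = 0.05,
    gate: float = 0.70,
    n_trees: int = 1000,
    n_repeats: int = 10,
    seed: int = 0,
    screening_depth: int | None = None,
) -> CascadeResult:
    """Run screen -> rank -> select -> calibrate -> gate on relative abundances.

    ``discovery_abund`` / ``validation_abund`` are taxa x samples matrices on
    the same taxon set (validation may omit taxa only if ids align).
    """
    ids = list(taxon_ids)
    screen = mann_whitney_screen(discovery_abund, discovery_labels)
    screen.insert(0, "taxon_id", ids)
    screen["q_bh"] = bh_adjust(screen["p_raw"].to_numpy())
    imp = rf_rank(discovery_abund, discovery_labels, n_trees=n_trees,
                  n_repeats=n_repeats, seed=seed)
    screen["rf_importance"] = imp
    candidates = select_candidates(
        ids, screen["p_raw"], screen["q_bh"], imp,
        literature_taxa=literature_taxa, alpha=alpha, top_frac=top_frac,
    )
    models = []
    for cand in candidates:
        if cand.taxon_id not in ids:
            continue
        i = ids.index(cand.taxon_id)
        model = youden_calibrate(
            discovery_abund[i], discovery_labels, taxon_id=cand.taxon_id,
            screening_depth=screening_depth,
        )
        if model.auroc_p >= alpha:
            # AUROC not significant: taxon cannot allocate patients; skip gate
            models.append(replace(model, passed_gate=False))
            continue
        model = validate_gate(model, validation_abund[i], validation_labels,
                              gate=gate)
        models.append(model)
    return CascadeResult(candidates=candidates, models=models, screen=screen)
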