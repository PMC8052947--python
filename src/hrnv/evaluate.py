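"""Cross-validated model evaluation: ROC/AUC with DeLong CIs, operating points,
calibration curves, and the full model comparison (stepwise LR, eight
dimensionality-reduction models at their sweep-optimal dimension, and the
HEART/TIMI/GRACE clinical scores used directly as ranking scores), with and
without the cardiac-troponin candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .dimreduce import METHODS, best_dimension, dimension_sweep, reduced_cv_probs
from .model import derive_seed
from .preselect import DEFAULT_GRID, backward_stepwise, threshold_sweep

__all__ = [
    "crossval_predict",
    "roc_auc_ci",
    "delong_variance",
    "operating_point",
    "calibration_curve",
    "compare_models",
    "EvaluationReport",
    "EvalConfig",
    "reports_to_table",
]

SCORE_COLUMNS = ("heart", "timi", "grace")


# ---------------------------------------------------------------------------
# Out-of-fold predictions
# ---------------------------------------------------------------------------

def crossval_predict(X, y, folds: int = 5, seed: int = 0,
                     method: str | None = None, d: int | None = None) -> np.ndarray:
    """One out-of-fold probability per patient from stratified K-fold LR.

    Optionally inserts a dimensionality-reduction step (fit inside each
    training fold) before the logistic fit.
    """
    probs = reduced_cv_probs(X, y, method, d, folds=folds, seed=seed)
    if not np.all(np.isfinite(probs)):
        raise RuntimeError("cross-validation left some patients unpredicted")
    return probs


# ---------------------------------------------------------------------------
# AUC with DeLong confidence interval
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(probs, y) -> tuple[float, float]:
    """(AUC, variance of AUC) by DeLong's structural-components method."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    pos, neg = probs[y == 1], probs[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes are required for ROC analysis")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n           # structural components, positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m     # structural components, negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc_ci(probs, y, alpha: float = 0.05) -> dict[str, float]:
    """AUC with a DeLong 95% confidence interval (clipped to [0, 1])."""
    auc, var = delong_variance(probs, y)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return {"auc": auc, "ci_low": max(0.0, auc - half), "ci_high": min(1.0, auc + half)}


# ---------------------------------------------------------------------------
# Operating point and calibration
# ---------------------------------------------------------------------------

def _wald_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half) * 100, min(1.0, p + half) * 100)


def operating_point(probs, y) -> dict:
    """Cut-off nearest the ROC upper-left corner and its confusion metrics.

    Ties in corner distance are broken toward higher sensitivity.  Metrics are
    percentages with Wald 95% CIs; the confusion counts are included so every
    figure can be recomputed.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    fpr, tpr, thr = roc_curve(y, probs)
    dist2 = fpr**2 + (1 - tpr) ** 2
    best = np.lexsort((-tpr, dist2))[0]
    cutoff = float(thr[best])
    pred = probs >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    out = {"cutoff": cutoff, "tp": tp, "fp": fp, "fn": fn, "tn": tn}
    for key, k, n in (("sensitivity", tp, tp + fn), ("specificity", tn, tn + fp),
                      ("ppv", tp, tp + fp), ("npv", tn, tn + fn)):
        out[key] = 100.0 * k / n if n else np.nan
        out[f"{key}_ci"] = _wald_ci(k, n)
    return out


def calibration_curve(probs, y, bins: int = 10) -> pd.DataFrame:
    """Equal-width probability bins: mean predicted vs observed event fraction.

    Empty bins are omitted; bin counts sum to the number of patients.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({"bin": b, "mean_predicted": float(probs[sel].mean()),
                     "observed_fraction": float(y[sel].mean()),
                     "count": int(sel.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full model comparison
# ---------------------------------------------------------------------------

@dataclass
class EvalConfig:
    grid: Sequence[float] = DEFAULT_GRID
    methods: Sequence[str] = METHODS
    d_range: Sequence[int] = (2, 4, 8, 15, 22, 30)
    folds: int = 5
    seed: int = 0
    troponin_included: bool = True
    troponin_column: str = "troponin"
    outcome: str = "mace"
    calibration_bins: int = 10


@dataclass
class EvaluationReport:
    name: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    metrics: dict
    roc: pd.DataFrame = field(repr=False)
    calibration: pd.DataFrame = field(repr=False)
    troponin_included: bool = True
    d: int | None = None
    extra: dict = field(default_factory=dict, repr=False)


def _report(name: str, probs: np.ndarray, y: np.ndarray, cfg: EvalConfig,
            cal_probs: np.ndarray | None = None, d: int | None = None,
            **extra) -> EvaluationReport:
    ci = roc_auc_ci(probs, y)
    op = operating_point(probs, y)
    fpr, tpr, thr = roc_curve(y, probs)
    roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    cal = calibration_curve(cal_probs if cal_probs is not None else probs, y,
                            bins=cfg.calibration_bins)
    return EvaluationReport(
        name=name, auc=ci["auc"], ci_low=ci["ci_low"], ci_high=ci["ci_high"],
        cutoff=op["cutoff"], metrics=op, roc=roc_df, calibration=cal,
        troponin_included=cfg.troponin_included, d=d, extra=extra,
    )


def compare_models(cohort: pd.DataFrame, candidates: list[str],
                   cfg: EvalConfig) -> list[EvaluationReport]:
    """Evaluate stepwise LR, the eight reduction models, and the clinical scores.

    ``candidates`` are the candidate predictor columns; the troponin column is
    removed from them when ``cfg.troponin_included`` is False (the clinical
    scores are left untouched in both variants).  Reduction models are
    evaluated at their dimension-sweep optimum.
    """
    y = np.asarray(cohort[cfg.outcome], dtype=int)
    cand = [c for c in candidates if cfg.troponin_included
            or c != cfg.troponin_column]

    reports: list[EvaluationReport] = []

    # (a) backward stepwise comparator
    step = backward_stepwise(cohort, entry_p=0.2, stay_p=0.05,
                             outcome=cfg.outcome, candidates=cand)
    step_vars = step.variables
    if step_vars:
        probs = crossval_predict(cohort[step_vars], y, folds=cfg.folds,
                                 seed=derive_seed(cfg.seed, 1))
        reports.append(_report("stepwise", probs, y, cfg, variables=step_vars))

    # (b) preselection + dimensionality reduction at the sweep-optimal d
    presel = threshold_sweep(cohort, grid=cfg.grid, folds=cfg.folds,
                             seed=derive_seed(cfg.seed, 2),
                             outcome=cfg.outcome, candidates=cand)
    X = cohort[presel.retained]
    d_range = sorted({min(int(d), presel.d_tilde) for d in cfg.d_range})
    sweeps = {}
    for i, method in enumerate(cfg.methods):
        mseed = derive_seed(cfg.seed, 3, i)
        sweep = dimension_sweep(method, X, y, d_range, folds=cfg.folds, seed=mseed)
        d_best = best_dimension(sweep)
        probs = crossval_predict(X, y, folds=cfg.folds, seed=mseed,
                                 method=method, d=d_best)
        reports.append(_report(method, probs, y, cfg, d=d_best,
                               preselection_threshold=presel.threshold,
                               n_retained=presel.d_tilde))
        sweeps[method] = sweep

    # (c) clinical scores as ranking scores (integer cut-offs, no refit)
    for score in SCORE_COLUMNS:
        if score not in cohort.columns:
            import warnings
            warnings.warn(f"score column {score!r} missing; skipped")
            continue
        s = np.asarray(cohort[score], dtype=float)
        span = s.max() - s.min()
        cal = (s - s.min()) / span if span > 0 else np.full_like(s, 0.5)
        reports.append(_report(score, s, y, cfg, cal_probs=cal))

    for rep in reports:
        rep.extra.setdefault("sweep", sweeps.get(rep.name))
        rep.extra["preselection"] = {"threshold": presel.threshold,
                                     "n_retained": presel.d_tilde}
    return reports


def reports_to_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Flatten reports into an operating-point comparison table (CSV-ready)."""
    rows = []
    for r in reports:
        m = r.metrics
        rows.append({
            "model": r.name, "d": r.d, "auc": round(r.auc, 3),
            "auc_ci_low": round(r.ci_low, 3), "auc_ci_high": round(r.ci_high, 3),
            "cutoff": r.cutoff,
            "sensitivity": round(m["sensitivity"], 1),
            "sensitivity_ci_low": round(m["sensitivity_ci"][0], 1),
            "sensitivity_ci_high": round(m["sensitivity_ci"][1], 1),
            "specificity": round(m["specificity"], 1),
            "specificity_ci_low": round(m["specificity_ci"][0], 1),
            "specificity_ci_high": round(m["specificity_ci"][1], 1),
            "ppv": round(m["ppv"], 1),
            "ppv_ci_low": round(m["ppv_ci"][0], 1),
            "ppv_ci_high": round(m["ppv_ci"][1], 1),
            "npv": round(m["npv"], 1),
            "npv_ci_low": round(m["npv_ci"][0], 1),
            "npv_ci_high": round(m["npv_ci"][1], 1),
            "troponin_included": r.troponin_included,
        })
    return pd.DataFrame(rows)
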