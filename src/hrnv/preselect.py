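"""Univariable screening, cross-validated threshold selection, and stepwise comparator.

Candidate variables are screened one at a time against the binary 30-day
MACE outcome: continuous variables with Welch's two-sample t-test, binary
variables with the Yates-corrected chi-square test on the 2x2 table.  The
screening threshold P~ is then chosen by sweeping a grid of thresholds and
scoring each retained variable set with full-rank PCA + unpenalized logistic
regression under stratified 5-fold cross-validation, keeping the threshold
with the best pooled out-of-fold AUC (ties favour the larger threshold).

The comparator model is classical backward stepwise logistic regression:
candidates enter at univariable p < 0.2 and are removed one at a time
(largest Wald p first) until every remaining variable has p <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from sklearn.metrics import roc_auc_score

from .model import ColumnStandardizer
from .dimreduce import reduced_cv_probs

__all__ = [
    "univariable_pvalues",
    "threshold_sweep",
    "backward_stepwise",
    "PreselectionResult",
    "StepwiseResult",
]

DEFAULT_GRID = (1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005, 0.001)


def _is_binary(col: pd.Series) -> bool:
    return col.dropna().nunique() <= 2


def univariable_pvalues(cohort: pd.DataFrame, outcome: str = "mace",
                        candidates: list[str] | None = None) -> pd.DataFrame:
    """Per-variable association test against the outcome.

    Returns a DataFrame with columns (name, test, statistic, p_value).
    Zero-variance variables get p = 1.0 with a warning.
    """
    y = np.asarray(cohort[outcome], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if candidates is None:
        candidates = [c for c in cohort.columns if c != outcome]
    rows = []
    for name in candidates:
        col = cohort[name]
        x = np.asarray(col, dtype=float)
        valid = np.isfinite(x)
        xv, yv = x[valid], y[valid]
        if np.nanstd(xv) == 0 or len(np.unique(xv)) < 2:
            warnings.warn(f"variable {name!r} has zero variance; p set to 1.0")
            rows.append({"name": name, "test": "none", "statistic": np.nan,
                         "p_value": 1.0})
            continue
        if _is_binary(col):
            tab = pd.crosstab(xv, yv).to_numpy()
            try:
                res = stats.chi2_contingency(tab, correction=True)
                stat, p = float(res[0]), float(res[1])
            except ValueError:
                stat, p = np.nan, 1.0
            rows.append({"name": name, "test": "chi_square", "statistic": stat,
                         "p_value": p})
        else:
            t, p = stats.ttest_ind(xv[yv == 1], xv[yv == 0], equal_var=False)
            rows.append({"name": name, "test": "t_test", "statistic": float(t),
                         "p_value": float(p)})
    return pd.DataFrame(rows)


@dataclass
class PreselectionResult:
    threshold: float
    retained: list[str]
    curve: pd.DataFrame  # columns: threshold, cv_auc, n_retained
    pvalues: pd.DataFrame

    @property
    def d_tilde(self) -> int:
        return len(self.retained)


def threshold_sweep(cohort: pd.DataFrame, grid=DEFAULT_GRID, folds: int = 5,
                    seed: int = 0, outcome: str = "mace",
                    candidates: list[str] | None = None) -> PreselectionResult:
    """Choose the screening threshold by the cross-validated PCA + LR sweep.

    For each threshold the variables with p < threshold are retained,
    standardized, rotated by full-rank PCA and scored with pooled out-of-fold
    logistic-regression AUC.  The returned threshold maximises that AUC; at
    ties the larger threshold (more variables) wins.
    """
    report = univariable_pvalues(cohort, outcome=outcome, candidates=candidates)
    y = np.asarray(cohort[outcome], dtype=int)
    pv = report.set_index("name")["p_value"]
    grid = sorted(set(float(g) for g in grid), reverse=True)

    def retained_at(thr: float) -> list[str]:
        # a threshold of 1.0 means no screening at all (p can be exactly 1.0
        # for sparse contingency tables, which strict p < 1 would exclude)
        if thr >= 1.0:
            return list(pv.index)
        return list(pv.index[pv < thr])

    rows = []
    for thr in grid:
        names = retained_at(thr)
        if len(names) < 2:
            rows.append({"threshold": thr, "cv_auc": np.nan,
                         "n_retained": len(names)})
            continue
        X = cohort[names]
        d = min(len(names), len(y) - int(np.ceil(len(y) / folds)))
        probs = reduced_cv_probs(X, y, "pca", d, folds=folds, seed=seed)
        rows.append({"threshold": thr, "cv_auc": float(roc_auc_score(y, probs)),
                     "n_retained": len(names)})
    curve = pd.DataFrame(rows)
    valid = curve.dropna(subset=["cv_auc"])
    if valid.empty:
        raise ValueError("no threshold on the grid retained >= 2 variables")
    best_auc = valid["cv_auc"].max()
    # ties -> larger threshold (grid is sorted descending)
    best_thr = float(valid.loc[valid["cv_auc"] >= best_auc - 1e-12, "threshold"].max())
    retained = retained_at(best_thr)
    return PreselectionResult(threshold=best_thr, retained=retained,
                              curve=curve, pvalues=report)


@dataclass
class StepwiseResult:
    variables: list[str]
    params: pd.Series = field(default=None)
    pvalues: pd.Series = field(default=None)


def backward_stepwise(cohort: pd.DataFrame, entry_p: float = 0.2,
                      stay_p: float = 0.05, outcome: str = "mace",
                      candidates: list[str] | None = None) -> StepwiseResult:
    """Backward stepwise logistic regression.

    Candidates with univariable p < entry_p enter; the variable with the
    largest Wald p-value is removed until all remaining are <= stay_p.
    Missing predictor values are imputed with the column median before
    fitting.
    """
    uni = univariable_pvalues(cohort, outcome=outcome, candidates=candidates)
    current = list(uni.loc[uni["p_value"] < entry_p, "name"])
    y = np.asarray(cohort[outcome], dtype=int)

    def standardized(names: list[str]) -> np.ndarray:
        X = cohort[names].to_numpy(dtype=float)
        return ColumnStandardizer().fit_transform(X)

    def drop_aliased(names: list[str]) -> list[str]:
        # exact linear aliases (e.g. lf_norm + hf_norm = const across streams)
        # make the information matrix singular; keep a maximal independent set
        Xz = standardized(names)
        _, R, piv = linalg.qr(Xz, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        keep_idx = sorted(piv[i] for i in range(min(len(names), diag.size))
                          if diag[i] > 1e-8 * max(diag[0], 1.0))
        return [names[i] for i in keep_idx]

    def fit(names: list[str]):
        design = sm.add_constant(
            pd.DataFrame(standardized(names), columns=names), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # IRLS tolerates near-singular information matrices (inflated SEs
            # simply push the offending variables out first)
            return sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)

    def most_dependent(names: list[str]) -> str:
        _, _, piv = linalg.qr(standardized(names), mode="economic", pivoting=True)
        return names[piv[-1]]

    current = drop_aliased(current)
    res = None
    retries = 0
    while current:
        try:
            res = fit(current)
        except Exception as exc:  # singular Hessian / separation
            retries += 1
            if len(current) <= 1 or retries > len(current) + 5:
                raise RuntimeError(
                    f"logistic fit failed for variable set {current}: {exc}"
                ) from exc
            current = [v for v in current if v != most_dependent(current)]
            res = None
            continue
        wald = res.pvalues.drop("const")
        worst = wald.idxmax()
        if wald[worst] <= stay_p:
            break
        current = [v for v in current if v != worst]
        res = None
    if not current:
        return StepwiseResult(variables=[], params=None, pvalues=None)
    if res is None:
        res = fit(current)
    return StepwiseResult(variables=current, params=res.params,
                          pvalues=res.pvalues)
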