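"""Eight unsupervised dimensionality-reduction methods behind one fit/transform contract.

Methods: PCA, kernel PCA (polynomial kernel), latent semantic analysis (LSA,
truncated SVD of the uncentred matrix), Gaussian and sparse random projection,
metric multidimensional scaling (MDS), Isomap, and locally linear embedding
(LLE).  All are label-blind: fitting uses only the feature matrix.

Out-of-sample handling: PCA/KPCA/LSA/GRP/SRP are parametric maps; Isomap and
LLE use scikit-learn's kernel/reconstruction-weight extensions; MDS places new
points by per-point stress majorization against the frozen training embedding,
so cross-validation folds never leak.

The dimension sweep evaluates, for each target dimension d, pooled
out-of-fold logistic-regression predictions under stratified K-fold CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.decomposition import PCA, KernelPCA
from sklearn.manifold import Isomap, LocallyLinearEmbedding
from sklearn.metrics import roc_auc_score
from sklearn.random_projection import GaussianRandomProjection, SparseRandomProjection

from .model import ColumnStandardizer, make_logistic, stratified_folds

__all__ = [
    "METHODS",
    "Reducer",
    "fit_reducer",
    "transform",
    "dimension_sweep",
    "reduced_cv_probs",
]

METHODS: tuple[str, ...] = ("pca", "kpca", "lsa", "grp", "srp", "mds", "isomap", "lle")


# ---------------------------------------------------------------------------
# Metric MDS with an explicit out-of-sample extension
# ---------------------------------------------------------------------------

class _MetricMDS:
    """SMACOF metric MDS initialised from the classical (Torgerson) solution.

    The classical initialisation makes the fit deterministic; majorization
    iterations then minimise raw stress against the Euclidean dissimilarities
    of the training matrix.
    """

    def __init__(self, d: int, max_iter: int = 150, tol: float = 1e-7):
        self.d = d
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _classical(D: np.ndarray, d: int) -> np.ndarray:
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1][:d]
        lam = np.clip(w[order], 0.0, None)
        return V[:, order] * np.sqrt(lam)

    @staticmethod
    def _guttman(D: np.ndarray, Z: np.ndarray) -> np.ndarray:
        n = D.shape[0]
        E = cdist(Z, Z)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(E > 0, D / E, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        return B @ Z / n

    def fit(self, X: np.ndarray) -> "_MetricMDS":
        self.X_train_ = np.asarray(X, dtype=float)
        D = cdist(self.X_train_, self.X_train_)
        Z = self._classical(D, self.d)
        stress = np.sum((cdist(Z, Z) - D) ** 2) / 2
        for _ in range(self.max_iter):
            Z = self._guttman(D, Z)
            new_stress = np.sum((cdist(Z, Z) - D) ** 2) / 2
            if stress - new_stress <= self.tol * max(stress, 1.0):
                stress = new_stress
                break
            stress = new_stress
        self.embedding_ = Z
        self.stress_ = float(stress)
        return self

    def transform(self, X_new: np.ndarray, n_iter: int = 150) -> np.ndarray:
        """Per-point stress minimisation against the fixed training embedding."""
        delta = cdist(np.asarray(X_new, dtype=float), self.X_train_)
        Z = self.embedding_
        # start at the mean embedding of the nearest training points
        k = min(10, Z.shape[0])
        out = Z[np.argsort(delta, axis=1)[:, :k]].mean(axis=1)
        n = Z.shape[0]
        for _ in range(n_iter):
            E = cdist(out, Z)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(E > 0, delta / E, 0.0)
            out = (ratio[:, :, None] * (out[:, None, :] - Z[None, :, :])).sum(axis=1)
            out = (out + Z.sum(axis=0)[None, :]) / n
        return out


class _LSA:
    """Truncated SVD of the (uncentred) matrix; transform = projection on V_d."""

    def __init__(self, d: int):
        self.d = d

    def fit(self, X: np.ndarray) -> "_LSA":
        _, _, Vt = np.linalg.svd(np.asarray(X, dtype=float), full_matrices=False)
        self.components_ = Vt[: self.d]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.components_.T


@dataclass
class Reducer:
    """A fitted dimensionality-reduction transform to d dimensions."""

    method: str
    d: int
    seed: int
    n_features_in_: int
    _backend: object
    _X_fit: np.ndarray = None

    def transform(self, X_new) -> np.ndarray:
        return transform(self, X_new)

    @property
    def training_embedding_(self) -> np.ndarray:
        """Embedding of the training matrix as fitted (no re-projection)."""
        be = self._backend
        if hasattr(be, "embedding_"):  # mds, isomap, lle
            return np.asarray(be.embedding_, dtype=float)
        return np.asarray(be.transform(self._X_fit), dtype=float)


def fit_reducer(method: str, d: int, X_train, seed: int = 0) -> Reducer:
    """Fit one of the eight reduction methods on a (standardized) training matrix.

    ``X_train`` is expected column-standardized (scale-only for ``lsa``); the
    fit never sees outcome labels.
    """
    X = np.asarray(X_train, dtype=float)
    n, D = X.shape
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if not 1 <= d <= min(n, D):
        raise ValueError(f"target dimension d={d} outside [1, min(n={n}, D={D})]")
    seed = int(seed)
    if method == "pca":
        backend = PCA(n_components=d, svd_solver="full", random_state=seed).fit(X)
    elif method == "kpca":
        # kernel scale 1/(degree * D) keeps the polynomial expansion in its
        # near-linear regime for z-scored features; the cubic term then acts
        # as a perturbation rather than dominating the embedding
        backend = KernelPCA(n_components=d, kernel="poly", degree=3,
                            gamma=1.0 / (3 * D), random_state=seed).fit(X)
    elif method == "lsa":
        backend = _LSA(d).fit(X)
    elif method == "grp":
        backend = GaussianRandomProjection(n_components=d, random_state=seed).fit(X)
    elif method == "srp":
        backend = SparseRandomProjection(n_components=d, random_state=seed,
                                         dense_output=True).fit(X)
    elif method == "mds":
        backend = _MetricMDS(d).fit(X)
    elif method == "isomap":
        # neighborhood must grow with n for consistent geodesic estimates
        k = max(10, min(n // 10, n - 1))
        backend = Isomap(n_components=d, n_neighbors=k).fit(X)
    else:  # lle
        k = min(max(d + 2, 10, n // 10), n - 1)
        variant = "modified" if k > d else "standard"
        backend = LocallyLinearEmbedding(n_components=d, n_neighbors=k,
                                         method=variant,
                                         random_state=seed).fit(X)
    return Reducer(method=method, d=d, seed=seed, n_features_in_=D,
                   _backend=backend, _X_fit=X)


def transform(reducer: Reducer, X_new) -> np.ndarray:
    """Embed new rows with a fitted reducer; output has exactly d columns."""
    X = np.asarray(X_new, dtype=float)
    if X.ndim != 2 or X.shape[1] != reducer.n_features_in_:
        raise ValueError(
            f"expected {reducer.n_features_in_} columns, got shape {X.shape}"
        )
    Z = reducer._backend.transform(X)
    return np.asarray(Z, dtype=float)


# ---------------------------------------------------------------------------
# Cross-validated dimension sweep
# ---------------------------------------------------------------------------

def reduced_cv_probs(X, y, method: str | None, d: int | None,
                     folds: int = 5, seed: int = 0) -> np.ndarray:
    """Pooled out-of-fold logistic-regression probabilities.

    Within each stratified fold: standardize on the training part (scale-only
    for lsa), optionally fit/apply the reducer, fit unpenalized logistic
    regression, and predict the held-out part.  ``method=None`` skips the
    reduction step (plain LR on the standardized features).
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=int)
    probs = np.full(len(ya), np.nan)
    mode = "scale" if method == "lsa" else "zscore"
    for tr, te in stratified_folds(ya, folds, seed):
        std = ColumnStandardizer(mode=mode).fit(Xa[tr])
        Ztr, Zte = std.transform(Xa[tr]), std.transform(Xa[te])
        if method is not None:
            red = fit_reducer(method, int(d), Ztr, seed=seed)
            # training rows keep their fitted embedding; only held-out rows
            # go through the out-of-sample extension
            Ztr, Zte = red.training_embedding_, transform(red, Zte)
        with warnings.catch_warnings():
            # separable training folds legitimately stop at the iteration cap
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = make_logistic().fit(Ztr, ya[tr])
        probs[te] = clf.predict_proba(Zte)[:, 1]
    return probs


def dimension_sweep(method: str, X, y, d_range: Sequence[int],
                    folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """AUC of pooled out-of-fold predictions as a function of target dimension.

    Returns a DataFrame with columns (method, d, auc), one row per d.  The
    best dimension is the smallest d attaining the maximum AUC.
    """
    ya = np.asarray(y, dtype=int)
    rows = []
    for d in d_range:
        probs = reduced_cv_probs(X, ya, method, int(d), folds=folds, seed=seed)
        rows.append({"method": method, "d": int(d),
                     "auc": float(roc_auc_score(ya, probs))})
    return pd.DataFrame(rows)


def best_dimension(sweep: pd.DataFrame) -> int:
    """Smallest dimension attaining the maximum sweep AUC."""
    best = sweep["auc"].max()
    return int(sweep.loc[sweep["auc"] >= best - 1e-12, "d"].min())
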