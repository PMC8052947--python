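"""Shared estimator plumbing: standardization, folds, logistic regression, seeds.

Everything downstream of feature extraction runs through these helpers so
that preprocessing is learned strictly on training folds (no leakage) and
every source of randomness is a function of one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ColumnStandardizer",
    "make_logistic",
    "stratified_folds",
    "derive_seed",
]


def derive_seed(seed: int, *keys: int) -> int:
    """Derive an independent sub-seed (< 2^31) from a root seed and a key path.

    Uses numpy's SeedSequence spawning so stages and patients get streams that
    are independent of each other yet fully determined by the root seed.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ColumnStandardizer:
    """Per-column z-scoring with training-median imputation of missing values.

    ``mode='zscore'`` subtracts the training mean and divides by the training
    standard deviation; ``mode='scale'`` divides by the standard deviation only
    (used for latent-semantic analysis, which operates on uncentred data).
    Zero-variance columns are passed through unscaled.
    """

    mode: str = "zscore"
    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)
    median_: np.ndarray = field(default=None, repr=False)

    def fit(self, X) -> "ColumnStandardizer":
        A = np.asarray(X, dtype=float)
        self.median_ = np.nanmedian(A, axis=0)
        self.median_ = np.where(np.isfinite(self.median_), self.median_, 0.0)
        A = self._impute(A)
        self.mean_ = A.mean(axis=0)
        sd = A.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def _impute(self, A: np.ndarray) -> np.ndarray:
        mask = ~np.isfinite(A)
        if mask.any():
            A = A.copy()
            A[mask] = np.broadcast_to(self.median_, A.shape)[mask]
        return A

    def transform(self, X) -> np.ndarray:
        A = self._impute(np.asarray(X, dtype=float))
        if self.mode == "zscore":
            return (A - self.mean_) / self.scale_
        if self.mode == "scale":
            return A / self.scale_
        raise ValueError(f"unknown standardization mode {self.mode!r}")

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


def make_logistic() -> LogisticRegression:
    """Unpenalized maximum-likelihood logistic regression.

    Tight tolerances so that rank-preserving linear reparameterisations of the
    design (e.g. full-rank PCA) leave fitted probabilities unchanged to ~1e-8.
    """
    return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)


def stratified_folds(y, n_splits: int = 5, seed: int = 0):
    """Shuffled stratified K-fold assignment, reproducible from the seed."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed))
    return list(skf.split(np.zeros_like(y), y))
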