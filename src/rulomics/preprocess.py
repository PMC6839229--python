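"""Gene filtering, top-n selection and discretization.

Rule mining needs a binary "molecular event" matrix, so a continuous
expression or methylation matrix is binarized per gene across samples.
Five simple, individually testable binarization rules are provided:

``zscore``
    1 iff the per-gene z-score exceeds ``threshold`` in the requested
    direction (``both`` compares ``|z|``).  Default: 1.96, two-sided.
``quantile``
    1 iff the value lies strictly below the ``q``-th or strictly above the
    ``(1-q)``-th empirical quantile of that gene (``threshold`` = q).
``top_fraction``
    1 for the samples whose absolute deviation from the gene's median is
    among the ``ceil(f*m)`` largest (``threshold`` = f); ``up``/``down``
    keep only the positive/negative side of that selection.
``mean_sd``
    1 iff the value deviates from the gene mean by more than
    ``threshold`` standard deviations.
``fixed``
    1 iff the raw value exceeds ``threshold`` (``up``), falls below
    ``-threshold`` (``down``), or exceeds ``threshold`` in absolute
    value (``both``).

All rules act column-by-column, so permuting genes commutes with
discretization, and the ``up`` and ``down`` calls OR together to the
``both`` call.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import MatrixError, validate_matrix

__all__ = [
    "Discretizer",
    "discretize",
    "drop_missing_genes",
    "select_top_genes",
    "METHODS",
    "DIRECTIONS",
]

METHODS = ("zscore", "quantile", "top_fraction", "mean_sd", "fixed")
DIRECTIONS = ("both", "up", "down")


def drop_missing_genes(M: pd.DataFrame) -> pd.DataFrame:
    """Remove genes (columns) that have any missing value."""
    validate_matrix(M)
    keep = ~M.isna().any(axis=0)
    if not keep.any():
        raise MatrixError(
            f"all {M.shape[1]} genes contain missing values; nothing left to mine"
        )
    return M.loc[:, keep]


def select_top_genes(
    M: pd.DataFrame, n_top: int, ranking: dict | pd.Series | None = None
) -> pd.DataFrame:
    """Keep the ``n_top`` highest-scoring genes, ordered by descending score.

    Without an explicit ``ranking`` (gene -> score), per-gene variance
    across samples is used — a neutral stand-in when no differential
    statistic is available.  Ties break lexicographically on gene ID.
    """
    validate_matrix(M)
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    if ranking is None:
        scores = M.var(axis=0, ddof=1)
    else:
        scores = pd.Series(ranking, dtype=float)
        missing = [g for g in M.columns if g not in scores.index]
        if missing:
            raise KeyError(f"ranking lacks scores for genes: {missing[:5]}")
        scores = scores.loc[M.columns]
    order = sorted(M.columns, key=lambda g: (-scores[g], str(g)))
    return M.loc[:, order[: min(n_top, M.shape[1])]]


class Discretizer(BaseEstimator, TransformerMixin):
    """Binarize a continuous matrix gene-by-gene.

    scikit-learn transformer: ``fit`` learns per-gene statistics (mean,
    SD, quantile cuts, deviation cutoffs), ``transform`` applies the
    chosen rule.  DataFrame in, DataFrame out (labels preserved); plain
    arrays are also accepted.

    Parameters
    ----------
    method : one of METHODS
    threshold : float
        Positive for ``zscore``/``mean_sd``/``fixed``; a fraction in
        (0, 0.5] for ``quantile``/``top_fraction``.
    direction : {'both', 'up', 'down'}
    """

    def __init__(
        self,
        method: str = "zscore",
        threshold: float = 1.96,
        direction: str = "both",
    ):
        self.method = method
        self.threshold = threshold
        self.direction = direction

    # -- validation -------------------------------------------------
    def _validate_params(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        t = self.threshold
        if self.method in ("zscore", "mean_sd") and not t > 0:
            raise ValueError(f"{self.method} threshold must be positive, got {t}")
        if self.method in ("quantile", "top_fraction") and not 0 < t <= 0.5:
            raise ValueError(f"{self.method} threshold must be in (0, 0.5], got {t}")

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return validate_matrix(X, allow_missing=False)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        return pd.DataFrame(
            X,
            index=[f"s{i}" for i in range(X.shape[0])],
            columns=[f"g{j}" for j in range(X.shape[1])],
        )

    # -- estimator API ----------------------------------------------
    def fit(self, X, y=None) -> "Discretizer":
        self._validate_params()
        M = self._as_frame(X)
        self.feature_names_in_ = np.asarray(M.columns, dtype=object)
        self.n_features_in_ = M.shape[1]
        V = M.to_numpy(dtype=float)
        self.mean_ = V.mean(axis=0)
        self.sd_ = V.std(axis=0, ddof=1) if V.shape[0] > 1 else np.zeros(V.shape[1])
        self.median_ = np.median(V, axis=0)
        if self.method == "quantile":
            q = self.threshold
            self.lower_cut_ = np.quantile(V, q, axis=0)
            self.upper_cut_ = np.quantile(V, 1 - q, axis=0)
        if self.method == "top_fraction":
            k = int(np.ceil(self.threshold * V.shape[0]))
            # cutoff = k-th largest |deviation|; transform marks dev >= cutoff,
            # direction then restricts the selected set by sign
            self.k_ = k
            self.dev_cutoff_ = np.sort(np.abs(V - self.median_), axis=0)[::-1][k - 1]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise AttributeError("Discretizer is not fitted yet")
        M = self._as_frame(X)
        V = M.to_numpy(dtype=float)
        t, direction = self.threshold, self.direction

        if self.method in ("zscore", "mean_sd"):
            sd = self.sd_.copy()
            dead = sd == 0
            if dead.any():
                warnings.warn(
                    f"{int(dead.sum())} constant gene(s) cannot be z-scored; "
                    "their columns are all 0",
                    UserWarning,
                    stacklevel=2,
                )
                sd[dead] = np.inf
            z = (V - self.mean_) / sd
            if self.direction == "both":
                B = np.abs(z) > t
            else:
                B = self._combine(z > t, z < -t)
        elif self.method == "quantile":
            B = self._combine(V > self.upper_cut_, V < self.lower_cut_)
        elif self.method == "top_fraction":
            d = V - self.median_
            sel = np.abs(d) >= self.dev_cutoff_
            B = self._combine(sel & (d > 0), sel & (d < 0))
            if self.direction == "both":
                B = sel
        else:  # fixed: symmetric raw-value cut, so up OR down == both
            B = self._combine(V > t, V < -t)
        return pd.DataFrame(B.astype(int), index=M.index, columns=M.columns)

    def _combine(self, up: np.ndarray, down: np.ndarray) -> np.ndarray:
        if self.direction == "up":
            return up
        if self.direction == "down":
            return down
        return up | down

    def get_feature_names_out(self, input_features=None):
        return self.feature_names_in_


def discretize(
    M: pd.DataFrame,
    method: str = "zscore",
    threshold: float = 1.96,
    direction: str = "both",
) -> pd.DataFrame:
    """Fit-and-apply a :class:`Discretizer` on the same matrix."""
    return Discretizer(method, threshold, direction).fit(M).transform(M)
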