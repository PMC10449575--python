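"""Cross-case indicator analytics: Pearson significance matrix and Kaiser PCA.

Input is an *index matrix*: case studies (farms) as rows, indicator
indices (impact or performance utilities) as columns.  Correlations are
pairwise-complete Pearson r with two-sided t-test p-values and a
significance flag at a configurable alpha (0.05 by default, no
multiple-testing correction -- surfaced in the output metadata).  PCA is
performed on the correlation matrix (columns standardized) and components
are retained by the Kaiser criterion: eigenvalue strictly greater than 1,
ties at exactly 1.0 excluded.  Per-component variance fraction is
eigenvalue / number of columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "KaiserPCA",
    "PearsonMatrixResult",
    "index_matrix",
    "pca_kaiser",
    "pearson_matrix",
]


def index_matrix(results: pd.DataFrame, kind: str = "impact") -> pd.DataFrame:
    """Pivot a long scored-results table into a case x indicator index matrix.

    ``results`` is the table produced by scoring (one row per farm and
    indicator, e.g. ``ApoiaScorer.transform`` output or a concatenation of
    per-farm results tables); rows of the output are farms, columns are
    indicators, values are the requested utilities. Missing entries stay NaN.
    """
    col = {"impact": "utility_impact", "performance": "utility_performance"}[kind]
    return results.pivot(index="farm_id", columns="indicator_id", values=col)


@dataclass
class PearsonMatrixResult:
    """Pairwise Pearson correlations with significance flags.

    ``r``, ``r2``, ``p`` and ``significant`` are square DataFrames indexed
    by column name; undefined cells (constant columns, fewer than 3
    pairwise-complete observations) are NaN and listed in ``flags``.
    """

    r: pd.DataFrame
    r2: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n_obs: pd.DataFrame
    flags: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def pearson_matrix(m: pd.DataFrame, alpha: float = 0.05) -> PearsonMatrixResult:
    """Pairwise-complete Pearson correlation matrix with two-sided p-values.

    Each pair needs at least 3 complete observations; a constant column
    within the pairwise-complete subset leaves r undefined (NaN, flagged).
    """
    if m.columns.duplicated().any():
        raise ValueError("index matrix column names must be unique")
    cols = list(m.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n_obs = np.zeros((k, k), dtype=int)
    flags: list[str] = []
    values = m.to_numpy(dtype=float)
    for i in range(k):
        for j in range(i, k):
            pair = values[:, [i, j]]
            ok = ~np.isnan(pair).any(axis=1)
            x, y = pair[ok, 0], pair[ok, 1]
            n = int(ok.sum())
            n_obs[i, j] = n_obs[j, i] = n
            if n < 3:
                flags.append(f"{cols[i]}~{cols[j]}: only {n} pairwise-complete observations")
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                flags.append(f"{cols[i]}~{cols[j]}: constant column, r undefined")
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df < alpha) & r_df.notna()
    return PearsonMatrixResult(
        r=r_df,
        r2=r_df**2,
        p=p_df,
        significant=sig,
        alpha=alpha,
        n_obs=pd.DataFrame(n_obs, index=cols, columns=cols),
        flags=flags,
        metadata={"multiple_testing_correction": "none"},
    )


class KaiserPCA(BaseEstimator, TransformerMixin):
    """PCA on the correlation matrix with Kaiser-criterion retention.

    Columns are standardized (zero mean, unit sample variance), so the
    decomposition is an eigendecomposition of the Pearson correlation
    matrix; eigenvalues sum to the number of columns.  Components with
    eigenvalue strictly greater than 1 are retained.

    Parameters
    ----------
    missing : {"error", "mean"}
        How to handle NaNs: refuse, or mean-impute per column (flagged in
        ``flags_``).

    Attributes
    ----------
    eigenvalues_ : all eigenvalues, descending.
    loadings_ : (n_features, n_components_) eigenvectors of retained components.
    n_components_ : number retained by the Kaiser criterion.
    explained_variance_ratio_ : eigenvalue / n_features per retained component.
    """

    def __init__(self, missing: str = "error"):
        self.missing = missing

    def fit(self, X, y=None) -> "KaiserPCA":
        X = self._validate(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations (rows) for PCA")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 indicator columns for PCA")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            const = np.where(self.scale_ == 0)[0]
            names = [self.feature_names_in_[i] for i in const] if hasattr(self, "feature_names_in_") else list(const)
            raise ValueError(f"constant columns have undefined correlations: {names}")
        Z = (X - self.mean_) / self.scale_
        corr = (Z.T @ Z) / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # eigh can return tiny negative eigenvalues for rank-deficient input
        evals = np.where(np.abs(evals) < 1e-12, 0.0, evals)
        self.eigenvalues_ = evals
        self.n_components_ = int(np.sum(evals > 1.0))  # strict: ties at 1.0 excluded
        self.components_ = evecs[:, : self.n_components_].T
        self.loadings_ = evecs[:, : self.n_components_]
        self.explained_variance_ratio_ = evals[: self.n_components_] / X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "eigenvalues_")
        X = self._validate(X)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.loadings_

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if X.columns.duplicated().any():
                raise ValueError("index matrix column names must be unique")
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            if self.missing == "mean":
                col_means = np.nanmean(X, axis=0)
                idx = np.where(np.isnan(X))
                X = X.copy()
                X[idx] = np.take(col_means, idx[1])
                self.flags_ = ["missing values mean-imputed per column"]
            else:
                raise ValueError(
                    "index matrix contains missing values; use missing='mean' to impute"
                )
        return X


def pca_kaiser(m: pd.DataFrame, missing: str = "error") -> KaiserPCA:
    """Fit :class:`KaiserPCA` on an index matrix and return the fitted model."""
    return KaiserPCA(missing=missing).fit(m)
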