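"""Confounder correction of statin-minus-control expression changes.

The pipeline order is: delta computation, across-sample quantile
normalization, regression on experiment batch, PCA of the between-sample
covariance of the gene-centered matrix, selection of up to 25 leading PCs
(each explaining at least 0.5% of the variance), progressive removal of
PCs 1..k with re-quantile-normalization of the residuals, and PC-covariate
diagnostics.  Leading PCs act as proxies for unmeasured technical
confounders; removing them strips shared structure that would otherwise
corrupt the downstream differential statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DeltaExpression",
    "PCAResult",
    "PCCorrector",
    "compute_delta",
    "quantile_normalize",
    "regress_out_batch",
    "pca_samples",
    "select_n_pcs",
    "remove_pcs",
    "pc_correction_sweep",
    "pc_covariate_diagnostics",
]


@dataclass
class DeltaExpression:
    """Genes x samples matrix of statin-minus-control changes with provenance."""

    values: pd.DataFrame
    quantile_normalized: bool = False
    batch_adjusted: bool = False
    n_pcs_removed: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if not np.isfinite(v.to_numpy()).all():
            raise ValueError("delta matrix contains non-finite values")
        if v.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class PCAResult:
    """Sample-space PCA: scores (samples x components) and variance shares."""

    scores: pd.DataFrame
    variance_explained: np.ndarray


def compute_delta(statin: pd.DataFrame, control: pd.DataFrame) -> DeltaExpression:
    """Statin minus control, aligned to the statin matrix's gene/sample order."""
    if set(statin.index) != set(control.index) or \
            set(statin.columns) != set(control.columns):
        raise ValueError("statin and control matrices index different genes/samples")
    control = control.reindex(index=statin.index, columns=statin.columns)
    for name, m in (("statin", statin), ("control", control)):
        if not np.isfinite(m.to_numpy()).all():
            raise ValueError(f"{name} matrix contains non-finite values")
    return DeltaExpression(values=statin - control)


def _quantile_normalize_array(a: np.ndarray) -> np.ndarray:
    """Columns mapped onto the across-column mean order distribution.

    Ties within a column receive the mean of the reference values they span.
    """
    g, n = a.shape
    order = np.argsort(a, axis=0, kind="stable")
    ref = np.take_along_axis(a, order, axis=0).mean(axis=1)
    out = np.empty_like(a, dtype=float)
    for j in range(n):
        srt = order[:, j]
        col_sorted = a[srt, j]
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        ends = np.r_[starts[1:], g]
        csum = np.r_[0.0, np.cumsum(ref)]
        means = (csum[ends] - csum[starts]) / (ends - starts)
        out[srt, j] = np.repeat(means, ends - starts)
    return out


def quantile_normalize(values):
    """Quantile-normalize columns (samples) of a matrix or DeltaExpression."""
    if isinstance(values, DeltaExpression):
        vn = quantile_normalize(values.values)
        return replace(values, values=vn, quantile_normalized=True)
    arr = np.asarray(values, dtype=float) if not isinstance(values, pd.DataFrame) \
        else values.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("need a non-empty 2-D matrix")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values")
    if arr.shape[1] == 1:
        out = arr.copy()
    else:
        out = _quantile_normalize_array(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def regress_out_batch(delta: DeltaExpression, batch: pd.Series) -> DeltaExpression:
    """Per gene, residualize on batch indicators; re-center to the gene mean."""
    batch = pd.Series(batch)
    if not set(delta.sample_ids) <= set(batch.index):
        batch = pd.Series(np.asarray(batch), index=delta.sample_ids)
    batch = batch.reindex(delta.sample_ids)
    if batch.isna().any():
        raise ValueError("batch undefined for some samples")
    levels, idx = np.unique(batch.to_numpy(), return_inverse=True)
    counts = np.bincount(idx)
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(f"batch level(s) with < 2 samples: {list(bad)}")
    if len(levels) == 1:
        return replace(delta, batch_adjusted=True)
    d = delta.values.to_numpy(dtype=float)
    gene_means = d.mean(axis=1, keepdims=True)
    # regression on batch factor == subtracting within-batch means
    resid = d.copy()
    for k in range(len(levels)):
        cols = idx == k
        resid[:, cols] -= d[:, cols].mean(axis=1, keepdims=True)
    resid += gene_means
    vals = pd.DataFrame(resid, index=delta.gene_ids, columns=delta.sample_ids)
    return replace(delta, values=vals, batch_adjusted=True)


def pca_samples(delta: DeltaExpression) -> PCAResult:
    """PCA of the between-sample covariance of the gene-centered matrix.

    Implemented via SVD of the gene-centered matrix; ``scores`` are the
    sample-space singular vectors scaled by their singular values, so
    ``variance_explained_k = eigenvalue_k / sum(eigenvalues)`` of the
    explicit sample covariance.
    """
    d = delta.values.to_numpy(dtype=float)
    g, n = d.shape
    if g < 2 or n < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    dc = d - d.mean(axis=1, keepdims=True)
    if not np.any(dc):
        raise ValueError("zero-variance matrix")
    # SVD of dc (g x n): sample-space directions are the right singular vectors
    _, s, vt = np.linalg.svd(dc, full_matrices=False)
    v = vt.T  # n x k, orthonormal
    # deterministic sign: largest-|.| element of each component positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    scores = v * s
    var = s ** 2
    ve = var / var.sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=delta.sample_ids, columns=cols),
        variance_explained=ve,
    )


def select_n_pcs(variance_explained, threshold: float = 0.005,
                 cap: int = 25) -> int:
    """Largest k <= cap with every leading share >= threshold (0 if none)."""
    ve = np.asarray(variance_explained, dtype=float)
    k = 0
    for share in ve[:cap]:
        if share >= threshold:
            k += 1
        else:
            break
    return k


def remove_pcs(delta: DeltaExpression, pca: PCAResult, k: int, *,
               renormalize: bool = True) -> DeltaExpression:
    """Residualize every gene on score columns 1..k (with intercept).

    The residual matrix is then quantile normalized (matching the pipeline's
    re-normalization after each progressive correction) unless
    ``renormalize=False``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > pca.scores.shape[1]:
        raise ValueError("k exceeds available components")
    d = delta.values.to_numpy(dtype=float)
    if k == 0:
        resid = d
    else:
        q = pca.scores.to_numpy()[:, :k]
        q = q / np.linalg.norm(q, axis=0)  # orthonormal basis of the score span
        # score columns are mean-zero, so the intercept fit is the gene mean;
        # the residual excludes both the intercept and the PC contributions
        dc = d - d.mean(axis=1, keepdims=True)
        resid = dc - (dc @ q) @ q.T
    vals = pd.DataFrame(resid, index=delta.gene_ids, columns=delta.sample_ids)
    out = replace(delta, values=vals, n_pcs_removed=k)
    if renormalize:
        out = quantile_normalize(out)
    return out


def pc_correction_sweep(delta: DeltaExpression, k_max: int,
                        pca: PCAResult | None = None,
                        *, recompute_pca_per_k: bool = False
                        ) -> list[DeltaExpression]:
    """Corrected datasets for k = 1..k_max, sharing one PCA of the input."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if pca is None:
        pca = pca_samples(delta)
    if k_max > pca.scores.shape[1]:
        raise ValueError("k_max exceeds the number of components")
    datasets = []
    current = delta
    for k in range(1, k_max + 1):
        if recompute_pca_per_k:
            ds = remove_pcs(current, pca_samples(current), 1)
            ds = replace(ds, n_pcs_removed=k)
            current = ds
        else:
            ds = remove_pcs(delta, pca, k)
        datasets.append(ds)
    return datasets


def pc_covariate_diagnostics(pca: PCAResult, phenotypes: pd.DataFrame,
                             n_pcs: int = 20,
                             covariates: list[str] | None = None
                             ) -> pd.DataFrame:
    """Associate leading PCs with covariates.

    Numeric covariates: Spearman correlation; categorical: Kruskal-Wallis.
    Constant covariates are flagged with undefined (NaN) statistics.
    """
    if covariates is None:
        covariates = [c for c in ("age", "sex", "smoker", "batch")
                      if c in phenotypes.columns]
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes \
        else phenotypes
    pheno = pheno.loc[pca.scores.index]
    n_pcs = min(n_pcs, pca.scores.shape[1])
    rows = []
    for j in range(n_pcs):
        pc = pca.scores.iloc[:, j].to_numpy()
        for cov in covariates:
            values = pheno[cov]
            numeric = pd.api.types.is_numeric_dtype(values)
            if values.nunique() < 2:
                rows.append((f"PC{j + 1}", cov, "constant", np.nan, np.nan, True))
                continue
            if numeric:
                rho, p = stats.spearmanr(pc, values.to_numpy(dtype=float))
                rows.append((f"PC{j + 1}", cov, "spearman", rho, p, False))
            else:
                groups = [pc[(values == lev).to_numpy()]
                          for lev in values.unique()]
                stat, p = stats.kruskal(*groups)
                rows.append((f"PC{j + 1}", cov, "kruskal", stat, p, False))
    return pd.DataFrame(rows, columns=["pc", "covariate", "test",
                                       "statistic", "p", "undefined"])


class PCCorrector(BaseEstimator, TransformerMixin):
    """Principal-component confounder correction, sklearn-transformer style.

    Operates on ``X`` of shape (n_samples, n_genes).  ``fit`` performs PCA of
    the between-sample covariance of the gene-centered matrix; ``transform``
    residualizes every gene on the leading ``n_pcs`` score columns and
    quantile-normalizes the residuals.  The correction is transductive: the
    scores belong to the fitted samples, so ``transform`` accepts only the
    matrix it was fitted on.

    Parameters
    ----------
    n_pcs : int or None
        Number of leading PCs to remove.  ``None`` applies the selection
        rule: up to ``cap`` PCs, stopping before the first PC explaining
        less than ``threshold`` of the variance.
    threshold, cap : selection-rule parameters (default 0.005, 25).
    renormalize : re-quantile-normalize residuals (default True).
    """

    def __init__(self, n_pcs: int | None = None, threshold: float = 0.005,
                 cap: int = 25, renormalize: bool = True):
        self.n_pcs = n_pcs
        self.threshold = threshold
        self.cap = cap
        self.renormalize = renormalize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        delta = DeltaExpression(values=pd.DataFrame(X.T))
        self.pca_ = pca_samples(delta)
        self.variance_explained_ = self.pca_.variance_explained
        self.n_pcs_ = (select_n_pcs(self.variance_explained_, self.threshold,
                                    self.cap)
                       if self.n_pcs is None else int(self.n_pcs))
        self._fitted_shape = X.shape
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape != self._fitted_shape:
            raise ValueError("PCCorrector is transductive: transform() accepts "
                             "only the matrix it was fitted on")
        delta = DeltaExpression(values=pd.DataFrame(X.T))
        out = remove_pcs(delta, self.pca_, self.n_pcs_,
                         renormalize=self.renormalize)
        return out.values.to_numpy().T
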