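"""Moderated relative-difference statistic and permutation p-values.

For gene *i* with high- and low-responder delta-expression values, the
statistic is the SAM-style relative difference::

    d(i) = (xbar_H(i) - xbar_L(i)) / (s(i) + s0)

where ``s(i)`` is the pooled two-sample standard error and ``s0`` is a
single table-level fudge factor chosen to stabilize the variance of ``d``
across the range of ``s`` (an empirical-Bayes shrinkage of the
denominator).  Significance is assessed by permuting the high/low labels:
the empirical p-value of a gene is the fraction of permutations whose
|d| reaches the observed |d|, with a reporting floor of 1/B when no
permutation does.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import DeltaExpression

__all__ = [
    "SignatureTable",
    "SignatureSelector",
    "pooled_sd",
    "relative_difference",
    "estimate_s0",
    "compute_signature",
    "permutation_pvalues",
    "top_k_genes",
]


@dataclass
class SignatureTable:
    """Per-gene signature statistics plus the table-level s0 and settings.

    ``table`` columns: gene_id (index), mean_high, mean_low, pooled_sd, d,
    p_empirical, floor_flag, rank.  ``rank`` orders genes by |d| descending,
    ties broken by gene_id.  ``floor`` is 1/B; floor-flagged genes had zero
    permutation exceedances and are reported as p < floor.
    """

    table: pd.DataFrame
    s0: float
    s0_method: str
    n_permutations: int = 0
    seed: int | None = None

    @property
    def floor(self) -> float:
        return 1.0 / self.n_permutations if self.n_permutations else np.nan


def pooled_sd(values_high, values_low) -> float:
    """Pooled two-sample standard error of the mean difference.

    ``s = sqrt((1/n_H + 1/n_L) * (SS_H + SS_L) / (n_H + n_L - 2))`` — the
    denominator of the classical pooled two-sample t statistic.
    """
    h = np.asarray(values_high, dtype=float)
    l = np.asarray(values_low, dtype=float)
    if h.size < 2 or l.size < 2:
        raise ValueError("each group needs at least 2 values")
    ss = ((h - h.mean()) ** 2).sum() + ((l - l.mean()) ** 2).sum()
    return math.sqrt((1.0 / h.size + 1.0 / l.size) * ss / (h.size + l.size - 2))


def relative_difference(mean_high: float, mean_low: float, s: float,
                        s0: float) -> float:
    """The moderated statistic ``(mean_high - mean_low) / (s + s0)``."""
    if s < 0 or s0 < 0:
        raise ValueError("s and s0 must be non-negative")
    if s + s0 == 0:
        raise ValueError("s + s0 must be positive")
    return (mean_high - mean_low) / (s + s0)


def _group_stats(d: np.ndarray, high: np.ndarray, low: np.ndarray):
    """Vectorized per-gene means and pooled standard errors.

    ``d``: genes x samples; ``high``/``low``: boolean sample masks.
    """
    nh, nl = int(high.sum()), int(low.sum())
    if nh < 2 or nl < 2:
        raise ValueError("each class needs at least 2 samples")
    mh = d[:, high].mean(axis=1)
    ml = d[:, low].mean(axis=1)
    ssh = ((d[:, high] - mh[:, None]) ** 2).sum(axis=1)
    ssl = ((d[:, low] - ml[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / nh + 1.0 / nl) * (ssh + ssl) / (nh + nl - 2))
    return mh, ml, s


def estimate_s0(mean_high, mean_low, s, method: str = "cv_min",
                n_windows: int = 100) -> float:
    """Choose the fudge factor s0.

    ``cv_min`` (default): candidates are the 0th, 5th, ..., 100th
    percentiles of {s(i)}.  For each candidate, genes are binned into
    ~``n_windows`` equal-count windows by s(i); the candidate minimizing
    the coefficient of variation of the per-window median absolute
    deviation of d is chosen, ties going to the smallest candidate.
    ``percentile:q`` and ``fixed:v`` are explicit overrides.
    """
    s = np.asarray(s, dtype=float)
    diff = np.asarray(mean_high, dtype=float) - np.asarray(mean_low, dtype=float)
    if method.startswith("fixed:"):
        v = float(method.split(":", 1)[1])
        if v < 0:
            raise ValueError("fixed s0 must be non-negative")
        return v
    if method.startswith("percentile:"):
        q = float(method.split(":", 1)[1])
        return float(np.percentile(s, q))
    if method != "cv_min":
        raise ValueError(f"unknown s0 method {method!r}")
    if s.size < 20:
        raise ValueError("cv_min needs at least 20 genes")
    if np.all(s == 0):
        raise ValueError("all pooled sds are zero")
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, min(n_windows, s.size))
    best_s0, best_cv = None, None
    for cand in candidates:
        d = diff / (s + cand)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w])))
                         for w in windows])
        mean_mad = mads.mean()
        cv = mads.std() / mean_mad if mean_mad > 0 else np.inf
        if best_cv is None or cv < best_cv - 1e-12 or \
                (abs(cv - best_cv) <= 1e-12 and cand < best_s0):
            best_s0, best_cv = float(cand), cv
    return best_s0


def _resolve_labels(delta: DeltaExpression, labels) -> tuple[np.ndarray, np.ndarray]:
    """High/low boolean masks over the delta's sample axis."""
    labels = pd.Series(labels)
    if not set(labels.index) & set(delta.sample_ids):
        labels = pd.Series(np.asarray(labels), index=delta.sample_ids)
    labels = labels.reindex(delta.sample_ids)
    high = (labels == "high").to_numpy()
    low = (labels == "low").to_numpy()
    if not high.any() or not low.any():
        raise ValueError("both 'high' and 'low' classes must be present")
    return high, low


def _rank_by_abs_d(d: np.ndarray, gene_ids) -> np.ndarray:
    """Ranks 1..n by |d| descending, ties broken by gene_id ascending."""
    gene_ids = np.asarray(gene_ids)
    order = np.lexsort((gene_ids, -np.abs(d)))
    ranks = np.empty(len(d), dtype=int)
    ranks[order] = np.arange(1, len(d) + 1)
    return ranks


def compute_signature(delta: DeltaExpression, labels,
                      s0_method: str = "cv_min", B: int = 0,
                      seed: int | None = None) -> SignatureTable:
    """Full signature table: means, pooled sd, s0, d, ranks, optional p-values.

    Only samples labeled ``high`` or ``low`` enter the statistic.  When
    ``B > 0``, label-permutation empirical p-values are appended with the
    s0 held at its observed-data value.
    """
    high, low = _resolve_labels(delta, labels)
    d_mat = delta.values.to_numpy(dtype=float)
    mh, ml, s = _group_stats(d_mat, high, low)
    s0 = estimate_s0(mh, ml, s, method=s0_method)
    denom = s + s0
    if np.any(denom == 0):
        flagged = delta.gene_ids[denom == 0]
        raise ValueError(f"genes with s + s0 = 0: {list(flagged[:5])}")
    d = (mh - ml) / denom
    table = pd.DataFrame({
        "mean_high": mh,
        "mean_low": ml,
        "pooled_sd": s,
        "d": d,
        "p_empirical": np.nan,
        "floor_flag": False,
        "rank": _rank_by_abs_d(d, delta.gene_ids),
    }, index=pd.Index(delta.gene_ids, name="gene_id"))
    sig = SignatureTable(table=table, s0=s0, s0_method=s0_method,
                         n_permutations=int(B), seed=seed)
    if B > 0:
        p, flo = permutation_pvalues(delta, labels, B=B, seed=seed, s0=s0)
        sig.table["p_empirical"] = p
        sig.table["floor_flag"] = flo
    return sig


def permutation_pvalues(delta: DeltaExpression, labels, B: int = 5000,
                        seed: int | None = None, s0: float | None = None,
                        s0_method: str = "cv_min", batch_size: int = 500
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene empirical p-values from uniform label permutations.

    ``p(i) = #{b : |d_b(i)| >= |d_obs(i)|} / B`` with s0 fixed at the
    observed-data value.  Genes with zero exceedances are floor-flagged
    (reported as p < 1/B).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    high, low = _resolve_labels(delta, labels)
    labeled = high | low
    d_mat = delta.values.to_numpy(dtype=float)[:, labeled]
    is_high = high[labeled]
    n, nh = is_high.size, int(is_high.sum())
    nl = n - nh
    if math.comb(n, nh) < B:
        warnings.warn(f"only C({n},{nh}) = {math.comb(n, nh)} distinct "
                      f"label permutations exist; B = {B} resamples them")
    mh, ml, s = _group_stats(d_mat[:, :], is_high, ~is_high)
    if s0 is None:
        s0 = estimate_s0(mh, ml, s, method=s0_method)
    d_obs = np.abs((mh - ml) / (s + s0))

    rng = np.random.default_rng(seed)
    dsq = d_mat ** 2
    tot = d_mat.sum(axis=1, keepdims=True)
    tot_sq = dsq.sum(axis=1, keepdims=True)
    const = (1.0 / nh + 1.0 / nl) / (n - 2)
    exceed = np.zeros(d_mat.shape[0], dtype=np.int64)
    done = 0
    while done < B:
        nb = min(batch_size, B - done)
        # nb stratified label permutations: first nh of a shuffle are 'high'
        u = rng.random((nb, n))
        picks = np.argsort(u, axis=1)[:, :nh]
        mask = np.zeros((n, nb))
        mask[picks.T, np.arange(nb)[None, :].repeat(nh, axis=0)] = 1.0
        sum_h = d_mat @ mask
        sumsq_h = dsq @ mask
        mean_h = sum_h / nh
        mean_l = (tot - sum_h) / nl
        ss_h = sumsq_h - nh * mean_h ** 2
        ss_l = (tot_sq - sumsq_h) - nl * mean_l ** 2
        s_b = np.sqrt(np.maximum(const * (ss_h + ss_l), 0.0))
        d_b = np.abs((mean_h - mean_l) / (s_b + s0))
        exceed += (d_b >= d_obs[:, None]).sum(axis=1)
        done += nb
    p = exceed / B
    return p, exceed == 0


def top_k_genes(signature: SignatureTable, k: int) -> list[str]:
    """The k highest-|d| gene ids, in rank order."""
    n = len(signature.table)
    if k > n:
        raise ValueError(f"k = {k} exceeds {n} genes")
    ordered = signature.table.sort_values("rank")
    return list(ordered.index[:k])


class SignatureSelector(BaseEstimator, TransformerMixin):
    """Signature-gene selection as an sklearn transformer.

    ``fit(X, y)`` takes ``X`` of shape (n_samples, n_genes) and binary
    labels ``y`` ('high'/'low'); it computes the moderated
    relative-difference table and keeps the top ``k`` genes by |d|.
    ``transform`` restricts a matrix to the selected columns.

    Attributes
    ----------
    signature_ : SignatureTable
    s0_ : float
    support_ : boolean mask of selected columns
    selected_genes_ : column indices (or names) of the panel, rank order
    """

    def __init__(self, k: int = 100, s0_method: str = "cv_min",
                 n_permutations: int = 0, random_state: int | None = None):
        self.k = k
        self.s0_method = s0_method
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        y = np.asarray(y)
        gene_ids = [f"g{j}" for j in range(X.shape[1])]
        delta = DeltaExpression(values=pd.DataFrame(X.T, index=gene_ids))
        labels = pd.Series(np.where(y == _positive(y), "high", "low"),
                           index=delta.sample_ids)
        self.signature_ = compute_signature(
            delta, labels, s0_method=self.s0_method,
            B=self.n_permutations, seed=self.random_state)
        self.s0_ = self.signature_.s0
        top = top_k_genes(self.signature_, min(self.k, X.shape[1]))
        idx = [int(g[1:]) for g in top]
        self.selected_genes_ = np.array(idx)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[idx] = True
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_genes_]


def _positive(y: np.ndarray):
    """'high' when present, else the second sorted class."""
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    return "high" if "high" in classes else classes[1]
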