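"""Phenotype association of signature-gene expression changes.

Clinical phenotype changes are delta-log measures, ln(mean on-treatment)
minus ln(mean pre-treatment).  Signature-gene deltas are associated with
lipid phenotypes (cellular cholesterol-ester change, plasma lipid changes)
by Spearman rank correlation with Bonferroni adjustment over the panel,
and high-vs-low group differences use the two-sided pooled-variance
two-sample t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DeltaExpression

__all__ = [
    "delta_log_phenotype",
    "spearman_assoc",
    "bonferroni",
    "panel_phenotype_scan",
    "group_difference_test",
    "residualize_on_covariates",
]


def delta_log_phenotype(pre_values, post_values) -> float:
    """ln(mean(post)) - ln(mean(pre)); all values must be positive."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("each side needs at least one value")
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("phenotype values must be positive")
    return float(np.log(post.mean()) - np.log(pre.mean()))


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    The p-value uses the t-approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom.
    Constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, _ = stats.spearmanr(x, y)
    n = x.size
    if abs(rho) >= 1.0:
        return float(rho), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


def bonferroni(p_raw: float, m_tests: int) -> float:
    """min(1, m * p)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must be in [0, 1]")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, m_tests * p_raw)


def panel_phenotype_scan(delta: DeltaExpression, panel, phenotype: pd.Series
                         ) -> pd.DataFrame:
    """Spearman scan of every panel gene against one phenotype.

    Samples lacking the phenotype are dropped per gene; ``m_tests`` is the
    panel size and ``p_adjusted`` the Bonferroni-corrected p.  Rows are
    sorted by ``p_adjusted`` (ties by raw p, then gene id).
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    phenotype = pd.Series(phenotype).reindex(delta.sample_ids)
    usable = phenotype.notna().to_numpy()
    if usable.sum() < 3:
        raise ValueError("phenotype available for fewer than 3 samples")
    y = phenotype.to_numpy(dtype=float)[usable]
    m = len(panel)
    name = phenotype.name or "phenotype"
    rows = []
    for gene in panel:
        x = delta.values.loc[gene].to_numpy(dtype=float)[usable]
        rho, p = spearman_assoc(x, y)
        padj = bonferroni(p, m) if np.isfinite(p) else np.nan
        rows.append((gene, name, int(usable.sum()), rho, p, padj, m))
    out = pd.DataFrame(rows, columns=["gene_id", "phenotype", "n", "rho",
                                      "p_raw", "p_adjusted", "m_tests"])
    return out.sort_values(["p_adjusted", "p_raw", "gene_id"],
                           na_position="last").reset_index(drop=True)


def group_difference_test(values_high, values_low) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test (high minus low)."""
    h = np.asarray(values_high, dtype=float)
    l = np.asarray(values_low, dtype=float)
    if h.size < 2 or l.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(h, l, equal_var=True)
    return float(t), float(p)


def residualize_on_covariates(values: pd.Series, covariates: pd.DataFrame
                              ) -> pd.Series:
    """Least-squares residual of a phenotype on covariates (pre-step option).

    Categorical covariate columns are one-hot encoded; an intercept is
    always included and the residuals keep the original mean.
    """
    y = values.to_numpy(dtype=float)
    X = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta + y.mean()
    return pd.Series(resid, index=values.index, name=values.name)
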