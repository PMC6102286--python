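"""Minimal plotting helpers: ROC curves and phenotype scatter plots."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_roc", "plot_ce_scatter", "fold_change"]


def fold_change(control_vst, statin_vst) -> np.ndarray:
    """Figure-style fold change 2**(control - statin).

    The variance-stabilized scale is roughly log2, so this approximates the
    control/statin expression ratio; a display convention only — statistics
    operate on the variance-stabilized deltas.
    """
    return 2.0 ** (np.asarray(control_vst, float) - np.asarray(statin_vst, float))


def plot_roc(roc_points, auc_value: float | None = None, ax=None):
    """Plot one ROC curve from (fpr, tpr) points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pts = np.asarray(roc_points, float)
    label = None if auc_value is None else f"AUC = {auc_value:.2f}"
    ax.plot(pts[:, 0], pts[:, 1], label=label)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_ce_scatter(gene_delta, ce_delta, rho: float | None = None, ax=None):
    """Scatter of a gene's expression change vs cholesterol-ester change."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x = np.asarray(gene_delta, float)
    y = np.asarray(ce_delta, float)
    keep = np.isfinite(x) & np.isfinite(y)
    ax.scatter(x[keep], y[keep], s=12, alpha=0.7)
    ax.set_xlabel("expression change (statin - control)")
    ax.set_ylabel("delta cholesterol ester")
    if rho is not None:
        ax.set_title(f"Spearman rho = {rho:.3f}")
    return ax
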