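"""Figures: per-gene pooled histograms and QQ plots by age category,
score/p-value histograms, and per-pattern boxplots.

Gene-level plots pool the cells of all samples within each age category.
All functions are pure in their inputs and return the arrays they plotted,
so the plotted content can be tested without decoding image files.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from distage.datamodel import CellExpressionDataset

QQ_MAX_POINTS = 1000


def _pooled_by_age(ds: CellExpressionDataset, gene_id: str) -> dict[float, np.ndarray]:
    col = ds.gene_index(gene_id)
    age_of = ds.ages
    labels = np.asarray([str(s) for s in ds.cell_sample_ids])
    cell_ages = age_of.reindex(labels).to_numpy(dtype=float)
    return {
        age: ds.expression[cell_ages == age, col] for age in np.unique(cell_ages)
    }


def gene_histogram(
    ds: CellExpressionDataset, gene_id: str, bins: int = 50, path: str | None = None
) -> dict[float, np.ndarray]:
    """One histogram panel per age category, sharing the pooled x-range."""
    pooled = _pooled_by_age(ds, gene_id)
    lo = min(v.min() for v in pooled.values())
    hi = max(v.max() for v in pooled.values())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, bins + 1)
    fig, axes = plt.subplots(1, len(pooled), figsize=(3.2 * len(pooled), 2.8),
                             sharex=True, sharey=True, squeeze=False)
    for ax, (age, values) in zip(axes.ravel(), sorted(pooled.items())):
        ax.hist(values, bins=edges, color="steelblue")
        ax.set_title(f"age {age:g} (n={values.size})")
        ax.set_xlabel("expression")
    axes[0, 0].set_ylabel("cells")
    fig.suptitle(gene_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    plt.close(fig)
    return pooled


def gene_qq(
    ds: CellExpressionDataset, gene_id: str, path: str | None = None
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Quantiles of each older age's pooled distribution vs the youngest age.

    Quantiles are taken at matched probability points (1..m)/(m+1) with
    m capped at 1,000; a variance change shows as tails fanning away from
    the identity line.
    """
    pooled = _pooled_by_age(ds, gene_id)
    if len(pooled) < 2:
        raise ValueError("QQ plot requires at least two age categories")
    ages = sorted(pooled)
    youngest = pooled[ages[0]]
    m = min(QQ_MAX_POINTS, min(v.size for v in pooled.values()))
    probs = np.arange(1, m + 1) / (m + 1)
    qx = np.quantile(youngest, probs)
    out: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    fig, axes = plt.subplots(1, len(ages) - 1, figsize=(3.2 * (len(ages) - 1), 3.2),
                             squeeze=False)
    for ax, age in zip(axes.ravel(), ages[1:]):
        qy = np.quantile(pooled[age], probs)
        out[age] = (qx, qy)
        ax.plot(qx, qy, ".", ms=3)
        lims = [min(qx.min(), qy.min()), max(qx.max(), qy.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(f"age {ages[0]:g} quantiles")
        ax.set_ylabel(f"age {age:g} quantiles")
    fig.suptitle(gene_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    plt.close(fig)
    return out


def score_histogram(
    results: pd.DataFrame, bins: int = 50, path: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Side-by-side histograms of rho and BH-adjusted Mantel p across genes."""
    if results.empty:
        raise ValueError("empty association table")
    rho = results["rho"].to_numpy(dtype=float)
    adj = results["adjusted_p"].to_numpy(dtype=float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    ax1.hist(rho[np.isfinite(rho)], bins=bins, range=(-1, 1), color="steelblue")
    ax1.set_xlabel("Spearman rho")
    ax1.set_ylabel("genes")
    ax2.hist(adj[np.isfinite(adj)], bins=bins, range=(0, 1), color="indianred")
    ax2.set_xlabel("adjusted Mantel p")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    plt.close(fig)
    return rho, adj


def pattern_boxplot(
    joined: pd.DataFrame, value: str = "rho", path: str | None = None
) -> dict[str, np.ndarray]:
    """Boxplot of a score column grouped by true simulation pattern.

    ``joined`` must carry ``true_pattern`` and the chosen value column
    (merge the association table with the ground-truth labels first).
    """
    if "true_pattern" not in joined.columns:
        raise ValueError("expected a true_pattern column")
    groups = {
        str(p): grp[value].to_numpy(dtype=float)
        for p, grp in joined.groupby("true_pattern", sort=True)
    }
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    names = list(groups)
    ax.boxplot([groups[n][np.isfinite(groups[n])] for n in names], tick_labels=names)
    ax.set_ylabel(value)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    plt.close(fig)
    return groups
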