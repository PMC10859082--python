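"""Distance-matrix association between expression distributions and age.

For each gene a sample x sample distance matrix is built from the pairwise
distribution distances; donor age gives a second distance matrix from
absolute age differences. Association is scored as the Spearman rank
correlation between the strictly-upper-triangle entries of the two
matrices, and its significance is assessed with a one-sided Mantel
permutation test (rows and columns of the age matrix permuted together).
Across genes, Mantel p-values receive a Benjamini-Hochberg adjustment and
genes are classified by a correlation cutoff (0.85 by default).

A pseudo-bulk comparator (Spearman of per-sample mean expression vs age)
is included: pure variance changes leave per-sample means flat, so its
correlations sit near zero where the distribution-level score does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from distage.datamodel import CellExpressionDataset, DatasetError
from distage.density import estimate_pair_pmfs
from distage.distances import METRICS, hellinger, js_distance, ks_distance

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_CUTOFF = 0.85

#: fixed metric order used when deriving per-(gene, metric) RNG streams
_METRIC_ORDER = {"hellinger": 0, "js": 1, "ks": 2}


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample x sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match the number of sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.matrix < -1e-12):
            raise ValueError("distance matrix must be nonnegative")
        self.matrix = np.clip(self.matrix, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """The n(n-1)/2 strictly-above-diagonal entries, row-major."""
    matrix = np.asarray(matrix)
    return matrix[np.triu_indices(matrix.shape[0], k=1)]


def age_distance_matrix(
    ages: "pd.Series | Sequence[float]", sample_ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Distance matrix of absolute donor-age differences, |age_i - age_j|."""
    if sample_ids is None:
        if not isinstance(ages, pd.Series):
            raise ValueError("sample_ids required unless ages is a pandas Series")
        sample_ids = list(ages.index)
    a = np.asarray(ages, dtype=float)
    if a.size < 3:
        raise ValueError("at least 3 samples are required for association analysis")
    return DistanceMatrix(list(sample_ids), np.abs(a[:, None] - a[None, :]))


def gene_distance_matrices(
    ds: CellExpressionDataset,
    gene_id: str,
    metrics: Sequence[str] = ("hellinger",),
    k: int = 1000,
    bandwidth_rule: str = "nrd0",
) -> dict[str, DistanceMatrix]:
    """Sample x sample distance matrices for one gene under several metrics.

    The pooled-grid PMF pair is estimated once per unordered sample pair
    and shared by all PMF-based metrics, so requesting hellinger and js
    together costs a single density pass.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    vecs = ds.gene_vectors(gene_id)
    sids = ds.sample_ids
    empty = [s for s in sids if vecs[s].size == 0]
    if empty:
        raise DatasetError(f"samples without cells for gene {gene_id!r}: {empty}")
    n = len(sids)
    mats = {m: np.zeros((n, n)) for m in metrics}
    pmf_metrics = [m for m in metrics if METRICS[m]]
    for i in range(n):
        xi = vecs[sids[i]]
        for j in range(i + 1, n):
            yj = vecs[sids[j]]
            if pmf_metrics:
                p, q = estimate_pair_pmfs(xi, yj, k=k, bandwidth_rule=bandwidth_rule)
                for m in pmf_metrics:
                    d = hellinger(p, q) if m == "hellinger" else js_distance(p, q)
                    mats[m][i, j] = mats[m][j, i] = d
            if "ks" in metrics:
                d = ks_distance(xi, yj)
                mats["ks"][i, j] = mats["ks"][j, i] = d
    return {m: DistanceMatrix(sids, mats[m]) for m in metrics}


def gene_distance_matrix(
    ds: CellExpressionDataset,
    gene_id: str,
    metric: str = "hellinger",
    k: int = 1000,
    bandwidth_rule: str = "nrd0",
) -> DistanceMatrix:
    """Sample x sample distance matrix for one gene under one metric."""
    return gene_distance_matrices(ds, gene_id, (metric,), k, bandwidth_rule)[metric]


def _check_aligned(d1: DistanceMatrix, d2: DistanceMatrix) -> None:
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices must share sample ids in the same order")
    if d1.n < 3:
        raise ValueError("at least 3 samples required")


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    return float(u @ v / denom)


def upper_triangle_spearman(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Spearman rho between the upper-triangle entries of two distance matrices.

    Average ranks are used for ties. Returns NaN (the undefined flag) if
    either unfolded vector is constant.
    """
    _check_aligned(d1, d2)
    u = upper_triangle(d1.matrix)
    v = upper_triangle(d2.matrix)
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return float("nan")
    return _pearson(rankdata(u), rankdata(v))


def _score_matrix(matrix: np.ndarray, stat: str) -> np.ndarray:
    """Symmetric matrix whose cells carry the statistic's per-entry scores.

    For Spearman the score of a cell is the average rank of its value among
    the upper-triangle entries; for Pearson it is the raw value. Because
    simultaneous row/column permutation only re-selects the same unordered
    pairs, the scores are permutation-invariant, so a permuted statistic is
    a plain Pearson correlation of re-indexed score vectors.
    """
    if stat == "pearson":
        return matrix
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(matrix[iu])
    scored = np.zeros_like(matrix, dtype=float)
    scored[iu] = ranks
    return scored + scored.T


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: "int | np.random.Generator | None" = None,
    stat: str = "spearman",
) -> tuple[float, float]:
    """One-sided Mantel permutation test between two distance matrices.

    The observed statistic (Spearman by default, Pearson via ``stat``) is
    computed on the upper triangles; the null re-samples it by permuting
    the rows and columns of ``d2`` together. Returns ``(statistic, p)``
    with ``p = (1 + #{perm >= observed}) / (1 + n_perm)``. A constant
    unfolded vector gives ``(nan, 1.0)`` by convention.
    """
    _check_aligned(d1, d2)
    if stat not in ("spearman", "pearson"):
        raise ValueError(f"unknown statistic {stat!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    u = _score_matrix(d1.matrix, stat)[iu]
    if np.ptp(u) == 0 or np.ptp(upper_triangle(d2.matrix)) == 0:
        return float("nan"), 1.0
    scored2 = _score_matrix(d2.matrix, stat)
    v = scored2[iu]
    observed = _pearson(u, v)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # score multiset is permutation-invariant: precompute centred u and
    # the constant moments of v, then each permutation is one dot product
    uc = u - u.mean()
    u_norm = np.sqrt(uc @ uc)
    v_mean = v.mean()
    v_norm = np.sqrt(((v - v_mean) ** 2).sum())
    m = u.size
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        vp = scored2[np.ix_(p, p)][iu]
        r = (uc @ vp) / (u_norm * v_norm)  # vp mean/norm equal v's
        if r >= observed - 1e-12:
            exceed += 1
    return observed, (1 + exceed) / (1 + n_perm)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# whole-dataset workflows
# ---------------------------------------------------------------------------

def _gene_rng(seed: int, gene_index: int, metric: str) -> np.random.Generator:
    # independent, reproducible stream per (gene, metric)
    return np.random.default_rng([seed, gene_index, _METRIC_ORDER[metric]])


def run_workflow_multi(
    ds: CellExpressionDataset,
    metrics: Sequence[str] = ("hellinger",),
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    k: int = 1000,
    bandwidth_rule: str = "nrd0",
    stat: str = "spearman",
    progress: Callable[[int, int], None] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full association workflow under one or more metrics at once.

    Returns one association table per metric. PMF estimation is shared
    across PMF-based metrics, and each (gene, metric) permutation stream is
    derived independently from ``seed``, so a single-metric run reproduces
    the corresponding table of a multi-metric run exactly.
    """
    age_dm = age_distance_matrix(ds.ages)
    rows: dict[str, list[dict]] = {m: [] for m in metrics}
    n_genes = ds.n_genes
    for gi, gene in enumerate(ds.gene_ids):
        dms = gene_distance_matrices(ds, gene, metrics, k=k, bandwidth_rule=bandwidth_rule)
        for m in metrics:
            rng = _gene_rng(seed, gi, m)
            rho, p = mantel_test(dms[m], age_dm, n_perm=n_perm, seed=rng, stat=stat)
            rows[m].append(
                {
                    "gene_id": gene,
                    "rho": rho,
                    "mantel_p": p,
                    "n_samples": age_dm.n,
                    "n_permutations": n_perm,
                    "metric": m,
                }
            )
        if progress is not None:
            progress(gi + 1, n_genes)
    out = {}
    for m in metrics:
        tbl = pd.DataFrame(rows[m])
        tbl["adjusted_p"] = bh_adjust(tbl["mantel_p"].to_numpy())
        tbl["passed_cutoff"] = tbl["rho"] > cutoff
        out[m] = tbl[
            [
                "gene_id",
                "rho",
                "mantel_p",
                "adjusted_p",
                "n_samples",
                "n_permutations",
                "metric",
                "passed_cutoff",
            ]
        ]
    return out


def run_workflow(
    ds: CellExpressionDataset,
    metric: str = "hellinger",
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    k: int = 1000,
    bandwidth_rule: str = "nrd0",
    stat: str = "spearman",
    progress: Callable[[int, int], None] | None = None,
) -> pd.DataFrame:
    """Per-gene distribution-vs-age association table for one metric.

    For every gene: build the distance matrix, correlate its upper triangle
    with the age distance matrix, run the Mantel test; then BH-adjust the
    p-values across genes and classify by ``rho > cutoff``. Genes with an
    undefined correlation (constant distances, e.g. unexpressed genes) are
    retained with ``rho = NaN`` and ``mantel_p = 1``.
    """
    return run_workflow_multi(
        ds,
        (metric,),
        n_perm=n_perm,
        seed=seed,
        cutoff=cutoff,
        k=k,
        bandwidth_rule=bandwidth_rule,
        stat=stat,
        progress=progress,
    )[metric]


def pseudobulk_correlation(ds: CellExpressionDataset) -> pd.DataFrame:
    """Spearman correlation of per-sample mean expression with donor age.

    The mean-based comparator: one row per gene with the rank correlation
    between the per-sample pseudo-bulk values and the donor ages (NaN when
    the means are constant).
    """
    if len(ds.sample_ids) < 3:
        raise ValueError("at least 3 samples required")
    labels = pd.Categorical(
        [str(s) for s in ds.cell_sample_ids], categories=ds.sample_ids
    )
    means = (
        pd.DataFrame(ds.expression)
        .groupby(labels, observed=True)
        .mean()
        .reindex(ds.sample_ids)
        .to_numpy()
    )
    age_ranks = rankdata(ds.ages.to_numpy())
    rhos = np.full(ds.n_genes, np.nan)
    for gi in range(ds.n_genes):
        col = means[:, gi]
        if np.ptp(col) > 0 and np.ptp(age_ranks) > 0:
            rhos[gi] = _pearson(rankdata(col), age_ranks)
    return pd.DataFrame({"gene_id": ds.gene_ids, "rho": rhos})
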