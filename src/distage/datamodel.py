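"""Dataset container and I/O for the supported single-cell formats.

The in-memory model is deliberately small: a dense cells x genes matrix,
per-cell sample labels (plus optional per-cell annotations such as sex or
cell type), and a per-sample metadata table carrying donor age. Three
on-disk formats are supported: an h5ad annotated matrix (via anndata), a
MatrixMarket triplet directory, and a dense TSV directory. The directory
layouts for MTX / dense TSV are::

    <dir>/matrix.mtx + genes.tsv     or    <dir>/expression.tsv
    <dir>/cells.tsv     # cell_id, <sample column>, optional annotations
    <dir>/samples.tsv   # sample id (first column), <age column>, optional

Expression values are used as given: no log transform or normalisation is
applied anywhere in this package (inputs are assumed preprocessed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class DatasetError(ValueError):
    """Invalid dataset contents (unmatched samples, bad ages, empty subsets)."""


class MissingColumnError(KeyError):
    """A requested annotation/metadata column does not exist."""


@dataclass
class GeneSampleVector:
    """Expression of one gene over all cells of one sample."""

    gene_id: str
    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise DatasetError(
                f"empty expression vector for gene {self.gene_id!r} "
                f"in sample {self.sample_id!r}"
            )


@dataclass
class CellExpressionDataset:
    """Cells x genes expression with sample labels and donor-age metadata.

    Parameters
    ----------
    expression
        Dense ``(n_cells, n_genes)`` float matrix of processed expression.
    gene_ids
        Unique gene identifiers, one per expression column.
    cell_sample_ids
        Sample label per cell (row).
    sample_metadata
        Indexed by sample id; must contain an ``age`` column with a finite
        numeric donor age per sample (months for real data, ordinal
        category for simulations).
    cell_annotations
        Optional per-cell table (sex, tissue, cell_type, ...), aligned with
        the expression rows.
    """

    expression: np.ndarray
    gene_ids: list[str]
    cell_sample_ids: np.ndarray
    sample_metadata: pd.DataFrame
    cell_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 2:
            raise DatasetError("expression must be a 2-D cells x genes matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise DatasetError(f"duplicate gene ids: {dupes[:5]}")
        if self.expression.shape[1] != len(self.gene_ids):
            raise DatasetError(
                f"{self.expression.shape[1]} expression columns for "
                f"{len(self.gene_ids)} gene ids"
            )
        self.cell_sample_ids = np.asarray(self.cell_sample_ids, dtype=object)
        if self.cell_sample_ids.shape[0] != self.expression.shape[0]:
            raise DatasetError("one sample label required per cell")
        if pd.isna(self.cell_sample_ids).any():
            raise DatasetError("cells with missing sample labels are not allowed")

        if "age" not in self.sample_metadata.columns:
            raise MissingColumnError("sample_metadata must contain an 'age' column")
        present = pd.unique(self.cell_sample_ids)
        known = set(map(str, self.sample_metadata.index))
        unmatched = sorted(str(s) for s in present if str(s) not in known)
        if unmatched:
            raise DatasetError(
                f"cell sample labels missing from sample_metadata: {unmatched}"
            )
        # restrict metadata to samples that actually have cells, keeping order
        self.sample_metadata = self.sample_metadata.copy()
        self.sample_metadata.index = self.sample_metadata.index.map(str)
        self.sample_metadata = self.sample_metadata.loc[[str(s) for s in present]]

        ages = pd.to_numeric(self.sample_metadata["age"], errors="coerce")
        bad = self.sample_metadata.index[~np.isfinite(ages.to_numpy(dtype=float))]
        if len(bad):
            raise DatasetError(f"non-numeric or missing age for samples: {list(bad)}")
        self.sample_metadata["age"] = ages.astype(float)

        if self.cell_annotations is not None:
            if len(self.cell_annotations) != self.expression.shape[0]:
                raise DatasetError("cell_annotations must have one row per cell")
            self.cell_annotations = self.cell_annotations.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_metadata.index)

    @property
    def ages(self) -> pd.Series:
        return self.sample_metadata["age"]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def sample_cell_mask(self, sample_id: str) -> np.ndarray:
        return np.asarray([str(s) == str(sample_id) for s in self.cell_sample_ids])

    def gene_vector(self, gene_id: str, sample_id: str) -> GeneSampleVector:
        col = self.gene_index(gene_id)
        vals = self.expression[self.sample_cell_mask(sample_id), col]
        return GeneSampleVector(gene_id, str(sample_id), vals)

    def gene_vectors(self, gene_id: str) -> dict[str, np.ndarray]:
        """Per-sample raw value arrays for one gene, keyed by sample id."""
        col = self.gene_index(gene_id)
        labels = np.asarray([str(s) for s in self.cell_sample_ids])
        out: dict[str, np.ndarray] = {}
        for sid in self.sample_ids:
            out[sid] = self.expression[labels == sid, col]
        return out

    def annotation_frame(self) -> pd.DataFrame:
        """Per-cell frame combining cell annotations with broadcast sample metadata."""
        frame = pd.DataFrame({"sample_id": [str(s) for s in self.cell_sample_ids]})
        meta = self.sample_metadata
        for col in meta.columns:
            frame[col] = meta[col].reindex(frame["sample_id"]).to_numpy()
        if self.cell_annotations is not None:
            for col in self.cell_annotations.columns:
                frame[col] = self.cell_annotations[col].to_numpy()
        return frame


# ---------------------------------------------------------------------------
# subsetting and gene filtering
# ---------------------------------------------------------------------------

def subset_dataset(
    ds: CellExpressionDataset,
    predicate: str | Callable[[pd.DataFrame], Sequence[bool]],
) -> CellExpressionDataset:
    """Restrict to the cells matching a predicate over cell annotations.

    ``predicate`` is either a pandas ``query`` expression over the combined
    per-cell annotation frame (e.g. ``"sex == 'male'"``) or a callable
    returning a boolean mask. Samples left with zero cells are dropped from
    the metadata; an empty result is an error.
    """
    frame = ds.annotation_frame()
    if callable(predicate):
        mask = np.asarray(predicate(frame), dtype=bool)
    else:
        try:
            mask = frame.eval(predicate).to_numpy(dtype=bool)
        except pd.errors.UndefinedVariableError as exc:
            raise MissingColumnError(str(exc)) from None
    if mask.shape[0] != ds.n_cells:
        raise DatasetError("predicate mask length does not match cell count")
    if not mask.any():
        raise DatasetError(f"predicate {predicate!r} removes every cell")
    return CellExpressionDataset(
        expression=ds.expression[mask],
        gene_ids=list(ds.gene_ids),
        cell_sample_ids=ds.cell_sample_ids[mask],
        sample_metadata=ds.sample_metadata,
        cell_annotations=None
        if ds.cell_annotations is None
        else ds.cell_annotations.loc[mask].reset_index(drop=True),
    )


def filter_top_genes(
    ds: CellExpressionDataset, k: int = 3000, per_age: bool = True
) -> CellExpressionDataset:
    """Keep the most highly expressed genes.

    With ``per_age=True`` (default) the kept set is the union over age
    categories of the top-``k`` genes by mean expression within that age's
    cells; with ``per_age=False`` a single top-``k`` by overall mean is
    used. Gene order is preserved. ``k`` at least the gene count returns
    the dataset unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= ds.n_genes:
        return ds
    keep: set[int] = set()
    if per_age:
        age_of = ds.ages
        labels = np.asarray([str(s) for s in ds.cell_sample_ids])
        cell_ages = age_of.reindex(labels).to_numpy(dtype=float)
        for age in np.unique(cell_ages):
            means = ds.expression[cell_ages == age].mean(axis=0)
            keep.update(np.argsort(-means, kind="stable")[:k].tolist())
    else:
        means = ds.expression.mean(axis=0)
        keep.update(np.argsort(-means, kind="stable")[:k].tolist())
    idx = sorted(keep)
    return CellExpressionDataset(
        expression=ds.expression[:, idx],
        gene_ids=[ds.gene_ids[i] for i in idx],
        cell_sample_ids=ds.cell_sample_ids,
        sample_metadata=ds.sample_metadata,
        cell_annotations=ds.cell_annotations,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "gene_id",
    "rho",
    "mantel_p",
    "adjusted_p",
    "n_samples",
    "n_permutations",
    "metric",
    "passed_cutoff",
]


def _infer_format(path: str) -> str:
    if str(path).endswith(".h5ad"):
        return "h5ad"
    if os.path.isdir(path):
        if os.path.exists(os.path.join(path, "matrix.mtx")):
            return "mtx"
        if os.path.exists(os.path.join(path, "expression.tsv")):
            return "dense_tsv"
    raise DatasetError(f"cannot infer format of {path!r}")


def read_dataset(
    path: str,
    format: str | None = None,
    sample_key: str = "sample_id",
    age_key: str = "age",
) -> CellExpressionDataset:
    """Read a dataset from h5ad, MTX-directory, or dense-TSV-directory form.

    ``sample_key`` names the per-cell sample column (h5ad obs / cells.tsv)
    and ``age_key`` the donor-age column (h5ad obs / samples.tsv).
    """
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        return _read_h5ad(path, sample_key, age_key)
    if fmt in ("mtx", "dense_tsv"):
        return _read_dir(path, fmt, sample_key, age_key)
    raise ValueError(f"unknown format {fmt!r}")


def _read_h5ad(path: str, sample_key: str, age_key: str) -> CellExpressionDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    obs = adata.obs
    for key in (sample_key, age_key):
        if key not in obs.columns:
            raise MissingColumnError(
                f"annotation column {key!r} not found in obs "
                f"(available: {list(obs.columns)})"
            )
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    samples = obs[sample_key].astype(str).to_numpy()
    meta = (
        pd.DataFrame({"sample": samples, "age": obs[age_key].to_numpy()})
        .groupby("sample", sort=False)
        .agg(age=("age", "first"), _n=("age", "nunique"))
    )
    conflict = meta.index[meta["_n"] > 1]
    if len(conflict):
        raise DatasetError(f"conflicting ages within samples: {list(conflict)}")
    meta = meta.drop(columns="_n")
    ages_num = pd.to_numeric(meta["age"].astype(str).str.replace("m", ""), errors="coerce")
    bad = meta.index[ages_num.isna()]
    if len(bad):
        raise DatasetError(f"non-numeric age for samples: {list(bad)}")
    meta["age"] = ages_num
    annot_cols = [c for c in obs.columns if c not in (sample_key, age_key)]
    annotations = obs[annot_cols].reset_index(drop=True) if annot_cols else None
    return CellExpressionDataset(
        expression=np.asarray(X, dtype=float),
        gene_ids=list(map(str, adata.var_names)),
        cell_sample_ids=samples,
        sample_metadata=meta,
        cell_annotations=annotations,
    )


def _read_dir(path: str, fmt: str, sample_key: str, age_key: str) -> CellExpressionDataset:
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", dtype=str)
    samples = pd.read_csv(os.path.join(path, "samples.tsv"), sep="\t")
    if sample_key not in cells.columns:
        raise MissingColumnError(
            f"column {sample_key!r} not found in cells.tsv "
            f"(available: {list(cells.columns)})"
        )
    if age_key not in samples.columns:
        raise MissingColumnError(
            f"column {age_key!r} not found in samples.tsv "
            f"(available: {list(samples.columns)})"
        )
    samples = samples.set_index(samples.columns[0])
    samples.index = samples.index.map(str)
    meta = samples.rename(columns={age_key: "age"})

    if fmt == "mtx":
        from scipy.io import mmread

        mat = mmread(os.path.join(path, "matrix.mtx"))
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        X = np.asarray(mat, dtype=float)
        gene_ids = (
            pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)[0]
            .astype(str)
            .tolist()
        )
    else:
        expr = pd.read_csv(os.path.join(path, "expression.tsv"), sep="\t", index_col=0)
        X = expr.to_numpy(dtype=float)
        gene_ids = list(map(str, expr.columns))

    if X.shape[0] != len(cells):
        raise DatasetError(
            f"matrix has {X.shape[0]} cells but cells.tsv lists {len(cells)}"
        )
    annot_cols = [c for c in cells.columns if c not in ("cell_id", sample_key)]
    annotations = cells[annot_cols] if annot_cols else None
    return CellExpressionDataset(
        expression=X,
        gene_ids=gene_ids,
        cell_sample_ids=cells[sample_key].astype(str).to_numpy(),
        sample_metadata=meta,
        cell_annotations=annotations,
    )


def write_dataset(ds: CellExpressionDataset, path: str, format: str = "h5ad") -> None:
    """Write a dataset in any supported format (inverse of :func:`read_dataset`)."""
    if format == "h5ad":
        import anndata as ad

        obs = pd.DataFrame({"sample_id": [str(s) for s in ds.cell_sample_ids]})
        for col in ds.sample_metadata.columns:
            obs[col] = ds.sample_metadata[col].reindex(obs["sample_id"]).to_numpy()
        if ds.cell_annotations is not None:
            for col in ds.cell_annotations.columns:
                obs[col] = ds.cell_annotations[col].to_numpy()
        obs.index = obs.index.map(str)
        adata = ad.AnnData(X=ds.expression.copy(), obs=obs)
        adata.var_names = ds.gene_ids
        adata.write_h5ad(path)
        return

    os.makedirs(path, exist_ok=True)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(ds.n_cells)],
            "sample_id": [str(s) for s in ds.cell_sample_ids],
        }
    )
    if ds.cell_annotations is not None:
        for col in ds.cell_annotations.columns:
            cells[col] = ds.cell_annotations[col].to_numpy()
    cells.to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)
    meta = ds.sample_metadata.reset_index(names="sample_id")
    meta.to_csv(os.path.join(path, "samples.tsv"), sep="\t", index=False)

    if format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(os.path.join(path, "matrix.mtx"), coo_matrix(ds.expression))
        with open(os.path.join(path, "genes.tsv"), "w") as fh:
            fh.write("\n".join(ds.gene_ids) + "\n")
    elif format == "dense_tsv":
        expr = pd.DataFrame(ds.expression, index=cells["cell_id"], columns=ds.gene_ids)
        expr.to_csv(os.path.join(path, "expression.tsv"), sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_results(table: pd.DataFrame, path: str) -> None:
    """Write an association table as TSV, ordered by descending rho then gene id.

    Undefined correlations (NaN rho) sort last. Round-trips through
    :func:`read_results`.
    """
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise MissingColumnError(f"association table lacks columns: {missing}")
    out = table.loc[:, RESULT_COLUMNS].copy()
    out = out.sort_values(
        ["rho", "gene_id"], ascending=[False, True], na_position="last", kind="stable"
    )
    out.to_csv(path, sep="\t", index=False)


def read_results(path: str) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in tbl.columns]
    if missing:
        raise MissingColumnError(f"results file lacks columns: {missing}")
    return tbl
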