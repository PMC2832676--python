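"""Reading and normalizing expression compendia.

A compendium is a collection of expression datasets, each a genes x arrays
matrix of log-ratio-scale values with possible missing entries.  Before any
downstream analysis every dataset is normalized with a fixed pipeline:

1. genes observed in less than half of the arrays are removed,
2. remaining missing values are filled by K-nearest-neighbour imputation
   (K = 10, Euclidean distance over mutually observed arrays),
3. technical replicate arrays are averaged.

The result is a complete, replicate-collapsed matrix per dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ExpressionDataset",
    "Compendium",
    "read_expression",
    "read_replicate_map",
    "filter_sparse_genes",
    "knn_impute",
    "average_replicates",
    "normalize",
    "write_expression",
]

#: cell contents interpreted as missing (case-insensitive)
MISSING_TOKENS = {"", "na", "nan", "null", "none"}

#: PCL bookkeeping column headers that are parsed and dropped from values
_PCL_META_COLUMNS = {"NAME", "GWEIGHT"}


@dataclass
class ExpressionDataset:
    """One experiment's genes x arrays expression matrix.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in ``array_ids[j]``;
    ``missing_mask`` is True where the value is unobserved.  ``replicate_groups``
    partitions ``array_ids`` into technical-replicate sets (singletons allowed).
    """

    dataset_id: str
    gene_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    replicate_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask must have the same shape")
        if self.values.shape != (len(self.gene_ids), len(self.array_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.array_ids)} arrays"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in dataset")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise ValueError("duplicate array ids in dataset")
        if not self.replicate_groups:
            self.replicate_groups = [[a] for a in self.array_ids]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_arrays(self, array_indices: np.ndarray) -> "ExpressionDataset":
        """Column-restricted copy (replicate groups collapse to singletons)."""
        idx = np.asarray(array_indices, dtype=int)
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            gene_ids=list(self.gene_ids),
            array_ids=[self.array_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )


@dataclass
class Compendium:
    """A collection of expression datasets with unique ids."""

    datasets: list[ExpressionDataset]

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset ids in compendium")

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for d in self.datasets:
            out.update(d.gene_ids)
        return out

    def __getitem__(self, dataset_id: str) -> ExpressionDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)


def _parse_cell(text: str) -> float:
    t = text.strip()
    if t.lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(t)
    except ValueError:
        return math.nan


def read_expression(path: str | Path, dialect: str = "auto") -> ExpressionDataset:
    """Read a PCL or plain-TSV expression file.

    The first column holds gene identifiers and the header row array
    identifiers.  The PCL dialect may carry NAME / GWEIGHT columns and an
    EWEIGHT row, which are recognized and excluded from the value matrix.
    Empty or non-numeric cells become missing values.  No normalization is
    applied.

    Parameters
    ----------
    path:
        Tab-separated input file.
    dialect:
        ``"pcl"``, ``"tsv"`` or ``"auto"`` (PCL when the header contains
        NAME/GWEIGHT or the extension is .pcl).
    """
    path = Path(path)
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row and at least one gene row")
    header = rows[0]
    if dialect == "auto":
        is_pcl = path.suffix.lower() == ".pcl" or any(
            h.strip().upper() in _PCL_META_COLUMNS for h in header[1:3]
        )
        dialect = "pcl" if is_pcl else "tsv"
    if dialect not in {"pcl", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")

    meta_cols: list[int] = []
    if dialect == "pcl":
        meta_cols = [
            j for j, h in enumerate(header) if j > 0 and h.strip().upper() in _PCL_META_COLUMNS
        ]
    keep_cols = [j for j in range(1, len(header)) if j not in meta_cols]
    array_ids = [header[j].strip() for j in keep_cols]

    gene_ids: list[str] = []
    seen: set[str] = set()
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        gene = row[0].strip()
        if dialect == "pcl" and gene.upper() == "EWEIGHT":
            continue
        if len(row) != len(header):
            raise ValueError(
                f"{path}: line {lineno} has {len(row)} fields, expected {len(header)}"
            )
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene id {gene!r}")
        seen.add(gene)
        gene_ids.append(gene)
        data.append([_parse_cell(row[j]) for j in keep_cols])

    values = np.array(data, dtype=float)
    return ExpressionDataset(
        dataset_id=path.stem,
        gene_ids=gene_ids,
        array_ids=array_ids,
        values=values,
        missing_mask=np.isnan(values),
    )


def read_replicate_map(path: str | Path, ds: ExpressionDataset) -> list[list[str]]:
    """Read a two-column TSV (array_id, group) into replicate groups.

    Arrays absent from the map become singleton groups.
    """
    group_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            array_id, group = line.split("\t")[:2]
            group_of[array_id] = group
    groups: dict[str, list[str]] = {}
    for a in ds.array_ids:
        groups.setdefault(group_of.get(a, a), []).append(a)
    return list(groups.values())


def filter_sparse_genes(
    ds: ExpressionDataset, log: dict | None = None
) -> ExpressionDataset:
    """Remove genes represented in less than half of the arrays.

    A gene observed in exactly half of the arrays is retained.  Removed gene
    ids are appended to ``log["removed_genes"]`` when a log dict is given.
    """
    observed = (~ds.missing_mask).sum(axis=1)
    keep = observed * 2 >= ds.n_arrays
    if not keep.any():
        raise ValueError(f"{ds.dataset_id}: no gene is observed in half of the arrays")
    if log is not None:
        log.setdefault("removed_genes", []).extend(
            [g for g, k in zip(ds.gene_ids, keep) if not k]
        )
    if keep.all():
        return ds
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
        array_ids=list(ds.array_ids),
        values=ds.values[keep],
        missing_mask=ds.missing_mask[keep],
        replicate_groups=[list(g) for g in ds.replicate_groups],
    )


def knn_impute(
    ds: ExpressionDataset, k: int = 10, log: dict | None = None
) -> ExpressionDataset:
    """Fill missing cells by averaging the K nearest genes (Euclidean).

    The distance between two genes is the mean squared difference over the
    arrays where both are observed (per-array scaling, so different overlap
    sizes are comparable).  A missing cell (gene g, array a) is replaced by
    the mean value at a of the k genes nearest to g that are observed at a.
    If no eligible neighbour exists the gene's own row mean is used and a
    fallback is counted in the log.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ds.missing_mask.any():
        return ds

    X = ds.values.copy()
    mask = ds.missing_mask
    obs = ~mask
    n = ds.n_genes

    # pairwise mean-squared-difference distances over mutually observed arrays
    Xz = np.where(obs, X, 0.0)
    obs_f = obs.astype(float)
    overlap = obs_f @ obs_f.T
    sq = Xz**2
    cross = Xz @ Xz.T
    ssq = sq @ obs_f.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (ssq + ssq.T - 2.0 * cross) / overlap
    dist[overlap == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    fallbacks = 0
    out = X.copy()
    for g in np.flatnonzero(mask.any(axis=1)):
        order = np.argsort(dist[g], kind="stable")
        order = order[np.isfinite(dist[g][order])]
        row_mean = X[g][obs[g]].mean() if obs[g].any() else 0.0
        for a in np.flatnonzero(mask[g]):
            neighbors = order[obs[order, a]][:k]
            if neighbors.size == 0:
                out[g, a] = row_mean
                fallbacks += 1
            else:
                out[g, a] = X[neighbors, a].mean()
    if log is not None:
        log["imputation_fallbacks"] = log.get("imputation_fallbacks", 0) + fallbacks
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        gene_ids=list(ds.gene_ids),
        array_ids=list(ds.array_ids),
        values=out,
        missing_mask=np.zeros_like(mask),
        replicate_groups=[list(g) for g in ds.replicate_groups],
    )


def average_replicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Collapse each technical-replicate group to its arithmetic mean array.

    Output arrays are named after the group's first member and ordered by
    group order; missing values (if any remain) are ignored in the mean.
    """
    groups = ds.replicate_groups
    col = {a: j for j, a in enumerate(ds.array_ids)}
    new_ids = [g[0] for g in groups]
    new_vals = np.empty((ds.n_genes, len(groups)))
    new_mask = np.empty((ds.n_genes, len(groups)), dtype=bool)
    for j, g in enumerate(groups):
        idx = [col[a] for a in g]
        vals = ds.values[:, idx]
        mm = ds.missing_mask[:, idx]
        with np.errstate(invalid="ignore"):
            mean = np.where(
                (~mm).any(axis=1),
                np.nansum(np.where(mm, np.nan, vals), axis=1) / (~mm).sum(axis=1),
                np.nan,
            )
        new_vals[:, j] = mean
        new_mask[:, j] = mm.all(axis=1)
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        gene_ids=list(ds.gene_ids),
        array_ids=new_ids,
        values=new_vals,
        missing_mask=new_mask,
    )


def normalize(
    ds: ExpressionDataset, k: int = 10, log: dict | None = None
) -> ExpressionDataset:
    """Full normalization pipeline: filter sparse genes, impute, average replicates."""
    if log is None:
        log = {}
    log["dataset_id"] = ds.dataset_id
    out = average_replicates(knn_impute(filter_sparse_genes(ds, log), k=k, log=log))
    assert not out.missing_mask.any()
    return out


def write_expression(ds: ExpressionDataset, path: str | Path, fmt: str = "%.6g") -> None:
    """Write a dataset as a plain TSV (gene ids in column 1, array ids in row 1)."""
    with open(path, "w") as fh:
        fh.write("GENE\t" + "\t".join(ds.array_ids) + "\n")
        for g, row, mrow in zip(ds.gene_ids, ds.values, ds.missing_mask):
            cells = ["" if m else fmt % v for v, m in zip(row, mrow)]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def write_log(log: dict, path: str | Path) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(log) + "\n")
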