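"""Reading standard formats and Seurat-style preprocessing.

Counts are held genes x cells (the orientation of MatrixMarket exports with
gene and cell sidecar files).  Preprocessing follows the usual single-cell
recipe: per-cell library-size normalization to a fixed scale factor with a
log1p transform, regression of a nuisance label (tumour of origin) out of the
normalized values, and per-gene centering/scaling.  QC filters drop genes
expressed in too few cells and cells whose library size is an outlier on the
log10 scale.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

logger = logging.getLogger(__name__)

SPIKE_IN_PREFIX = "ERCC"


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with aligned per-cell metadata.

    ``counts`` may be dense or scipy-sparse; ``cell_meta`` is indexed by
    cell id and carries at least ``region`` (core/periphery) and
    ``tumor_id`` when produced by the readers or the synthetic generator.
    """

    counts: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"cell_meta rows {len(self.cell_meta)} != matrix columns {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if self.cell_meta.index.duplicated().any():
            raise ValueError("duplicate cell ids")
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size and data.min() < 0:
            raise ValueError("negative counts")

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.cell_meta.index, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        m = self.counts.tocsr() if sp.issparse(self.counts) else self.counts
        return CountMatrix(m[mask_or_idx, :], self.gene_ids[mask_or_idx], self.cell_meta)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        sel = np.asarray(mask_or_idx)
        if sel.dtype == bool:
            sel = np.where(sel)[0]
        m = self.counts.tocsc() if sp.issparse(self.counts) else self.counts
        return CountMatrix(m[:, sel], self.gene_ids, self.cell_meta.iloc[sel])

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


@dataclass
class NormMatrix:
    """Real-valued gene x cell matrix with a record of the applied steps."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame
    transform_log: list = field(default_factory=list)
    scale_factor: float = 10000.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.cell_meta.index, dtype=object)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)


def _strip_spike_ins(counts, gene_ids):
    keep = ~np.char.startswith(
        np.char.upper(np.asarray(gene_ids, dtype=str)), SPIKE_IN_PREFIX
    )
    if not keep.all():
        logger.info("removed %d spike-in genes (prefix %s)", (~keep).sum(), SPIKE_IN_PREFIX)
        counts = counts.tocsr()[keep, :] if sp.issparse(counts) else counts[keep, :]
        gene_ids = np.asarray(gene_ids, dtype=object)[keep]
    return counts, np.asarray(gene_ids, dtype=object)


def read_counts(path, format: str = "mtx") -> CountMatrix:
    """Read a count matrix from MTX-with-sidecars or a dense TSV.

    For ``format='mtx'``, ``path`` is the matrix file; ``genes.tsv`` and
    ``cells.tsv`` are looked up next to it (``cells.tsv`` needs columns
    cell_id, region, tumor_id).  For ``format='tsv'`` the file is a dense
    genes x cells table whose header row holds cell ids; region/tumor
    metadata default to placeholders unless a ``cells.tsv`` sits alongside.
    Spike-in genes (ERCC prefix, case-insensitive) are dropped.
    """
    path = Path(path)
    if format == "mtx":
        with _open_maybe_gzip(path) as fh:
            mat = mmread(fh).tocsr()
        gene_file = path.parent / "genes.tsv"
        cell_file = path.parent / "cells.tsv"
        genes = pd.read_csv(gene_file, sep="\t", header=None).iloc[:, 0].astype(str).values
        meta = pd.read_csv(cell_file, sep="\t")
        if "cell_id" not in meta.columns:
            raise ValueError(f"{cell_file} lacks a cell_id column")
        meta = meta.set_index("cell_id")
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"{gene_file} lists {len(genes)} genes but {path.name} declares {mat.shape[0]} rows"
            )
        if mat.shape[1] != len(meta):
            raise ValueError(
                f"{cell_file} lists {len(meta)} cells but {path.name} declares {mat.shape[1]} columns"
            )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = sp.csr_matrix(df.values)
        genes = df.index.astype(str).values
        cell_file = path.parent / "cells.tsv"
        if cell_file.exists():
            meta = pd.read_csv(cell_file, sep="\t").set_index("cell_id")
            meta = meta.loc[df.columns]
        else:
            meta = pd.DataFrame(
                {"region": "core", "tumor_id": "NA"}, index=df.columns.astype(str)
            )
            meta.index.name = "cell_id"
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx' or 'tsv'")
    mat, genes = _strip_spike_ins(mat, genes)
    return CountMatrix(mat, genes, meta)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: set name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def lognormalize(m: CountMatrix, scale_factor: float = 10000.0) -> NormMatrix:
    """log1p of library-size-normalized counts.

    value(g, c) = log(1 + count(g, c) / total(c) * scale_factor).  Cells with
    zero total counts are dropped with a warning.
    """
    totals = m.cell_totals()
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} zero-total cells before log-normalization")
        m = m.subset_cells(keep)
        totals = totals[keep]
    dense = m.dense().astype(float)
    vals = np.log1p(dense / totals[None, :] * scale_factor)
    return NormMatrix(vals, m.gene_ids, m.cell_meta, ["lognorm"], float(scale_factor))


def regress_out_label(m: NormMatrix, labels) -> NormMatrix:
    """Replace each gene's values by residuals of an indicator regression on `labels`.

    Least squares on label indicators plus intercept; for a categorical
    design this equals subtracting each label group's mean, so within-label
    means are exactly zero afterwards.
    """
    labels = np.asarray(labels)
    if len(labels) != m.values.shape[1]:
        raise ValueError("labels must cover all cells")
    out = m.values.copy()
    for lab in pd.unique(labels):
        idx = labels == lab
        if idx.sum() == 1:
            warnings.warn(f"label {lab!r} has a single cell; its residuals are 0")
        out[:, idx] -= out[:, idx].mean(axis=1, keepdims=True)
    return NormMatrix(
        out, m.gene_ids, m.cell_meta, m.transform_log + ["regressed"], m.scale_factor
    )


def center_scale(m: NormMatrix, scale: bool = True) -> NormMatrix:
    """Per-gene centering and (population-SD) unit scaling; zero-variance genes stay 0."""
    vals = m.values - m.values.mean(axis=1, keepdims=True)
    steps = ["centered"]
    if scale:
        sd = vals.std(axis=1, keepdims=True)
        nz = sd.ravel() > 0
        vals[nz, :] = vals[nz, :] / sd[nz, :]
        steps.append("scaled")
    return NormMatrix(
        vals, m.gene_ids, m.cell_meta, m.transform_log + steps, m.scale_factor
    )


def filter_genes_min_cells(m: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Keep genes with a nonzero count in at least `min_cells` cells."""
    ncells_expr = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    keep = ncells_expr >= min_cells
    if not keep.any():
        raise ValueError(f"no gene is expressed in >= {min_cells} cells")
    return m.subset_genes(keep)


def filter_cells_depth_outliers(m: CountMatrix, n_sd: float = 2.0) -> CountMatrix:
    """Drop cells whose log10 total counts lie outside `n_sd` SDs of the mean."""
    if m.n_cells < 3:
        raise ValueError("need at least 3 cells")
    totals = m.cell_totals()
    pos = totals > 0
    if not pos.all():
        warnings.warn(f"removing {(~pos).sum()} zero-total cells before the log10 depth filter")
        m = m.subset_cells(pos)
        totals = totals[pos]
    lt = np.log10(totals)
    mu, sd = lt.mean(), lt.std()
    keep = np.abs(lt - mu) <= n_sd * sd if sd > 0 else np.ones(len(lt), bool)
    return m.subset_cells(keep)


def expression_fraction(m: CountMatrix, genes: Sequence[str]) -> pd.Series:
    """Fraction of cells with count > 0 for each requested gene (0 if absent)."""
    lookup = {g: i for i, g in enumerate(m.gene_ids)}
    expr = np.asarray((m.counts > 0).sum(axis=1)).ravel() / m.n_cells
    out = {}
    missing = []
    for g in genes:
        if g in lookup:
            out[g] = expr[lookup[g]]
        else:
            missing.append(g)
            out[g] = 0.0
    if missing:
        warnings.warn(f"{len(missing)} genes absent from matrix: {missing[:5]}")
    return pd.Series(out, dtype=float)
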