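"""Reading, quality control and normalization of 10x-style count matrices.

The substrate of the pipeline is an :class:`ExpressionMatrix`: a sparse
cells x genes matrix of UMI counts together with per-cell metadata
(patient, sample, timepoint, batch, clinical outcome).  QC follows the
standard droplet conventions: cells expressing fewer than
``min_genes_per_cell`` distinct genes or with a mitochondrial UMI
fraction above ``max_mito_fraction`` are removed; surviving cells are
library-size scaled to ``target_sum`` and log1p-transformed.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "QCParams",
    "NormalizedMatrix",
    "read_10x",
    "read_h5ad",
    "write_10x",
    "read_metadata",
    "compute_mito_fraction",
    "qc_filter",
    "normalize_log",
]

#: metadata columns every cell annotation table must provide
REQUIRED_META_COLUMNS = ("patient", "sample", "timepoint", "batch", "outcome")


@dataclass
class ExpressionMatrix:
    """Sparse cells x genes UMI counts with aligned per-cell metadata."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids has {len(self.cell_ids)} entries for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValueError("counts must be integral")
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_cells} cells"
            )
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta.index = pd.Index(self.cell_ids, name="cell_id")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            counts=self.counts[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx],
        )


@dataclass(frozen=True)
class QCParams:
    """Cell-level QC thresholds and normalization target.

    ``min_genes_per_cell``: keep cells with at least this many genes
    detected (count > 0); the default 200 encodes the usual "fewer than
    200 genes" removal rule as a strict ``< 200`` cut.
    ``max_mito_fraction``: keep cells whose mitochondrial UMI fraction is
    at most this value (strictly greater is removed).
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.10
    target_sum: float = 1e4
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not (0 < self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be > 0")


@dataclass
class NormalizedMatrix:
    """log1p of library-size-scaled counts, with provenance."""

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    provenance: QCParams = field(default_factory=QCParams)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_index(self, genes: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            values=self.values[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            provenance=self.provenance,
        )


def _find_file(dir_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dir_path / (stem + suffix)
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} (or .gz) found in {dir_path}")


def _read_tsv_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return rows


def read_10x(dir_path: str | Path, metadata: str | Path | None = None) -> ExpressionMatrix:
    """Read a 10x-style directory (matrix.mtx[.gz] + barcodes/features TSV).

    The on-disk matrix may be either genes x cells (the 10x convention)
    or cells x genes; orientation is resolved against the barcode and
    feature list lengths.  If ``metadata`` is not given and a
    ``metadata.tsv`` file is present in the directory it is used.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_file(dir_path, ("matrix.mtx",))
    barcodes = _read_tsv_column(_find_file(dir_path, ("barcodes.tsv",)))
    features = _read_tsv_column(_find_file(dir_path, ("features.tsv", "genes.tsv")))
    if not barcodes:
        raise ValueError(f"empty barcodes file in {dir_path}")
    if not features:
        raise ValueError(f"empty features file in {dir_path}")

    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    n_b, n_f = len(barcodes), len(features)
    if mat.shape == (n_f, n_b) and n_f != n_b:
        mat = sp.csr_matrix(mat.T)
    elif mat.shape == (n_b, n_f):
        pass
    elif mat.shape == (n_f, n_b):  # square case: assume genes x cells on disk
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {n_b} barcodes x {n_f} features "
            f"nor its transpose"
        )

    if metadata is None:
        candidate = dir_path / "metadata.tsv"
        metadata = candidate if candidate.exists() else None
    if metadata is not None:
        meta = read_metadata(metadata)
        meta = meta.reindex(barcodes)
        if meta.isna().all(axis=1).any():
            missing = meta.index[meta.isna().all(axis=1)][:5].tolist()
            raise ValueError(f"metadata missing for barcodes, e.g. {missing}")
    else:
        meta = pd.DataFrame(
            {c: ["unknown"] * n_b for c in REQUIRED_META_COLUMNS},
            index=pd.Index(barcodes, name="cell_id"),
        )
    return ExpressionMatrix(mat, features, barcodes, meta)


def write_10x(m: ExpressionMatrix, dir_path: str | Path) -> Path:
    """Write MTX (genes x cells, 10x convention) + barcodes/features/metadata TSV."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(m.counts.T))
    (dir_path / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
    (dir_path / "features.tsv").write_text("\n".join(m.gene_ids) + "\n")
    meta = m.cell_meta.reset_index()
    meta.to_csv(dir_path / "metadata.tsv", sep="\t", index=False)
    return dir_path


def read_h5ad(path: str | Path) -> ExpressionMatrix:
    """Read an AnnData .h5ad container into the same contract as read_10x.

    Expects raw counts in ``X`` (or ``layers['counts']``) and the required
    metadata columns in ``obs``.
    """
    import anndata

    adata = anndata.read_h5ad(path)
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    missing = [c for c in REQUIRED_META_COLUMNS if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"{path}: obs lacks required metadata columns {missing}")
    return ExpressionMatrix(
        counts=sp.csr_matrix(X),
        gene_ids=adata.var_names.tolist(),
        cell_ids=adata.obs_names.tolist(),
        cell_meta=adata.obs[list(REQUIRED_META_COLUMNS)].astype(str),
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cell metadata TSV/CSV with required columns, indexed by cell_id."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    meta = pd.read_csv(path, sep=sep)
    if "cell_id" not in meta.columns:
        raise ValueError(f"{path} lacks a cell_id column")
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path} lacks required metadata columns: {missing}")
    return meta.set_index("cell_id")


def compute_mito_fraction(m: ExpressionMatrix, prefix: str = "MT-") -> np.ndarray:
    """Per-cell fraction of UMIs on genes whose id starts with ``prefix``.

    Matching is case-insensitive.  Cells with zero total counts get
    fraction 0 (flagged via a warning).
    """
    pfx = prefix.upper()
    mito_cols = np.array([g.upper().startswith(pfx) for g in m.gene_ids])
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    mito = (
        np.asarray(m.counts[:, mito_cols].sum(axis=1)).ravel()
        if mito_cols.any()
        else np.zeros(m.n_cells)
    )
    frac = np.zeros(m.n_cells)
    nonzero = totals > 0
    frac[nonzero] = mito[nonzero] / totals[nonzero]
    if (~nonzero).any():
        warnings.warn(f"{(~nonzero).sum()} cells have zero total counts; mito fraction set to 0")
    return frac


def qc_filter(m: ExpressionMatrix, p: QCParams | None = None) -> ExpressionMatrix:
    """Remove low-quality cells; genes are never filtered.

    A cell is retained iff it detects at least ``min_genes_per_cell``
    genes (count > 0) and its mitochondrial fraction does not exceed
    ``max_mito_fraction``.  Raises if no cell survives.
    """
    p = p or QCParams()
    n_detected = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    mito = compute_mito_fraction(m, p.mito_prefix)
    keep = (n_detected >= p.min_genes_per_cell) & (mito <= p.max_mito_fraction)
    if not keep.any():
        raise ValueError(
            f"QC removed all {m.n_cells} cells "
            f"(min_genes_per_cell={p.min_genes_per_cell}, max_mito_fraction={p.max_mito_fraction})"
        )
    return m.subset_cells(keep)


def normalize_log(m: ExpressionMatrix, p: QCParams | None = None) -> NormalizedMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p."""
    p = p or QCParams()
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(
            f"{(totals == 0).sum()} cells have zero total counts; run qc_filter first"
        )
    scale = p.target_sum / totals
    values = sp.csr_matrix(m.counts, dtype=float)
    values = sp.diags(scale) @ values
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        cell_meta=m.cell_meta.copy(),
        provenance=p,
    )
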