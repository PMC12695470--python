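"""Count-matrix IO, cell quality control, log-normalization, scaling and PCA.

The conventions follow the standard droplet snRNA-seq workflow: a sparse
genes x cells integer count matrix read from matrix-market triplets with
companion ``genes.tsv`` / ``barcodes.tsv`` tables, cell filtering on detected
genes, total counts and mitochondrial fraction, per-cell log-normalization
``ln(1 + scale_factor * count / cell_total)``, per-gene z-scaling with
clipping, and PCA on the scaled matrix.

Boundary semantics for QC are strict-inequality *removal*: a cell with
exactly ``min_genes`` detected genes, exactly ``min_counts`` total counts or
a mitochondrial fraction exactly at ``max_mito_frac`` is retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from sklearn.decomposition import PCA

from cotransmit.errors import FormatError, CotransmitError

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "NormalizedMatrix",
    "Embedding",
    "read_counts",
    "write_counts",
    "qc_filter",
    "lognormalize",
    "scale_genes",
    "pca",
]

MITO_PREFIX = "mt-"


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell count matrix with identifiers."""

    values: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        self.values.eliminate_zeros()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene table has {len(self.gene_ids)} entries but matrix has {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"barcode table has {len(self.cell_ids)} entries but matrix has {n_cells} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()[:5]
                raise FormatError(f"duplicate {name} identifiers: {list(dupes)}")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[:, mask], self.gene_ids, self.cell_ids[mask])


@dataclass
class QCThresholds:
    """Cell-filter thresholds. Removal criteria are strict inequalities."""

    min_genes: int = 300
    max_genes: int = 6000
    min_counts: int = 500
    max_mito_frac: float = 0.01
    drop_doublets: bool = True

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise CotransmitError("QCThresholds: min_genes must be < max_genes")
        if min(self.min_genes, self.min_counts) < 0 or self.max_mito_frac < 0:
            raise CotransmitError("QCThresholds: thresholds must be non-negative")


@dataclass
class QCReport:
    """Removal bookkeeping. Per-criterion counts overlap; ``removed_total`` does not."""

    cells_in: int
    cells_out: int
    removed_low_genes: int
    removed_high_genes: int
    removed_low_counts: int
    removed_high_mito: int
    removed_doublets: int
    mito_criterion_applied: bool
    thresholds: QCThresholds

    @property
    def removed_total(self) -> int:
        return self.cells_in - self.cells_out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cells_in", self.cells_in),
            ("cells_out", self.cells_out),
            ("removed_total", self.removed_total),
            ("removed_low_genes", self.removed_low_genes),
            ("removed_high_genes", self.removed_high_genes),
            ("removed_low_counts", self.removed_low_counts),
            ("removed_high_mito", self.removed_high_mito),
            ("removed_doublets", self.removed_doublets),
            ("mito_criterion_applied", int(self.mito_criterion_applied)),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_json(self) -> str:
        d = {m: int(v) for m, v in self.to_frame().itertuples(index=False)}
        d["thresholds"] = {
            "min_genes": self.thresholds.min_genes,
            "max_genes": self.thresholds.max_genes,
            "min_counts": self.thresholds.min_counts,
            "max_mito_frac": self.thresholds.max_mito_frac,
            "drop_doublets": self.thresholds.drop_doublets,
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class NormalizedMatrix:
    """Log-normalized genes x cells matrix; zero iff the raw count was zero."""

    values: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 1e4
    transform: str = "ln(1 + scale_factor * count / cell_total)"

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not present in the matrix")
        return int(idx[0])


@dataclass
class Embedding:
    """PCA coordinates (cells x components), ordered by decreasing variance."""

    coordinates: np.ndarray
    explained_variance: np.ndarray
    cell_ids: np.ndarray
    n_components: int = 16


# ---------------------------------------------------------------------------
# IO


def _read_id_column(path: str | Path, what: str) -> np.ndarray:
    tab = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if tab.shape[1] < 1 or tab.empty and tab.shape[0] == 0:
        return np.asarray([], dtype=object)
    return tab.iloc[:, 0].to_numpy(dtype=object)


def read_counts(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a matrix-market triplet file plus gene / barcode TSV tables.

    Round-trips losslessly with :func:`write_counts`.
    """
    for p in (mtx_path, genes_path, barcodes_path):
        if not Path(p).exists():
            raise FormatError(f"input file not found: {p}")
    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"{mtx_path}: not a valid matrix-market file ({exc})") from exc
    mat = sparse.csr_matrix(mat)
    genes = np.asarray([], dtype=object)
    barcodes = np.asarray([], dtype=object)
    if mat.shape[0] > 0:
        genes = _read_id_column(genes_path, "gene")
    if mat.shape[1] > 0:
        barcodes = _read_id_column(barcodes_path, "barcode")
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative count entries")
    if not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path}: non-integer count entries")
    mat = mat.astype(np.int64)
    try:
        return CountMatrix(mat, genes, barcodes)
    except FormatError as exc:
        raise FormatError(f"{mtx_path} / {genes_path} / {barcodes_path}: {exc}") from exc


def write_counts(counts: CountMatrix, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / f"{prefix}matrix.mtx",
        "genes": out / f"{prefix}genes.tsv",
        "barcodes": out / f"{prefix}barcodes.tsv",
    }
    spio.mmwrite(str(paths["mtx"]), counts.values.tocoo(), field="integer")
    pd.Series(counts.gene_ids).to_csv(paths["genes"], sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return paths


# ---------------------------------------------------------------------------
# QC


def mito_mask(gene_ids: np.ndarray) -> np.ndarray:
    return np.array([str(g).lower().startswith(MITO_PREFIX) for g in gene_ids])


def qc_filter(
    counts: CountMatrix,
    meta: pd.DataFrame,
    thr: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Filter cells on detected genes, total counts, mito fraction and doublet flags.

    ``meta`` must be indexed (or indexable) by ``cell_id`` covering every cell
    and carry a boolean ``doublet`` column if ``thr.drop_doublets``.
    """
    thr = thr or QCThresholds()
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    missing = set(counts.cell_ids) - set(meta.index)
    if missing:
        raise CotransmitError(f"meta does not cover {len(missing)} cells, e.g. {sorted(missing)[:3]}")
    meta = meta.loc[counts.cell_ids]

    X = counts.values
    genes_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    total = np.asarray(X.sum(axis=0)).ravel()
    mito = mito_mask(counts.gene_ids)
    mito_applied = bool(mito.any())
    if mito_applied:
        mito_counts = np.asarray(X[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
        high_mito = mito_frac > thr.max_mito_frac
    else:
        warnings.warn("no genes with 'mt-' prefix found; mitochondrial criterion skipped")
        high_mito = np.zeros(counts.n_cells, dtype=bool)

    low_genes = genes_detected < thr.min_genes
    high_genes = genes_detected > thr.max_genes
    low_counts = total < thr.min_counts
    if thr.drop_doublets:
        if "doublet" not in meta.columns:
            raise CotransmitError("drop_doublets requested but meta has no 'doublet' column")
        doublet = meta["doublet"].astype(bool).to_numpy()
    else:
        doublet = np.zeros(counts.n_cells, dtype=bool)

    remove = low_genes | high_genes | low_counts | high_mito | doublet
    keep = ~remove
    report = QCReport(
        cells_in=counts.n_cells,
        cells_out=int(keep.sum()),
        removed_low_genes=int(low_genes.sum()),
        removed_high_genes=int(high_genes.sum()),
        removed_low_counts=int(low_counts.sum()),
        removed_high_mito=int(high_mito.sum()),
        removed_doublets=int(doublet.sum()),
        mito_criterion_applied=mito_applied,
        thresholds=thr,
    )
    return counts.subset_cells(keep), meta.loc[keep].reset_index().rename(columns={"index": "cell_id"}), report


# ---------------------------------------------------------------------------
# Normalization / scaling / PCA


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Per-cell log-normalization: ``ln(1 + scale_factor * count / cell_total)``."""
    total = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise CotransmitError(
            f"cells with zero total counts cannot be normalized: {list(counts.cell_ids[zero[:3]])}"
        )
    X = counts.values.astype(np.float64).tocsc()
    # scale each column by scale_factor / total, then log1p on stored entries
    X = X @ sparse.diags(scale_factor / total)
    X.data = np.log1p(X.data)
    return NormalizedMatrix(X.tocsr(), counts.gene_ids, counts.cell_ids, scale_factor=scale_factor)


def scale_genes(norm: NormalizedMatrix, clip: float = 10.0) -> np.ndarray:
    """Z-score each gene across cells (sample SD, ddof=1), clip to ``[-clip, clip]``.

    Constant genes become all-zero rows. Returns a dense genes x cells array.
    """
    if norm.values.shape[1] < 2:
        raise CotransmitError("scale_genes requires at least 2 cells")
    X = np.asarray(norm.values.todense(), dtype=np.float64)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(X)
    np.divide(X - mean, sd, out=out, where=sd > 0)
    np.clip(out, -clip, clip, out=out)
    return out


def pca(scaled: np.ndarray, n_components: int = 16, seed: int = 0) -> Embedding:
    """PCA of cells over the scaled genes x cells matrix.

    Deterministic for a fixed seed (up to per-component sign, which sklearn
    fixes by its own convention). Components are ordered by decreasing
    explained variance.
    """
    n_genes, n_cells = scaled.shape
    if n_components > min(n_genes, n_cells):
        raise CotransmitError(
            f"n_components={n_components} exceeds min(genes, cells)={min(n_genes, n_cells)}"
        )
    solver = "full" if min(n_genes, n_cells) <= 600 else "randomized"
    model = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    coords = model.fit_transform(scaled.T)
    return Embedding(
        coordinates=coords,
        explained_variance=model.explained_variance_,
        cell_ids=np.arange(n_cells),
        n_components=n_components,
    )
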