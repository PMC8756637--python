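"""Reading, filtering, and transforming paired single-cell RNA/ATAC matrices.

Input layouts mirror the 10x convention: a directory holding a matrix-market
file (features x cells) plus ``features.tsv`` and ``barcodes.tsv`` (gzipped
variants accepted), or a dense delimited table whose header row carries cell
IDs and whose first column carries feature IDs.  Matrices are held
cells-by-features in CSR form throughout the package.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger("pairedvae")

__all__ = [
    "JointProfile",
    "FilterSpec",
    "read_joint_profile",
    "filter_joint_profile",
    "tfidf_transform",
    "tfidf_inverse",
    "write_outputs",
    "write_triplet",
]


@dataclass
class JointProfile:
    """Paired per-cell count matrices with aligned cell identifiers.

    ``rna_counts`` and ``atac_counts`` are cells x features sparse matrices of
    raw counts; ``atac_tfidf``, when present, is the continuous TF-IDF
    transform of the peak matrix with the same sparsity pattern.
    """

    rna_counts: sparse.csr_matrix
    atac_counts: sparse.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    peak_ids: list[str]
    labels: list[str] | None = None
    atac_tfidf: sparse.csr_matrix | None = None

    def __post_init__(self):
        self.rna_counts = sparse.csr_matrix(self.rna_counts)
        self.atac_counts = sparse.csr_matrix(self.atac_counts)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        self.peak_ids = list(self.peak_ids)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def validate(self):
        n, g = self.rna_counts.shape
        n2, p = self.atac_counts.shape
        if n != n2 or n != len(self.cell_ids):
            raise ValueError(f"cell dimension mismatch: rna {n}, atac {n2}, ids {len(self.cell_ids)}")
        if g != len(self.gene_ids):
            raise ValueError(f"gene dimension mismatch: {g} vs {len(self.gene_ids)}")
        if p != len(self.peak_ids):
            raise ValueError(f"peak dimension mismatch: {p} vs {len(self.peak_ids)}")
        for name, ids in (("cell_ids", self.cell_ids), ("gene_ids", self.gene_ids),
                          ("peak_ids", self.peak_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contain duplicates")
        for name, m in (("rna_counts", self.rna_counts), ("atac_counts", self.atac_counts)):
            if m.nnz and m.data.min() < 0:
                raise ValueError(f"{name} has negative entries")
            if m.nnz and not np.allclose(m.data, np.round(m.data)):
                raise ValueError(f"{name} has non-integer entries")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match cell count")
        if self.atac_tfidf is not None:
            if self.atac_tfidf.shape != self.atac_counts.shape:
                raise ValueError("atac_tfidf shape differs from atac_counts")


@dataclass
class FilterSpec:
    """Quality thresholds: cells need >= ``min_features_per_cell`` detected
    genes AND peaks; features need >= ``min_cells_per_feature`` cells;
    ``max_cells_per_peak`` optionally drops near-ubiquitous peaks."""

    min_features_per_cell: int = 200
    min_cells_per_feature: int = 10
    max_cells_per_peak: int | None = None

    def __post_init__(self):
        if self.min_features_per_cell < 0 or self.min_cells_per_feature < 0:
            raise ValueError("thresholds must be >= 0")
        if self.max_cells_per_peak is not None and self.max_cells_per_peak <= self.min_cells_per_feature:
            raise ValueError("max_cells_per_peak must exceed min_cells_per_feature")


# ---------------------------------------------------------------------- read
def _open_maybe_gz(path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)


def _find(dirpath, stems):
    for stem in stems:
        for suffix in ("", ".gz"):
            p = os.path.join(dirpath, stem + suffix)
            if os.path.exists(p):
                return p
    raise FileNotFoundError(f"none of {stems} found under {dirpath}")


def _read_single(path):
    """Return (cells x features sparse matrix, barcodes, feature ids)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"input path does not exist: {path}")
    if os.path.isdir(path):
        mtx_path = _find(path, ["matrix.mtx"])
        feat_path = _find(path, ["features.tsv", "genes.tsv", "peaks.tsv"])
        bc_path = _find(path, ["barcodes.tsv"])
        with _open_maybe_gz(mtx_path) as fh:
            m = spio.mmread(fh)
        feats = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
        bcs = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
        m = sparse.csr_matrix(m.T)  # stored features x cells on disk
    else:
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        feats = df.index.astype(str).tolist()
        bcs = df.columns.astype(str).tolist()
        m = sparse.csr_matrix(df.to_numpy().T)
    if m.shape != (len(bcs), len(feats)):
        raise ValueError(f"matrix shape {m.shape} inconsistent with {len(bcs)} barcodes / {len(feats)} features")
    if m.nnz:
        if m.data.min() < 0:
            raise ValueError(f"negative entries in {path}")
        if not np.allclose(m.data, np.round(m.data)):
            raise ValueError(f"non-integer entries in {path}")
    return m.astype(np.int64), bcs, feats


def read_joint_profile(rna_path, atac_path) -> JointProfile:
    """Load both modalities and align them on the intersection of barcodes.

    Cell order follows the RNA file; a log line reports how many barcodes
    were dropped from each side.  Zero overlap is an error.
    """
    rna, rna_bcs, genes = _read_single(rna_path)
    atac, atac_bcs, peaks = _read_single(atac_path)
    atac_index = {b: i for i, b in enumerate(atac_bcs)}
    keep = [(i, atac_index[b]) for i, b in enumerate(rna_bcs) if b in atac_index]
    if not keep:
        raise ValueError("no overlapping cell barcodes between RNA and ATAC inputs")
    rna_idx = [i for i, _ in keep]
    atac_idx = [j for _, j in keep]
    dropped_rna = len(rna_bcs) - len(keep)
    dropped_atac = len(atac_bcs) - len(keep)
    log.info("barcode intersection: kept %d cells (dropped %d RNA-only, %d ATAC-only)",
             len(keep), dropped_rna, dropped_atac)
    return JointProfile(
        rna_counts=rna[rna_idx],
        atac_counts=atac[atac_idx],
        cell_ids=[rna_bcs[i] for i in rna_idx],
        gene_ids=genes,
        peak_ids=peaks,
    )


# -------------------------------------------------------------------- filter
def filter_joint_profile(jp: JointProfile, spec: FilterSpec) -> JointProfile:
    """Apply quality filtering: cells first, then features, in one pass.

    A cell is kept when it detects at least ``min_features_per_cell`` genes
    AND at least that many peaks; on the surviving cells, genes and peaks
    detected in fewer than ``min_cells_per_feature`` cells are removed, and
    peaks detected in more than ``max_cells_per_peak`` cells (when set) are
    removed as well.
    """
    genes_per_cell = np.asarray((jp.rna_counts > 0).sum(axis=1)).ravel()
    peaks_per_cell = np.asarray((jp.atac_counts > 0).sum(axis=1)).ravel()
    keep_cells = (genes_per_cell >= spec.min_features_per_cell) & \
                 (peaks_per_cell >= spec.min_features_per_cell)
    if not keep_cells.any():
        raise ValueError(f"filtering removed all {jp.n_cells} cells "
                         f"(min_features_per_cell={spec.min_features_per_cell})")
    rna = jp.rna_counts[keep_cells]
    atac = jp.atac_counts[keep_cells]

    cells_per_gene = np.asarray((rna > 0).sum(axis=0)).ravel()
    cells_per_peak = np.asarray((atac > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= spec.min_cells_per_feature
    keep_peaks = cells_per_peak >= spec.min_cells_per_feature
    if spec.max_cells_per_peak is not None:
        keep_peaks &= cells_per_peak <= spec.max_cells_per_peak
    if not keep_genes.any() or not keep_peaks.any():
        raise ValueError(f"filtering removed all features: {keep_genes.sum()} genes, "
                         f"{keep_peaks.sum()} peaks survive")
    cell_mask = keep_cells
    labels = [l for l, k in zip(jp.labels, cell_mask) if k] if jp.labels is not None else None
    log.info("filter: %d/%d cells, %d/%d genes, %d/%d peaks kept",
             int(keep_cells.sum()), jp.n_cells, int(keep_genes.sum()), len(jp.gene_ids),
             int(keep_peaks.sum()), len(jp.peak_ids))
    return JointProfile(
        rna_counts=rna[:, keep_genes],
        atac_counts=atac[:, keep_peaks],
        cell_ids=[c for c, k in zip(jp.cell_ids, cell_mask) if k],
        gene_ids=[g for g, k in zip(jp.gene_ids, keep_genes) if k],
        peak_ids=[p for p, k in zip(jp.peak_ids, keep_peaks) if k],
        labels=labels,
    )


# -------------------------------------------------------------------- tf-idf
def tfidf_transform(atac_counts, variant: str = "binary_tf", scale: float = 1e4) -> sparse.csr_matrix:
    """TF-IDF weighting of the peak matrix.

    Peaks are binarised to presence; term frequency is presence divided by
    the number of detected peaks in the cell; inverse document frequency is
    ``log(1 + N_cells / n_cells_with_peak)``; the product is multiplied by
    ``scale``.  Zeros are preserved exactly.  ``variant="raw_tf"`` uses the
    raw count instead of presence in the numerator.
    """
    m = sparse.csr_matrix(atac_counts)
    if m.nnz and m.data.min() < 0:
        raise ValueError("atac_counts must be non-negative")
    n_cells = m.shape[0]
    presence = m.copy()
    presence.data = (presence.data > 0).astype(np.float64)
    peaks_per_cell = np.asarray(presence.sum(axis=1)).ravel()
    if np.any(peaks_per_cell == 0):
        bad = int((peaks_per_cell == 0).sum())
        raise ValueError(f"{bad} cells have no detected peaks; filter cells before TF-IDF")
    df = np.asarray(presence.sum(axis=0)).ravel()
    idf = np.log1p(n_cells / np.maximum(df, 1.0))
    if variant == "binary_tf":
        tf = sparse.diags(1.0 / peaks_per_cell) @ presence
    elif variant == "raw_tf":
        tf = sparse.diags(1.0 / peaks_per_cell) @ m.astype(np.float64)
    else:
        raise ValueError(f"unknown TF-IDF variant: {variant!r}")
    out = tf @ sparse.diags(idf)
    out = out.multiply(scale).tocsr()
    out.eliminate_zeros()
    return out


def tfidf_inverse(values, atac_counts, scale: float = 1e4) -> np.ndarray:
    """Map a TF-IDF-space matrix back to presence/propensity scale.

    The forward transform multiplies presence by ``idf_j * scale / n_i``
    where ``n_i`` is the cell's detected-peak count and ``idf_j`` the peak's
    inverse document frequency, both computed from ``atac_counts``.  This
    undoes that deterministic weighting, so model-imputed TF-IDF rates can
    be compared with accessibility on the count scale.
    """
    values = np.asarray(values, dtype=np.float64)
    m = sparse.csr_matrix(atac_counts)
    presence = m.copy()
    presence.data = (presence.data > 0).astype(np.float64)
    n_i = np.asarray(presence.sum(axis=1)).ravel()
    df = np.asarray(presence.sum(axis=0)).ravel()
    idf = np.log1p(m.shape[0] / np.maximum(df, 1.0))
    return values * n_i[:, None] / (idf[None, :] * scale)


# --------------------------------------------------------------------- write
def write_triplet(matrix, feature_ids, cell_ids, out_dir):
    """Write a cells x features matrix as a 10x-style triplet directory."""
    os.makedirs(out_dir, exist_ok=True)
    m = sparse.coo_matrix(sparse.csr_matrix(matrix).T)  # features x cells on disk
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), m)
    pd.Series(list(feature_ids)).to_csv(os.path.join(out_dir, "features.tsv"),
                                        sep="\t", header=False, index=False)
    pd.Series(list(cell_ids)).to_csv(os.path.join(out_dir, "barcodes.tsv"),
                                     sep="\t", header=False, index=False)


def write_outputs(embedding, imputed_rna, imputed_atac, out_dir, *,
                  cell_ids, gene_ids, peak_ids):
    """Write the embedding table and imputed matrices under ``out_dir``.

    The embedding goes to ``embedding.tsv`` (cell column + ``z_1..z_D``
    headers, 6 decimal places); imputed matrices go to matrix-market triplet
    subdirectories ``imputed_rna/`` and ``imputed_atac/``.
    """
    embedding = np.asarray(embedding)
    if embedding.shape[0] == 0:
        raise ValueError("cannot write outputs for 0 cells")
    if embedding.shape[0] != len(cell_ids):
        raise ValueError("embedding rows do not match cell_ids")
    for name, m in (("imputed_rna", imputed_rna), ("imputed_atac", imputed_atac)):
        arr = m.data if sparse.issparse(m) else np.asarray(m)
        if arr.size and arr.min() < 0:
            raise ValueError(f"{name} has negative entries; imputation means must be >= 0")
    os.makedirs(out_dir, exist_ok=True)
    emb = pd.DataFrame(np.round(embedding, 6),
                       columns=[f"z_{i+1}" for i in range(embedding.shape[1])])
    emb.insert(0, "cell", list(cell_ids))
    emb_path = os.path.join(out_dir, "embedding.tsv")
    emb.to_csv(emb_path, sep="\t", index=False, float_format="%.6f")
    write_triplet(sparse.csr_matrix(imputed_rna), gene_ids, cell_ids,
                  os.path.join(out_dir, "imputed_rna"))
    write_triplet(sparse.csr_matrix(imputed_atac), peak_ids, cell_ids,
                  os.path.join(out_dir, "imputed_atac"))
    return {"embedding": emb_path,
            "imputed_rna": os.path.join(out_dir, "imputed_rna"),
            "imputed_atac": os.path.join(out_dir, "imputed_atac")}


def read_embedding(path) -> tuple[np.ndarray, list[str]]:
    """Read an ``embedding.tsv`` written by :func:`write_outputs`."""
    df = pd.read_csv(path, sep="\t")
    cells = df["cell"].astype(str).tolist()
    z = df.drop(columns="cell").to_numpy(dtype=np.float64)
    return z, cells
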