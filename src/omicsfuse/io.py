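"""Reading paired single-cell matrices and the normalization the model consumes.

The model's RNA likelihood is evaluated on raw counts while the encoder sees a
normalized view (median-library-size scaling followed by ``log1p``); ATAC is
binarized because the accessibility likelihood is Bernoulli. Both raw and
normalized representations therefore coexist downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio


class AlignmentError(ValueError):
    """The two modalities do not describe the same cells."""


@dataclass
class PairedOmics:
    """Aligned scRNA-seq and scATAC-seq matrices for the same N cells.

    Matrices are oriented cells x features. ``labels`` carries optional
    ground-truth cell types used only for evaluation.
    """

    rna_counts: np.ndarray
    atac_counts: np.ndarray
    cell_ids: list[str]
    rna_feature_ids: list[str]
    atac_feature_ids: list[str]
    labels: list | None = None

    def __post_init__(self):
        self.rna_counts = np.asarray(self.rna_counts, dtype=np.float64)
        self.atac_counts = np.asarray(self.atac_counts, dtype=np.float64)
        n = self.rna_counts.shape[0]
        if n < 2:
            raise ValueError("need at least 2 cells")
        if self.atac_counts.shape[0] != n:
            raise AlignmentError(
                f"RNA has {n} cells but ATAC has {self.atac_counts.shape[0]}"
            )
        for mat, name in ((self.rna_counts, "rna"), (self.atac_counts, "atac")):
            if not np.isfinite(mat).all():
                raise ValueError(f"{name} matrix contains non-finite entries")
            if (mat < 0).any():
                raise ValueError(f"{name} matrix contains negative entries")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(self.rna_feature_ids) != self.rna_counts.shape[1]:
            raise ValueError("rna_feature_ids length mismatch")
        if len(self.atac_feature_ids) != self.atac_counts.shape[1]:
            raise ValueError("atac_feature_ids length mismatch")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of cells")

    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[0]


def _read_dense(path: str, sep: str) -> tuple[np.ndarray, list[str], list[str]]:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=np.float64)
    except ValueError as err:
        raise ValueError(f"non-numeric entry while parsing {path}: {err}") from err
    return mat, [str(i) for i in df.index], [str(c) for c in df.columns]


def _read_mtx(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    raw = spio.mmread(path)
    mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=np.float64)
    base = os.path.dirname(os.path.abspath(path))
    barcodes = features = None
    for cand in ("barcodes.tsv", "barcodes.txt"):
        p = os.path.join(base, cand)
        if os.path.exists(p):
            barcodes = [line.strip().split("\t")[0] for line in open(p) if line.strip()]
    for cand in ("features.tsv", "genes.tsv", "features.txt"):
        p = os.path.join(base, cand)
        if os.path.exists(p):
            features = [line.strip().split("\t")[0] for line in open(p) if line.strip()]
    if barcodes is None or features is None:
        raise FileNotFoundError(
            f"MTX companion files (barcodes.tsv / features.tsv) not found next to {path}"
        )
    # MTX is conventionally stored features x cells; detect by barcode count
    if mat.shape[0] == len(barcodes) and mat.shape[1] == len(features):
        pass
    elif mat.shape[0] == len(features) and mat.shape[1] == len(barcodes):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(barcodes)} barcodes "
            f"x {len(features)} features nor its transpose"
        )
    return mat, barcodes, features


def load_paired_matrices(
    rna_path: str,
    atac_path: str,
    format: str = "csv",
    labels_path: str | None = None,
) -> PairedOmics:
    """Load the two modalities and align them by barcode.

    Paired protocols measure both modalities in the same cells, so a barcode
    mismatch is rejected (naming the first offending barcode) rather than
    silently intersected.
    """
    readers = {
        "csv": lambda p: _read_dense(p, ","),
        "tsv": lambda p: _read_dense(p, "\t"),
        "mtx": _read_mtx,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected mtx, csv or tsv")
    rna, rna_cells, rna_feats = readers[format](rna_path)
    atac, atac_cells, atac_feats = readers[format](atac_path)

    if rna_cells != atac_cells:
        rna_set, atac_set = set(rna_cells), set(atac_cells)
        missing_in_atac = [c for c in rna_cells if c not in atac_set]
        missing_in_rna = [c for c in atac_cells if c not in rna_set]
        if missing_in_atac or missing_in_rna:
            parts = []
            if missing_in_atac:
                parts.append(f"barcode {missing_in_atac[0]!r} present only in RNA")
            if missing_in_rna:
                parts.append(f"barcode {missing_in_rna[0]!r} present only in ATAC")
            raise AlignmentError("cell sets differ: " + "; ".join(parts))
        # same set, different order: reorder ATAC to the RNA barcode order
        order = [atac_cells.index(c) for c in rna_cells]
        atac = atac[order]

    labels = None
    if labels_path is not None:
        labels = [line.strip() for line in open(labels_path) if line.strip()]
    return PairedOmics(rna, atac, rna_cells, rna_feats, atac_feats, labels)


def save_paired_csv(data: PairedOmics, rna_path: str, atac_path: str,
                    labels_path: str | None = None) -> None:
    """Write both matrices (and optional labels) in the CSV layout load expects."""
    pd.DataFrame(data.rna_counts, index=data.cell_ids,
                 columns=data.rna_feature_ids).to_csv(rna_path)
    pd.DataFrame(data.atac_counts, index=data.cell_ids,
                 columns=data.atac_feature_ids).to_csv(atac_path)
    if labels_path is not None and data.labels is not None:
        with open(labels_path, "w") as fh:
            for lab in data.labels:
                fh.write(f"{lab}\n")


def normalize_rna(counts: np.ndarray) -> np.ndarray:
    """Median-library-size scaling then log1p.

    Each cell's counts are rescaled so its library size equals the median
    library size over cells, making the normalized values comparable across
    cells of different sequencing depth; all-zero cells pass through as zeros.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=1)
    nonzero = lib > 0
    if not nonzero.any():
        return np.zeros_like(counts)
    median = np.median(lib[nonzero])
    scale = np.ones_like(lib)
    scale[nonzero] = median / lib[nonzero]
    return np.log1p(counts * scale[:, None])


def binarize_atac(counts: np.ndarray) -> np.ndarray:
    """Map accessibility to presence/absence, as the Bernoulli likelihood needs."""
    counts = np.asarray(counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return (counts > 0).astype(np.float64)


def select_features(matrix: np.ndarray, n_top: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``n_top`` highest-variance columns (ties to the lower index).

    Returns the reduced matrix and the kept column indices, sorted ascending.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    d = matrix.shape[1]
    if n_top > d:
        raise ValueError(f"n_top={n_top} exceeds number of features {d}")
    var = matrix.var(axis=0)
    # stable sort on -var keeps lower indices first among ties
    order = np.argsort(-var, kind="stable")[:n_top]
    kept = np.sort(order)
    return matrix[:, kept], kept
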