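"""In-memory containers shared across pipeline stages.

Orientation convention: count and normalized matrices are genes x cells
(the 10x deposition convention); discretized matrices used for Bayesian
network learning are cells x genes (observations x variables), matching
the scikit-learn sample/feature convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Metadata columns the pipeline stages rely on.
REQUIRED_META_COLUMNS = ("sample", "cell_type", "genotype", "treatment")


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells, with gene annotations.

    Parameters
    ----------
    counts : scipy.sparse matrix
        Non-negative integer counts with genes as rows.
    genes : pandas.Index
        Gene identifiers (unique).
    barcodes : pandas.Index
        Cell barcodes (unique).
    mito : numpy.ndarray of bool
        Per-gene flag marking mitochondrial genes.
    """

    counts: sp.spmatrix
    genes: pd.Index
    barcodes: pd.Index
    mito: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        self.mito = np.asarray(self.mito, dtype=bool)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.mito.shape != (len(self.genes),):
            raise ValueError("mito flag length must equal number of genes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with at least one count, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def library_size(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fraction_per_cell(self) -> np.ndarray:
        """Fraction of each cell's counts assigned to mitochondrial genes."""
        total = self.library_size().astype(float)
        mito_counts = np.asarray(self.counts[self.mito, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito_counts / total, 0.0)
        return frac

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.counts[:, idx], self.genes, self.barcodes[idx], self.mito
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.counts[idx, :], self.genes[idx], self.barcodes, self.mito[idx]
        )


def validate_cell_metadata(meta: pd.DataFrame, counts: CountMatrix | None = None) -> None:
    """Check a per-cell metadata table against the pipeline's expectations."""
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata missing required columns: {missing}")
    if counts is not None and len(meta) != counts.n_cells:
        raise ValueError(
            f"metadata has {len(meta)} rows but count matrix has "
            f"{counts.n_cells} cells"
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells.

    values[g, c] = ln(1 + scale_factor * count[g, c] / library_size[c]).
    """

    values: np.ndarray
    genes: pd.Index
    barcodes: pd.Index
    scale_factor: float = 1e4
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("normalized matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "NormalizedMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0])
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        return NormalizedMatrix(
            self.values[idx, :], self.genes[idx], self.barcodes,
            self.scale_factor, dict(self.provenance),
        )

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            self.values[:, idx], self.genes, self.barcodes[idx],
            self.scale_factor, dict(self.provenance),
        )


@dataclass
class DiscretizedMatrix:
    """Interval-discretized expression, cells x genes, integer bins.

    ``breaks[j]`` holds the interior cut points of gene ``j``; intervals are
    half-open [lo, hi) except the last, which is closed so the maximum maps
    into the top bin. A constant gene has no breaks (single level) and is
    flagged in ``constant``.
    """

    values: np.ndarray
    genes: pd.Index
    breaks: list
    n_bins: int = 3
    constant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.genes = pd.Index(self.genes)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.genes):
            raise ValueError("discretized matrix must be cells x genes")
        if self.constant is None:
            self.constant = np.array([len(b) == 0 for b in self.breaks])
        self.constant = np.asarray(self.constant, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def cardinalities(self) -> np.ndarray:
        """Number of discrete levels per gene (len(breaks) + 1)."""
        return np.array([len(b) + 1 for b in self.breaks], dtype=np.int64)


@dataclass
class PseudobulkMatrix:
    """Donor x region pseudobulk expression with per-sample covariates.

    ``values`` is genes x samples. ``samples`` carries one row per
    pseudo-sample with at least the grouping keys and any covariates
    (CAG, age, sex, batch, region).
    """

    values: np.ndarray
    genes: pd.Index
    samples: pd.DataFrame
    raw_sums: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("pseudobulk matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]
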