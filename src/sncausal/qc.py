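"""Cell and gene quality control and log-normalization.

Cell filters follow the snRNA-seq convention for nuclei: detected-gene
bounds of [200, 6000] (inclusive) and a mitochondrial-read fraction of at
most 2%. Normalization is the standard scaled log transform
ln(1 + scale_factor * count / library_size).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix
from .exceptions import ConfigurationError, DegenerateCellError


def filter_cells(
    counts: CountMatrix,
    meta: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.02,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Keep cells with min_genes <= detected genes <= max_genes and
    mito fraction <= max_mito (all bounds inclusive).

    The mito fraction is read from ``meta['mito_frac']``; cell order is
    preserved. An empty result warns rather than raising.
    """
    if min_genes <= 0 or max_genes <= 0 or max_mito < 0:
        raise ConfigurationError("QC thresholds must be positive")
    if "mito_frac" not in meta.columns:
        raise ConfigurationError("metadata lacks required 'mito_frac' column")
    detected = counts.detected_genes_per_cell()
    mito = meta["mito_frac"].to_numpy(dtype=float)
    keep = (detected >= min_genes) & (detected <= max_genes) & (mito <= max_mito)
    if not keep.any():
        warnings.warn("cell QC removed every cell")
    return counts.subset_cells(keep), meta.loc[keep].copy()


def filter_genes_min_frac(counts: CountMatrix, min_frac: float = 0.25) -> pd.Index:
    """Genes with at least 1 count in at least ``min_frac`` of all cells.

    The fraction comparison is inclusive (>=).
    """
    if not 0 < min_frac <= 1:
        raise ConfigurationError("min_frac must lie in (0, 1]")
    n_expr = np.asarray((counts.counts > 0).sum(axis=1)).ravel()
    keep = n_expr >= min_frac * counts.n_cells
    return counts.genes[keep]


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """ln(1 + scale_factor * count / library_size), genes x cells dense."""
    total = counts.library_size().astype(float)
    if (total == 0).any():
        raise DegenerateCellError("cells with zero library size; run QC first")
    dense = counts.counts.toarray().astype(float)
    values = np.log1p(scale_factor * dense / total[None, :])
    return NormalizedMatrix(
        values, counts.genes, counts.barcodes, scale_factor,
        provenance={"scale_factor": scale_factor},
    )
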