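"""Wilcoxon rank-sum differential expression with an expression-fraction
filter.

A gene is tested only when it is detected (count > 0) in at least
``min_frac`` of either group. Small balanced groups (both <= 25 cells, no
ties) use the exact rank-sum distribution; larger groups use the normal
approximation with tie and continuity corrections. Fold changes are
reported as log2 of the ratio of mean de-logged normalized expression
(Seurat-version conventions differ between ln and log2; this package
standardizes on log2, as the output header states).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import NormalizedMatrix
from .stats import bh_adjust

#: Largest per-group size at which the exact rank-sum null is used.
EXACT_MAX_N = 25
_PSEUDO = 1e-9

DEG_COLUMNS = ("gene", "log2fc", "pct1", "pct2", "p", "p_adj",
               "significant", "direction")


def _log2fc(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """log2 fold change of mean de-logged expression, rows = genes."""
    m1 = np.expm1(x1).mean(axis=1) + _PSEUDO
    m2 = np.expm1(x2).mean(axis=1) + _PSEUDO
    return np.log2(m1 / m2)


def wilcoxon_deg(
    norm: NormalizedMatrix,
    group1,
    group2,
    min_frac: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DEGs between two cell groups.

    Parameters
    ----------
    norm : NormalizedMatrix
        Log-normalized expression (genes x cells).
    group1, group2 : boolean masks, integer indices, or barcode sequences
        Disjoint, non-empty cell groups; group sizes below 3 are refused.
    min_frac : float
        Minimum detection fraction in either group for a gene to be tested.
    alpha : float
        BH-adjusted significance cutoff (adjustment spans tested genes only).

    Returns
    -------
    pandas.DataFrame with one row per *tested* gene and columns
    ``gene, log2fc, pct1, pct2, p, p_adj, significant, direction``.
    """
    idx1 = _resolve_cells(norm, group1)
    idx2 = _resolve_cells(norm, group2)
    if np.intersect1d(idx1, idx2).size:
        raise ValueError("groups must be disjoint")
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValueError(
            f"group sizes {len(idx1)} and {len(idx2)} too small (minimum 3)"
        )
    x1 = norm.values[:, idx1]
    x2 = norm.values[:, idx2]
    pct1 = (x1 > 0).mean(axis=1)
    pct2 = (x2 > 0).mean(axis=1)
    tested = (pct1 >= min_frac) | (pct2 >= min_frac)
    x1, x2 = x1[tested], x2[tested]
    genes = norm.genes[tested]

    n1, n2 = x1.shape[1], x2.shape[1]
    if len(genes) == 0:
        p = np.empty(0)
    elif n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        p = np.array([_small_n_p(a, b) for a, b in zip(x1, x2)])
    else:
        p = mannwhitneyu(x1, x2, alternative="two-sided",
                         method="asymptotic", axis=1).pvalue
    p = np.minimum(p, 1.0)
    lfc = _log2fc(x1, x2)
    p_adj = bh_adjust(p)
    out = pd.DataFrame({
        "gene": genes,
        "log2fc": lfc,
        "pct1": pct1[tested],
        "pct2": pct2[tested],
        "p": p,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
        "direction": np.where(lfc >= 0, "up", "down"),
    }).set_index("gene", drop=False)
    out.index.name = None
    return out


def _small_n_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact rank-sum p when the pooled sample is tie-free, otherwise the
    tie-corrected normal approximation."""
    pooled = np.concatenate([a, b])
    method = "exact" if np.unique(pooled).size == pooled.size else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _resolve_cells(norm: NormalizedMatrix, group) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if group.shape != (norm.n_cells,):
            raise ValueError("boolean mask length must equal cell count")
        return np.flatnonzero(group)
    if np.issubdtype(group.dtype, np.integer):
        return group
    idx = norm.barcodes.get_indexer(pd.Index(group))
    if (idx < 0).any():
        raise KeyError("unknown barcodes in group")
    return idx


def significant_genes(deg: pd.DataFrame) -> set:
    """The set of genes flagged significant in a DEG table."""
    return set(deg.loc[deg["significant"], "gene"])
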