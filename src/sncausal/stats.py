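"""Shared statistical utilities: BH adjustment, hypergeometric set overlap,
and Z-scoring of log2 fold changes."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Values are monotone in the input ranks and capped at 1.

    Parameters
    ----------
    p : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray of the same length.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_overlap(set_a, set_b, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of the observed set overlap.

    Returns ``(overlap, p)`` where ``p = P(X >= overlap)`` for
    ``X ~ Hypergeom(|universe|, |A|, |B|)``. Both sets must be subsets of
    the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both gene sets must be subsets of the universe")
    overlap = len(set_a & set_b)
    # sf(k-1) = P(X >= k), inclusive upper tail
    p = float(_sps.hypergeom.sf(overlap - 1, len(universe), len(set_a), len(set_b)))
    return overlap, min(p, 1.0)


def zscore_log2fc(deg: pd.DataFrame, column: str = "log2fc") -> pd.Series:
    """Z-score the log2 fold changes of a DEG table.

    Uses the population (n-denominator) standard deviation over all tested
    genes in the table. A zero-variance table yields all zeros with a
    warning.
    """
    if len(deg) < 2:
        raise ValueError("need at least 2 genes to Z-score")
    x = deg[column].to_numpy(dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn("zero variance in log2fc; Z-scores set to 0")
        return pd.Series(np.zeros(len(x)), index=deg.index, name="z")
    return pd.Series((x - x.mean()) / sd, index=deg.index, name="z")
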