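"""Donor x region pseudobulk construction and per-gene regression of
expression on CAG repeat length with covariates.

The regression is ordinary least squares of scaled pseudobulk expression
on [intercept, CAG, age, sex, batch dummies, region dummies] with a
two-sided t-test on the CAG coefficient and BH adjustment across genes.
An optional empirical-Bayes variance shrinkage (pooling residual
variances) is available for small sample counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.base import BaseEstimator

from .containers import CountMatrix, PseudobulkMatrix
from .exceptions import CollinearityError
from .stats import bh_adjust

DEFAULT_COVARIATES = ("age", "sex")
DEFAULT_DUMMY_COLS = ("batch", "region")


def pseudobulk_sum(
    counts: CountMatrix,
    meta: pd.DataFrame,
    group_keys: tuple = ("donor", "region"),
    cell_type: str | None = None,
    celltype_col: str = "cell_type",
    scale_factor: float = 1e4,
    covariate_cols: tuple = ("cag", "age", "sex", "batch", "region"),
) -> PseudobulkMatrix:
    """Sum counts per (donor, region) pseudo-sample, then log-normalize per
    sample and scale each gene to zero mean / unit variance across samples.

    Groups emptied by the cell-type filter are dropped with a warning.
    Covariates must be constant within a group; the first value is taken.
    """
    for key in group_keys:
        if key not in meta.columns:
            raise KeyError(f"group key {key!r} missing from metadata")
    mask = np.ones(len(meta), dtype=bool)
    if cell_type is not None:
        mask &= (meta[celltype_col] == cell_type).to_numpy()
    if mask.sum() == 0:
        warnings.warn("no cells left after cell-type filter")
    sub_counts = counts.subset_cells(mask)
    sub_meta = meta.loc[mask]

    groups = sub_meta.groupby(list(group_keys), sort=True, observed=True)
    sums, rows = [], []
    for key, idx in groups.indices.items():
        if len(idx) == 0:
            continue
        block = np.asarray(sub_counts.counts[:, idx].sum(axis=1)).ravel()
        sums.append(block)
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_keys, key))
        row["n_cells"] = len(idx)
        for cov in covariate_cols:
            if cov in sub_meta.columns and cov not in row:
                row[cov] = sub_meta[cov].iloc[idx[0]]
        rows.append(row)
    if not sums:
        raise ValueError("no pseudo-samples could be formed")
    raw = np.column_stack(sums)  # genes x samples
    samples = pd.DataFrame(rows)
    samples.index = [
        "_".join(str(v) for v in r) for r in
        samples[list(group_keys)].itertuples(index=False)
    ]

    totals = raw.sum(axis=0).astype(float)
    norm = np.log1p(scale_factor * raw / totals[None, :])
    mean = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)
    degenerate = sd.ravel() == 0
    if raw.shape[1] < 2:
        warnings.warn("degenerate design: fewer than 2 pseudo-samples; "
                      "scaled values are all zero")
    sd[sd == 0] = 1.0
    values = (norm - mean) / sd
    values[degenerate, :] = 0.0
    return PseudobulkMatrix(values, counts.genes, samples, raw_sums=raw)


def _build_design(
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    dummy_cols=DEFAULT_DUMMY_COLS,
    cag_col: str = "cag",
) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    cols.append(samples[cag_col].to_numpy(dtype=float))
    names.append(cag_col)
    for cov in covariates:
        if cov in samples.columns:
            cols.append(samples[cov].to_numpy(dtype=float))
            names.append(cov)
    for dc in dummy_cols:
        if dc not in samples.columns:
            continue
        levels = sorted(samples[dc].astype(str).unique())
        for level in levels[1:]:  # first level is the reference
            cols.append((samples[dc].astype(str) == level).to_numpy(float))
            names.append(f"{dc}[{level}]")
    return np.column_stack(cols), names


class CagRegression(BaseEstimator):
    """Per-gene OLS of pseudobulk expression on CAG length plus covariates.

    Parameters
    ----------
    covariates : numeric covariate columns to include (default age, sex).
    dummy_cols : categorical columns expanded to treatment-coded dummies
        with the first level as reference (default batch, region).
    alpha : BH-adjusted significance cutoff for the CAG coefficient.
    shrink_variance : if True, residual variances are pooled toward their
        mean with prior weight ``shrink_df`` residual degrees of freedom
        (a light empirical-Bayes moderation for small designs).

    ``fit(pb)`` accepts a PseudobulkMatrix (or a genes x samples array
    with a samples DataFrame). Fitted attributes: ``results_`` (DataFrame
    gene, beta_cag, se, t, p, p_adj, significant), ``design_names_``.
    """

    def __init__(self, covariates=DEFAULT_COVARIATES,
                 dummy_cols=DEFAULT_DUMMY_COLS, cag_col="cag",
                 alpha=0.05, shrink_variance=False, shrink_df=4.0):
        self.covariates = covariates
        self.dummy_cols = dummy_cols
        self.cag_col = cag_col
        self.alpha = alpha
        self.shrink_variance = shrink_variance
        self.shrink_df = shrink_df

    def fit(self, pb: PseudobulkMatrix, y=None):
        X, names = _build_design(
            pb.samples, self.covariates, self.dummy_cols, self.cag_col
        )
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(
                f"need more samples ({n}) than design columns + 1 ({p + 1})"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            aliased = _aliased_columns(X, names)
            raise CollinearityError(aliased)
        Y = pb.values.T  # samples x genes
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ Y  # p x genes
        resid = Y - X @ beta
        df = n - p
        sigma2 = (resid ** 2).sum(axis=0) / df
        if self.shrink_variance:
            prior = float(np.mean(sigma2))
            sigma2 = (df * sigma2 + self.shrink_df * prior) / (df + self.shrink_df)
            df = df + self.shrink_df
        cag_i = names.index(self.cag_col)
        se = np.sqrt(sigma2 * XtX_inv[cag_i, cag_i])
        b = beta[cag_i]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, b / se, 0.0)
        pvals = 2.0 * _sps.t.sf(np.abs(t), df)
        p_adj = bh_adjust(np.clip(pvals, 0.0, 1.0))
        self.design_names_ = names
        self.coef_ = pd.DataFrame(beta.T, index=pb.genes, columns=names)
        self.results_ = pd.DataFrame({
            "gene": pb.genes,
            "beta_cag": b,
            "se": se,
            "t": t,
            "p": np.clip(pvals, 0.0, 1.0),
            "p_adj": p_adj,
            "significant": p_adj < self.alpha,
        }).set_index("gene", drop=False).rename_axis(None)
        return self


def _aliased_columns(X: np.ndarray, names: list) -> list:
    """Columns linearly dependent on the columns before them."""
    aliased, kept = [], []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            aliased.append(names[j])
        else:
            kept.append(j)
    return aliased


def cag_fit(pb: PseudobulkMatrix, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`CagRegression`; returns the fit table."""
    return CagRegression(**kwargs).fit(pb).results_


def classify_cag_quadrants(
    fit_opc: pd.DataFrame, fit_ol: pd.DataFrame
) -> pd.DataFrame:
    """Cross-classify genes by CAG-coefficient significance and sign in
    two cell types (e.g. OPC and OL).

    Category is OPC_only / OL_only / both / neither from the two
    significance flags; the quadrant encodes coefficient signs as
    (x = OL, y = OPC), e.g. "+/+" is the upper-right quadrant (positive
    correlation in both). Non-significant genes carry no quadrant.
    """
    genes = fit_opc.index.intersection(fit_ol.index)
    sig_opc = fit_opc.loc[genes, "significant"].to_numpy(bool)
    sig_ol = fit_ol.loc[genes, "significant"].to_numpy(bool)
    b_opc = fit_opc.loc[genes, "beta_cag"].to_numpy(float)
    b_ol = fit_ol.loc[genes, "beta_cag"].to_numpy(float)
    category = np.select(
        [sig_opc & sig_ol, sig_opc & ~sig_ol, ~sig_opc & sig_ol],
        ["both", "OPC_only", "OL_only"], default="neither",
    )
    quadrant = np.array([
        f"{'+' if xo >= 0 else '-'}/{'+' if yo >= 0 else '-'}"
        for xo, yo in zip(b_ol, b_opc)
    ], dtype=object)
    quadrant[category == "neither"] = ""
    return pd.DataFrame({
        "gene": genes,
        "beta_opc": b_opc,
        "beta_ol": b_ol,
        "category": category,
        "quadrant": quadrant,
    }).set_index("gene", drop=False).rename_axis(None)
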