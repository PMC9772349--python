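"""Signed weighted co-expression modules: soft-thresholded adjacency,
topological overlap, hierarchical module detection, eigengenes, kME, and
module-trait / module-DEG association.

The module detector uses a static tree cut on 1 - TOM dissimilarity
followed by eigengene-correlation merging; this keeps the procedure
deterministic and testable. Label 0 is the unassigned ("grey") module.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import betainc
from sklearn.base import BaseEstimator

from .stats import hypergeometric_overlap

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


def signed_adjacency(expr: np.ndarray, power: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed WGCNA adjacency a_ij = ((1 + cor(i, j)) / 2) ** power.

    ``expr`` is genes x cells. Constant genes (undefined correlation) are
    dropped with a warning; returns ``(adjacency, kept_gene_indices)``.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if power < 1:
        raise ValueError("power must be >= 1")
    sd = expr.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < expr.shape[0]:
        warnings.warn(
            f"dropping {expr.shape[0] - kept.size} constant gene(s) "
            "with undefined correlation"
        )
    cor = np.corrcoef(expr[kept])
    cor = np.clip(cor, -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    return adj, kept


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity distribution.

    Returns ``(signed_r2, slope)`` where signed_r2 is the squared
    correlation between log10(bin frequency) and log10(mean bin
    connectivity), negated when the fitted slope is positive (a scale-free
    network requires a decreasing frequency-connectivity relation).
    """
    k = np.asarray(connectivity, dtype=float)
    if np.allclose(k, k[0]):
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return np.nan, np.nan
    xs, ys = np.array(xs), np.array(ys)
    r = np.corrcoef(xs, ys)[0, 1]
    slope = np.polyfit(xs, ys, 1)[0]
    r2 = r * r
    return (-r2 if slope > 0 else r2), slope


def pick_soft_threshold(
    expr: np.ndarray,
    candidate_powers=DEFAULT_POWERS,
    r2_cut: float = 0.8,
    min_mean_connectivity: float = 1.0,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power whose signed scale-free fit reaches
    ``r2_cut``; falls back to the power with the best fit.

    Candidates whose network retains a mean connectivity below
    ``min_mean_connectivity`` are excluded from selection: when soft
    thresholding drives nearly all adjacencies to zero the log-log fit is
    computed on noise, so apparent scale-free behavior there is spurious.

    Returns ``(power, diagnostics)`` where diagnostics has one row per
    candidate (power, signed_r2, slope, mean_connectivity).
    """
    candidate_powers = list(candidate_powers)
    if len(candidate_powers) < 2:
        raise ValueError("need at least 2 candidate powers")
    rows = []
    for beta in candidate_powers:
        adj, _ = signed_adjacency(expr, beta)
        a0 = adj.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": r2, "slope": slope,
                     "mean_connectivity": k.mean()})
    diag = pd.DataFrame(rows)
    return select_power(diag, r2_cut, min_mean_connectivity), diag


def select_power(
    diag: pd.DataFrame, r2_cut: float = 0.8,
    min_mean_connectivity: float = 1.0,
) -> int:
    """Apply the power-selection rule to a soft-threshold diagnostic table."""
    usable = diag[diag["mean_connectivity"] >= min_mean_connectivity]
    if usable.empty:
        usable = diag
    ok = usable["signed_r2"] >= r2_cut
    if ok.any():
        return int(usable.loc[ok, "power"].iloc[0])
    if usable["signed_r2"].notna().any():
        return int(usable.loc[usable["signed_r2"].idxmax(), "power"])
    warnings.warn("degenerate connectivity; falling back to smallest power")
    return int(diag["power"].iloc[0])


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal (with zero-diagonal adjacency used internally) and TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(expr: np.ndarray) -> np.ndarray:
    """First principal component scores of a module's expression.

    ``expr`` is member genes x cells. Genes are standardized first; the
    scores are scaled to unit (population) variance and the sign is fixed
    so the mean correlation with member genes is non-negative. A rank-0
    submatrix yields a zero vector with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 cells")
    sd = expr.std(axis=1)
    nz = sd > 0
    if not nz.any():
        warnings.warn("rank-0 module submatrix; eigengene set to 0")
        return np.zeros(expr.shape[1])
    z = (expr[nz] - expr[nz].mean(axis=1, keepdims=True)) / sd[nz, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    if scores.std() == 0:
        warnings.warn("degenerate eigengene; returning zeros")
        return np.zeros(expr.shape[1])
    scores = (scores - scores.mean()) / scores.std()
    mean_cor = np.mean([np.corrcoef(scores, g)[0, 1] for g in z])
    if mean_cor < 0:
        scores = -scores
    return scores


def kme(expr: np.ndarray, eigengenes: np.ndarray) -> np.ndarray:
    """Pearson correlation of each gene (rows of expr) with each eigengene
    (rows of eigengenes); constant genes get kME 0."""
    expr = np.asarray(expr, dtype=float)
    eig = np.atleast_2d(np.asarray(eigengenes, dtype=float))
    out = np.zeros((expr.shape[0], eig.shape[0]))
    sd_g = expr.std(axis=1)
    sd_e = eig.std(axis=1)
    zc = (expr - expr.mean(axis=1, keepdims=True))
    ze = (eig - eig.mean(axis=1, keepdims=True))
    n = expr.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (zc @ ze.T) / n / np.outer(sd_g, sd_e)
    ok = np.outer(sd_g > 0, sd_e > 0)
    out[ok] = np.clip(raw[ok], -1.0, 1.0)
    return out


def detect_modules(
    tom: np.ndarray,
    expr: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_cor: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` become label 0; modules
    whose eigengenes correlate above ``merge_cor`` are merged. Labels are
    renumbered 1..M by decreasing module size. Returns
    ``(labels, linkage_matrix)``.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        return np.zeros(n, dtype=int), None
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    next_label = 1
    for c in np.unique(raw):
        members = raw == c
        if members.sum() >= min_module_size:
            labels[members] = next_label
            next_label += 1
    labels = _merge_close_modules(labels, expr, merge_cor)
    return _relabel_by_size(labels), z


def _merge_close_modules(labels, expr, merge_cor):
    labels = labels.copy()
    while True:
        mods = [m for m in np.unique(labels) if m != 0]
        if len(mods) < 2:
            return labels
        eigs = np.array([module_eigengene(expr[labels == m]) for m in mods])
        cor = np.corrcoef(eigs)
        np.fill_diagonal(cor, 0.0)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= merge_cor:
            return labels
        labels[labels == mods[j]] = mods[i]


def _relabel_by_size(labels):
    out = np.zeros_like(labels)
    mods = [m for m in np.unique(labels) if m != 0]
    sizes = [(int((labels == m).sum()), m) for m in mods]
    for new, (_, old) in enumerate(
        sorted(sizes, key=lambda t: (-t[0], t[1])), start=1
    ):
        out[labels == old] = new
    return out


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of module eigengenes with cell-level traits.

    ``eigengenes`` is modules x cells; ``traits`` is cells x traits (e.g. a
    one-hot encoding of cell types). P-values are two-sided Student
    asymptotic: t = r sqrt(n-2) / sqrt(1 - r^2). Constant traits are
    reported with r = 0, p = 1 and ``degenerate=True``.
    """
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("need at least 3 cells")
    if traits.shape[0] != n:
        raise ValueError("traits must have one row per cell")
    rows = []
    for mod, e in eigengenes.iterrows():
        ev = e.to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            degenerate = tv.std() == 0 or ev.std() == 0
            if degenerate:
                r, p = 0.0, 1.0
            else:
                r = float(np.clip(np.corrcoef(ev, tv)[0, 1], -1.0, 1.0))
                p = student_correlation_p(r, n)
            rows.append({"module": mod, "trait": trait, "r": r, "p": p,
                         "degenerate": degenerate})
    return pd.DataFrame(rows)


def student_correlation_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t distribution with
    n - 2 df, computed through the regularized incomplete beta function."""
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t2 = r * r * df / (1.0 - r * r)
    # P(|T| >= t) = I_{df/(df+t^2)}(df/2, 1/2)
    return float(betainc(df / 2.0, 0.5, df / (df + t2)))


def module_deg_enrichment(
    labels: np.ndarray, genes: pd.Index, deg_genes, universe
) -> pd.DataFrame:
    """Hypergeometric enrichment of each module (label > 0) for DEGs.

    ``universe`` should be the analyzed-gene universe; DEGs are
    intersected with it. The grey module (label 0) is excluded.
    """
    universe = set(universe)
    deg_genes = set(deg_genes) & universe
    rows = []
    for m in sorted(set(labels) - {0}):
        members = set(genes[np.asarray(labels) == m]) & universe
        overlap, p = hypergeometric_overlap(members, deg_genes, universe)
        rows.append({"module": m, "size": len(members), "overlap": overlap,
                     "p": p})
    return pd.DataFrame(rows, columns=["module", "size", "overlap", "p"])


class CoexpressionModules(BaseEstimator):
    """Signed co-expression module detection as an sklearn-style estimator.

    Parameters
    ----------
    power : int or "auto"
        Soft-threshold power; "auto" selects the smallest candidate whose
        signed scale-free fit R^2 reaches 0.8.
    candidate_powers : sequence of int
        Candidates tried when power="auto".
    min_module_size, cut_height, merge_cor :
        Static-cut module detection parameters.
    max_cells : int
        Cells are subsampled (seeded) to this cap before gene-gene
        correlation, for tractability.
    random_state : int or None

    Attributes
    ----------
    labels_ : ndarray (n_genes,) module labels, 0 = unassigned
    power_ : int selected soft threshold
    eigengenes_ : DataFrame (modules x fitted cells), rows "ME1"...
    kme_ : DataFrame (genes x modules) eigengene-based connectivity
    tree_ : scipy linkage matrix used for cutting
    """

    def __init__(self, power="auto", candidate_powers=DEFAULT_POWERS,
                 min_module_size=30, cut_height=0.99, merge_cor=0.75,
                 max_cells=10000, random_state=None):
        self.power = power
        self.candidate_powers = candidate_powers
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_cor = merge_cor
        self.max_cells = max_cells
        self.random_state = random_state

    def fit(self, X, y=None, feature_names=None):
        """Detect modules in X (cells x genes)."""
        X = np.asarray(X, dtype=float)
        n_cells, n_genes = X.shape
        if feature_names is None:
            feature_names = pd.Index([f"g{i}" for i in range(n_genes)])
        else:
            feature_names = pd.Index(feature_names)
        cells = np.arange(n_cells)
        if n_cells > self.max_cells:
            rng = np.random.default_rng(self.random_state)
            cells = np.sort(rng.choice(n_cells, self.max_cells, replace=False))
        expr = X[cells].T  # genes x cells

        if self.power == "auto":
            self.power_, self.soft_threshold_diagnostics_ = pick_soft_threshold(
                expr, self.candidate_powers
            )
        else:
            self.power_ = int(self.power)
        adj, kept = signed_adjacency(expr, self.power_)
        tom = tom_similarity(adj)
        labels_kept, self.tree_ = detect_modules(
            tom, expr[kept], self.min_module_size, self.cut_height,
            self.merge_cor,
        )
        labels = np.zeros(n_genes, dtype=int)
        labels[kept] = labels_kept
        self.labels_ = labels
        self.genes_ = feature_names
        self.cells_used_ = cells

        mods = [m for m in np.unique(labels) if m != 0]
        eig_rows = [module_eigengene(expr[labels == m]) for m in mods]
        self.eigengenes_ = pd.DataFrame(
            eig_rows, index=[f"ME{m}" for m in mods],
            columns=cells,
        )
        if mods:
            self.kme_ = pd.DataFrame(
                kme(expr, np.array(eig_rows)), index=feature_names,
                columns=[f"ME{m}" for m in mods],
            )
        else:
            self.kme_ = pd.DataFrame(index=feature_names)
        return self

    def module_genes(self, module: int) -> list:
        return list(self.genes_[self.labels_ == module])
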