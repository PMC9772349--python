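"""Discrete Bayesian network structure learning and model averaging.

The learning stack is: interval discretization of log-normalized
expression into a small number of levels (default 3), BDeu (Bayesian
Dirichlet likelihood-equivalent, uniform) scoring, greedy hill climbing
over single-arc moves, and bootstrap model averaging (fractional
subsampling, default 200 rounds at 50%) summarized as per-arc strength
and direction frequencies. Averaged condition networks are thresholded
(strength >= 0.85, direction >= 0.5), merged across conditions with
node/edge provenance, and mined for key drivers (out-degree hubs and
hub-to-hub connectors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import DiscretizedMatrix, NormalizedMatrix
from .exceptions import PipelineError

_EPS = 1e-10
_MAX_PARENT_CONFIGS = 1_000_000


# ---------------------------------------------------------------------------
# feature selection and discretization
# ---------------------------------------------------------------------------

def select_features(cell_type_degs, module_genes) -> list:
    """Sorted union of a cell type's DEGs and its correlated module's genes."""
    union = sorted(set(cell_type_degs) | set(module_genes))
    if not union:
        raise PipelineError("empty feature set: no DEGs and no module genes")
    return union


class IntervalDiscretizer(TransformerMixin, BaseEstimator):
    """Equal-width interval discretization per feature.

    Bins span [min, max] of each feature with half-open intervals
    [lo, hi) except the last, which is closed. Constant features get a
    single level (no breaks) and are flagged.
    """

    def __init__(self, n_bins: int = 3):
        self.n_bins = n_bins

    def fit(self, X, y=None):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        X = np.asarray(X, dtype=float)
        self.breaks_ = []
        for j in range(X.shape[1]):
            lo, hi = X[:, j].min(), X[:, j].max()
            if hi > lo:
                self.breaks_.append(np.linspace(lo, hi, self.n_bins + 1)[1:-1])
            else:
                self.breaks_.append(np.array([]))
        self.constant_ = np.array([b.size == 0 for b in self.breaks_])
        if self.constant_.any():
            warnings.warn(
                f"{int(self.constant_.sum())} constant feature(s) assigned a "
                "single bin"
            )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape, dtype=np.int64)
        for j, breaks in enumerate(self.breaks_):
            if breaks.size:
                out[:, j] = np.searchsorted(breaks, X[:, j], side="right")
        return out


def discretize_interval(expr, n_bins: int = 3) -> DiscretizedMatrix:
    """Discretize expression into equal-width intervals.

    Accepts a :class:`NormalizedMatrix` (genes x cells) or a plain
    cells x genes array.
    """
    if isinstance(expr, NormalizedMatrix):
        X = expr.values.T
        genes = expr.genes
    else:
        X = np.asarray(expr, dtype=float)
        genes = pd.Index([f"g{i}" for i in range(X.shape[1])])
    disc = IntervalDiscretizer(n_bins=n_bins).fit(X)
    return DiscretizedMatrix(
        disc.transform(X), genes, disc.breaks_, n_bins, disc.constant_
    )


# ---------------------------------------------------------------------------
# BDeu scoring
# ---------------------------------------------------------------------------

def _family_score(values, cards, child, parents, iss) -> float:
    """BDeu log marginal-likelihood contribution of one (child, parents)
    family. ``values`` is cells x genes int, ``cards`` per-gene level counts."""
    r = int(cards[child])
    q = 1
    for p in parents:
        q *= int(cards[p])
        if q > _MAX_PARENT_CONFIGS:
            return -math.inf
    child_vals = values[:, child]
    if parents:
        config = np.zeros(values.shape[0], dtype=np.int64)
        for p in parents:
            config = config * int(cards[p]) + values[:, p]
    else:
        config = np.zeros(values.shape[0], dtype=np.int64)
    counts = np.bincount(config * r + child_vals, minlength=q * r)
    counts = counts.reshape(q, r).astype(float)
    n_j = counts.sum(axis=1)
    a_jk = iss / (r * q)
    a_j = iss / q
    score = (gammaln(a_j) - gammaln(a_j + n_j)).sum()
    score += (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
    return float(score)


def bde_score(data: DiscretizedMatrix, dag: nx.DiGraph, iss: float = 1.0) -> float:
    """Total BDeu log score of a DAG on discretized data.

    Decomposes over nodes; the DAG's node labels must all be genes of the
    data. Cyclic inputs are rejected before scoring.
    """
    if iss <= 0:
        raise ValueError("iss must be positive")
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph is cyclic; BDe score is defined for DAGs only")
    col = {g: i for i, g in enumerate(data.genes)}
    missing = [n for n in dag.nodes if n not in col]
    if missing:
        raise ValueError(f"nodes absent from data: {missing[:5]}")
    cards = data.cardinalities
    total = 0.0
    for node in dag.nodes:
        parents = tuple(sorted(col[p] for p in dag.predecessors(node)))
        total += _family_score(data.values, cards, col[node], parents, iss)
    return total


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------

def _has_path(children: list[set], src: int, dst: int, skip=None) -> bool:
    """Depth-first reachability src -> dst, optionally ignoring one edge."""
    if src == dst:
        return True
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if skip is not None and (u, v) == skip:
                continue
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def hill_climb(
    data: DiscretizedMatrix,
    iss: float = 1.0,
    max_in_degree: int | None = None,
    return_trajectory: bool = False,
):
    """Greedy BDeu hill climbing from the empty graph.

    Each step applies the single arc addition, deletion, or reversal that
    most improves the total score, subject to acyclicity and the optional
    in-degree cap, until no move improves. Ties are broken by operation
    type (add < delete < reverse), then parent label, then child label, so
    the result is deterministic.
    """
    n = data.n_genes
    if n < 2:
        raise ValueError("need at least 2 variables")
    values = data.values
    cards = data.cardinalities
    genes = list(data.genes)
    order = sorted(range(n), key=lambda i: genes[i])

    parents: list[tuple] = [() for _ in range(n)]
    children: list[set] = [set() for _ in range(n)]
    cache: dict = {}

    def fs(child, pa):
        key = (child, pa)
        if key not in cache:
            cache[key] = _family_score(values, cards, child, pa, iss)
        return cache[key]

    node_score = [fs(i, ()) for i in range(n)]
    trajectory = [sum(node_score)]

    while True:
        best = None  # (delta, op_rank, parent, child, payload)
        for u in order:
            for v in order:
                if u == v:
                    continue
                if v not in children[u]:
                    # add u -> v
                    if max_in_degree is not None and len(parents[v]) >= max_in_degree:
                        continue
                    if _has_path(children, v, u):
                        continue
                    new_pa = tuple(sorted(parents[v] + (u,)))
                    delta = fs(v, new_pa) - node_score[v]
                    cand = (delta, 0, genes[u], genes[v], (u, v, new_pa))
                    if delta > _EPS and (best is None or delta > best[0] + _EPS):
                        best = cand
        for u in order:
            for v in order:
                if v in children[u]:
                    # delete u -> v
                    new_pa = tuple(p for p in parents[v] if p != u)
                    delta = fs(v, new_pa) - node_score[v]
                    if delta > _EPS and (best is None or delta > best[0] + _EPS):
                        best = (delta, 1, genes[u], genes[v], (u, v, new_pa))
        for u in order:
            for v in order:
                if v in children[u]:
                    # reverse u -> v  to  v -> u
                    if max_in_degree is not None and len(parents[u]) >= max_in_degree:
                        continue
                    if _has_path(children, u, v, skip=(u, v)):
                        continue
                    pa_v = tuple(p for p in parents[v] if p != u)
                    pa_u = tuple(sorted(parents[u] + (v,)))
                    delta = (fs(v, pa_v) - node_score[v]) + (fs(u, pa_u) - node_score[u])
                    if delta > _EPS and (best is None or delta > best[0] + _EPS):
                        best = (delta, 2, genes[u], genes[v], (u, v, pa_v, pa_u))
        if best is None:
            break
        op = best[1]
        if op == 0:
            u, v, new_pa = best[4]
            parents[v] = new_pa
            children[u].add(v)
            node_score[v] = fs(v, new_pa)
        elif op == 1:
            u, v, new_pa = best[4]
            parents[v] = new_pa
            children[u].discard(v)
            node_score[v] = fs(v, new_pa)
        else:
            u, v, pa_v, pa_u = best[4]
            parents[v] = pa_v
            parents[u] = pa_u
            children[u].discard(v)
            children[v].add(u)
            node_score[v] = fs(v, pa_v)
            node_score[u] = fs(u, pa_u)
        trajectory.append(sum(node_score))

    dag = nx.DiGraph()
    dag.add_nodes_from(genes)
    for v in range(n):
        for p in parents[v]:
            dag.add_edge(genes[p], genes[v])
    if return_trajectory:
        return dag, trajectory
    return dag


class BDeHillClimb(BaseEstimator):
    """Hill-climbing BDeu structure learner (sklearn-style).

    ``fit(X)`` expects discretized integer data, cells x genes. Fitted
    attributes: ``dag_`` (networkx DiGraph), ``score_`` (final BDeu log
    score), ``trajectory_`` (score after each accepted move).
    """

    def __init__(self, iss: float = 1.0, max_in_degree: int | None = None,
                 n_bins: int = 3):
        self.iss = iss
        self.max_in_degree = max_in_degree
        self.n_bins = n_bins

    def fit(self, X, y=None, feature_names=None):
        data = self._as_discretized(X, feature_names)
        self.dag_, self.trajectory_ = hill_climb(
            data, iss=self.iss, max_in_degree=self.max_in_degree,
            return_trajectory=True,
        )
        self.score_ = self.trajectory_[-1]
        return self

    def _as_discretized(self, X, feature_names):
        if isinstance(X, DiscretizedMatrix):
            return X
        X = np.asarray(X)
        if np.issubdtype(X.dtype, np.integer):
            genes = pd.Index(feature_names) if feature_names is not None else \
                pd.Index([f"g{i}" for i in range(X.shape[1])])
            breaks = [np.arange(1, X[:, j].max() + 1) - 0.5
                      for j in range(X.shape[1])]
            return DiscretizedMatrix(X, genes, breaks, self.n_bins)
        dm = discretize_interval(X, self.n_bins)
        if feature_names is not None:
            dm.genes = pd.Index(feature_names)
        return dm


# ---------------------------------------------------------------------------
# bootstrap model averaging
# ---------------------------------------------------------------------------

@dataclass
class BootstrapStrength:
    """Per-arc bootstrap presence (strength) and orientation (direction)
    frequencies over replicate structure learns."""

    nodes: list
    n_replicates: int
    pair_counts: dict = field(default_factory=dict)   # frozenset-like sorted pair -> int
    dir_counts: dict = field(default_factory=dict)    # ordered pair -> int

    def strength(self, a, b) -> float:
        return self.pair_counts.get(tuple(sorted((a, b))), 0) / self.n_replicates

    def direction(self, a, b) -> float:
        pair = tuple(sorted((a, b)))
        total = self.pair_counts.get(pair, 0)
        if total == 0:
            return 0.0
        return self.dir_counts.get((a, b), 0) / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), cnt in sorted(self.pair_counts.items()):
            rows.append({
                "node_a": a, "node_b": b,
                "strength": cnt / self.n_replicates,
                "direction_ab": self.direction(a, b),
                "direction_ba": self.direction(b, a),
            })
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "strength",
                           "direction_ab", "direction_ba"]
        )


def bootstrap_strength(
    data: DiscretizedMatrix,
    n_boot: int = 200,
    sample_frac: float = 0.5,
    iss: float = 1.0,
    seed: int = 0,
    max_in_degree: int | None = None,
    replace: bool = False,
) -> BootstrapStrength:
    """Bootstrap arc strength/direction over replicate hill climbs.

    Each replicate draws ceil(sample_frac * n_cells) rows (without
    replacement by default), reuses the full-data discretization bins, and
    learns a DAG. Replicate seeds derive deterministically from ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must lie in (0, 1]")
    n_rows = data.n_cells
    size = math.ceil(sample_frac * n_rows)
    bs = BootstrapStrength(nodes=list(data.genes), n_replicates=n_boot)
    for rep in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        rows = rng.choice(n_rows, size=size, replace=replace)
        sub = DiscretizedMatrix(
            data.values[rows], data.genes, data.breaks, data.n_bins,
            data.constant,
        )
        dag = hill_climb(sub, iss=iss, max_in_degree=max_in_degree)
        for a, b in dag.edges:
            pair = tuple(sorted((a, b)))
            bs.pair_counts[pair] = bs.pair_counts.get(pair, 0) + 1
            bs.dir_counts[(a, b)] = bs.dir_counts.get((a, b), 0) + 1
    return bs


def averaged_network(
    bs: BootstrapStrength,
    strength_thr: float = 0.85,
    direction_thr: float = 0.5,
) -> nx.DiGraph:
    """Threshold bootstrap frequencies into an averaged network.

    Arcs are kept when strength >= strength_thr and oriented toward the
    direction frequency >= direction_thr. An exact 0.5/0.5 split is
    oriented lexicographically (flagged on the edge). Because
    thresholding each arc independently can create cycles, any cycle is
    repaired by dropping its weakest-strength arc (with a warning).
    """
    if not (0 <= strength_thr <= 1 and 0 <= direction_thr <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    g = nx.DiGraph()
    g.add_nodes_from(bs.nodes)
    for (a, b), cnt in sorted(bs.pair_counts.items()):
        strength = cnt / bs.n_replicates
        if strength < strength_thr:
            continue
        d_ab = bs.direction(a, b)
        tie = abs(d_ab - 0.5) < 1e-12
        if tie:
            src, dst, d = a, b, 0.5  # lexicographic: a < b by construction
            warnings.warn(f"orientation tie for arc {a}--{b}; "
                          "oriented lexicographically")
        elif d_ab >= direction_thr:
            src, dst, d = a, b, d_ab
        else:
            src, dst, d = b, a, 1.0 - d_ab
        g.add_edge(src, dst, strength=strength, direction=d, tie=tie)
    # cycle repair
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        weakest = min(cycle, key=lambda e: g.edges[e[0], e[1]]["strength"])
        warnings.warn(
            f"cycle repair: dropping weakest arc {weakest[0]}->{weakest[1]}"
        )
        g.remove_edge(weakest[0], weakest[1])
    return g


class BootstrapNetwork(BaseEstimator):
    """Bootstrap-averaged Bayesian network as an sklearn-style estimator.

    ``fit(X)`` runs discretization (if X is continuous), bootstrap
    structure learning, and threshold averaging. Fitted attributes:
    ``strengths_`` (BootstrapStrength), ``network_`` (thresholded
    averaged DiGraph), ``strength_frame_`` (tidy per-pair table).
    """

    def __init__(self, n_boot=200, sample_frac=0.5, iss=1.0, n_bins=3,
                 strength_thr=0.85, direction_thr=0.5,
                 max_in_degree=None, random_state=0, replace=False):
        self.n_boot = n_boot
        self.sample_frac = sample_frac
        self.iss = iss
        self.n_bins = n_bins
        self.strength_thr = strength_thr
        self.direction_thr = direction_thr
        self.max_in_degree = max_in_degree
        self.random_state = random_state
        self.replace = replace

    def fit(self, X, y=None, feature_names=None):
        if isinstance(X, DiscretizedMatrix):
            data = X
        else:
            data = discretize_interval(np.asarray(X, dtype=float), self.n_bins)
            if feature_names is not None:
                data.genes = pd.Index(feature_names)
        self.strengths_ = bootstrap_strength(
            data, n_boot=self.n_boot, sample_frac=self.sample_frac,
            iss=self.iss, seed=self.random_state,
            max_in_degree=self.max_in_degree, replace=self.replace,
        )
        self.network_ = averaged_network(
            self.strengths_, self.strength_thr, self.direction_thr
        )
        self.strength_frame_ = self.strengths_.to_frame()
        return self


# ---------------------------------------------------------------------------
# condition merging and key drivers
# ---------------------------------------------------------------------------

def merge_condition_networks(
    net_ctrl: nx.DiGraph,
    net_case: nx.DiGraph,
    deg: pd.DataFrame | None = None,
    ctrl_name: str = "NT",
    case_name: str = "HD",
) -> nx.DiGraph:
    """Merge per-condition averaged networks with provenance.

    Nodes and edges are tagged ``ctrl_name`` / ``case_name`` / "both";
    where an edge exists in both conditions the control condition's
    strength is kept as the weight. Node regulation flags (up/down/ns)
    come from the DEG table when given.
    """
    merged = nx.DiGraph()
    for node in sorted(set(net_ctrl.nodes) | set(net_case.nodes)):
        in_ctrl = node in net_ctrl
        in_case = node in net_case
        prov = "both" if (in_ctrl and in_case) else (
            ctrl_name if in_ctrl else case_name)
        reg = "ns"
        if deg is not None and node in deg.index:
            row = deg.loc[node]
            if bool(row["significant"]):
                reg = str(row["direction"])
        merged.add_node(node, provenance=prov, regulation=reg)
    for u, v, attrs in net_ctrl.edges(data=True):
        both = net_case.has_edge(u, v)
        merged.add_edge(
            u, v,
            provenance="both" if both else ctrl_name,
            weight=float(attrs.get("strength", 1.0)),
            direction=float(attrs.get("direction", 1.0)),
        )
    for u, v, attrs in net_case.edges(data=True):
        if not merged.has_edge(u, v):
            merged.add_edge(
                u, v, provenance=case_name,
                weight=float(attrs.get("strength", 1.0)),
                direction=float(attrs.get("direction", 1.0)),
            )
    return merged


def find_key_drivers(net: nx.DiGraph, hub_out_degree: int = 10) -> pd.DataFrame:
    """Hubs (out-degree strictly above ``hub_out_degree``) and connectors
    (non-hub X with hub H1 -> X and X -> hub H2, H1 != H2)."""
    out_deg = dict(net.out_degree())
    hubs = {n for n, d in out_deg.items() if d > hub_out_degree}
    rows = [{"gene": h, "role": "hub", "out_degree": out_deg[h]}
            for h in sorted(hubs)]
    for x in sorted(net.nodes):
        if x in hubs:
            continue
        up_hubs = {p for p in net.predecessors(x) if p in hubs}
        down_hubs = {c for c in net.successors(x) if c in hubs}
        if any(h1 != h2 for h1 in up_hubs for h2 in down_hubs):
            rows.append({"gene": x, "role": "connector",
                         "out_degree": out_deg[x]})
    return pd.DataFrame(rows, columns=["gene", "role", "out_degree"])


def skeleton_f1(learned: nx.DiGraph, true_edges) -> float:
    """F1 of the learned skeleton against a planted skeleton (undirected
    edge sets; orientation is only identifiable up to the Markov
    equivalence class)."""
    learned_sk = {tuple(sorted(e)) for e in learned.edges}
    true_sk = {tuple(sorted(e)) for e in true_edges}
    tp = len(learned_sk & true_sk)
    if tp == 0:
        return 0.0
    precision = tp / len(learned_sk)
    recall = tp / len(true_sk)
    return 2 * precision * recall / (precision + recall)
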