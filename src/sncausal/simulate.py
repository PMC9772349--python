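"""Seeded synthetic single-nucleus RNA-seq generator with planted ground truth.

The generator emulates every statistical structure the downstream stages
assume:

* negative-binomial UMI counts with cell-type-biased co-expression modules
  (a shared per-cell latent factor per module),
* a planted causal DAG among a dedicated gene block, acting through linear
  Gaussian structural equations on latent log-expression, with a fraction
  of edges lost in the disease (HD) condition,
* planted genotype DEGs entering on the log scale (so realized fold
  changes are mean-preserving), a planted fraction of which is rescued
  (effect set to zero) under treatment,
* donor-level CAG-repeat-dependent expression slopes on a dedicated gene
  block, and
* designated mitochondrial genes with a per-cell beta-distributed mito
  fraction, including a configurable fraction of high-mito "bad" cells so
  the QC filter has true positives.

Counts are parameterized as NB(mean mu, dispersion theta) with variance
mu + mu^2/theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix
from .exceptions import InvalidArmError, InvalidDesignError

GENOTYPES = ("NT", "HD")
TREATMENTS = ("vehicle", "T&B")
REGIONS = ("striatum", "cortex")

#: CAG length subtracted before applying per-gene CAG slopes.
CAG_REFERENCE = 20.0


@dataclass
class Donor:
    donor_id: str
    genotype: str
    treatment: str
    cag: float
    age: float
    sex: int  # 0/1
    batch: str


def default_donors() -> list[Donor]:
    """Twelve donors, three per genotype x treatment arm.

    NT donors carry near-normal CAG lengths (18-23); HD donors carry
    expanded repeats (45-70), spanning enough range for slope recovery.
    """
    specs = [
        ("NT", "vehicle", (18, 20, 22)),
        ("NT", "T&B", (19, 21, 23)),
        ("HD", "vehicle", (45, 55, 70)),
        ("HD", "T&B", (48, 60, 66)),
    ]
    donors = []
    i = 0
    for genotype, treatment, cags in specs:
        for cag in cags:
            donors.append(
                Donor(
                    donor_id=f"D{i:02d}",
                    genotype=genotype,
                    treatment=treatment,
                    cag=float(cag),
                    age=50.0 + 3.0 * i,
                    sex=i % 2,
                    batch=f"B{(i // 2) % 2}",
                )
            )
            i += 1
    return donors


@dataclass
class SyntheticDesign:
    """Full parameterization of a synthetic dataset.

    Gene indices are laid out in disjoint blocks, in order: module genes,
    DAG genes, DEG genes, CAG genes, background genes, mitochondrial
    genes (last). The resulting assignments are recorded in the exported
    :class:`GroundTruth`.
    """

    n_genes: int = 2000
    cell_types: dict = field(
        default_factory=lambda: {"MSN": 150, "OL": 150, "OPC": 150, "Astro": 150}
    )
    n_modules: int = 4
    module_size: int = 50
    module_factor_sd: float = 1.0
    dag_genes: int = 20
    dag_max_parents: int = 3
    edge_effect: float = 0.8
    hd_edge_loss_frac: float = 0.3
    n_deg: int = 100
    deg_lfc: float = 1.5
    rescue_frac: float = 0.8
    n_cag_genes: int = 50
    cag_slope: float = 0.02
    donors: list = field(default_factory=default_donors)
    nb_dispersion: float = 2.0
    libsize_lognormal_params: tuple = (math.log(5000.0), 0.3)
    mito_gene_frac: float = 0.01
    bad_cell_frac: float = 0.05
    mito_beta_params: tuple = (2.0, 248.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_modules, self.module_size, self.dag_genes,
            self.dag_max_parents, self.n_deg, self.n_cag_genes,
        )
        if any(c < 0 for c in counts):
            raise InvalidDesignError("all counts must be non-negative")
        for name in ("hd_edge_loss_frac", "rescue_frac", "mito_gene_frac",
                     "bad_cell_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidDesignError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise InvalidDesignError("nb_dispersion must be positive")
        if self.module_factor_sd < 0:
            raise InvalidDesignError("module_factor_sd must be non-negative")
        if not self.cell_types:
            raise InvalidDesignError("at least one cell type is required")
        if any(n <= 0 for n in self.cell_types.values()):
            raise InvalidDesignError("cells per arm must be positive")
        n_special = (self.n_modules * self.module_size + self.dag_genes
                     + self.n_deg + self.n_cag_genes)
        self._n_mito = int(np.ceil(self.mito_gene_frac * self.n_genes))
        if n_special + self._n_mito > self.n_genes:
            raise InvalidDesignError(
                "gene blocks (modules + DAG + DEG + CAG + mito) exceed n_genes"
            )

    @property
    def n_mito(self) -> int:
        return self._n_mito

    def gene_names(self) -> pd.Index:
        n_reg = self.n_genes - self.n_mito
        names = [f"G{i:04d}" for i in range(n_reg)]
        names += [f"mt-G{i:04d}" for i in range(n_reg, self.n_genes)]
        return pd.Index(names)


@dataclass
class GroundTruth:
    """Planted structure exported alongside a synthetic dataset."""

    module_labels: np.ndarray          # per gene; 0 = unassigned
    dag_nt: list                       # directed edges, gene-name pairs
    dag_hd: list                       # subset of dag_nt
    deg_effects: dict                  # gene -> signed log2 effect
    rescued_genes: set
    cag_slopes: dict                   # gene -> natural-log slope per CAG unit
    genes: pd.Index = None
    dag_gene_names: list = field(default_factory=list)
    baseline_log: np.ndarray = None    # internal: per-gene baseline log weight
    module_anchor_type: dict = field(default_factory=dict)

    def validate(self) -> None:
        for edges, name in ((self.dag_nt, "dag_nt"), (self.dag_hd, "dag_hd")):
            g = nx.DiGraph(edges)
            if not nx.is_directed_acyclic_graph(g):
                raise InvalidDesignError(f"{name} contains a cycle")
        if not set(self.dag_hd) <= set(self.dag_nt):
            raise InvalidDesignError("dag_hd must be a subset of dag_nt")
        if not self.rescued_genes <= {
            g for g, e in self.deg_effects.items() if e != 0
        }:
            raise InvalidDesignError(
                "rescued genes must have nonzero planted DEG effects"
            )

    def module_gene_names(self, module: int) -> list:
        idx = np.flatnonzero(self.module_labels == module)
        return list(self.genes[idx])


def generate_dag(n_nodes: int, max_parents: int, seed: int) -> nx.DiGraph:
    """Random DAG in which every node has at most ``max_parents`` parents.

    Nodes 0..n-1 are generated in a fixed topological order (parents have
    smaller indices), so acyclicity holds by construction. Deterministic
    given the seed.
    """
    if n_nodes < 1:
        raise InvalidDesignError("n_nodes must be at least 1")
    if max_parents < 0:
        raise InvalidDesignError("max_parents must be non-negative")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for child in range(1, n_nodes):
        k = int(rng.integers(0, min(child, max_parents) + 1))
        if k > 0:
            parents = rng.choice(child, size=k, replace=False)
            for p in sorted(int(x) for x in parents):
                g.add_edge(p, child)
    return g


def build_ground_truth(design: SyntheticDesign) -> GroundTruth:
    """Draw the planted structure implied by a design (seeded)."""
    ss = np.random.SeedSequence([design.seed, 0])
    rng = np.random.default_rng(ss)
    genes = design.gene_names()
    n = design.n_genes

    labels = np.zeros(n, dtype=int)
    pos = 0
    for m in range(1, design.n_modules + 1):
        labels[pos:pos + design.module_size] = m
        pos += design.module_size
    dag_idx = np.arange(pos, pos + design.dag_genes)
    pos += design.dag_genes
    deg_idx = np.arange(pos, pos + design.n_deg)
    pos += design.n_deg
    cag_idx = np.arange(pos, pos + design.n_cag_genes)

    dag_seed = int(rng.integers(0, 2**31 - 1))
    if design.dag_genes > 0:
        g = generate_dag(design.dag_genes, design.dag_max_parents, dag_seed)
        name = {i: genes[dag_idx[i]] for i in range(design.dag_genes)}
        dag_nt = [(name[a], name[b]) for a, b in sorted(g.edges())]
    else:
        dag_nt = []
    n_remove = int(round(design.hd_edge_loss_frac * len(dag_nt)))
    removed = set()
    if n_remove > 0:
        drop = rng.choice(len(dag_nt), size=n_remove, replace=False)
        removed = {dag_nt[i] for i in drop}
    dag_hd = [e for e in dag_nt if e not in removed]

    # Alternate up/down effects in pairs; the paired baseline weights set
    # below make the total expression mass mean-preserving under the
    # effects, so library-size normalization leaves non-DEG genes null.
    signs = np.where(np.arange(design.n_deg) % 2 == 0, 1.0, -1.0)
    deg_effects = {genes[i]: float(s * design.deg_lfc)
                   for i, s in zip(deg_idx, signs)}
    n_rescued = int(round(design.rescue_frac * design.n_deg))
    rescued = set()
    if n_rescued > 0:
        pick = rng.choice(design.n_deg, size=n_rescued, replace=False)
        rescued = {genes[deg_idx[i]] for i in pick}

    slope_mag = rng.uniform(0.25, 1.0, size=design.n_cag_genes)
    slope_sign = rng.choice([-1.0, 1.0], size=design.n_cag_genes)
    cag_slopes = {genes[i]: float(design.cag_slope * m * s)
                  for i, m, s in zip(cag_idx, slope_mag, slope_sign)}

    # Baseline log-weights: biologically "interesting" genes are kept at
    # moderate-to-high expression so they survive the 25%-expression
    # filter; background genes span a wide dynamic range.
    special = np.zeros(n, dtype=bool)
    special[:design.n_modules * design.module_size] = True
    special[dag_idx] = True
    special[deg_idx] = True
    special[cag_idx] = True
    baseline = rng.normal(0.0, 1.5, size=n)
    baseline[special] = rng.normal(1.2, 0.4, size=int(special.sum()))
    # Pair each up-regulated DEG gene with the next (down-regulated) one
    # and give the down gene 2^lfc times the up gene's baseline weight:
    # the up gene's expression gain under the effect then exactly offsets
    # the down gene's loss, so the per-cell total rate is unchanged and
    # realized fold changes are not distorted by renormalization.
    for k in range(0, design.n_deg - 1, 2):
        baseline[deg_idx[k + 1]] = (
            baseline[deg_idx[k]] + math.log(2.0) * design.deg_lfc
        )
    baseline[n - design.n_mito:] = 0.0  # mito handled via target fraction

    cell_types = list(design.cell_types)
    anchors = {m: cell_types[(m - 1) % len(cell_types)]
               for m in range(1, design.n_modules + 1)}

    truth = GroundTruth(
        module_labels=labels,
        dag_nt=dag_nt,
        dag_hd=dag_hd,
        deg_effects=deg_effects,
        rescued_genes=rescued,
        cag_slopes=cag_slopes,
        genes=genes,
        dag_gene_names=list(genes[dag_idx]),
        baseline_log=baseline,
        module_anchor_type=anchors,
    )
    truth.validate()
    return truth


def _structural_values(edges, n_nodes, node_index, effect, n_cells, rng):
    """Linear Gaussian structural equations in topological order.

    Each node is standardized to unit marginal variance after its
    structural equation: multi-parent chains would otherwise accumulate
    variance multiplicatively, and exp() of such heavy-tailed log values
    dominates the per-cell rate normalization. Standardization is
    scale-free for the parent-child dependence the downstream learner
    uses while keeping latent log-expression in a realistic range.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from([(node_index[a], node_index[b]) for a, b in edges])
    x = np.zeros((n_cells, n_nodes))
    for node in nx.topological_sort(g):
        noise = rng.normal(0.0, 1.0, size=n_cells)
        parents = list(g.predecessors(node))
        v = effect * x[:, parents].sum(axis=1) + noise
        sd = v.std()
        x[:, node] = v / sd if sd > 0 else v
    return x


def dag_structural_matrix(
    truth: GroundTruth,
    n_cells: int,
    edge_effect: float,
    rng: np.random.Generator,
    condition: str = "NT",
) -> pd.DataFrame:
    """Latent structural values of the planted DAG genes (cells x genes).

    This is the linear-Gaussian layer the count model observes through
    negative-binomial sampling; learning directly from it (after interval
    discretization) isolates the structure learner from observation
    noise. ``condition`` selects the NT or HD edge set.
    """
    edges = truth.dag_nt if condition == "NT" else truth.dag_hd
    nodes = truth.dag_gene_names
    node_index = {g: i for i, g in enumerate(nodes)}
    x = _structural_values(edges, len(nodes), node_index, edge_effect,
                           n_cells, rng)
    return pd.DataFrame(x, columns=nodes)


def simulate_latent_expression(
    design: SyntheticDesign,
    truth: GroundTruth,
    cell_arm: tuple,
    n_cells: int,
    rng: np.random.Generator,
    donor_cag: np.ndarray | None = None,
    mito_target: np.ndarray | None = None,
) -> np.ndarray:
    """Latent natural-log relative expression, cells x genes.

    ``cell_arm`` is ``(genotype, treatment, cell_type)``. The latent values
    are log-scale contributions to a per-gene relative rate; exp(latent)
    sums to ~1 per cell so library-size scaling in :func:`sample_counts`
    yields the intended totals.
    """
    genotype, treatment, cell_type = cell_arm
    if genotype not in GENOTYPES:
        raise InvalidArmError(f"unknown genotype {genotype!r}")
    if treatment not in TREATMENTS:
        raise InvalidArmError(f"unknown treatment {treatment!r}")
    if cell_type not in design.cell_types:
        raise InvalidArmError(f"unknown cell type {cell_type!r}")

    genes = truth.genes
    n = design.n_genes
    n_mito = design.n_mito
    regular = slice(0, n - n_mito)

    latent = np.tile(truth.baseline_log, (n_cells, 1)).astype(float)

    # Module factors: shared per-cell latent factor, loading 1; the
    # module's anchor cell type gets a +1 mean shift so module eigengenes
    # correlate with cell-type traits.
    for m in range(1, design.n_modules + 1):
        shift = 1.0 if truth.module_anchor_type.get(m) == cell_type else 0.0
        factor = rng.normal(shift, design.module_factor_sd, size=n_cells)
        idx = np.flatnonzero(truth.module_labels == m)
        latent[:, idx] += factor[:, None]

    # Planted causal DAG on latent log-expression.
    dag_edges = truth.dag_nt if genotype == "NT" else truth.dag_hd
    dag_nodes = sorted({g for e in truth.dag_nt for g in e})
    if dag_nodes:
        node_index = {g: i for i, g in enumerate(dag_nodes)}
        x = _structural_values(
            dag_edges, len(dag_nodes), node_index, design.edge_effect,
            n_cells, rng,
        )
        col = genes.get_indexer(pd.Index(dag_nodes))
        latent[:, col] += x

    # Genotype DEG effects (log2 -> natural log); treatment rescues a
    # planted subset by zeroing the effect.
    if genotype == "HD" and truth.deg_effects:
        eff = np.zeros(n)
        for g, lfc in truth.deg_effects.items():
            if treatment == "T&B" and g in truth.rescued_genes:
                continue
            eff[genes.get_loc(g)] = math.log(2.0) * lfc
        latent += eff[None, :]

    # Donor CAG slopes.
    if donor_cag is not None and truth.cag_slopes:
        donor_cag = np.asarray(donor_cag, dtype=float)
        for g, slope in truth.cag_slopes.items():
            latent[:, genes.get_loc(g)] += slope * (donor_cag - CAG_REFERENCE)

    # Normalize regular genes to relative rates, then split the per-cell
    # rate between mito and non-mito genes according to the target mito
    # fraction.
    reg = latent[:, regular]
    reg -= np.log(np.exp(reg).sum(axis=1))[:, None]
    latent[:, regular] = reg
    if n_mito > 0:
        if mito_target is None:
            mito_target = np.zeros(n_cells)
        mito_target = np.clip(np.asarray(mito_target, dtype=float), 0.0, 0.99)
        with np.errstate(divide="ignore"):
            latent[:, regular] += np.log1p(-mito_target)[:, None]
            latent[:, n - n_mito:] = (
                np.log(np.where(mito_target > 0, mito_target, np.nan))[:, None]
                - math.log(n_mito)
            )
        latent[:, n - n_mito:] = np.nan_to_num(
            latent[:, n - n_mito:], nan=-np.inf, neginf=-np.inf
        )
    return latent


def sample_counts(
    latent: np.ndarray,
    libsize_params: tuple,
    nb_dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial counts (cells x genes) from latent log rates.

    Per-cell library sizes are lognormal; the NB mean for gene g in cell c
    is ``L_c * exp(latent[c, g])`` and the variance is mu + mu^2/theta.
    """
    if nb_dispersion <= 0:
        raise InvalidDesignError("nb_dispersion must be positive")
    mu_log, sigma_log = libsize_params
    n_cells = latent.shape[0]
    libsize = rng.lognormal(mu_log, sigma_log, size=n_cells)
    mean = libsize[:, None] * np.exp(latent)
    theta = float(nb_dispersion)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p).astype(np.int64)


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate counts, cell metadata, and ground truth for a design.

    Cells are laid out arm by arm in a fixed order (cell type, then
    genotype, then treatment); within an arm, donors of the matching
    genotype x treatment group are assigned round-robin and cells are
    split evenly across the two regions.
    """
    truth = build_ground_truth(design)
    ss = np.random.SeedSequence([design.seed, 1])
    rng_latent, rng_counts, rng_mito = [
        np.random.default_rng(c) for c in ss.spawn(3)
    ]

    blocks = []
    meta_rows = []
    for cell_type, n_cells in design.cell_types.items():
        for genotype in GENOTYPES:
            for treatment in TREATMENTS:
                donors = [d for d in design.donors
                          if d.genotype == genotype and d.treatment == treatment]
                if not donors:
                    raise InvalidDesignError(
                        f"no donors for arm {genotype}/{treatment}"
                    )
                arm_donors = [donors[i % len(donors)] for i in range(n_cells)]
                cag = np.array([d.cag for d in arm_donors])
                n_bad = int(round(design.bad_cell_frac * n_cells))
                a, b = design.mito_beta_params
                mito_target = rng_mito.beta(a, b, size=n_cells)
                if n_bad > 0:
                    bad = rng_mito.choice(n_cells, size=n_bad, replace=False)
                    mito_target[bad] = rng_mito.uniform(0.03, 0.10, size=n_bad)
                latent = simulate_latent_expression(
                    design, truth, (genotype, treatment, cell_type),
                    n_cells, rng_latent, donor_cag=cag,
                    mito_target=mito_target if design.n_mito > 0 else None,
                )
                counts = sample_counts(
                    latent, design.libsize_lognormal_params,
                    design.nb_dispersion, rng_counts,
                )
                blocks.append(sp.csr_matrix(counts))
                for i, d in enumerate(arm_donors):
                    meta_rows.append({
                        "sample": f"{d.donor_id}_{REGIONS[i % 2]}",
                        "donor": d.donor_id,
                        "cell_type": cell_type,
                        "genotype": genotype,
                        "treatment": treatment,
                        "region": REGIONS[i % 2],
                        "age": d.age,
                        "sex": d.sex,
                        "batch": d.batch,
                        "cag": d.cag,
                    })

    counts_cg = sp.vstack(blocks).tocsr()  # cells x genes
    genes = truth.genes
    mito = np.zeros(design.n_genes, dtype=bool)
    if design.n_mito > 0:
        mito[design.n_genes - design.n_mito:] = True
    barcodes = pd.Index([f"cell{i:06d}" for i in range(counts_cg.shape[0])])
    cm = CountMatrix(counts_cg.T.tocsr(), genes, barcodes, mito)
    meta = pd.DataFrame(meta_rows, index=barcodes)
    meta["library_size"] = cm.library_size()
    meta["mito_frac"] = cm.mito_fraction_per_cell()
    meta["n_genes_detected"] = cm.detected_genes_per_cell()
    return cm, meta, truth
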