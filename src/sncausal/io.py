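"""File I/O, run configuration, and the end-to-end pipeline orchestrator.

Formats: Matrix Market (.mtx) with genes/barcodes TSVs (10x-style, genes
as rows), TSV tables for DEG/module/network outputs, GraphML for merged
networks, JSON for ground truth and the run manifest. All randomness
flows from the single configured seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io as scio
import scipy.sparse as sp
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import bayesnet, cag, coexpression, qc, rescue
from .containers import CountMatrix, validate_cell_metadata
from .deg import significant_genes, wilcoxon_deg
from .exceptions import FormatError, PipelineError
from .simulate import GroundTruth, SyntheticDesign, generate_dataset

logger = logging.getLogger("sncausal")


# ---------------------------------------------------------------------------
# matrix + metadata I/O
# ---------------------------------------------------------------------------

def read_counts_mtx(path_mtx, path_genes, path_barcodes) -> CountMatrix:
    """Read a 10x-style Matrix Market bundle (genes x cells).

    Gene names are deduplicated with numeric suffixes (warning logged);
    dimension mismatches and non-integer entries raise FormatError. A
    'mito' column in the gene file, or a 'mt-' name prefix, flags
    mitochondrial genes.
    """
    try:
        mat = scio.mmread(str(path_mtx))
    except Exception as exc:  # malformed header/entries
        raise FormatError(f"cannot parse {path_mtx}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError(f"{path_mtx} contains non-integer entries")
        mat = mat.astype(np.int64)
    genes_df = pd.read_csv(path_genes, sep="\t")
    barcodes = pd.read_csv(path_barcodes, sep="\t", header=None)[0]
    if mat.shape != (len(genes_df), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape} but gene/barcode files describe "
            f"({len(genes_df)}, {len(barcodes)})"
        )
    names = genes_df.iloc[:, 0].astype(str)
    if names.duplicated().any():
        dupes = names[names.duplicated()].unique()
        warnings.warn(f"duplicated gene names suffixed: {list(dupes)[:5]}")
        names = pd.Index(_make_unique(names))
    if "mito" in genes_df.columns:
        mito = genes_df["mito"].astype(bool).to_numpy()
    else:
        mito = names.str.lower().str.startswith("mt-").to_numpy()
    return CountMatrix(mat.tocsr(), pd.Index(names), pd.Index(barcodes), mito)


def _make_unique(names: pd.Series) -> list:
    seen: dict = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def write_dataset(out_dir, counts: CountMatrix, meta: pd.DataFrame,
                  truth: GroundTruth | None = None) -> dict:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_metadata.tsv
    (+ ground_truth.json). Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
        "metadata": out / "cell_metadata.tsv",
    }
    scio.mmwrite(str(paths["matrix"]), counts.counts.astype(np.int64))
    pd.DataFrame({"gene": counts.genes, "mito": counts.mito.astype(int)}) \
        .to_csv(paths["genes"], sep="\t", index=False)
    pd.Series(counts.barcodes).to_csv(paths["barcodes"], sep="\t",
                                      index=False, header=False)
    meta.to_csv(paths["metadata"], sep="\t", index_label="barcode")
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        with open(paths["ground_truth"], "w") as fh:
            json.dump(ground_truth_to_dict(truth), fh, indent=1)
    return paths


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "module_labels": {g: int(m) for g, m in
                          zip(truth.genes, truth.module_labels) if m != 0},
        "dag_nt": [list(e) for e in truth.dag_nt],
        "dag_hd": [list(e) for e in truth.dag_hd],
        "deg_effects": {g: float(v) for g, v in truth.deg_effects.items()},
        "rescued_genes": sorted(truth.rescued_genes),
        "cag_slopes": {g: float(v) for g, v in truth.cag_slopes.items()},
    }


def write_network_graphml(net: nx.DiGraph, path) -> None:
    """GraphML with node/edge attributes preserved (numeric stays numeric)."""
    nx.write_graphml(net, str(path))


def read_network_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(str(path))


def network_to_frame(net: nx.DiGraph) -> pd.DataFrame:
    """Edge-list TSV form: parent, child, plus all edge attributes."""
    rows = []
    for u, v, attrs in net.edges(data=True):
        row = {"parent": u, "child": v}
        row.update(attrs)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_genes: int = Field(200, gt=0)
    max_genes: int = Field(6000, gt=0)
    max_mito: float = Field(0.02, ge=0, le=1)


class DEGConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.05, gt=0, lt=1)
    min_frac: float = Field(0.25, gt=0, le=1)


class ModulesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    condition: str = "NT"
    min_module_size: int = Field(30, ge=2)
    cut_height: float = Field(0.99, gt=0, le=1)
    merge_cor: float = Field(0.75, gt=0, le=1)
    max_cells: int = Field(10000, gt=0)


class BnetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_boot: int = Field(200, ge=1)
    sample_frac: float = Field(0.5, gt=0, le=1)
    iss: float = Field(1.0, gt=0)
    n_bins: int = Field(3, ge=2)
    strength: float = Field(0.85, ge=0, le=1)
    direction: float = Field(0.5, ge=0, le=1)
    max_in_degree: int | None = None
    max_features: int = Field(50, ge=2)
    hub_out_degree: int = Field(10, ge=1)
    cell_types: list[str] | None = None


class RescueConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    alpha: float = Field(0.05, gt=0, lt=1)
    pseudocount: float = Field(1.0, gt=0)


class CagConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    cell_types: list[str] | None = None
    covariates: list[str] = ["age", "sex"]
    dummy_cols: list[str] = ["batch", "region"]
    alpha: float = Field(0.05, gt=0, lt=1)


class RunConfig(BaseModel):
    """Validated end-to-end pipeline configuration. Unknown keys are
    rejected; all parameters are range-checked before any stage runs."""

    model_config = ConfigDict(extra="forbid")
    matrix: str | None = None
    genes: str | None = None
    barcodes: str | None = None
    metadata: str | None = None
    out_dir: str = "sncausal_run"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict | None = None
    qc: QCConfig = QCConfig()
    deg: DEGConfig = DEGConfig()
    modules: ModulesConfig = ModulesConfig()
    bnet: BnetConfig = BnetConfig()
    rescue: RescueConfig = RescueConfig()
    cag: CagConfig = CagConfig()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


# ---------------------------------------------------------------------------
# pipeline orchestrator
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> qc -> deg -> modules -> features ->
    bnet (per condition) -> merge -> drivers -> rescue -> cag.

    Writes stage outputs under ``config.out_dir`` and returns (and
    writes) a JSON manifest with the parameter echo, per-stage status,
    and output file hashes. Stage failures abort with the stage named.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "parameters": config.model_dump(),
                "stages": [], "outputs": {}}
    truth = None

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        if config.matrix is not None:
            counts = read_counts_mtx(config.matrix, config.genes,
                                     config.barcodes)
            meta = pd.read_csv(config.metadata, sep="\t", index_col=0)
        else:
            stage("simulate")
            overrides = dict(config.simulate or {})
            overrides.setdefault("seed", config.seed)
            design = SyntheticDesign(**overrides)
            counts, meta, truth = generate_dataset(design)
            write_dataset(out / "simulated", counts, meta, truth)
        validate_cell_metadata(meta, counts)

        stage("qc")
        counts, meta = qc.filter_cells(
            counts, meta, config.qc.min_genes, config.qc.max_genes,
            config.qc.max_mito,
        )
        kept_genes = qc.filter_genes_min_frac(counts, config.deg.min_frac)
        norm = qc.log_normalize(counts)

        stage("deg")
        cell_types = list(dict.fromkeys(meta["cell_type"]))
        vehicle_mask = (meta["treatment"] == "vehicle").to_numpy() \
            if "treatment" in meta.columns else np.ones(len(meta), bool)
        degs = {}
        for ct in cell_types:
            ct_mask = (meta["cell_type"] == ct).to_numpy()
            g1 = ct_mask & vehicle_mask & (meta["genotype"] == "HD").to_numpy()
            g2 = ct_mask & vehicle_mask & (meta["genotype"] == "NT").to_numpy()
            if g1.sum() < 3 or g2.sum() < 3:
                continue
            degs[ct] = wilcoxon_deg(norm, g1, g2, config.deg.min_frac,
                                    config.deg.alpha)
            degs[ct].to_csv(out / f"deg_{ct}.tsv", sep="\t", index=False)

        stage("modules")
        nt_mask = (meta["genotype"] == config.modules.condition).to_numpy()
        norm_f = norm.subset_genes(kept_genes)
        X_mod = norm_f.values[:, nt_mask].T
        cm = coexpression.CoexpressionModules(
            min_module_size=config.modules.min_module_size,
            cut_height=config.modules.cut_height,
            merge_cor=config.modules.merge_cor,
            max_cells=config.modules.max_cells,
            random_state=config.seed,
        ).fit(X_mod, feature_names=norm_f.genes)
        pd.DataFrame({"gene": norm_f.genes, "module": cm.labels_}) \
            .to_csv(out / "modules.tsv", sep="\t", index=False)

        stage("module_traits")
        nt_idx = np.flatnonzero(nt_mask)
        traits = pd.get_dummies(
            meta.iloc[nt_idx[cm.cells_used_]]["cell_type"]
        ).astype(float).reset_index(drop=True)
        mt = coexpression.module_trait_correlation(cm.eigengenes_, traits)
        mt.to_csv(out / "module_traits.tsv", sep="\t", index=False)

        stage("bnet")
        bnet_cts = config.bnet.cell_types or cell_types
        networks = {}
        for ct in bnet_cts:
            if ct not in degs:
                continue
            merged = _bnet_for_celltype(
                config, norm_f, meta, ct, degs[ct], cm, mt, out, truth
            )
            if merged is not None:
                networks[ct] = merged

        if config.rescue.enabled and "treatment" in meta.columns \
                and set(meta["treatment"]) >= {"vehicle", "T&B"}:
            stage("rescue")
            rescue_rows = []
            for ct in cell_types:
                try:
                    tables = rescue.run_contrasts(
                        norm, meta, ct, min_frac=config.deg.min_frac,
                        alpha=config.rescue.alpha,
                    )
                except Exception:
                    continue
                rt = rescue.classify_rescue(tables["genotype"],
                                            tables["treatment"])
                red = rescue.deg_reduction(
                    len(significant_genes(tables["residual"])),
                    len(significant_genes(tables["genotype"])),
                    config.rescue.pseudocount,
                )
                rescue_rows.append({
                    "cell_type": ct,
                    "rescue_fraction": rescue.rescue_fraction(rt),
                    "n_overlap": len(rt),
                    "n_vehicle_degs": red.n_vehicle,
                    "n_treated_degs": red.n_treated,
                    "log2_deg_ratio": red.log2_ratio,
                })
                rt.to_csv(out / f"rescue_{ct}.tsv", sep="\t", index=False)
            pd.DataFrame(rescue_rows).to_csv(out / "rescue_summary.tsv",
                                             sep="\t", index=False)

        if config.cag.enabled and "cag" in meta.columns \
                and meta["cag"].nunique() > 1:
            stage("cag")
            cag_cts = config.cag.cell_types or cell_types[:2]
            fits = {}
            for ct in cag_cts:
                pb = cag.pseudobulk_sum(counts, meta, cell_type=ct)
                fit = cag.CagRegression(
                    covariates=tuple(config.cag.covariates),
                    dummy_cols=tuple(config.cag.dummy_cols),
                    alpha=config.cag.alpha,
                ).fit(pb)
                fits[ct] = fit.results_
                fit.results_.to_csv(out / f"cag_{ct}.tsv", sep="\t",
                                    index=False)
            if len(fits) >= 2:
                cts = list(fits)
                quad = cag.classify_cag_quadrants(fits[cts[0]], fits[cts[1]])
                quad.to_csv(out / "cag_quadrants.tsv", sep="\t", index=False)

        stage("manifest")
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        raise PipelineError(f"stage {failed!r} failed: {exc}") from exc


def _bnet_for_celltype(config, norm_f, meta, ct, deg_table, cm, mt, out,
                       truth):
    """Feature selection + per-condition bootstrap networks + merge for
    one cell type; returns the merged network or None."""
    ct_degs = significant_genes(deg_table) & set(norm_f.genes)
    mt_ct = mt[(mt["trait"] == ct) & (~mt["degenerate"])]
    module_genes: set = set()
    best_module = None
    if len(mt_ct) and mt_ct["r"].max() > 0:
        best_module = mt_ct.loc[mt_ct["r"].idxmax(), "module"]
        m_id = int(str(best_module).replace("ME", ""))
        module_genes = set(cm.module_genes(m_id))
    if not ct_degs and not module_genes:
        return None
    features = bayesnet.select_features(ct_degs, module_genes)
    if len(features) > config.bnet.max_features:
        features = _rank_features(features, ct_degs, module_genes,
                                  deg_table, cm, best_module,
                                  config.bnet.max_features)
    ct_mask = (meta["cell_type"] == ct).to_numpy()
    if "treatment" in meta.columns:
        ct_mask &= (meta["treatment"] == "vehicle").to_numpy()
    sub = norm_f.subset_genes(features)
    # bins from all cells of the cell type so NT and HD share a coding
    data_all = bayesnet.discretize_interval(
        sub.subset_cells(ct_mask), config.bnet.n_bins
    )
    nets = {}
    for cond in ("NT", "HD"):
        cond_rows = (meta.loc[ct_mask, "genotype"] == cond).to_numpy()
        if cond_rows.sum() < 10:
            return None
        from .containers import DiscretizedMatrix
        data = DiscretizedMatrix(
            data_all.values[cond_rows], data_all.genes, data_all.breaks,
            data_all.n_bins, data_all.constant,
        )
        bs = bayesnet.bootstrap_strength(
            data, n_boot=config.bnet.n_boot,
            sample_frac=config.bnet.sample_frac, iss=config.bnet.iss,
            seed=config.seed, max_in_degree=config.bnet.max_in_degree,
        )
        nets[cond] = bayesnet.averaged_network(
            bs, config.bnet.strength, config.bnet.direction
        )
        network_to_frame(nets[cond]).to_csv(
            out / f"bnet_{ct}_{cond}.tsv", sep="\t", index=False
        )
    merged = bayesnet.merge_condition_networks(
        nets["NT"], nets["HD"], deg_table
    )
    drivers = bayesnet.find_key_drivers(merged, config.bnet.hub_out_degree)
    for node, row in zip(drivers["gene"], drivers["role"]):
        merged.nodes[node]["key_driver_role"] = row
    write_network_graphml(merged, out / f"bnet_{ct}_merged.graphml")
    drivers.to_csv(out / f"key_drivers_{ct}.tsv", sep="\t", index=False)
    return merged


def _rank_features(features, ct_degs, module_genes, deg_table, cm,
                   best_module, max_features):
    """Deterministic cap: module genes ranked by kME to the correlated
    module, then remaining DEGs by adjusted p."""
    ranked = []
    if best_module is not None and best_module in cm.kme_.columns:
        kme_col = cm.kme_[best_module]
        ranked += sorted(
            (g for g in features if g in module_genes),
            key=lambda g: (-float(kme_col.get(g, 0.0)), g),
        )
    rest = [g for g in features if g not in set(ranked)]
    in_deg = deg_table.index.intersection(rest)
    ranked += list(deg_table.loc[in_deg].sort_values("p_adj").index)
    ranked += sorted(g for g in rest if g not in set(ranked))
    return sorted(ranked[:max_features])
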