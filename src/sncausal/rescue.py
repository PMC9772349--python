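"""Treatment-rescue analysis: three-contrast DEG calling, overlap
significance, Z-scored log2FC discordance classification, and DEG-count
reduction ratios.

Rescue is operationalized as sign discordance: a gene significant in both
the genotype contrast (case+vehicle vs ctrl+vehicle) and the treatment
contrast (case+treated vs case+vehicle) whose Z-scored effects have
opposite signs is "rescued"; same-sign genes are "exacerbated".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix
from .deg import significant_genes, wilcoxon_deg
from .exceptions import MissingArmError
from .stats import hypergeometric_overlap, zscore_log2fc


def run_contrasts(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    genotype_col: str = "genotype",
    treatment_col: str = "treatment",
    ctrl: str = "NT",
    case: str = "HD",
    vehicle: str = "vehicle",
    treated: str = "T&B",
    min_frac: float = 0.25,
    alpha: float = 0.05,
) -> dict:
    """Three Wilcoxon DEG tables for one cell type.

    genotype : (case, vehicle) vs (ctrl, vehicle)
    treatment: (case, treated) vs (case, vehicle)
    residual : (case, treated) vs (ctrl, vehicle)
    """
    ct_mask = (meta["cell_type"] == cell_type).to_numpy()
    arms = {}
    for g, t in ((ctrl, vehicle), (ctrl, treated), (case, vehicle), (case, treated)):
        mask = ct_mask & (meta[genotype_col] == g).to_numpy() \
            & (meta[treatment_col] == t).to_numpy()
        if mask.sum() < 3:
            raise MissingArmError(
                f"arm ({g}, {t}) for cell type {cell_type!r} has "
                f"{int(mask.sum())} cells (minimum 3)"
            )
        arms[(g, t)] = mask
    kwargs = {"min_frac": min_frac, "alpha": alpha}
    return {
        "genotype": wilcoxon_deg(norm, arms[(case, vehicle)],
                                 arms[(ctrl, vehicle)], **kwargs),
        "treatment": wilcoxon_deg(norm, arms[(case, treated)],
                                  arms[(case, vehicle)], **kwargs),
        "residual": wilcoxon_deg(norm, arms[(case, treated)],
                                 arms[(ctrl, vehicle)], **kwargs),
    }


def overlap_significance(
    deg_genotype: pd.DataFrame,
    deg_treatment: pd.DataFrame,
    universe=None,
) -> tuple[int, float]:
    """Hypergeometric upper-tail significance of the overlap between the
    genotype-significant and treatment-significant gene sets. The default
    universe is the set of genes tested in both contrasts."""
    if universe is None:
        universe = set(deg_genotype["gene"]) & set(deg_treatment["gene"])
    universe = set(universe)
    sig_g = significant_genes(deg_genotype) & universe
    sig_t = significant_genes(deg_treatment) & universe
    return hypergeometric_overlap(sig_g, sig_t, universe)


def classify_rescue(
    deg_genotype: pd.DataFrame,
    deg_treatment: pd.DataFrame,
) -> pd.DataFrame:
    """Classify genes significant in both contrasts by Z-scored log2FC
    sign discordance.

    Returns a table with columns ``gene, z_genotype, z_treatment, class``
    where class is rescued (opposite signs), exacerbated (same sign), or
    unchanged (a zero Z-score). Empty overlap yields an empty table with
    a warning.
    """
    z_g = zscore_log2fc(deg_genotype)
    z_t = zscore_log2fc(deg_treatment)
    overlap = sorted(significant_genes(deg_genotype)
                     & significant_genes(deg_treatment))
    if not overlap:
        warnings.warn("no genes significant in both contrasts")
        return pd.DataFrame(
            columns=["gene", "z_genotype", "z_treatment", "class"]
        )
    zg = z_g.loc[overlap].to_numpy()
    zt = z_t.loc[overlap].to_numpy()
    cls = np.where(
        (zg == 0) | (zt == 0), "unchanged",
        np.where(np.sign(zg) != np.sign(zt), "rescued", "exacerbated"),
    )
    return pd.DataFrame({
        "gene": overlap, "z_genotype": zg, "z_treatment": zt, "class": cls,
    }).set_index("gene", drop=False).rename_axis(None)


def rescue_fraction(rescue_table: pd.DataFrame) -> float:
    """rescued / (rescued + exacerbated); 0.0 when nothing is classified."""
    n_res = int((rescue_table["class"] == "rescued").sum())
    n_exa = int((rescue_table["class"] == "exacerbated").sum())
    if n_res + n_exa == 0:
        return 0.0
    return n_res / (n_res + n_exa)


@dataclass
class DegReduction:
    """DEG-count reduction by treatment for one cell type."""

    n_vehicle: int
    n_treated: int
    log2_ratio: float


def deg_reduction(
    n_treated: int, n_vehicle: int, pseudocount: float = 1.0
) -> DegReduction:
    """log2((n_treated + eps) / (n_vehicle + eps)) with eps = 1 pseudocount.

    ``n_treated`` counts significant DEGs in case+treated vs ctrl+vehicle;
    ``n_vehicle`` counts case+vehicle vs ctrl+vehicle. Negative values
    indicate a net reduction of disease DEGs by treatment.
    """
    if n_treated < 0 or n_vehicle < 0:
        raise ValueError("DEG counts must be non-negative")
    ratio = math.log2((n_treated + pseudocount) / (n_vehicle + pseudocount))
    return DegReduction(int(n_vehicle), int(n_treated), ratio)
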