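"""Multiplex-IF spatial statistics: phenotype gating, compartment assignment,
cell densities, density ratios, nearest-neighbor shortest distances and
distance ratios, with recurrence-group comparisons.

Distances are centroid-to-centroid Euclidean in micrometers, without edge
correction; "total CD8" means PD1-negative plus PD1-positive CD8 T cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._stats import rank_sum_test
from .exceptions import (
    DegenerateCompartmentError,
    EmptyClassError,
    SchemaError,
    SpatialTMEError,
    UncomputableRatioError,
)
from .synthetic import CellMap, in_any_nest

GATING_MARKERS = ["CK", "CD8", "PD1", "CD68", "FOXP3", "CD56"]

#: "total CD8" aggregates both PD1 states
CD8_TOTAL = ("CD8_PD1neg", "CD8_PD1pos")


def _resolve_phenotype(cells: pd.DataFrame, phenotype) -> pd.Series:
    if phenotype == "CD8_total":
        return cells["phenotype"].isin(CD8_TOTAL)
    if isinstance(phenotype, (list, tuple, set)):
        return cells["phenotype"].isin(phenotype)
    return cells["phenotype"] == phenotype


def gate_phenotypes(
    cells: pd.DataFrame, thresholds: Mapping[str, float]
) -> pd.DataFrame:
    """Assign phenotypes from marker intensities by a fixed priority.

    Priority for multi-positive cells: CK+ -> cancer; else CD68+ ->
    macrophage; else FOXP3+ -> Treg; else CD8+ split by PD1; else CD56+ ->
    NK; else other.  A marker is positive when its intensity strictly
    exceeds its threshold.
    """
    missing = [m for m in GATING_MARKERS if m not in cells.columns]
    if missing:
        raise SchemaError(f"missing marker columns: {missing}")
    for m in GATING_MARKERS:
        if m not in thresholds:
            raise SchemaError(f"missing threshold for marker {m!r}")

    out = cells.copy()
    pos = {m: out[m] > thresholds[m] for m in GATING_MARKERS}
    phenotype = np.full(len(out), "other", dtype=object)
    phenotype[pos["CD56"]] = "NK"
    cd8 = pos["CD8"].to_numpy()
    phenotype[cd8 & ~pos["PD1"].to_numpy()] = "CD8_PD1neg"
    phenotype[cd8 & pos["PD1"].to_numpy()] = "CD8_PD1pos"
    phenotype[pos["FOXP3"]] = "Treg"
    phenotype[pos["CD68"]] = "macrophage"
    phenotype[pos["CK"]] = "cancer"
    out["phenotype"] = phenotype
    return out


def assign_compartment(
    cells: pd.DataFrame, nest_regions: Sequence[tuple[float, float, float]]
) -> pd.DataFrame:
    """Label cells tumor_nest / stroma from disc nest regions.

    A cell on a disc boundary counts as inside the nest.
    """
    out = cells.copy()
    if len(nest_regions) == 0:
        out["compartment"] = "stroma"
        return out
    inside = in_any_nest(
        out["x_um"].to_numpy(), out["y_um"].to_numpy(), list(nest_regions)
    )
    out["compartment"] = np.where(inside, "tumor_nest", "stroma")
    return out


def cell_density(cell_map: CellMap, phenotype, compartment: str = "all") -> float:
    """Density (cells/mm²) of a phenotype within a compartment."""
    area = cell_map.compartment_area_mm2(compartment)
    if area <= 0:
        raise DegenerateCompartmentError(
            f"compartment {compartment!r} has zero area"
        )
    cells = cell_map.cells
    mask = _resolve_phenotype(cells, phenotype)
    if compartment != "all":
        mask &= cells["compartment"] == compartment
    return float(mask.sum()) / area


def density_table(
    cell_maps: Mapping[str, CellMap],
    phenotypes: Sequence = ("cancer", "CD8_PD1neg", "CD8_PD1pos", "CD8_total",
                            "Treg", "macrophage", "NK"),
    compartments: Sequence[str] = ("tumor_nest", "stroma"),
) -> pd.DataFrame:
    """Per-sample, per-compartment, per-phenotype densities (cells/mm²)."""
    rows = []
    for sample, cmap in cell_maps.items():
        for comp in compartments:
            area = cmap.compartment_area_mm2(comp)
            for pheno in phenotypes:
                rows.append(
                    {
                        "sample": sample,
                        "compartment": comp,
                        "phenotype": pheno if isinstance(pheno, str) else "+".join(pheno),
                        "density": cell_density(cmap, pheno, comp) if area > 0 else np.nan,
                        "area_mm2": area,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class RatioComparison:
    ratios: pd.Series        # per-sample ratio
    mean_non_recur: float
    mean_recur: float
    fold: float              # recur / non_recur group mean
    pvalue: float


def density_ratio(
    densities: pd.DataFrame,
    numerator: str,
    denominator: str,
    compartment: str,
    groups: Mapping[str, str] | None = None,
) -> pd.Series | RatioComparison:
    """Per-sample density ratio; with group labels, also the group contrast.

    Samples with a zero denominator density are excluded (flagged by NaN).
    The group contrast reports the recur/non-recur fold of group mean
    ratios and a two-sided Wilcoxon rank-sum p.
    """
    sub = densities[densities["compartment"] == compartment]
    num = sub[sub["phenotype"] == numerator].set_index("sample")["density"]
    den = sub[sub["phenotype"] == denominator].set_index("sample")["density"]
    ratios = num / den.where(den > 0, np.nan)
    ratios.name = f"{numerator}/{denominator} ({compartment})"
    if groups is None:
        return ratios
    grp = pd.Series(groups)
    valid = ratios.dropna()
    x = valid[grp.reindex(valid.index) == "recur"]
    y = valid[grp.reindex(valid.index) == "non_recur"]
    if x.empty or y.empty:
        raise UncomputableRatioError(
            "a group has no sample with a computable ratio"
        )
    return RatioComparison(
        ratios=ratios,
        mean_non_recur=float(y.mean()),
        mean_recur=float(x.mean()),
        fold=float(x.mean() / y.mean()) if y.mean() > 0 else np.inf,
        pvalue=rank_sum_test(x.to_numpy(), y.to_numpy()),
    )


def nearest_neighbor_distance(
    cell_map: CellMap | pd.DataFrame,
    reference,
    target,
    compartment: str = "all",
) -> float:
    """Mean shortest distance (µm) from reference cells to target cells.

    For each reference cell the Euclidean distance to its nearest target
    cell is found (excluding the cell itself when the classes coincide);
    the mean over reference cells is returned.
    """
    cells = cell_map.cells if isinstance(cell_map, CellMap) else cell_map
    if compartment != "all":
        cells = cells[cells["compartment"] == compartment]
    ref = cells[_resolve_phenotype(cells, reference)]
    tgt = cells[_resolve_phenotype(cells, target)]
    if ref.empty:
        raise EmptyClassError(f"no cells of reference class {reference!r}")
    if tgt.empty:
        raise EmptyClassError(f"no cells of target class {target!r}")
    ref_xy = ref[["x_um", "y_um"]].to_numpy(dtype=float)
    tgt_xy = tgt[["x_um", "y_um"]].to_numpy(dtype=float)
    ref_ids = ref["cell_id"].to_numpy()
    tgt_ids = tgt["cell_id"].to_numpy()
    tree = cKDTree(tgt_xy)
    # a cell may belong to both classes (e.g. CD8_PD1neg within CD8_total);
    # exclude self-matches by identity, not by class equality
    k = 2 if len(tgt) >= 2 else 1
    d, idx = tree.query(ref_xy, k=k)
    d = np.atleast_2d(d.T).T if k == 1 else d
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    best = d[:, 0].astype(float).copy()
    is_self = tgt_ids[idx[:, 0]] == ref_ids
    if k == 2:
        best[is_self] = d[is_self, 1]
        valid = np.ones(len(best), dtype=bool)
    else:
        valid = ~is_self
    if not valid.any():
        raise EmptyClassError(
            "no reference cell has a distinct target cell available"
        )
    # identical positions across distinct cells legitimately give 0
    return float(np.mean(best[valid]))


def distance_table(
    cell_maps: Mapping[str, CellMap],
    reference: str = "cancer",
    targets: Sequence = ("CD8_PD1neg", "CD8_total", "Treg", "macrophage"),
    compartment: str = "all",
) -> pd.DataFrame:
    """Per-sample mean shortest distances from a reference phenotype.

    Samples missing either class are recorded with NaN and a warning flag
    rather than dropped silently.
    """
    rows = []
    for sample, cmap in cell_maps.items():
        for tgt in targets:
            name = tgt if isinstance(tgt, str) else "+".join(tgt)
            try:
                d = nearest_neighbor_distance(cmap, reference, tgt, compartment)
                ok = True
            except EmptyClassError:
                d, ok = np.nan, False
            n_ref = int(_resolve_phenotype(cmap.cells, reference).sum())
            rows.append(
                {
                    "sample": sample,
                    "reference": reference,
                    "target": name,
                    "mean_distance_um": d,
                    "n_reference": n_ref,
                    "computable": ok,
                }
            )
    return pd.DataFrame(rows)


def distance_ratio(
    distances: pd.DataFrame,
    numerator_target: str,
    denominator_target: str,
    reference: str = "cancer",
    groups: Mapping[str, str] | None = None,
) -> pd.Series | RatioComparison:
    """Ratio of mean shortest distances (e.g. Treg->cancer over CD8->cancer).

    With group labels, reports the recur/non-recur fold of group mean
    ratios and a Wilcoxon rank-sum p; samples with an uncomputable
    component are excluded.
    """
    sub = distances[distances["reference"] == reference]
    num = sub[sub["target"] == numerator_target].set_index("sample")["mean_distance_um"]
    den = sub[sub["target"] == denominator_target].set_index("sample")["mean_distance_um"]
    ratios = num / den.where(den > 0, np.nan)
    ratios.name = f"{numerator_target}/{denominator_target} from {reference}"
    if groups is None:
        return ratios
    grp = pd.Series(groups)
    valid = ratios.dropna()
    x = valid[grp.reindex(valid.index) == "recur"]
    y = valid[grp.reindex(valid.index) == "non_recur"]
    if x.empty or y.empty:
        raise SpatialTMEError("a group has no sample with a computable ratio")
    return RatioComparison(
        ratios=ratios,
        mean_non_recur=float(y.mean()),
        mean_recur=float(x.mean()),
        fold=float(x.mean() / y.mean()) if y.mean() > 0 else np.inf,
        pvalue=rank_sum_test(x.to_numpy(), y.to_numpy()),
    )
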