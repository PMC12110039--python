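"""End-to-end orchestration: simulate (or load) -> QC -> deconvolution ->
differential expression -> mIF spatial metrics -> survival -> integration.

Every random stage draws its seed deterministically from one master seed,
so a run is byte-reproducible.  The summary is machine-readable JSON; all
intermediate tables are written as plain-text CSV/TSV next to it, and the
run manifest records seed and thresholds as key=value lines.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import deconvolution, differential_expression as de, geomx_qc, io
from . import mif_spatial, pathway_scores, survival as surv, synthetic
from .panel import builtin_pathways, builtin_signature

log = logging.getLogger("spatialtme")


@dataclass
class RunConfig:
    """Pipeline settings; defaults replicate the emulated study design."""

    out_dir: str = "spatialtme_run"
    seed: int = 0
    synthetic: bool = True
    n_patients: int = 12
    n_recur: int = 8
    loq_sd: float = 2.0
    min_frac_aois: float = 0.10
    lfc_min: float = 1.0
    p_max: float = 0.001
    delta: float = 0.5
    # optional external inputs (used when synthetic=False)
    counts_path: str | None = None
    annotations_path: str | None = None
    clinical_path: str | None = None
    signature_path: str | None = None
    gmt_path: str | None = None
    extra: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Read a flat key=value config file into a RunConfig."""
    raw = io.read_manifest(path)
    cfg = RunConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            cfg.extra[key] = value
            continue
        current = getattr(cfg, key)
        if isinstance(current, bool):
            value = value.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        setattr(cfg, key, value)
    return cfg


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] or [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


@dataclass
class PipelineResult:
    summary: dict
    counts: pd.DataFrame
    annotation: pd.DataFrame
    normalized: pd.DataFrame
    fractions: deconvolution.CellFractions | None
    deg_tables: dict[str, pd.DataFrame]
    densities: pd.DataFrame | None
    distances: pd.DataFrame | None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write artifacts under ``config.out_dir``."""
    io.ensure_dir(config.out_dir)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed}
    design = synthetic.default_design(config.n_patients)

    # ------------------------------------------------------------------ input
    if config.synthetic:
        cohort = synthetic.generate_cohort(config.n_patients, config.n_recur, seeds[0])
        patient_effects = synthetic.generate_patient_effects(
            cohort, seeds[1], cell_types=("macrophage",), sigma=0.5
        )
        counts, neg_flags, annot = synthetic.generate_aoi_counts(
            cohort, design, seed=seeds[2], patient_effects=patient_effects
        )
        cell_maps = synthetic.cohort_cell_maps(
            cohort, seed=seeds[3], density_scale=patient_effects
        )
        io.write_counts_tsv(os.path.join(config.out_dir, "counts.tsv"), counts, neg_flags)
        io.write_annotations_csv(os.path.join(config.out_dir, "annotations.csv"), annot)
        cohort.to_csv(os.path.join(config.out_dir, "cohort.csv"), index=False)
    else:
        if not config.counts_path or not config.annotations_path:
            raise ValueError("non-synthetic runs need counts_path and annotations_path")
        counts, neg_flags = io.read_counts_tsv(config.counts_path)
        annot = io.read_annotations_csv(config.annotations_path)
        cohort = (
            pd.read_csv(config.clinical_path) if config.clinical_path else None
        )
        cell_maps = None
        patient_effects = None

    summary["design"] = {
        "n_patients": int(design.n_patients),
        "n_rois": int(design.n_rois),
        "n_aois": int(design.n_aois),
        "avg_rois_per_patient": round(design.n_rois / design.n_patients, 1),
        "roi_width_um": design.roi_width_um,
        "roi_height_um": design.roi_height_um,
    }
    if config.synthetic:
        summary["cohort"] = {
            "n_recur": int((cohort["group"] == "recur").sum()),
            "n_non_recur": int((cohort["group"] == "non_recur").sum()),
        }
    summary["n_aois_observed"] = int(annot.shape[0])
    summary["n_rois_observed"] = int(annot["roi_id"].nunique())

    # -------------------------------------------------------------------- QC
    log.info("stage qc: LOQ filtering and Q3 normalization")
    neg_counts = counts.loc[neg_flags]
    loq = geomx_qc.compute_loq(neg_counts, n_sd=config.loq_sd)
    filt = geomx_qc.filter_genes_by_loq(
        counts, loq, min_frac_aois=config.min_frac_aois, is_negative_probe=neg_flags
    )
    norm = geomx_qc.q3_normalize(filt.counts)
    summary["qc"] = {
        "n_genes_assayed": filt.n_assayed,
        "n_genes_retained": filt.n_retained,
        "retained_fraction": round(filt.retained_fraction, 4),
        "mean_loq": float(loq.mean()),
    }
    norm.values.to_csv(os.path.join(config.out_dir, "normalized.tsv"), sep="\t")

    # ----------------------------------------------------------- deconvolution
    log.info("stage deconvolution")
    signature = (
        deconvolution.read_signature_csv(config.signature_path)
        if config.signature_path
        else builtin_signature()
    )
    fractions = deconvolution.deconvolve(norm.values, signature, delta=config.delta)
    fractions.percentages.to_csv(os.path.join(config.out_dir, "cell_fractions.csv"))
    decon_summary = {}
    if "group" in annot.columns and annot["group"].nunique() == 2:
        for cell_type, comp in [
            ("macrophage", "all"),
            ("monocyte", "PanCK"),
            ("neutrophil", "CD45"),
        ]:
            cmp_res = deconvolution.compare_fractions(fractions, annot, cell_type, comp)
            decon_summary[f"{cell_type}_{comp}"] = {
                "mean_non_recur_pct": round(cmp_res.mean_non_recur, 2),
                "mean_recur_pct": round(cmp_res.mean_recur, 2),
                "pvalue": cmp_res.pvalue,
            }
    summary["deconvolution"] = decon_summary

    # ---------------------------------------------------------------------- DE
    log.info("stage differential expression")
    deg_tables: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, set] = {}
    deg_summary = {}
    for comp in design.compartments:
        table = de.nb_deg(filt.counts, annot, comp)
        deg_tables[comp] = table
        table.to_csv(os.path.join(config.out_dir, f"deg_{comp}.csv"), index=False)
        sel = de.select_degs(table, lfc_min=config.lfc_min, p_max=config.p_max)[comp]
        deg_sets[comp] = sel["up_non_recur"] | sel["up_recur"]
        deg_summary[comp] = {
            "n_up_non_recur": len(sel["up_non_recur"]),
            "n_up_recur": len(sel["up_recur"]),
            "up_non_recur": sorted(sel["up_non_recur"]),
            "up_recur": sorted(sel["up_recur"]),
        }
    overlap = de.overlap_sets(deg_sets)
    summary["deg"] = deg_summary
    summary["deg_overlap"] = {"+".join(k): sorted(v) for k, v in overlap.items()}

    pathways = (
        io.read_gmt(config.gmt_path) if config.gmt_path else builtin_pathways()
    )
    universe = set(filt.counts.index)
    query = deg_sets.get("PanCK", set()) & universe
    if query:
        enrich = de.enrich_hypergeometric(query, pathways, universe)
        enrich.to_csv(os.path.join(config.out_dir, "enrichment.csv"), index=False)
        summary["enrichment_significant"] = sorted(
            enrich.loc[enrich["padj"] < 0.05, "gene_set"]
        )
    else:
        summary["enrichment_significant"] = []

    # ---------------------------------------------------------------- mIF maps
    densities = distances = None
    if cell_maps is not None:
        log.info("stage mIF spatial metrics")
        groups = dict(zip(cohort["patient_id"], cohort["group"]))
        densities = mif_spatial.density_table(cell_maps)
        distances = mif_spatial.distance_table(
            cell_maps, reference="cancer",
            targets=("CD8_PD1neg", "CD8_total", "Treg", "macrophage"),
        )
        densities.to_csv(os.path.join(config.out_dir, "densities.csv"), index=False)
        distances.to_csv(os.path.join(config.out_dir, "distances.csv"), index=False)
        mif_summary = {}
        for comp in ("tumor_nest", "stroma"):
            rc = mif_spatial.density_ratio(
                densities, "Treg", "CD8_total", comp, groups=groups
            )
            mif_summary[f"treg_cd8_density_ratio_{comp}"] = {
                "fold_recur_over_non_recur": round(rc.fold, 2),
                "pvalue": rc.pvalue,
            }
        dr = mif_spatial.distance_ratio(
            distances, "Treg", "CD8_PD1neg", reference="cancer", groups=groups
        )
        mif_summary["treg_pd1neg_cd8_distance_ratio"] = {
            "mean_recur": round(dr.mean_recur, 3),
            "mean_non_recur": round(dr.mean_non_recur, 3),
            "fold_recur_over_non_recur": round(dr.fold, 2),
            "pvalue": dr.pvalue,
        }
        summary["mif"] = mif_summary

    # ---------------------------------------------------------------- survival
    if cohort is not None and {"pfs_months", "event"} <= set(cohort.columns):
        log.info("stage survival")
        surv_summary = {}
        markers = {}
        if "NKG7" in norm.values.index:
            cd45 = annot[annot["compartment"] == "CD45"]
            vals = {
                pid: float(norm.values.loc["NKG7", list(sub["aoi_id"])].mean())
                for pid, sub in cd45.groupby("patient_id")
            }
            markers["NKG7_CD45"] = (pd.Series(vals), "median")
        if densities is not None:
            ratios = mif_spatial.density_ratio(
                densities, "macrophage", "CD8_total", "tumor_nest"
            )
            markers["macrophage_cd8_density_ratio_nest"] = (ratios.dropna(), "mean")
        clin = cohort.set_index("patient_id")
        for name, (values, rule) in markers.items():
            values = values.reindex(clin.index).dropna()
            try:
                labels, cutoff = surv.dichotomize(values, rule=rule)
                km = surv.km_logrank(
                    clin.loc[labels.index, "pfs_months"],
                    clin.loc[labels.index, "event"],
                    labels,
                )
                cox = surv.cox_ph(
                    clin.loc[labels.index, "pfs_months"],
                    clin.loc[labels.index, "event"],
                    (labels == "high").astype(int),
                )
                surv_summary[name] = {
                    "cutoff": round(cutoff, 3),
                    "logrank_p": km.pvalue,
                    "hazard_ratio_high_vs_low": cox.hazard_ratio,
                    "cox_p": cox.pvalue,
                    "separation_flagged": cox.separation_flagged,
                }
            except (surv.DegenerateSplitError, ValueError) as exc:
                surv_summary[name] = {"skipped": str(exc)}
        summary["survival"] = surv_summary
    else:
        log.warning("stage survival skipped: no clinical table")
        summary["survival"] = "skipped: no clinical table"

    # ------------------------------------------------------------- integration
    if densities is not None:
        log.info("stage integration")
        log_expr = np.log2(norm.values + 1.0)
        scores = pathway_scores.score_matrix(log_expr, pathways)
        scores.to_csv(os.path.join(config.out_dir, "pathway_scores.csv"))
        gate = pathway_scores.cross_platform_check(
            densities, norm.values, "CD68", annot
        )
        integ = {"cd68_macrophage_gate": {
            "rho": gate.rho, "pvalue": gate.pvalue, "n": gate.n,
        }}
        for grp in ("recur", "non_recur"):
            try:
                corr = pathway_scores.integrate_density_pathways(
                    densities, scores, annot, grp
                )
                corr.rho.to_csv(
                    os.path.join(config.out_dir, f"correlation_{grp}.csv")
                )
                integ[grp] = {
                    "n_patients": corr.n,
                    "mean_rho": float(corr.rho.to_numpy(dtype=float).mean()),
                }
            except pathway_scores.InsufficientDataError as exc:
                integ[grp] = {"skipped": str(exc)}
        summary["integration"] = integ

    # ------------------------------------------------------------------ output
    summary = _jsonable(summary)
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {k: v for k, v in asdict(config).items() if k != "extra"}
    io.write_manifest(os.path.join(config.out_dir, "manifest.txt"), manifest)
    return PipelineResult(
        summary=summary,
        counts=counts,
        annotation=annot,
        normalized=norm.values,
        fractions=fractions,
        deg_tables=deg_tables,
        densities=densities,
        distances=distances,
    )
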