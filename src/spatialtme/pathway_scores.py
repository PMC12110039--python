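"""Single-sample gene-set (ssGSEA-style) pathway scoring and the
density-pathway Spearman integration.

Each AOI's score for a gene set is the integrated difference between the
rank-weighted in-set running ECDF and the uniform out-of-set ECDF over the
expression ranking (rank weight 0.25 by default), rescaled by the range of
scores across AOIs.  Scores depend on the expression vector only through
ranks, so they are invariant to any strictly monotone transform.

Integration correlates per-patient immune-cell densities (mIF, tumor-nest
compartment) with per-patient pathway scores (mean over the patient's
tumor AOIs) within a recurrence group, by Spearman's rank correlation with
tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._stats import significance_stars, spearman
from .exceptions import (
    EmptySetError,
    InsufficientDataError,
    JoinError,
)

DEFAULT_RANK_WEIGHT = 0.25


def _ssgsea_es(expr_col: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Running-sum enrichment statistic for one sample."""
    n = len(expr_col)
    ranks = rankdata(expr_col)          # 1 = lowest expression; ties averaged
    # iterate genes from highest to lowest expression (stable tie-break)
    desc = np.argsort(-expr_col, kind="stable")
    r = ranks[desc]
    s = in_set[desc]
    n_in = int(s.sum())
    n_out = n - n_in
    if n_in == 0:
        raise EmptySetError("gene set has no overlap with the expression matrix")
    w_in = np.where(s, r**weight, 0.0)
    denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in
    if n_out == 0:
        p_out = np.zeros(n)
    else:
        p_out = np.cumsum(np.where(s, 0.0, 1.0)) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: Iterable[str],
    weight: float = DEFAULT_RANK_WEIGHT,
    rescale: bool = True,
) -> pd.Series:
    """Per-AOI ssGSEA score of one gene set.

    Parameters
    ----------
    expr
        Genes x AOIs expression (log-transformed normalized counts are
        conventional; only ranks matter).
    gene_set
        Gene identifiers; genes absent from ``expr`` are ignored.
    weight
        Exponent on ranks for the in-set running sum.
    rescale
        Divide by the score range across AOIs (skipped when the range is
        zero or there is a single AOI).
    """
    genes = expr.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any():
        raise EmptySetError("gene set has no overlap with the expression matrix")
    scores = pd.Series(
        {
            aoi: _ssgsea_es(expr[aoi].to_numpy(dtype=float), in_set, weight)
            for aoi in expr.columns
        },
        name="score",
    )
    if rescale and len(scores) > 1:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return scores


def score_matrix(
    expr: pd.DataFrame,
    collections: Mapping[str, Iterable[str]],
    weight: float = DEFAULT_RANK_WEIGHT,
) -> pd.DataFrame:
    """Pathways x AOIs score matrix for a GMT-style collection."""
    rows = {
        name: ssgsea_score(expr, genes, weight=weight)
        for name, genes in collections.items()
    }
    return pd.DataFrame(rows).T


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame       # densities x pathways Spearman coefficients
    pvalues: pd.DataFrame
    stars: pd.DataFrame     # significance markers at 0.05 / 0.01 / 0.001
    group: str
    n: int                  # paired observations per cell


def integrate_density_pathways(
    densities: pd.DataFrame,
    scores: pd.DataFrame,
    annot: pd.DataFrame,
    group: str,
    density_compartment: str = "tumor_nest",
    expr_compartment: str = "PanCK",
    phenotypes: Sequence[str] = ("CD8_total", "CD8_PD1neg", "Treg", "macrophage", "NK"),
) -> CorrelationMatrix:
    """Correlate immune-cell densities with pathway scores within a group.

    Densities come from mIF cell maps at patient level; AOI-level pathway
    scores are averaged per patient over the requested expression
    compartment before correlating.
    """
    patients = annot.loc[annot["group"] == group, "patient_id"].unique()
    aois = annot[
        (annot["compartment"] == expr_compartment)
        & annot["patient_id"].isin(patients)
    ]
    per_patient_scores = {}
    for pid, sub in aois.groupby("patient_id"):
        cols = [c for c in sub["aoi_id"] if c in scores.columns]
        if cols:
            per_patient_scores[pid] = scores[cols].mean(axis=1)
    score_df = pd.DataFrame(per_patient_scores)  # pathways x patients

    dens = densities[densities["compartment"] == density_compartment]
    dens = dens[dens["sample"].isin(patients)]
    dens_wide = dens.pivot_table(index="sample", columns="phenotype", values="density")

    shared = sorted(set(score_df.columns) & set(dens_wide.index))
    if len(shared) < 4:
        raise InsufficientDataError(
            f"need >= 4 paired patients, got {len(shared)}"
        )
    score_df = score_df[shared]
    dens_wide = dens_wide.loc[shared]

    use_phenos = [p for p in phenotypes if p in dens_wide.columns]
    rho = pd.DataFrame(index=use_phenos, columns=score_df.index, dtype=float)
    pvals = rho.copy()
    for pheno in use_phenos:
        for pathway in score_df.index:
            r, p = spearman(dens_wide[pheno], score_df.loc[pathway])
            rho.loc[pheno, pathway] = r
            pvals.loc[pheno, pathway] = p
    stars = pvals.map(significance_stars)
    return CorrelationMatrix(
        rho=rho, pvalues=pvals, stars=stars, group=group, n=len(shared)
    )


@dataclass
class CrossPlatformResult:
    rho: float
    pvalue: float
    n: int
    flagged: bool            # True when a variable is degenerate (constant)


def cross_platform_check(
    densities: pd.DataFrame,
    expr: pd.DataFrame,
    marker_gene: str,
    annot: pd.DataFrame,
    phenotype: str = "macrophage",
    density_compartment: str = "tumor_nest",
    expr_compartment: str = "PanCK",
) -> CrossPlatformResult:
    """Spearman agreement between mIF density and marker-gene expression.

    Used as the consistency gate before integrating the two platforms
    (e.g. macrophage density in the tumor nest vs CD68 expression in the
    tumor AOIs of the same patients).
    """
    dens = densities[
        (densities["compartment"] == density_compartment)
        & (densities["phenotype"] == phenotype)
    ].set_index("sample")["density"]
    aois = annot[annot["compartment"] == expr_compartment]
    expr_per_patient = {}
    for pid, sub in aois.groupby("patient_id"):
        cols = [c for c in sub["aoi_id"] if c in expr.columns]
        if cols and marker_gene in expr.index:
            expr_per_patient[pid] = float(expr.loc[marker_gene, cols].mean())
    expr_s = pd.Series(expr_per_patient)
    shared = sorted(set(dens.index) & set(expr_s.index))
    if not shared:
        raise JoinError("no matched samples across platforms")
    x = dens.loc[shared].to_numpy()
    y = expr_s.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CrossPlatformResult(
            rho=float("nan"), pvalue=float("nan"), n=len(shared), flagged=True
        )
    r, p = spearman(x, y)
    return CrossPlatformResult(rho=r, pvalue=p, n=len(shared), flagged=False)
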