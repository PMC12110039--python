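"""Negative-binomial differential expression, DEG selection, set overlaps
and hypergeometric over-representation.

The two-group NB model is fit per gene on raw counts with upper-quartile
size factors as offsets: counts are NB(mu = s_i * m_group, var = mu +
alpha * mu^2).  Gene-wise dispersions are moment estimates shrunk toward
the across-gene trend with a prior weight of 10 residual degrees of
freedom, in the spirit of empirical-Bayes moderation.  Group means are the
exact NB-GLM maximum-likelihood solutions (Newton on the score equation),
and the test is a Wald contrast of log means referred to a t distribution
with the residual degrees of freedom.  Benjamini-Hochberg adjusted
p-values are reported alongside the raw ones.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, geomean
from .exceptions import EmptyGroupError, EmptyInputError, SpatialTMEError

PRIOR_DF = 10.0
LFC_PSEUDO = 0.5


def q3_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-AOI upper-quartile size factors (geometric-mean centered)."""
    q3 = {}
    for aoi in counts.columns:
        col = counts[aoi].to_numpy(dtype=float)
        pos = col[col > 0]
        q3[aoi] = float(np.percentile(pos, 75)) if pos.size else np.nan
    q3 = pd.Series(q3)
    if q3.isna().any() or (q3 <= 0).any():
        raise SpatialTMEError("an AOI has no positive counts; cannot size-factor")
    return q3 / geomean(q3)


def _nb_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorized Newton solve of the NB-GLM score equation per gene.

    y: genes x samples counts; s: per-sample size factors; alpha: per-gene
    dispersion.  Returns the MLE of the group mean on the normalized scale.
    """
    tot = y.sum(axis=1)
    m = tot / s.sum()
    active = m > 0
    a = alpha[:, None]
    for _ in range(50):
        mu = s[None, :] * m[:, None]
        denom = 1.0 + a * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(s[None, :] * (1.0 + a * y) / denom**2).sum(axis=1)
        step = np.where(active, f / fp, 0.0)
        m_new = m - step
        m_new = np.where(m_new <= 0, m / 2.0, m_new)
        if np.max(np.abs(m_new - m) / np.maximum(m, 1e-12)) < 1e-10:
            m = m_new
            break
        m = m_new
    return m


def _log_mean_info(m: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fisher information of log(m): sum_i mu_i / (1 + alpha mu_i)."""
    mu = s[None, :] * m[:, None]
    return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)


def estimate_dispersions(
    y: np.ndarray, s: np.ndarray, groups: np.ndarray, prior_df: float = PRIOR_DF
) -> np.ndarray:
    """Moment (Pearson-residual) dispersions shrunk toward the trend."""
    n = y.shape[1]
    resid_df = max(n - 2, 1)
    mu = np.zeros_like(y, dtype=float)
    for g in np.unique(groups):
        idx = groups == g
        m = y[:, idx].sum(axis=1) / s[idx].sum()
        mu[:, idx] = s[idx][None, :] * m[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = ((y - mu) ** 2 - mu) / mu**2
    pearson = np.where(np.isfinite(pearson), pearson, 0.0)
    alpha_hat = np.clip(pearson.sum(axis=1) / resid_df, 0.0, 10.0)
    expressed = mu.sum(axis=1) > 0
    trend = float(np.median(alpha_hat[expressed])) if expressed.any() else 0.0
    return (prior_df * trend + resid_df * alpha_hat) / (prior_df + resid_df)


def nb_deg(
    counts: pd.DataFrame,
    annot: pd.DataFrame,
    compartment: str,
    prior_df: float = PRIOR_DF,
    lfc_pseudo: float = LFC_PSEUDO,
) -> pd.DataFrame:
    """Per-gene differential expression between recurrence groups.

    Parameters
    ----------
    counts
        Biological genes x AOIs raw counts (negative probes removed).
    annot
        AOI annotation with ``aoi_id``, ``compartment`` and ``group``.
    compartment
        Which compartment's AOIs to test ("all" for every AOI).

    Returns
    -------
    DataFrame with ``gene, compartment, log2fc, pvalue, padj,
    mean_non_recur, mean_recur, flagged``; log2fc is non-recur over recur.
    """
    if counts.empty:
        raise EmptyInputError("count matrix is empty")
    sel = annot if compartment == "all" else annot[annot["compartment"] == compartment]
    sel = sel[sel["aoi_id"].isin(counts.columns)]
    for grp in ("non_recur", "recur"):
        if (sel["group"] == grp).sum() < 2:
            raise EmptyGroupError(f"need >= 2 AOIs per group; {grp} has too few")
    cols = sel["aoi_id"].to_numpy()
    groups = sel["group"].to_numpy()
    sub = counts[cols]
    s = q3_size_factors(sub).to_numpy()
    y = sub.to_numpy(dtype=float)

    alpha = estimate_dispersions(y, s, groups, prior_df=prior_df)

    idx_nr = groups == "non_recur"
    idx_r = groups == "recur"
    m1 = _nb_group_mean(y[:, idx_nr], s[idx_nr], alpha)
    m2 = _nb_group_mean(y[:, idx_r], s[idx_r], alpha)

    all_zero = (y.sum(axis=1) == 0)
    # pseudo-mean for groups with no counts so contrasts stay finite
    floor1 = lfc_pseudo / s[idx_nr].mean()
    floor2 = lfc_pseudo / s[idx_r].mean()
    m1t = np.where(m1 > 0, m1, floor1)
    m2t = np.where(m2 > 0, m2, floor2)

    info1 = _log_mean_info(m1t, s[idx_nr], alpha)
    info2 = _log_mean_info(m2t, s[idx_r], alpha)
    se = np.sqrt(1.0 / info1 + 1.0 / info2)
    beta = np.log(m1t) - np.log(m2t)
    df = len(cols) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)

    log2fc = np.log2(m1 + lfc_pseudo) - np.log2(m2 + lfc_pseudo)
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvals = np.where(all_zero, 1.0, pvals)

    out = pd.DataFrame(
        {
            "gene": counts.index,
            "compartment": compartment,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
            "mean_non_recur": m1,
            "mean_recur": m2,
            "flagged": all_zero,
        }
    )
    return out


def select_degs(
    table: pd.DataFrame, lfc_min: float = 1.0, p_max: float = 0.001,
    use_adjusted: bool = False,
) -> dict[str, dict[str, set[str]]]:
    """Partition DEGs per compartment into up-in-non-recur / up-in-recur.

    Selection uses |log2FC| >= lfc_min and p < p_max (strict, so a gene at
    exactly p = p_max is excluded).  ``use_adjusted`` switches the p
    criterion to BH-adjusted values.
    """
    if table.empty:
        raise EmptyInputError("DEG table is empty")
    pcol = "padj" if use_adjusted else "pvalue"
    out: dict[str, dict[str, set[str]]] = {}
    for comp, sub in table.groupby("compartment"):
        hits = sub[(sub["log2fc"].abs() >= lfc_min) & (sub[pcol] < p_max)]
        out[comp] = {
            "up_non_recur": set(hits.loc[hits["log2fc"] > 0, "gene"]),
            "up_recur": set(hits.loc[hits["log2fc"] < 0, "gene"]),
        }
    return out


def overlap_sets(sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], set[str]]:
    """Venn partition of up to three gene sets.

    Returns exclusive memberships keyed by the sorted tuple of set names a
    gene belongs to (all 2^k - 1 regions; empty regions map to empty sets).
    """
    names = list(sets)
    if len(names) > 3:
        raise SpatialTMEError("overlap partition supports at most 3 sets")
    sets = {k: set(v) for k, v in sets.items()}
    universe = set().union(*sets.values()) if sets else set()
    from itertools import combinations

    regions: dict[tuple[str, ...], set[str]] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(sorted(names), k):
            regions[combo] = set()
    for gene in universe:
        member = tuple(sorted(n for n in names if gene in sets[n]))
        regions[member].add(gene)
    return regions


def enrich_hypergeometric(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    For a set S: p = P(X >= k) with X ~ Hypergeometric(N = |universe|,
    K = |S intersect universe|, n = |query|); BH adjusted across sets.
    """
    universe = set(universe)
    if not universe:
        raise SpatialTMEError("universe is empty")
    query = set(query)
    if not query <= universe:
        raise SpatialTMEError("query must be a subset of the universe")
    rows = []
    N, n = len(universe), len(query)
    for name, genes in collections.items():
        S = set(genes) & universe
        K = len(S)
        k = len(S & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": K,
                "universe_size": N,
                "query_size": n,
                "pvalue": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["pvalue"]) if len(table) else []
    return table
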