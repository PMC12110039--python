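"""Constrained log-normal cell-type deconvolution of AOI expression.

Each AOI profile ``y`` (normalized counts over genes) is modeled as a
non-negative combination of cell-type signature columns ``X`` with optional
per-gene background ``b``; abundances beta solve

    argmin_{beta >= 0}  sum_g ( log(y_g + delta) - log((X beta)_g + b_g + delta) )^2

with a stabilizing offset delta (default 0.5).  Log residuals make the fit
robust to the right-skewed, multiplicative noise of counting data.  Raw
abundances are also reported as row-normalized percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._stats import rank_sum_test
from .exceptions import EmptyGroupError, InsufficientOverlapError

MIN_SHARED_GENES = 20


@dataclass
class CellFractions:
    beta: pd.DataFrame         # AOIs x cell types, raw abundance scores >= 0
    percentages: pd.DataFrame  # AOIs x cell types, rows sum to 100
    converged: pd.Series       # per-AOI optimizer status


def _objective_and_grad(beta, X, logy, b, delta):
    pred = X @ beta + b + delta
    r = np.log(pred) - logy
    grad = 2.0 * (X.T @ (r / pred))
    return float(r @ r), grad


def _fit_one(y, X, b, delta):
    logy = np.log(y + delta)
    # equal-abundance start scaled to match total signal
    colsum = X.sum(axis=0)
    k = X.shape[1]
    scale = max(y.sum() - b.sum(), 1e-6) / max(colsum.sum() / k, 1e-12) / k
    beta0 = np.full(k, max(scale, 1e-6))
    res = optimize.minimize(
        _objective_and_grad,
        beta0,
        args=(X, logy, b, delta),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * k,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    beta = np.clip(res.x, 0.0, None)
    if not res.success:
        # fallback: non-negative least squares on log-shifted values
        beta, _ = optimize.nnls(X, np.maximum(y - b, 0.0))
    return beta, bool(res.success)


def deconvolve(
    norm_counts: pd.DataFrame,
    signature: pd.DataFrame,
    background: pd.Series | None = None,
    delta: float = 0.5,
) -> CellFractions:
    """Estimate cell-type abundances for every AOI.

    Parameters
    ----------
    norm_counts
        Genes x AOIs normalized expression (e.g. Q3-normalized counts).
    signature
        Genes x cell-types mean expression profiles.
    background
        Optional per-gene additive background on the scale of
        ``norm_counts`` (defaults to zero).
    delta
        Log-stabilizing offset.

    Raises
    ------
    InsufficientOverlapError
        If fewer than 20 genes are shared with the signature.
    """
    shared = norm_counts.index.intersection(signature.index)
    if len(shared) < MIN_SHARED_GENES:
        raise InsufficientOverlapError(
            f"only {len(shared)} genes shared with the signature "
            f"(need >= {MIN_SHARED_GENES})"
        )
    X = signature.loc[shared].to_numpy(dtype=float)
    if np.any((X <= 0).all(axis=0)):
        raise ValueError("signature contains an all-zero cell-type column")
    b = (
        background.reindex(shared).fillna(0.0).to_numpy(dtype=float)
        if background is not None
        else np.zeros(len(shared))
    )
    betas, converged = {}, {}
    for aoi in norm_counts.columns:
        y = norm_counts.loc[shared, aoi].to_numpy(dtype=float)
        beta, ok = _fit_one(y, X, b, delta)
        betas[aoi] = beta
        converged[aoi] = ok
    beta_df = pd.DataFrame(betas, index=signature.columns).T
    totals = beta_df.sum(axis=1)
    pct = beta_df.div(totals.where(totals > 0, np.nan), axis=0) * 100.0
    return CellFractions(
        beta=beta_df,
        percentages=pct.fillna(0.0),
        converged=pd.Series(converged),
    )


def log_ssq_objective(beta, y, X, b=None, delta: float = 0.5) -> float:
    """The deconvolution objective for an explicit beta (for verification)."""
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    b = np.zeros(len(y)) if b is None else np.asarray(b, dtype=float)
    r = np.log(y + delta) - np.log(X @ beta + b + delta)
    return float(r @ r)


@dataclass
class GroupComparison:
    cell_type: str
    compartment: str
    mean_non_recur: float
    mean_recur: float
    fold: float            # non_recur / recur group mean
    pvalue: float
    n_non_recur: int
    n_recur: int


def compare_fractions(
    fractions: CellFractions,
    annot: pd.DataFrame,
    cell_type: str,
    compartment: str = "all",
) -> GroupComparison:
    """Compare one cell type's per-AOI percentage between recurrence groups.

    Two-sided Wilcoxon rank-sum (exact for small tie-free samples, normal
    approximation with tie correction otherwise); group means of per-AOI
    percentages and their fold difference are reported.
    """
    annot = annot.set_index("aoi_id") if "aoi_id" in annot.columns else annot
    pct = fractions.percentages[cell_type]
    if compartment != "all":
        keep = annot.index[annot["compartment"] == compartment]
        pct = pct.loc[pct.index.intersection(keep)]
    groups = annot.loc[pct.index, "group"]
    x = pct[groups == "non_recur"].to_numpy()
    y = pct[groups == "recur"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise EmptyGroupError(
            f"no AOIs for one group (non_recur={x.size}, recur={y.size})"
        )
    p = rank_sum_test(x, y)
    mx, my = float(np.mean(x)), float(np.mean(y))
    fold = mx / my if my > 0 else np.inf
    return GroupComparison(
        cell_type=cell_type,
        compartment=compartment,
        mean_non_recur=mx,
        mean_recur=my,
        fold=float(fold),
        pvalue=p,
        n_non_recur=int(x.size),
        n_recur=int(y.size),
    )


def read_signature_csv(path) -> pd.DataFrame:
    """Load a genes x cell-types signature CSV (header row of type names)."""
    sig = pd.read_csv(path, index_col=0)
    if sig.index.duplicated().any():
        raise ValueError("signature gene IDs must be unique")
    return sig
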