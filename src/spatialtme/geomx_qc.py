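"""Negative-probe LOQ, gene detection filtering and Q3 normalization.

Digital spatial profiling panels carry negative-control probes with no
biological target; their counts estimate segment-specific background.  The
limit of quantitation (LOQ) of an AOI is the geometric mean of its negative
probes times the geometric standard deviation raised to ``n_sd`` (default 2).
Genes are called detected in an AOI when their count strictly exceeds that
AOI's LOQ, and retained when detected in at least a given fraction of AOIs.
Q3 (upper-quartile) normalization then scales every AOI so its 75th-percentile
count equals the geometric mean of all AOI Q3s, absorbing differences in
segment area and cellularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateAOIError,
    EmptyInputError,
    InsufficientProbesError,
)


def compute_loq(neg_probe_counts: pd.DataFrame, n_sd: float = 2.0) -> pd.Series:
    """Per-AOI limit of quantitation from negative-probe counts.

    Parameters
    ----------
    neg_probe_counts
        Negative probes x AOIs count matrix (>= 2 rows).
    n_sd
        Exponent on the geometric standard deviation; the conventional
        detection threshold uses 2.

    Returns
    -------
    Series of ``geomean * geoSD**n_sd`` indexed by AOI.

    Notes
    -----
    Zero counts are replaced by a pseudo-count of 1 before taking logs
    (thresholding convention); the geometric SD uses the sample (n-1)
    standard deviation of natural-log counts.
    """
    x = np.asarray(neg_probe_counts, dtype=float)
    if x.shape[0] < 2:
        raise InsufficientProbesError(
            f"need >= 2 negative probes per AOI, got {x.shape[0]}"
        )
    if np.any(x < 0):
        raise ValueError("negative probe counts must be non-negative")
    logs = np.log(np.where(x < 1, 1.0, x))
    gmean = np.exp(logs.mean(axis=0))
    gsd = np.exp(logs.std(axis=0, ddof=1))
    loq = gmean * gsd**n_sd
    return pd.Series(loq, index=neg_probe_counts.columns, name="loq")


@dataclass
class FilterResult:
    counts: pd.DataFrame          # retained biological genes x AOIs
    retained_fraction: float      # retained / assayed biological genes
    n_assayed: int
    n_retained: int
    detected_aois: pd.Series      # per assayed gene: AOIs with count > LOQ


def filter_genes_by_loq(
    counts: pd.DataFrame,
    loq: pd.Series,
    min_frac_aois: float = 0.10,
    is_negative_probe: pd.Series | None = None,
) -> FilterResult:
    """Keep genes whose count strictly exceeds the LOQ in enough AOIs.

    A gene is retained when detected in at least ``ceil(min_frac_aois * n_AOIs)``
    AOIs.  Negative-probe rows are always removed from the biological output.
    """
    if counts.empty:
        raise EmptyInputError("count matrix is empty")
    loq = loq.reindex(counts.columns)
    if loq.isna().any():
        raise ValueError("LOQ vector missing AOIs present in the count matrix")
    if is_negative_probe is not None:
        bio = counts.loc[~is_negative_probe.reindex(counts.index, fill_value=False)]
    else:
        bio = counts
    n_aois = bio.shape[1]
    min_aois = math.ceil(min_frac_aois * n_aois)
    detected = (bio.gt(loq, axis=1)).sum(axis=1)
    keep = detected >= min_aois
    retained = bio.loc[keep]
    return FilterResult(
        counts=retained,
        retained_fraction=float(keep.mean()) if len(keep) else 0.0,
        n_assayed=int(bio.shape[0]),
        n_retained=int(keep.sum()),
        detected_aois=detected,
    )


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame          # genes x AOIs normalized counts
    method: str
    scale_factors: pd.Series      # multiply raw column by factor -> normalized


def q3_normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """Upper-quartile scale each AOI to the geometric mean of AOI Q3s.

    The Q3 of an AOI is the linear-interpolation 75th percentile over genes
    with count > 0.  After normalization every AOI's Q3 equals the common
    target, so relative expression is comparable across segments of
    different area.
    """
    if counts.empty:
        raise EmptyInputError("count matrix is empty")
    q3 = {}
    for aoi in counts.columns:
        col = counts[aoi].to_numpy(dtype=float)
        pos = col[col > 0]
        q = float(np.percentile(pos, 75)) if pos.size else 0.0
        if q <= 0:
            raise DegenerateAOIError(f"AOI {aoi!r} has a zero 75th-percentile count")
        q3[aoi] = q
    q3 = pd.Series(q3)
    target = float(np.exp(np.mean(np.log(q3))))
    factors = target / q3
    return NormalizedMatrix(
        values=counts.mul(factors, axis=1),
        method="q3",
        scale_factors=factors,
    )
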