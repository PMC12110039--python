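"""Marker dichotomization and progression-free-survival analysis.

Markers are split at a median, mean or explicit cut-off (boundary values go
to the low group); strata are compared by Kaplan-Meier curves with a 1-df
log-rank test, and effect sizes come from a Cox proportional-hazards model
with Efron tie handling (lifelines).  Monotone-likelihood separation is
detected and refit with a small ridge penalty, flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test

from .exceptions import DegenerateSplitError, EmptyStratumError, SpatialTMEError


def dichotomize(values: pd.Series, rule="median") -> tuple[pd.Series, float]:
    """Split values into high/low at a cut-off.

    ``rule`` is "median", "mean" or an explicit numeric cut-off.  Values
    strictly above the cut-off are "high"; boundary values go to "low".
    Returns (labels, cutoff).
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise SpatialTMEError("need at least 2 patients to dichotomize")
    if rule == "median":
        cutoff = float(values.median())
    elif rule == "mean":
        cutoff = float(values.mean())
    else:
        cutoff = float(rule)
    labels = pd.Series(
        np.where(values > cutoff, "high", "low"), index=values.index
    )
    if rule == "median" and labels.nunique() < 2:
        raise DegenerateSplitError(
            "median rule cannot split: all values identical"
        )
    return labels, cutoff


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]   # stratum -> (timeline, survival)
    statistic: float                  # log-rank chi-square, 1 df
    pvalue: float


def km_logrank(
    times: pd.Series, events: pd.Series, strata: pd.Series
) -> KMResult:
    """Kaplan-Meier curves per stratum and the two-stratum log-rank test."""
    df = pd.DataFrame({"time": times, "event": events, "stratum": strata})
    levels = sorted(df["stratum"].unique())
    if len(levels) != 2:
        raise EmptyStratumError(
            f"need exactly 2 non-empty strata, got {len(levels)}"
        )
    curves = {}
    for level, sub in df.groupby("stratum"):
        if sub.empty:
            raise EmptyStratumError(f"stratum {level!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(level))
        curves[level] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(level): "survival"}
        )
    a = df[df["stratum"] == levels[0]]
    b = df[df["stratum"] == levels[1]]
    if a["event"].sum() == 0 and b["event"].sum() == 0:
        return KMResult(curves=curves, statistic=0.0, pvalue=1.0)
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
    )


@dataclass
class CoxResult:
    hazard_ratio: float
    coef: float
    pvalue: float
    ci_lower: float
    ci_upper: float
    separation_flagged: bool


def cox_ph(
    times: pd.Series, events: pd.Series, covariate: pd.Series
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    The covariate may be numeric or binary (0/1).  If the partial
    likelihood is monotone (complete separation), the model is refit with a
    ridge penalty of 0.1 and the result flagged.
    """
    cov = pd.Series(covariate).astype(float)
    if cov.nunique() < 2:
        raise SpatialTMEError("covariate is constant")
    if pd.Series(events).sum() < 1:
        raise SpatialTMEError("need at least one event")
    df = pd.DataFrame({"time": times, "event": events, "x": cov})
    flagged = False
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ConvergenceWarning, Exception):
        flagged = True
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    ci = cph.confidence_intervals_
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        coef=coef,
        pvalue=float(cph.summary.loc["x", "p"]),
        ci_lower=float(np.exp(ci.iloc[0, 0])),
        ci_upper=float(np.exp(ci.iloc[0, 1])),
        separation_flagged=flagged,
    )
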