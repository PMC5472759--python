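"""Kaplan-Meier estimation, log-rank comparison and Cox PH fitting.

Genotype strata (V as the reference class) are compared on overall
survival; Cox models optionally adjust for TNM stage and Fuhrman grade
entered as ordinal integers.  Estimation is delegated to lifelines
(product-limit estimator, unweighted log-rank, Newton-Raphson partial
likelihood with the Efron approximation for tied event times) behind this
module's validated interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import ValidationError
from .types import validate_clinical

GENOTYPE_REFERENCE = "V"


@dataclass
class KMEstimate:
    """Product-limit survival curve: event times, S(t) and numbers at risk."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if (np.diff(self.survival) > 1e-12).any():
            raise ValidationError("survival must be non-increasing")


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier estimate from a clinical table with time/event columns.

    Censored times reduce the risk set without introducing steps.  The
    returned grid contains the distinct event times in ascending order.
    """
    if records.empty:
        raise ValidationError("no records")
    validate_clinical(records)
    fitter = KaplanMeierFitter()
    fitter.fit(records["time"], records["event"])
    event_times = np.sort(records.loc[records["event"] == 1, "time"].unique())
    if event_times.size == 0:
        return KMEstimate(np.array([]), np.array([]), np.array([]))
    surv = (
        fitter.survival_function_at_times(event_times).to_numpy().astype(float)
    )
    at_risk = np.array(
        [(records["time"] >= t).sum() for t in event_times], dtype=int
    )
    return KMEstimate(event_times, surv, at_risk)


def logrank_test(groups: Sequence[pd.DataFrame]) -> tuple[float, int, float]:
    """Unweighted log-rank test across two or more strata.

    Returns (chi-square statistic, degrees of freedom, p).  At least one
    event must be present across all groups combined.
    """
    if len(groups) < 2:
        raise ValidationError("log-rank needs at least 2 groups")
    for g in groups:
        if g.empty:
            raise ValidationError("log-rank group with no records")
        validate_clinical(g)
    total_events = sum(int(g["event"].sum()) for g in groups)
    if total_events == 0:
        raise ValidationError("no events in any group")
    times = np.concatenate([g["time"].to_numpy() for g in groups])
    events = np.concatenate([g["event"].to_numpy() for g in groups])
    labels = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(groups)]
    )
    result = multivariate_logrank_test(times, labels, events)
    df = len(groups) - 1
    return float(result.test_statistic), df, float(result.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    coef: pd.Series
    hazard_ratio: pd.Series
    se: pd.Series
    p: pd.Series
    converged: bool
    iterations: int


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str] = ("genotype",),
    reference: str = GENOTYPE_REFERENCE,
) -> CoxFit:
    """Cox PH fit with genotype indicators (reference class dropped).

    ``covariates`` may include ``genotype`` (expanded to indicator columns
    against ``reference``) and numeric columns such as ordinal stage and
    grade.  Tied event times use the Efron approximation.  Constant
    covariates are rejected; a non-converged fit (e.g. monotone likelihood
    from separation) is returned with ``converged=False``.
    """
    validate_clinical(records)
    if records["time"].nunique() < 2 or records["event"].sum() < 2:
        raise ValidationError("need at least 2 distinct event times")
    design = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov == "genotype":
            if "genotype" not in records.columns:
                raise ValidationError("records lack a genotype column")
            levels = [
                g for g in pd.unique(records["genotype"]) if g != reference
            ]
            if not levels:
                raise ValidationError("genotype has a single level")
            for level in sorted(map(str, levels)):
                design[f"genotype_{level}"] = (
                    records["genotype"].astype(str) == level
                ).astype(float)
        else:
            if cov not in records.columns:
                raise ValidationError(f"unknown covariate {cov!r}")
            design[cov] = pd.to_numeric(records[cov], errors="raise")
    for col in design.columns:
        if design[col].nunique() < 2:
            raise ValidationError(f"covariate {col!r} is constant")
    frame = design.copy()
    frame["time"] = records["time"].to_numpy()
    frame["event"] = records["event"].to_numpy()
    frame = frame.dropna()
    fitter = CoxPHFitter()
    converged = True
    try:
        fitter.fit(frame, duration_col="time", event_col="event")
    except ConvergenceError:
        # monotone likelihood / separation: report a non-converged fit
        nan = pd.Series(np.nan, index=design.columns)
        return CoxFit(nan, nan, nan, nan, converged=False, iterations=-1)
    summary = fitter.summary
    return CoxFit(
        coef=summary["coef"],
        hazard_ratio=summary["exp(coef)"],
        se=summary["se(coef)"],
        p=summary["p"],
        converged=converged,
        iterations=getattr(fitter, "_n_iter", -1),
    )
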