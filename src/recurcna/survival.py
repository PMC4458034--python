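"""Survival endpoints and proportional-hazards marker models.

Endpoint definitions: overall survival (OS) is time from surgery to death by
any cause; disease-specific survival (DSS) to death by rectal cancer (other
deaths censor); local and distant recurrence-free periods (LRFP, DRFP) to the
first local/distant recurrence (death without that recurrence censors).  All
endpoints are administratively censored at the follow-up horizon (12 years by
default).  Marker effects are estimated with the Cox proportional-hazards
model (Efron tie handling), either univariate or with the fixed clinical
covariate set: TNM stage, age at surgery, sex and CRM involvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

ENDPOINTS = ("OS", "DSS", "LRFP", "DRFP")


class NoEventsError(ValueError):
    """Raised when a model is requested for an endpoint with zero events."""


@dataclass
class RawEvents:
    """Consistent per-patient event history (times in years from surgery)."""

    death_time: float | None = None
    death_cause: str | None = None  # "cancer" or "other"
    local_recurrence_time: float | None = None
    distant_recurrence_time: float | None = None
    censor_time: float = np.inf


@dataclass
class Endpoint:
    name: str
    time: float
    event: int


def build_endpoints(raw: RawEvents, horizon: float = 12.0) -> dict[str, Endpoint]:
    """Derive the four endpoints from one patient's event history."""
    for t in (
        raw.death_time,
        raw.local_recurrence_time,
        raw.distant_recurrence_time,
        raw.censor_time,
    ):
        if t is not None and t < 0:
            raise ValueError("negative event time")
    death = raw.death_time if raw.death_time is not None else np.inf
    obs_end = min(death, raw.censor_time, horizon)

    death_observed = death <= min(raw.censor_time, horizon)
    os_ep = Endpoint("OS", obs_end, int(death_observed))
    dss_ep = Endpoint("DSS", obs_end, int(death_observed and raw.death_cause == "cancer"))

    def _recurrence(name: str, t: float | None) -> Endpoint:
        if t is not None and t <= obs_end:
            return Endpoint(name, t, 1)
        return Endpoint(name, obs_end, 0)

    return {
        "OS": os_ep,
        "DSS": dss_ep,
        "LRFP": _recurrence("LRFP", raw.local_recurrence_time),
        "DRFP": _recurrence("DRFP", raw.distant_recurrence_time),
    }


def endpoint_frame(cohort: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Extract (patient_id, time, event) for one endpoint from a cohort table."""
    name = endpoint.lower()
    if f"{name}_time" not in cohort.columns:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "time": cohort[f"{name}_time"].astype(float),
            "event": cohort[f"{name}_event"].astype(int),
        }
    )


def _covariate_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fixed clinical covariates: TNM as indicator contrasts (II vs I, III vs I),
    age continuous, sex and CRM binary."""
    return pd.DataFrame(
        {
            "tnm_II": (cohort["tnm"] == "II").astype(float),
            "tnm_III": (cohort["tnm"] == "III").astype(float),
            "age": cohort["age"].astype(float),
            "male": (cohort["sex"] == "male").astype(float),
            "crm": cohort["crm"].astype(bool).astype(float),
        },
        index=cohort.index,
    )


def fit_marker_model(
    endpoint_data: pd.DataFrame,
    marker: pd.Series,
    covariates: pd.DataFrame | None = None,
    mode: str = "univariate",
) -> dict:
    """Cox proportional-hazards fit for a per-patient marker.

    ``endpoint_data`` needs columns ``time`` and ``event`` aligned to
    ``marker`` (and ``covariates`` for ``mode="multivariate"``).  Returns the
    marker's hazard ratio, 95% CI, Wald p, coefficient, number of events, a
    convergence flag and the full term summary table.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    n_events = int(endpoint_data["event"].sum())
    if n_events == 0:
        raise NoEventsError("no events in endpoint data")
    df = pd.DataFrame(
        {
            "time": endpoint_data["time"].to_numpy(float),
            "event": endpoint_data["event"].to_numpy(int),
            "marker": np.asarray(marker, dtype=float),
        }
    )
    if mode == "multivariate":
        if covariates is None:
            raise ValueError("multivariate mode requires covariates")
        for col in covariates.columns:
            df[col] = covariates[col].to_numpy(float)

    fitter = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        converged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter = CoxPHFitter(penalizer=0.1)
            fitter.fit(df, duration_col="time", event_col="event")
    summary = fitter.summary
    row = summary.loc["marker"]
    with np.errstate(over="ignore"):  # huge CI bounds on sparse events -> inf
        ci_low = float(np.exp(row["coef lower 95%"]))
        ci_high = float(np.exp(row["coef upper 95%"]))
    return {
        "coef": float(row["coef"]),
        "hr": float(row["exp(coef)"]),
        "ci_low": ci_low,
        "ci_high": ci_high,
        "p": float(row["p"]),
        "n_events": n_events,
        "converged": converged,
        "summary": summary,
    }


def fit_cohort_marker(
    cohort: pd.DataFrame,
    marker: pd.Series,
    endpoint: str,
    mode: str = "multivariate",
) -> dict:
    """Convenience wrapper: endpoint extraction + covariate design + fit.

    ``marker`` is indexed by patient_id; patients missing a marker value are
    dropped.
    """
    sub = cohort[cohort["patient_id"].isin(marker.dropna().index)].reset_index(drop=True)
    ep = endpoint_frame(sub, endpoint)
    cov = _covariate_design(sub) if mode == "multivariate" else None
    return fit_marker_model(
        ep, marker.loc[sub["patient_id"]].reset_index(drop=True), cov, mode=mode
    )
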