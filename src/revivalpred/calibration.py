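"""Landmark-based calibration of dynamic survival predictions.

At each landmark ``t_LM`` the subjects still at risk are followed over a
window to ``t_hor = t_LM + window`` with administrative censoring at the
horizon.  Three calibration fits compare predictions with outcomes:

* a one-parameter rate factor ``lambda_cal = c * lambda_ref`` (``c = 1`` is
  a perfectly calibrated marginal);
* the exponential calibration regression
  ``ln lambda(t | H_pred) = alpha_c + beta_c * ln H_pred``, whose perfect
  reference for a 2-year window is ``beta_c = 1``, ``alpha_c = ln 0.5``;
* a Cox proportional-hazards fit with ``ln H_pred`` as the only covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .params import RevivalParams
from .predict import (
    KMCurve,
    posterior_T_alternative,
    posterior_T_standard,
    predictive_survival,
)

__all__ = [
    "build_landmark",
    "simple_calibration",
    "km_simple_calibration",
    "exp_calibration",
    "cox_calibration",
    "CalibrationReport",
    "calibration_table",
    "standard_prediction_engine",
    "alternative_prediction_engine",
    "reports_frame",
]

logger = logging.getLogger(__name__)

#: ln(0.5): intercept of a perfectly calibrated 2-year-window predictor.
PERFECT_ALPHA = float(np.log(0.5))


def build_landmark(cohort, predictions: dict, t_lm: float, t_hor: float) -> pd.DataFrame:
    """Landmark dataset: at-risk subjects with window exposure and events.

    ``predictions`` maps subject id to ``H_pred`` over ``(t_lm, t_hor]``.
    Follow-up is administratively censored at ``t_hor``; a subject censored
    inside the window contributes exposure to the censoring time.
    """
    if t_hor <= t_lm:
        raise ValueError("t_hor must exceed t_lm")
    rows = []
    for s in cohort:
        if s.observed_time <= t_lm:
            continue
        if s.id not in predictions:
            raise KeyError(f"missing prediction for at-risk subject {s.id}")
        end = min(s.observed_time, t_hor)
        event = bool(s.event and s.observed_time <= t_hor)
        rows.append((s.id, float(predictions[s.id]), end - t_lm, event))
    return pd.DataFrame(rows, columns=["id", "H_pred", "exposure", "event"])


def _rate_factor(deaths: int, expected: float) -> tuple[float, float]:
    if expected <= 0:
        raise ValueError("total expected hazard (exposure) must be positive")
    if deaths == 0:
        logger.warning("no events in window: calibration factor 0 with infinite se")
        return 0.0, np.inf
    c = deaths / expected
    return c, c / np.sqrt(deaths)


def simple_calibration(rows: pd.DataFrame, lambda_ref: float) -> tuple[float, float]:
    """MLE of ``c`` in ``lambda_cal = c * lambda_ref`` on the landmark data.

    ``c_hat = deaths / (lambda_ref * total exposure)`` with standard error
    ``c_hat / sqrt(deaths)`` (exponential-rate asymptotics).
    """
    if lambda_ref <= 0:
        raise ValueError("lambda_ref must be positive")
    deaths = int(rows["event"].sum())
    return _rate_factor(deaths, lambda_ref * float(rows["exposure"].sum()))


def km_simple_calibration(rows: pd.DataFrame, km: KMCurve, t_lm: float) -> tuple[float, float]:
    """Rate factor against the KM-implied reference: observed window deaths
    over the summed KM cumulative hazard accrued on each subject's own
    exposure.  Model-free marginal, so ``c`` hovers at 1 up to KM
    discreteness."""
    deaths = int(rows["event"].sum())
    expected = float(
        sum(km.cumulative_hazard(t_lm, t_lm + e) for e in rows["exposure"])
    )
    return _rate_factor(deaths, expected)


def _lnH_design(rows: pd.DataFrame) -> pd.DataFrame:
    usable = rows[rows["H_pred"] > 0]
    dropped = len(rows) - len(usable)
    if dropped:
        logger.info("excluded %d rows with H_pred = 0 from ln(H_pred) fits", dropped)
    if usable["H_pred"].nunique() < 2:
        raise ValueError("ln(H_pred) is constant: calibration slope not identifiable")
    if usable["event"].sum() < 1:
        raise ValueError("no events: calibration regression undefined")
    return usable


def exp_calibration(rows: pd.DataFrame) -> tuple[float, float, float, float, float]:
    """Fit ``ln lambda(t | H_pred) = alpha + beta * ln H_pred``.

    The censored-exponential likelihood is maximized as a Poisson event-count
    regression with a log-exposure offset (identical score equations).
    Returns ``(alpha, alpha_se, beta, beta_se, z)`` with ``z`` the Wald
    statistic of the slope.
    """
    usable = _lnH_design(rows)
    X = sm.add_constant(np.log(usable["H_pred"].to_numpy()))
    y = usable["event"].to_numpy(dtype=float)
    offset = np.log(usable["exposure"].to_numpy())
    fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    alpha, beta = fit.params
    alpha_se, beta_se = fit.bse
    return float(alpha), float(alpha_se), float(beta), float(beta_se), float(beta / beta_se)


def cox_calibration(rows: pd.DataFrame) -> tuple[float, float, float]:
    """Cox proportional-hazards calibration with covariate ``ln H_pred``.

    Partial likelihood with Breslow tie handling; returns
    ``(beta, beta_se, z)``.
    """
    usable = _lnH_design(rows)
    df = pd.DataFrame(
        {
            "duration": usable["exposure"].to_numpy(),
            "event": usable["event"].to_numpy(dtype=int),
            "lnH": np.log(usable["H_pred"].to_numpy()),
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="duration", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(f"Cox calibration failed to converge (separation?): {exc}")
    beta = float(cph.params_["lnH"])
    se = float(cph.standard_errors_["lnH"])
    return beta, se, beta / se


@dataclass
class CalibrationReport:
    """One landmark row of the calibration table."""

    t_lm: float
    t_hor: float
    n: int
    deaths: int
    c_hat: float
    c_se: float
    hpred_mean: float
    hpred_sd: float
    alpha_hat: float
    alpha_se: float
    beta_hat: float
    beta_se: float
    beta_cox: float
    beta_cox_se: float
    z: float
    error: Optional[str] = None


def standard_prediction_engine(
    params: RevivalParams, grid_step: float = 0.02, grid_span: float = 60.0
) -> Callable:
    """Engine computing H_pred under the exponential-marginal standard model."""

    def engine(subject, t_lm: float, t_hor: float) -> float:
        times, values = subject.history_at(t_lm)
        dist = posterior_T_standard(
            times, values, subject.arm, t_lm, params,
            grid_step=grid_step, grid_span=grid_span,
        )
        return predictive_survival(dist, t_hor, subject.id).H_pred

    return engine


def alternative_prediction_engine(km, fit_lt, fit_survivor, t_lim: float = 9.0) -> Callable:
    """Engine computing H_pred under the KM observation-limit model."""

    def engine(subject, t_lm: float, t_hor: float) -> float:
        times, values = subject.history_at(t_lm)
        dist = posterior_T_alternative(
            times, values, subject.arm, t_lm, km, fit_lt, fit_survivor, t_lim
        )
        return predictive_survival(dist, t_hor, subject.id).H_pred

    return engine


def calibration_table(
    cohort,
    engine: Callable,
    landmarks: Sequence[float],
    window: float = 2.0,
    lambda_ref: Optional[float] = None,
    km_ref: Optional[KMCurve] = None,
) -> list[CalibrationReport]:
    """Assemble one calibration report per landmark.

    The simple rate factor uses ``lambda_ref`` (standard model) or the
    KM-implied reference ``km_ref`` (alternative model).  Per-landmark
    failures are recorded on the report row, not raised.
    """
    if not len(landmarks):
        raise ValueError("no landmarks given")
    if (lambda_ref is None) == (km_ref is None):
        raise ValueError("give exactly one of lambda_ref or km_ref")
    reports = []
    for t_lm in landmarks:
        t_hor = t_lm + window
        at_risk = cohort.at_risk(t_lm)
        try:
            predictions = {s.id: engine(s, t_lm, t_hor) for s in at_risk}
            rows = build_landmark(cohort, predictions, t_lm, t_hor)
            deaths = int(rows["event"].sum())
            if lambda_ref is not None:
                c_hat, c_se = simple_calibration(rows, lambda_ref)
            else:
                c_hat, c_se = km_simple_calibration(rows, km_ref, t_lm)
            alpha, alpha_se, beta, beta_se, z = exp_calibration(rows)
            beta_cox, beta_cox_se, _ = cox_calibration(rows)
            reports.append(
                CalibrationReport(
                    t_lm=t_lm,
                    t_hor=t_hor,
                    n=len(rows),
                    deaths=deaths,
                    c_hat=c_hat,
                    c_se=c_se,
                    hpred_mean=float(rows["H_pred"].mean()),
                    hpred_sd=float(rows["H_pred"].std(ddof=1)),
                    alpha_hat=alpha,
                    alpha_se=alpha_se,
                    beta_hat=beta,
                    beta_se=beta_se,
                    beta_cox=beta_cox,
                    beta_cox_se=beta_cox_se,
                    z=z,
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("landmark t_lm=%.3g failed: %s", t_lm, exc)
            reports.append(
                CalibrationReport(
                    t_lm=t_lm, t_hor=t_hor, n=len(at_risk),
                    deaths=0, c_hat=np.nan, c_se=np.nan,
                    hpred_mean=np.nan, hpred_sd=np.nan,
                    alpha_hat=np.nan, alpha_se=np.nan,
                    beta_hat=np.nan, beta_se=np.nan,
                    beta_cox=np.nan, beta_cox_se=np.nan, z=np.nan,
                    error=str(exc),
                )
            )
    return reports


def reports_frame(reports: Sequence[CalibrationReport]) -> pd.DataFrame:
    """Calibration reports as one table (a row per landmark)."""
    cols = [f.name for f in dc_fields(CalibrationReport)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in reports], columns=cols)
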