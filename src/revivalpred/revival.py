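"""The reverse-time ("revival") Gaussian biomarker model.

The biomarker of a subject dying at ``T`` is viewed as a process in revival
time ``s = T - t``.  Its mean is

    mu(s; T, arm) = beta_const + arm offset + beta_T*T + beta_s*s
                    + beta_log*ln(s + delta),

and observations at revival times ``s_1, ..., s_k`` are jointly Gaussian
with covariance

    Cov(i, j) = sigma2_b + sigma2_w * exp(-|s_i - s_j| / phi) + sigma2_e*1{i=j}.

Because the covariance depends only on lags ``|s_i - s_j| = |t_i - t_j|``, the
likelihood of a fixed history can be scanned over candidate death times ``T``
with a single Cholesky factorization; :func:`history_loglik_grid` exploits
this and is the computational core of both profile inference and the
predictive posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .params import RevivalParams

__all__ = [
    "revival_mean",
    "null_treatment_mean",
    "revival_covariance",
    "history_loglik",
    "history_loglik_grid",
    "tolerance_band",
    "fit_revival",
    "FittedRevival",
    "SUBSET_TAGS",
]

logger = logging.getLogger(__name__)

SUBSET_TAGS = ("all_uncensored", "uncensored_lt_tlim", "survivors_ge_tlim")

_LOG2PI = np.log(2.0 * np.pi)


def revival_mean(s, T, arm: str, params: RevivalParams):
    """Expected biomarker level at revival time ``s`` for a subject with
    survival time ``T`` on the given arm.  Vectorized over ``s`` and ``T``."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("revival time s must be nonnegative")
    out = (
        params.beta_const
        + params.arm_offset(arm)
        + params.beta_T * np.asarray(T, dtype=float)
        + params.beta_s * s
        + params.beta_log * np.log(s + params.delta)
    )
    return out if out.ndim else float(out)


def null_treatment_mean(s, T, params: RevivalParams):
    """Revival mean with both arm offsets removed (additive treatment effect
    corrected away)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("revival time s must be nonnegative")
    out = (
        params.beta_const
        + params.beta_T * np.asarray(T, dtype=float)
        + params.beta_s * s
        + params.beta_log * np.log(s + params.delta)
    )
    return out if out.ndim else float(out)


def revival_covariance(s_values, params: RevivalParams) -> np.ndarray:
    """Covariance matrix of observations at revival times ``s_values``."""
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise ValueError("s_values must be nonempty")
    if np.any(s < 0):
        raise ValueError("revival times must be nonnegative")
    lag = np.abs(s[:, None] - s[None, :])
    cov = params.sigma2_b + params.sigma2_w * np.exp(-lag / params.phi)
    cov = cov + params.sigma2_e * np.eye(s.size)
    return cov


def _gauss_loglik(resid: np.ndarray, cov: np.ndarray) -> float:
    k = resid.size
    L = np.linalg.cholesky(cov)
    z = solve_triangular(L, resid, lower=True)
    return float(-0.5 * (k * _LOG2PI + z @ z) - np.log(np.diag(L)).sum())


def history_loglik(
    measurement_times, values, arm: str, T: float, params: RevivalParams
) -> float:
    """Log-likelihood of a biomarker history given a candidate death time.

    The history at times ``t_i`` with values ``y_i`` is Gaussian with mean
    ``revival_mean(T - t_i)`` and the revival covariance.  An empty history
    returns 0 (vacuous likelihood).  Times beyond ``T`` are an error;
    a measurement exactly at ``T`` (revival time 0) is allowed.
    """
    t = np.asarray(measurement_times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must have equal length")
    if t.size == 0:
        return 0.0
    s = T - t
    if np.any(s < 0):
        raise ValueError("measurement time exceeds the candidate death time T")
    mu = revival_mean(s, T, arm, params)
    return _gauss_loglik(y - mu, revival_covariance(s, params))


def history_loglik_grid(
    measurement_times, values, arm: str, T_grid, params: RevivalParams
) -> np.ndarray:
    """``history_loglik`` over a grid of candidate death times.

    The covariance depends only on measurement-time lags, so one Cholesky
    factorization serves every grid point; only the mean shifts with ``T``.
    """
    t = np.asarray(measurement_times, dtype=float)
    y = np.asarray(values, dtype=float)
    Tg = np.asarray(T_grid, dtype=float)
    if t.size == 0:
        return np.zeros(Tg.shape)
    if np.any(Tg < t.max()):
        raise ValueError("grid contains T below the last measurement time")
    s = Tg[None, :] - t[:, None]  # (k, m), all >= 0
    mu = (
        params.beta_const
        + params.arm_offset(arm)
        + params.beta_T * Tg[None, :]
        + params.beta_s * s
        + params.beta_log * np.log(s + params.delta)
    )
    # lags in s equal lags in t, so any nonnegative shift gives the same matrix
    cov = revival_covariance(t.max() - t, params)
    L = np.linalg.cholesky(cov)
    z = solve_triangular(L, y[:, None] - mu, lower=True)
    quad = np.einsum("km,km->m", z, z)
    return -0.5 * (t.size * _LOG2PI + quad) - np.log(np.diag(L)).sum()


def tolerance_band(
    params: RevivalParams, T: float, arm: str, t_grid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean curve and ``mu +/- 2*sd`` tolerance band in follow-up time.

    ``sd`` is the square root of the total variance (all three components),
    so with the default split the band half-width is 50 biomarker units.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or np.any(t > T):
        raise ValueError("t_grid must lie in [0, T]")
    mean = revival_mean(T - t, T, arm, params)
    half = 2.0 * np.sqrt(params.total_variance)
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FittedRevival:
    """Maximum-likelihood revival fit on one subject subset.

    The three-way split (constant, control offset, prednisone offset) is not
    identifiable from two arms; the fit estimates the identified
    parametrization — control-arm level and prednisone-vs-control contrast —
    and reports the familiar decomposition by anchoring the control offset
    at ``anchor_control``.
    """

    params: RevivalParams
    standard_errors: dict
    subset_tag: str
    n_subjects_used: int
    n_measurements_used: int
    loglik: float
    anchor_control: float
    level_control: float  # identified: beta_const + beta_control
    contrast_prednisone: float  # identified: beta_prednisone - beta_control
    survivor_T_proxy: str = "observed"

    def coef_table(self) -> dict:
        p = self.params
        return {
            "constant": p.beta_const,
            "control": p.beta_control,
            "prednisone": p.beta_prednisone,
            "T": p.beta_T,
            "s": p.beta_s,
            "log_s_delta": p.beta_log,
        }


def _subset_rows(cohort, subset_tag: str, t_lim: float, survivor_T_proxy: str):
    """Per-subject (times, values, arm, s, T_cov) tuples for one fit subset."""
    rows = []
    for subj in cohort:
        if subset_tag == "all_uncensored":
            if not subj.event:
                continue
            t, y = subj.measurement_times, subj.biomarker_values
            T_cov = subj.observed_time
            s = T_cov - t
        elif subset_tag == "uncensored_lt_tlim":
            if not subj.event or subj.observed_time >= t_lim:
                continue
            keep = subj.measurement_times < t_lim
            t, y = subj.measurement_times[keep], subj.biomarker_values[keep]
            T_cov = subj.observed_time
            s = T_cov - t
        elif subset_tag == "survivors_ge_tlim":
            if subj.observed_time < t_lim:
                continue
            keep = subj.measurement_times <= t_lim
            t, y = subj.measurement_times[keep], subj.biomarker_values[keep]
            # death time unobserved: revival clock anchored at the limit
            s = t_lim - t
            T_cov = subj.observed_time if survivor_T_proxy == "observed" else t_lim
        else:
            raise ValueError(f"unknown subset_tag {subset_tag!r}")
        if t.size == 0:
            continue
        rows.append((t, y, subj.arm, s, T_cov))
    return rows


def _gls_fit(rows, params: RevivalParams):
    """Profile the mean coefficients at fixed variance components (exact ML
    for a linear mean)."""
    A = np.zeros((5, 5))
    b = np.zeros(5)
    for t, y, arm, s, T_cov in rows:
        X = np.column_stack(
            [
                np.ones_like(s),
                np.full_like(s, 1.0 if arm == "prednisone" else 0.0),
                np.full_like(s, T_cov),
                s,
                np.log(s + params.delta),
            ]
        )
        V = revival_covariance(s, params)
        c, low = cho_factor(V, lower=True)
        Vi_X = cho_solve((c, low), X)
        A += X.T @ Vi_X
        b += Vi_X.T @ y
    # rank check: a missing arm leaves the contrast column aliased
    eigvals = np.linalg.eigvalsh(A)
    if eigvals.min() < 1e-8 * max(eigvals.max(), 1.0):
        raise ValueError(
            "singular design: the prednisone-vs-control contrast (or another "
            "coefficient) is not identifiable — is one arm absent from the subset?"
        )
    beta = np.linalg.solve(A, b)
    cov_beta = np.linalg.inv(A)
    return beta, cov_beta


def _subset_loglik(rows, params: RevivalParams) -> float:
    ll = 0.0
    for t, y, arm, s, T_cov in rows:
        mu = (
            params.beta_const
            + params.arm_offset(arm)
            + params.beta_T * T_cov
            + params.beta_s * s
            + params.beta_log * np.log(s + params.delta)
        )
        ll += _gauss_loglik(y - mu, revival_covariance(s, params))
    return ll


def fit_revival(
    cohort,
    subset_tag: str,
    t_lim: float = 9.0,
    params: Optional[RevivalParams] = None,
    anchor_control: Optional[float] = None,
    estimate_variances: bool = False,
    survivor_T_proxy: str = "observed",
) -> FittedRevival:
    """Fit the revival mean by maximum likelihood on one subject subset.

    Subsets: ``all_uncensored`` (event subjects, all measurements),
    ``uncensored_lt_tlim`` (events before the observation limit, measurements
    before it) and ``survivors_ge_tlim`` (subjects followed to the limit;
    revival clock ``s = t_lim - t``, with the ``T`` covariate standing in as
    the observed follow-up end or the limit itself, per ``survivor_T_proxy``).

    Variance components are fixed at their configured values by default;
    ``estimate_variances=True`` profiles them jointly by Nelder-Mead with the
    mean coefficients solved exactly at each step.
    """
    if params is None:
        params = cohort.config.revival
    if anchor_control is None:
        anchor_control = params.beta_control
    if survivor_T_proxy not in ("observed", "t_lim"):
        raise ValueError("survivor_T_proxy must be 'observed' or 't_lim'")

    rows = _subset_rows(cohort, subset_tag, t_lim, survivor_T_proxy)
    if not rows:
        raise ValueError(f"subset {subset_tag!r} is empty for t_lim={t_lim}")

    work = params
    if estimate_variances:
        def neg_profile(logv):
            s2b, s2w, phi, s2e = np.exp(logv)
            trial = params.replace(sigma2_b=s2b, sigma2_w=s2w, phi=phi, sigma2_e=s2e)
            try:
                beta, _ = _gls_fit(rows, trial)
            except (ValueError, np.linalg.LinAlgError):
                return 1e12
            fitted = trial.replace(
                beta_const=beta[0] - anchor_control,
                beta_control=anchor_control,
                beta_prednisone=beta[1] + anchor_control,
                beta_T=beta[2],
                beta_s=beta[3],
                beta_log=beta[4],
            )
            return -_subset_loglik(rows, fitted)

        x0 = np.log([params.sigma2_b, params.sigma2_w, params.phi, params.sigma2_e])
        res = minimize(neg_profile, x0, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
        s2b, s2w, phi, s2e = np.exp(res.x)
        work = params.replace(sigma2_b=s2b, sigma2_w=s2w, phi=phi, sigma2_e=s2e)
        logger.info("estimated variance components: b=%.2f w=%.2f phi=%.3f e=%.2f",
                    s2b, s2w, phi, s2e)

    beta, cov_beta = _gls_fit(rows, work)
    se = np.sqrt(np.diag(cov_beta))
    fitted = work.replace(
        beta_const=beta[0] - anchor_control,
        beta_control=anchor_control,
        beta_prednisone=beta[1] + anchor_control,
        beta_T=beta[2],
        beta_s=beta[3],
        beta_log=beta[4],
    )
    ll = _subset_loglik(rows, fitted)
    ses = {
        "constant": se[0],  # se of the identified control-arm level
        "control": 0.0,  # anchored, not estimated
        "prednisone": se[1],  # se of the identified contrast
        "T": se[2],
        "s": se[3],
        "log_s_delta": se[4],
    }
    return FittedRevival(
        params=fitted,
        standard_errors=ses,
        subset_tag=subset_tag,
        n_subjects_used=len(rows),
        n_measurements_used=int(sum(r[0].size for r in rows)),
        loglik=ll,
        anchor_control=anchor_control,
        level_control=float(beta[0]),
        contrast_prednisone=float(beta[1]),
        survivor_T_proxy=survivor_T_proxy,
    )
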