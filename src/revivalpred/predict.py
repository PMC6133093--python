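"""Dynamic prediction: posterior death-time distributions and H_pred.

Two predictive models for a subject at risk at a landmark ``t_LM``:

* **standard** — exponential marginal survival combined with the revival
  likelihood of the history, giving a continuous posterior density over
  ``T > t_LM`` (evaluated by cell-wise quadrature with an explicit tail
  atom, so that with no history it collapses exactly to the memoryless
  exponential tail);
* **alternative** — a Kaplan-Meier marginal after censoring everything at
  an observation limit ``t_lim``, giving a discrete posterior over the KM
  jump times plus a single residual atom for ``T >= t_lim``.  Nothing is
  modelled, imputed or evaluated beyond the limit.

The predicted cumulative hazard over a window ``(t_LM, t_hor]`` is
``H_pred = -ln P(T > t_hor | at risk at t_LM, history)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.special import logsumexp

from .params import RevivalParams
from .revival import (
    FittedRevival,
    _gauss_loglik,
    history_loglik_grid,
    revival_covariance,
)

__all__ = [
    "PredictiveDistribution",
    "PredictionResult",
    "posterior_T_standard",
    "predictive_survival",
    "km_marginal",
    "KMCurve",
    "posterior_T_alternative",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictiveDistribution:
    """Posterior of the death time given history and survival to ``t_lm``.

    ``standard``: ``support`` are cell midpoints on ``(t_lm, t_lm + span]``
    with cell edges in ``cell_edges``; the final weight is a tail atom for
    ``T`` beyond the grid.  ``alternative``: ``support`` are KM jump times
    and the final weight is the residual atom ``T >= t_lim``.
    """

    t_lm: float
    support: np.ndarray
    weights: np.ndarray  # len(support) + 1; last entry = tail/residual atom
    model_tag: str
    cell_edges: Optional[np.ndarray] = None  # standard only
    t_lim: Optional[float] = None  # alternative only

    def __post_init__(self) -> None:
        total = float(self.weights.sum())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-8:
            raise ValueError(f"posterior weights sum to {total}, not 1")
        if np.any(self.weights < 0):
            raise ValueError("posterior weights must be nonnegative")

    def survival_prob(self, t_hor: float) -> float:
        """Posterior mass of ``{T > t_hor}``."""
        if t_hor <= self.t_lm:
            raise ValueError("t_hor must exceed t_lm")
        if self.model_tag == "standard":
            e = self.cell_edges
            w = self.weights
            if t_hor >= e[-1]:
                return float(w[-1])
            j = int(np.searchsorted(e, t_hor, side="right")) - 1
            frac = (e[j + 1] - t_hor) / (e[j + 1] - e[j])
            return float(w[-1] + w[j + 1 : -1].sum() + frac * w[j])
        # alternative: atoms at jump times, residual atom means T >= t_lim
        if t_hor > self.t_lim:
            raise ValueError(
                "no prediction beyond the observation limit "
                f"t_lim={self.t_lim} (requested t_hor={t_hor})"
            )
        above = self.weights[:-1][self.support > t_hor].sum()
        return float(above + self.weights[-1])


@dataclass
class PredictionResult:
    subject_id: Optional[str]
    t_lm: float
    t_hor: float
    p_surv: float
    H_pred: float


def posterior_T_standard(
    measurement_times,
    values,
    arm: str,
    t_lm: float,
    params: RevivalParams,
    grid_step: float = 0.02,
    grid_span: float = 60.0,
) -> PredictiveDistribution:
    """Posterior of ``T`` under the exponential-marginal standard model.

    The density over ``T > t_lm`` is proportional to the revival history
    likelihood times the exponential density ``lambda0*exp(-lambda0*T)``.
    Each grid cell carries its exact exponential prior mass times the
    likelihood at the cell midpoint; the prior mass beyond the grid is kept
    as a tail atom with the likelihood frozen at the last edge.  With an
    empty history the construction is exact (memoryless exponential tail).
    """
    t = np.asarray(measurement_times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size and t.max() > t_lm:
        raise ValueError("history contains measurements after the landmark")
    lam = params.lambda0
    n = int(round(grid_span / grid_step))
    edges = t_lm + grid_step * np.arange(n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    # exact exponential prior log-mass per cell, plus the beyond-grid tail
    log_prior = -lam * edges[:-1] + np.log1p(-np.exp(-lam * grid_step))
    log_prior_tail = -lam * edges[-1]
    ll = history_loglik_grid(t, y, arm, mids, params)
    ll_tail = history_loglik_grid(t, y, arm, edges[-1:], params)[0]
    logw = np.concatenate([ll + log_prior, [ll_tail + log_prior_tail]])
    norm = logsumexp(logw)
    # log-space normalization cannot overflow, but a history that is
    # essentially impossible at every grid point means the grid misses the
    # posterior mass (or the data are off the model scale): fail loudly
    if not np.isfinite(norm) or (t.size and ll.max() < -1e4):
        raise ValueError(
            "posterior mass underflowed on the whole grid; widen grid_span "
            "or check the history against the model scale"
        )
    w = np.exp(logw - norm)
    w /= w.sum()
    if w[-1] > 1e-3:
        logger.info("truncated posterior tail mass %.3g at T=%.3g", w[-1], edges[-1])
    return PredictiveDistribution(
        t_lm=t_lm, support=mids, weights=w, model_tag="standard", cell_edges=edges
    )


def predictive_survival(
    dist: PredictiveDistribution, t_hor: float, subject_id: Optional[str] = None
) -> PredictionResult:
    """Conditional survival to ``t_hor`` and its cumulative hazard."""
    p = dist.survival_prob(t_hor)
    if p <= 0.0:
        raise ValueError("predicted survival probability is zero on the support")
    return PredictionResult(
        subject_id=subject_id, t_lm=dist.t_lm, t_hor=t_hor, p_surv=p, H_pred=-np.log(p)
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier marginal for the observation-limit alternative


@dataclass
class KMCurve:
    """Product-limit survival after administrative censoring at ``t_lim``."""

    jump_times: np.ndarray  # event times with at least one death, <= t_lim
    surv_values: np.ndarray  # S(t_j) just after each jump
    increments: np.ndarray  # S(t_j-) - S(t_j) > 0
    residual: float  # S at t_lim (mass carried past the limit)
    t_lim: float

    def sf(self, t) -> np.ndarray:
        """Step survival function S(t), right-continuous, S(0) = 1."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        s = np.concatenate([[1.0], self.surv_values])
        out = s[idx]
        return out if out.ndim else float(out)

    def cumulative_hazard(self, a: float, b: float) -> float:
        """KM-implied cumulative hazard over ``(a, b]``: -ln(S(b)/S(a))."""
        sa, sb = self.sf(a), self.sf(b)
        if sa <= 0:
            raise ValueError("no KM survival mass at the window start")
        if sb <= 0:
            return np.inf
        return float(-np.log(sb / sa))


def km_marginal(cohort, t_lim: float = 9.0) -> KMCurve:
    """Marginal survival by Kaplan-Meier with everyone censored at ``t_lim``."""
    subjects = list(cohort)
    if not subjects:
        raise ValueError("empty cohort")
    durations = np.array([min(s.observed_time, t_lim) for s in subjects])
    events = np.array([s.event and s.observed_time < t_lim for s in subjects], dtype=bool)
    if not events.any():
        logger.warning("no events before t_lim=%.3g: KM curve is flat", t_lim)
        return KMCurve(
            jump_times=np.empty(0),
            surv_values=np.empty(0),
            increments=np.empty(0),
            residual=1.0,
            t_lim=t_lim,
        )
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    table = kmf.event_table
    jumps = table.index[table["observed"] > 0].to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    surv_at = np.array([float(sf.loc[t]) for t in jumps])
    before = np.concatenate([[1.0], surv_at[:-1]])
    return KMCurve(
        jump_times=jumps,
        surv_values=surv_at,
        increments=before - surv_at,
        residual=float(kmf.predict(t_lim)),
        t_lim=t_lim,
    )


def _survivor_atom_loglik(
    times: np.ndarray,
    values: np.ndarray,
    arm: str,
    params: RevivalParams,
    t_lim: float,
    T_proxy: float,
) -> float:
    """History likelihood under the survivor model: revival clock anchored
    at the observation limit (s = t_lim - t), T covariate set to the proxy."""
    if times.size == 0:
        return 0.0
    s = t_lim - times
    if np.any(s < 0):
        raise ValueError("survivor-model history extends beyond t_lim")
    mu = (
        params.beta_const
        + params.arm_offset(arm)
        + params.beta_T * T_proxy
        + params.beta_s * s
        + params.beta_log * np.log(s + params.delta)
    )
    return _gauss_loglik(values - mu, revival_covariance(s, params))


def posterior_T_alternative(
    measurement_times,
    values,
    arm: str,
    t_lm: float,
    km: KMCurve,
    fit_lt: FittedRevival,
    fit_survivor: FittedRevival,
    t_lim: float = 9.0,
) -> PredictiveDistribution:
    """Posterior of ``T`` under the Kaplan-Meier observation-limit model.

    Discrete prior: KM increments at jump times in ``(t_lm, t_lim)`` plus
    the residual mass at the limit as one atom ``{T >= t_lim}``.  The jump
    likelihood uses the revival fit on events before the limit; the atom
    likelihood uses the survivor fit with the anchored revival clock.  No
    quantity is ever evaluated at a death time beyond ``t_lim``.
    """
    if t_lm >= t_lim:
        raise ValueError("t_lm must lie below the observation limit")
    if fit_lt.subset_tag != "uncensored_lt_tlim":
        raise ValueError("fit_lt must come from the uncensored_lt_tlim subset")
    if fit_survivor.subset_tag != "survivors_ge_tlim":
        raise ValueError("fit_survivor must come from the survivors_ge_tlim subset")
    t = np.asarray(measurement_times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size and t.max() > t_lm:
        raise ValueError("history contains measurements after the landmark")

    keep = (km.jump_times > t_lm) & (km.jump_times < t_lim)
    jumps = km.jump_times[keep]
    prior = km.increments[keep]
    if prior.size == 0 and km.residual <= 0:
        raise ValueError("no KM mass above the landmark")

    parts_logw = []
    parts_support = []
    if prior.size:
        ll = history_loglik_grid(t, y, arm, jumps, fit_lt.params)
        parts_logw.append(np.log(prior) + ll)
        parts_support.append(jumps)
    # the fitting-time T proxy (observed follow-up) is unknowable here;
    # the atom uses t_lim as the covariate value
    if km.residual > 0:
        ll_atom = _survivor_atom_loglik(t, y, arm, fit_survivor.params, t_lim, t_lim)
        parts_logw.append(np.array([np.log(km.residual) + ll_atom]))
    else:
        parts_logw.append(np.array([-np.inf]))
    logw = np.concatenate(parts_logw)
    norm = logsumexp(logw)
    if not np.isfinite(norm):
        raise ValueError("alternative posterior mass underflowed")
    w = np.exp(logw - norm)
    w /= w.sum()
    support = np.concatenate(parts_support) if parts_support else np.empty(0)
    return PredictiveDistribution(
        t_lm=t_lm, support=support, weights=w, model_tag="alternative", t_lim=t_lim
    )
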