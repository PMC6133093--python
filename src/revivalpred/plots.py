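"""Diagnostic figures: cohort overview and revival mean curves."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from lifelines import KaplanMeierFitter

from .params import RevivalParams
from .revival import null_treatment_mean, tolerance_band


def overview_figure(cohort, t_lim: float = 9.0):
    """Two-panel cohort overview.

    Left: KM survival with its exponential overlay at the configured rate,
    reverse-KM of censoring, and the fraction still at risk; annotated with
    the number of subjects carrying information past the observation limit.
    Right: per subject (ordered by follow-up time) the last measurement time
    against the follow-up end, with the 45-degree reference.
    """
    durations = np.array([s.observed_time for s in cohort])
    events = np.array([s.event for s in cohort], dtype=bool)
    lam = cohort.config.lambda0

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))

    km_s = KaplanMeierFitter()
    km_s.fit(durations, events, label="survival (KM)")
    km_s.plot_survival_function(ax=ax1, ci_show=False)
    km_c = KaplanMeierFitter()
    km_c.fit(durations, ~events, label="censoring (reverse KM)")
    km_c.plot_survival_function(ax=ax1, ci_show=False)
    tgrid = np.linspace(0, durations.max(), 200)
    ax1.plot(tgrid, np.exp(-lam * tgrid), "k--", lw=1,
             label=f"exponential, rate {lam:g}")
    at_risk = np.array([(durations > t).mean() for t in tgrid])
    ax1.plot(tgrid, at_risk, color="grey", lw=1, label="fraction at risk")
    n_past = int((durations >= t_lim).sum())
    n_past_cens = int(((durations >= t_lim) & ~events).sum())
    ax1.axvline(t_lim, color="red", lw=0.8, alpha=0.5)
    ax1.annotate(
        f"{n_past} subjects reach t={t_lim:g}\n({n_past_cens} censored there)",
        xy=(t_lim, 0.8), fontsize=8,
    )
    ax1.set_xlabel("years since randomization")
    ax1.set_ylabel("probability / fraction")
    ax1.legend(fontsize=7)

    order = np.argsort(durations)
    last_meas = np.array(
        [s.measurement_times[-1] if s.n_measurements else np.nan for s in cohort]
    )
    rank = np.arange(len(durations))
    ax2.plot(durations[order], rank, ".", ms=2, label="follow-up end")
    ax2.plot(last_meas[order], rank, ".", ms=2, color="orange", label="last measurement")
    ax2.set_xlabel("years")
    ax2.set_ylabel("subject (ordered by follow-up)")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    return fig


def revival_curves_figure(params: RevivalParams, T_values=range(1, 10), arm="control"):
    """Revival mean curves in follow-up time for a fan of death times.

    Solid: null-treatment means; dashed: arm-specific mean for the largest
    death time, with the mu +/- 2*sd tolerance band dotted.
    """
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for T in T_values:
        t = np.linspace(0, T - 1e-3, 200)
        ax.plot(t, null_treatment_mean(T - t, T, params), color="C0", lw=1)
    T_big = max(T_values)
    t = np.linspace(0, T_big - 1e-3, 200)
    mean, lo, hi = tolerance_band(params, T_big, arm, t)
    ax.plot(t, mean, "C1--", lw=1.2, label=f"{arm}, T={T_big}")
    ax.plot(t, lo, "C1:", lw=0.8)
    ax.plot(t, hi, "C1:", lw=0.8, label=r"$\mu \pm 2\,\mathrm{sd}$")
    ax.set_xlabel("follow-up time t (years)")
    ax.set_ylabel("expected biomarker level")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
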