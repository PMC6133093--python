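"""Synthetic joint longitudinal-survival cohorts.

Generates seeded cohorts with the structure the revival analysis assumes:
exponential marginal survival, randomized two-arm allocation, an independent
censoring mechanism with heavy early censoring, a planned visit schedule
thinned by attendance, and biomarker values drawn from the revival model
around each subject's (latent) death time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import RevivalParams, DEFAULT_PARAMS
from .revival import revival_mean

__all__ = [
    "CensoringModel",
    "CohortConfig",
    "Subject",
    "Cohort",
    "generate_cohort",
    "export_tables",
    "import_tables",
    "DEFAULT_VISIT_SCHEDULE",
]

logger = logging.getLogger(__name__)

ARMS = ("control", "prednisone")

#: Planned visit times in years from randomization: dense in the first year,
#: annual afterwards, up to the observation limit.
DEFAULT_VISIT_SCHEDULE: tuple[float, ...] = (
    0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0,
)


@dataclass(frozen=True)
class CensoringModel:
    """Independent censoring-time distribution.

    ``mixture_uniform`` (default) mixes a uniform(0, early_hi) component with
    weight ``w_early`` and a uniform(0, late_hi) component, reproducing a
    high rate of early censoring without asserting a fitted mechanism.
    ``uniform`` and ``exponential`` are plain alternatives.
    """

    kind: str = "mixture_uniform"
    w_early: float = 0.3
    early_hi: float = 2.0
    late_hi: float = 10.0
    rate: float = 0.1  # used by kind="exponential"

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "mixture_uniform":
            early = rng.random(n) < self.w_early
            c = np.where(
                early,
                rng.uniform(0.0, self.early_hi, n),
                rng.uniform(0.0, self.late_hi, n),
            )
            return c
        if self.kind == "uniform":
            return rng.uniform(0.0, self.late_hi, n)
        if self.kind == "exponential":
            return rng.exponential(1.0 / self.rate, n)
        raise ValueError(f"unknown censoring model {self.kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 500
    lambda0: float = 0.164
    p_prednisone: float = 0.5
    censoring: CensoringModel = field(default_factory=CensoringModel)
    visit_schedule: tuple[float, ...] = DEFAULT_VISIT_SCHEDULE
    attendance: float = 0.9
    t_lim: float = 9.0
    revival: RevivalParams = field(default_factory=lambda: DEFAULT_PARAMS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if not 0.0 <= self.p_prednisone <= 1.0:
            raise ValueError("p_prednisone must lie in [0, 1]")
        if not 0.0 <= self.attendance <= 1.0:
            raise ValueError("attendance must lie in [0, 1]")
        sched = np.asarray(self.visit_schedule, dtype=float)
        if sched.size == 0 or sched[0] != 0.0 or np.any(np.diff(sched) <= 0):
            raise ValueError("visit_schedule must be strictly increasing and start at 0")
        if self.t_lim <= 0:
            raise ValueError("t_lim must be positive")
        if sched[-1] > self.t_lim:
            logger.warning(
                "visit schedule extends beyond the observation limit t_lim=%.3g",
                self.t_lim,
            )
        if self.revival.lambda0 != self.lambda0:
            object.__setattr__(self, "revival", self.revival.replace(lambda0=self.lambda0))


@dataclass
class Subject:
    """One subject: latent survival truth, observation, biomarker history."""

    id: str
    arm: str
    observed_time: float
    event: bool
    measurement_times: np.ndarray
    biomarker_values: np.ndarray
    true_death_time: Optional[float] = None
    censoring_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.measurement_times = np.asarray(self.measurement_times, dtype=float)
        self.biomarker_values = np.asarray(self.biomarker_values, dtype=float)
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.measurement_times.shape != self.biomarker_values.shape:
            raise ValueError("measurement times and values must have equal length")
        if self.observed_time <= 0:
            raise ValueError("observed_time must be positive")
        if self.measurement_times.size:
            if np.any(np.diff(self.measurement_times) <= 0):
                raise ValueError("measurement times must be strictly increasing")
            if self.measurement_times[0] < 0 or self.measurement_times[-1] > self.observed_time:
                raise ValueError("measurement times must lie in [0, observed_time]")

    @property
    def n_measurements(self) -> int:
        return int(self.measurement_times.size)

    def history_at(self, t_lm: float) -> tuple[np.ndarray, np.ndarray]:
        """Measurements available at landmark time ``t_lm`` (times <= t_lm)."""
        keep = self.measurement_times <= t_lm
        return self.measurement_times[keep], self.biomarker_values[keep]


@dataclass
class Cohort:
    subjects: list[Subject]
    config: CohortConfig

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def at_risk(self, t_lm: float) -> list[Subject]:
        """Subjects still under follow-up and alive at ``t_lm``."""
        return [s for s in self.subjects if s.observed_time > t_lm]


def _simulate_biomarkers(
    rng: np.random.Generator,
    times: np.ndarray,
    T: float,
    arm: str,
    p: RevivalParams,
) -> np.ndarray:
    """Biomarker values at visit times: mu(s) + b + W(s) + eps, s = T - t."""
    k = times.size
    s = T - times
    mu = revival_mean(s, T, arm, p)
    b = rng.normal(0.0, np.sqrt(p.sigma2_b))
    if p.sigma2_w > 0 and k > 0:
        corr = np.exp(-np.abs(s[:, None] - s[None, :]) / p.phi)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
        w = np.sqrt(p.sigma2_w) * (chol @ rng.standard_normal(k))
    else:
        w = np.zeros(k)
    eps = rng.normal(0.0, np.sqrt(p.sigma2_e), k)
    return mu + b + w + eps


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> Cohort:
    """Simulate a cohort under the standard model used as data generator.

    Death times are exponential(``lambda0``); censoring is independent;
    visits are the planned schedule thinned by the attendance probability
    and truncated strictly before the observed end of follow-up.  The
    biomarker at visit time ``t`` is the revival mean at ``s = T - t`` (the
    latent death time ``T``, also for subjects later censored) plus the
    subject effect, serial process and measurement error.

    Identical ``(config, seed)`` pairs give identical cohorts.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    p = config.revival

    T = rng.exponential(1.0 / config.lambda0, n)
    arm_idx = rng.random(n) < config.p_prednisone
    C = config.censoring.draw(rng, n)
    sched = np.asarray(config.visit_schedule, dtype=float)

    subjects: list[Subject] = []
    width = len(str(n))
    for i in range(n):
        t_obs = min(T[i], C[i])
        if t_obs <= 0:  # zero-length follow-up carries no information
            t_obs = np.nextafter(0.0, 1.0)
        arm = "prednisone" if arm_idx[i] else "control"
        attended = rng.random(sched.size) < config.attendance
        times = sched[attended & (sched < t_obs)]
        values = _simulate_biomarkers(rng, times, T[i], arm, p)
        subjects.append(
            Subject(
                id=f"S{i:0{width}d}",
                arm=arm,
                observed_time=float(t_obs),
                event=bool(T[i] <= C[i]),
                measurement_times=times,
                biomarker_values=values,
                true_death_time=float(T[i]),
                censoring_time=float(C[i]),
            )
        )
    return Cohort(subjects=subjects, config=config)


def export_tables(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format export: a survival table and a longitudinal table.

    Survival columns ``id,time,status,arm`` (status 1=death, 0=censored);
    longitudinal columns ``id,time,value``.
    """
    if len(cohort) == 0:
        raise ValueError("cannot export an empty cohort")
    surv = pd.DataFrame(
        {
            "id": [s.id for s in cohort],
            "time": [s.observed_time for s in cohort],
            "status": [int(s.event) for s in cohort],
            "arm": [s.arm for s in cohort],
        }
    )
    rows = []
    for s in cohort:
        for t, v in zip(s.measurement_times, s.biomarker_values):
            rows.append((s.id, t, v))
    longi = pd.DataFrame(rows, columns=["id", "time", "value"])
    return surv, longi


def import_tables(
    surv: pd.DataFrame, longi: pd.DataFrame, config: Optional[CohortConfig] = None
) -> Cohort:
    """Rebuild a cohort from exported tables (latent truth not recoverable)."""
    if config is None:
        config = CohortConfig(n_subjects=max(len(surv), 1))
    by_id = {sid: grp for sid, grp in longi.groupby("id", sort=False)}
    subjects = []
    for rec in surv.itertuples(index=False):
        grp = by_id.get(rec.id)
        if grp is None:
            times = np.empty(0)
            values = np.empty(0)
        else:
            times = grp["time"].to_numpy(dtype=float)
            values = grp["value"].to_numpy(dtype=float)
        subjects.append(
            Subject(
                id=str(rec.id),
                arm=str(rec.arm),
                observed_time=float(rec.time),
                event=bool(rec.status),
                measurement_times=times,
                biomarker_values=values,
            )
        )
    return Cohort(subjects=subjects, config=config)


def save_cohort(cohort: Cohort, surv_path, longi_path, meta_path=None) -> None:
    surv, longi = export_tables(cohort)
    surv.to_csv(surv_path, index=False, float_format="%.10g")
    longi.to_csv(longi_path, index=False, float_format="%.10g")
    if meta_path is not None:
        cfg = asdict(cohort.config)
        cfg["revival"] = cohort.config.revival.to_dict()
        with open(meta_path, "w") as fh:
            json.dump({"config": cfg, "seed": cohort.config.seed}, fh, indent=1, default=list)


def load_cohort(surv_path, longi_path, config: Optional[CohortConfig] = None) -> Cohort:
    surv = pd.read_csv(surv_path)
    longi = pd.read_csv(longi_path)
    return import_tables(surv, longi, config)
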