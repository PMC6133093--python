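"""Parameter containers for the revival (reverse-time) biomarker model.

The biomarker (prothrombin index, %) of a subject who dies at time ``T`` is
modelled in *revival time* ``s = T - t``, i.e. time counted backward from
death.  Its mean is linear in the treatment arm, the survival time ``T``,
``s`` and ``ln(s + delta)``; around the mean sit three Gaussian variance
components: a subject-level random effect, a serial process with exponential
correlation in ``s``, and measurement error.  The marginal survival
distribution is exponential with rate ``lambda0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

__all__ = ["RevivalParams", "DEFAULT_PARAMS"]


@dataclass(frozen=True)
class RevivalParams:
    """Full parameter set of the revival model plus the marginal rate.

    Parameters
    ----------
    beta_const : float
        Baseline biomarker level (the "null treatment" intercept).
    beta_control, beta_prednisone : float
        Additive arm offsets relative to the null-treatment baseline.
    beta_T : float
        Slope per year of survival time ``T`` (longer-lived subjects run at
        a higher level).
    beta_s : float
        Slope per year of revival time ``s``.
    beta_log : float
        Coefficient of ``ln(s + delta)``; drives the steep drop of the
        biomarker in the last months before death.
    delta : float
        Offset (years) inside the logarithm; keeps the near-death drop
        finite.  Must be positive.
    sigma2_b : float
        Variance of the subject-level random effect.
    sigma2_w : float
        Variance of the serial (exponentially correlated) process.
    phi : float
        Correlation range (years) of the serial process:
        ``corr(s, s') = exp(-|s - s'| / phi)``.
    sigma2_e : float
        Measurement-error variance.
    lambda0 : float
        Marginal exponential death rate (events/year).
    """

    beta_const: float = 63.47
    beta_control: float = 2.49
    beta_prednisone: float = 13.56
    beta_T: float = 1.74
    beta_s: float = -2.11
    beta_log: float = 4.66
    delta: float = 0.1
    sigma2_b: float = 300.0
    sigma2_w: float = 200.0
    phi: float = 1.0
    sigma2_e: float = 125.0
    lambda0: float = 0.164

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if min(self.sigma2_b, self.sigma2_w, self.sigma2_e) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")

    @property
    def total_variance(self) -> float:
        """Sum of the three variance components (default split totals 625)."""
        return self.sigma2_b + self.sigma2_w + self.sigma2_e

    def arm_offset(self, arm: str) -> float:
        if arm == "control":
            return self.beta_control
        if arm == "prednisone":
            return self.beta_prednisone
        raise ValueError(f"unknown arm {arm!r}")

    def replace(self, **changes) -> "RevivalParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RevivalParams":
        return cls(**d)


#: Default configuration: mean coefficients from the uncensored-data fit of
#: the prednisone/liver-cirrhosis trial analysis, a 300/200/125 split of the
#: 625 total variance, and the exponential marginal rate 0.164/year.
DEFAULT_PARAMS = RevivalParams()
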