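"""Room-scale steady-state concentration and inhalation cancer risk.

The dwelling is a single well-mixed zone. A surface of area ``Area`` (m²)
emitting at rate ER (mg/(m²·h)) into a room of volume VOL (m³) ventilated at
ACH (h⁻¹), with an empirical mixing factor K for incomplete mixing, settles
at

    C_steady = ER · Area / (ACH · VOL · K)      [mg/m³ → reported in μg/m³]

K divides the denominator here, following the convention of the chamber-test
risk literature this package targets; note the physical caveat that a mixing
penalty (K < 1) therefore *raises* the predicted concentration.

Chronic daily intake follows the standard EPA inhalation form

    CDI = C · IR · ET · EF · ED · AF / (BW · AT)   [mg/(kg·day)]

and lifetime excess cancer risk is CDI × PF with PF the inhalation cancer
potency factor (2.0 × 10⁻² (mg/kg/day)⁻¹ for formaldehyde). Risk is linear
in concentration, so each exposure profile collapses to a unit risk
(risk per μg/m³) and the risk reduction achieved by a sorptive material is
the same kernel applied to C_unmitigated − C_steady.

Individual exposure-factor values for the reference Taiwanese population are
not published alongside the dwelling table this package reproduces — only
their product is identifiable. The default profiles therefore fix ET = 14
h/day (time-use surveys), AF = 1, PF = 0.02, lifetime exposure (ED = 70 y,
AT = 25550 d), representative body weights, and calibrate the inhalation
rate so the unit risks equal the through-origin slopes of the published
(C_steady, risk) pairs: 2.416678 × 10⁻⁶ (male) and 2.042072 × 10⁻⁶ (female)
per μg/m³. Every factor is overridable.
"""

from __future__ import annotations

import enum
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field

UNIT_RISK_MALE = 2.416678e-06
"""Calibrated male unit risk, per μg/m³ of steady indoor concentration."""

UNIT_RISK_FEMALE = 2.042072e-06
"""Calibrated female unit risk, per μg/m³."""

POTENCY_FACTOR = 2.0e-2
"""Inhalation cancer potency factor for formaldehyde, (mg/kg/day)⁻¹."""


class ApplicationSurface(str, enum.Enum):
    FLOOR = "floor"
    WALL = "wall"
    FLOOR_AND_WALL = "floor+wall"


class RoomScenario(BaseModel):
    """Model dwelling: geometry, ventilation, mixing, and the applied ER."""

    model_config = {"frozen": True}

    floor_area: float = Field(14.0, gt=0, description="m²")
    wall_area: float = Field(45.0, gt=0, description="m²")
    volume: float = Field(42.0, gt=0, description="VOL, m³")
    ach: float = Field(0.5, gt=0, description="air change rate, h⁻¹")
    mixing_factor: float = Field(0.5, gt=0, le=1, description="K")
    application_surface: ApplicationSurface = ApplicationSurface.FLOOR
    emission_rate: float = Field(0.0, ge=0, description="ER, mg/(m²·h)")

    @property
    def applied_area(self) -> float:
        if self.application_surface is ApplicationSurface.FLOOR:
            return self.floor_area
        if self.application_surface is ApplicationSurface.WALL:
            return self.wall_area
        return self.floor_area + self.wall_area


class ExposureProfile(BaseModel):
    """Per-person inhalation exposure factors (EPA CDI kernel)."""

    model_config = {"frozen": True}

    sex: str = "unspecified"
    inhalation_rate: float = Field(gt=0, description="IR, m³/h")
    exposure_time: float = Field(14.0, gt=0, le=24, description="ET, h/day")
    exposure_frequency: float = Field(365.0, gt=0, description="EF, days/year")
    exposure_duration: float = Field(70.0, gt=0, description="ED, years")
    absorbed_fraction: float = Field(1.0, gt=0, le=1, description="AF")
    body_weight: float = Field(gt=0, description="BW, kg")
    averaging_time: float = Field(25550.0, gt=0, description="AT, days")
    potency_factor: float = Field(POTENCY_FACTOR, gt=0, description="PF, (mg/kg/day)⁻¹")

    @property
    def unit_risk(self) -> float:
        """Lifetime excess cancer risk per μg/m³ of indoor concentration."""
        return (
            1e-3
            * self.inhalation_rate
            * self.exposure_time
            * self.exposure_frequency
            * self.exposure_duration
            * self.absorbed_fraction
            / (self.body_weight * self.averaging_time)
            * self.potency_factor
        )

    @classmethod
    def calibrated(
        cls, sex: str, unit_risk: float, body_weight: float, **overrides: float
    ) -> "ExposureProfile":
        """Build a profile whose IR is solved so ``unit_risk`` is met exactly."""
        probe = cls(sex=sex, inhalation_rate=1.0, body_weight=body_weight, **overrides)
        return probe.model_copy(
            update={"inhalation_rate": unit_risk / probe.unit_risk}
        )


def default_profiles() -> dict[str, ExposureProfile]:
    """Male/female profiles calibrated to the published unit risks."""
    return {
        "male": ExposureProfile.calibrated("male", UNIT_RISK_MALE, body_weight=65.0),
        "female": ExposureProfile.calibrated("female", UNIT_RISK_FEMALE, body_weight=55.0),
    }


class RiskResult(BaseModel):
    model_config = {"frozen": True}

    c_steady: float = Field(description="μg/m³")
    cdi: float = Field(description="chronic daily intake, mg/(kg·day)")
    risk: float = Field(description="lifetime excess cancer risk")
    unit_risk: float = Field(description="risk per μg/m³")
    risk_reduction: float = Field(0.0)


def steady_state_concentration(s: RoomScenario) -> float:
    """Steady indoor concentration, μg/m³, for the scenario's emitting surface."""
    denom = s.ach * s.volume * s.mixing_factor
    if denom <= 0:
        raise ValueError("ACH × VOL × K must be positive")
    return s.emission_rate * s.applied_area / denom * 1000.0


def inhalation_risk(c_ugm3: float, p: ExposureProfile) -> RiskResult:
    """Lifetime excess cancer risk at a constant indoor concentration."""
    if c_ugm3 < 0:
        raise ValueError("concentration must be non-negative")
    cdi = (
        c_ugm3
        * 1e-3
        * p.inhalation_rate
        * p.exposure_time
        * p.exposure_frequency
        * p.exposure_duration
        * p.absorbed_fraction
        / (p.body_weight * p.averaging_time)
    )
    risk = cdi * p.potency_factor
    return RiskResult(c_steady=c_ugm3, cdi=cdi, risk=risk, unit_risk=p.unit_risk)


def risk_reduction(
    c_unmitigated: float, c_steady: float, p: ExposureProfile
) -> float:
    """Risk averted by lowering the indoor concentration to C_steady.

    Applies the CDI kernel to (C_unmitigated − C_steady); by linearity this
    equals risk(C_unmitigated) − risk(C_steady). The chamber inlet
    concentration stands in for the unmitigated indoor level, a deliberately
    strong assumption of the underlying assessment.
    """
    if c_unmitigated < 0:
        raise ValueError("unmitigated concentration must be non-negative")
    return inhalation_risk(c_unmitigated - c_steady, p).risk


def fit_unit_risk(
    c_steady: Sequence[float], risks: Sequence[float]
) -> float:
    """Through-origin least-squares slope of risk on concentration.

    Identifies the per-concentration risk coefficient implied by a table of
    (C_steady, risk) pairs; with risk linear in concentration the pairs are
    collinear through the origin and the slope is the unit risk.
    """
    x = np.asarray(c_steady, dtype=float)
    y = np.asarray(risks, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("need equal-length, non-empty concentration and risk vectors")
    return float(x @ y / (x @ x))


class MonteCarloSummary(BaseModel):
    model_config = {"frozen": True}

    mean: float
    sd: float
    quantiles: dict[str, float]
    n: int
    seed: int


def monte_carlo_risk(
    scenario: RoomScenario,
    profile: ExposureProfile,
    distributions: Mapping[str, object],
    n: int,
    seed: int,
    quantiles: Sequence[float] = (0.05, 0.5, 0.95),
) -> MonteCarloSummary:
    """Propagate exposure-factor uncertainty through the risk kernel.

    ``distributions`` maps ExposureProfile field names to either a number
    (point mass) or a frozen scipy.stats distribution (anything with an
    ``rvs(size, random_state)`` method). Fields not mentioned keep the
    profile's value. With only point masses the mean equals the
    deterministic risk exactly and the SD is zero.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    fields = set(ExposureProfile.model_fields) - {"sex"}
    rng = np.random.default_rng(seed)
    c = steady_state_concentration(scenario)

    draws: dict[str, np.ndarray] = {}
    for name, dist in distributions.items():
        if name not in fields:
            raise ValueError(f"unknown exposure factor {name!r}")
        if isinstance(dist, (int, float)):
            draws[name] = np.full(n, float(dist))
        elif hasattr(dist, "rvs"):
            draws[name] = np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
        else:
            raise ValueError(
                f"distribution for {name!r} must be a number or a frozen "
                "scipy.stats distribution"
            )

    def field(name: str) -> np.ndarray | float:
        return draws.get(name, getattr(profile, name))

    cdi = (
        c
        * 1e-3
        * field("inhalation_rate")
        * field("exposure_time")
        * field("exposure_frequency")
        * field("exposure_duration")
        * field("absorbed_fraction")
        / (field("body_weight") * field("averaging_time"))
    )
    risk = np.broadcast_to(np.asarray(cdi * field("potency_factor")), (n,))
    if not distributions:
        risk = np.full(n, inhalation_risk(c, profile).risk)
    qs = {f"q{int(round(q * 100)):02d}": float(np.quantile(risk, q)) for q in quantiles}
    return MonteCarloSummary(
        mean=float(np.mean(risk)), sd=float(np.std(risk, ddof=0)), quantiles=qs, n=n, seed=seed
    )
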