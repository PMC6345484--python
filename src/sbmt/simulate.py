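"""Synthetic chamber runs, column breakthrough curves, and their ground truth.

The chamber generator replaces the laboratory: a well-mixed chamber of
volume V ventilated at n air changes per hour, fed at a constant inlet
concentration, with the specimen acting as a linear (deposition-velocity)
sink of strength v_d (m/h) over loading L (m²/m³):

    dC/dt = n·(C_in − C) − L·v_d·C

integrated in closed form, C(t) = C_ss + (C₀ − C_ss)·e^(−(n + L·v_d)·t)
with C_ss = n·C_in / (n + L·v_d). The linear sink is the minimal model
consistent with a constant adsorption rate, and it makes the steady-state
equivalent ventilation rate recover v_d exactly — the identity every
parameter-recovery test leans on. A saturating (Langmuir-style) variant is
available for stress tests only.

After ``reemission_start`` the inlet switches to clean air and the specimen
becomes a constant areal source ER (mg/(m²·h)); the sink is off in this
phase, so the chamber balance inverts exactly to the configured ER.

Gaussian measurement noise (truncated at zero) is added independently to
each inlet and outlet sample, with SD defaulting to the mid-range of
replicate SDs observed in small-chamber formaldehyde work (~8 μg/m³). All
randomness flows from the explicit seed.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .chamber import ChamberConfig, ChamberTest, Phase, QARecord, SamplePair
from .breakthrough import BreakthroughTest
from .units import ugm3_to_ppm

DEFAULT_SCHEDULE = (2, 4, 6, 8, 10, 12, 24, 72, 74, 76, 78, 84, 96)
"""Sampling times (h): every 2 h to 12 h, then 24 h and 72 h, then the
clean-air re-emission phase."""


class ChamberSimParams(BaseModel):
    model_config = {"frozen": True}

    config: ChamberConfig = ChamberConfig()
    inlet: float = Field(244.0, ge=0, description="inlet concentration, μg/m³")
    deposition_velocity: float = Field(1.0, ge=0, description="v_d, m/h")
    initial_concentration: Optional[float] = Field(
        None, ge=0, description="chamber concentration at t=0; default = inlet"
    )
    noise_sd: float = Field(8.0, ge=0, description="measurement noise SD, μg/m³")
    sampling_schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    reemission_start: float = Field(72.0, gt=0, description="clean-air switch, h")
    reemission_source: float = Field(0.0, ge=0, description="ER during re-emission, mg/(m²·h)")
    seed: int = 0
    material_id: str = "SIM"

    @model_validator(mode="after")
    def _check_schedule(self) -> "ChamberSimParams":
        t = self.sampling_schedule
        if not t or any(b <= a for a, b in zip(t, t[1:])) or t[0] <= 0:
            raise ValueError("sampling schedule must be positive and strictly increasing")
        return self


class ColumnSimParams(BaseModel):
    model_config = {"frozen": True}

    rho_s: float = Field(122.0, gt=0, description="inlet concentration, μg/m³")
    q_s: float = Field(0.006, gt=0, description="column flow, m³/h (100 mL/min)")
    m: float = Field(5.0, gt=0, description="sorbent mass, g")
    capacity: float = Field(gt=0, description="saturation capacity, μg/g")
    sharpness: float = Field(gt=0, description="logistic steepness, h⁻¹")
    n_points: int = Field(400, ge=3)
    ratio_noise_sd: float = Field(0.0, ge=0)
    seed: int = 0


def chamber_steady_state(params: ChamberSimParams) -> float:
    """Closed-form adsorption-phase steady concentration, μg/m³."""
    n = params.config.air_change_rate
    sink = params.config.loading * params.deposition_velocity
    return n * params.inlet / (n + sink)


def chamber_concentration(params: ChamberSimParams, t: float) -> float:
    """Noise-free chamber concentration at elapsed time t (h)."""
    cfg = params.config
    n, L = cfg.air_change_rate, cfg.loading
    k = n + L * params.deposition_velocity
    c0 = params.inlet if params.initial_concentration is None else params.initial_concentration
    c_ss = chamber_steady_state(params)
    t_r = params.reemission_start
    if t <= t_r:
        return c_ss + (c0 - c_ss) * math.exp(-k * t)
    c_r = c_ss + (c0 - c_ss) * math.exp(-k * t_r)
    source_ug = 1000.0 * params.reemission_source
    c_ss2 = L * source_ug / n
    return c_ss2 + (c_r - c_ss2) * math.exp(-n * (t - t_r))


def simulate_chamber(params: ChamberSimParams) -> ChamberTest:
    """Generate one phase-labelled chamber test record."""
    rng = np.random.default_rng(params.seed)
    samples = []
    for t in params.sampling_schedule:
        reemit = t > params.reemission_start
        inlet_true = 0.0 if reemit else params.inlet
        c_true = chamber_concentration(params, t)
        if params.noise_sd > 0:
            c_in = max(0.0, inlet_true + rng.normal(0.0, params.noise_sd))
            c_out = max(0.0, c_true + rng.normal(0.0, params.noise_sd))
        else:
            c_in, c_out = inlet_true, c_true
        samples.append(
            SamplePair(
                t_e=t,
                c_in=c_in,
                c_out=c_out,
                sd_in=params.noise_sd or None,
                sd_out=params.noise_sd or None,
                n_replicates=3,
                phase=Phase.REEMISSION if reemit else Phase.ADSORPTION,
            )
        )
    return ChamberTest(
        material_id=params.material_id,
        target_inlet_ppm=round(ugm3_to_ppm(params.inlet, fixed=True), 3),
        config=params.config,
        samples=tuple(samples),
        qa=QARecord(background_hcho=1.0, background_tvoc=5.0, empty_chamber_recovery=96.0),
    )


def simulate_chamber_saturating(
    params: ChamberSimParams, half_saturation: float, dt: float = 0.01
) -> ChamberTest:
    """Stress-test variant: Langmuir-style sink v_d/(1 + C/C_half).

    Forward-Euler integration (no closed form); intended for robustness
    checks of downstream estimators, not for calibrated recovery tests.
    """
    cfg = params.config
    n, L = cfg.air_change_rate, cfg.loading
    rng = np.random.default_rng(params.seed)
    c = params.inlet if params.initial_concentration is None else params.initial_concentration
    t = 0.0
    samples = []
    schedule = iter(params.sampling_schedule)
    target = next(schedule, None)
    while target is not None:
        step = min(dt, target - t)
        reemit = t >= params.reemission_start
        inlet_true = 0.0 if reemit else params.inlet
        sink = 0.0 if reemit else L * params.deposition_velocity / (1.0 + c / half_saturation)
        source = L * 1000.0 * params.reemission_source if reemit else 0.0
        c += step * (n * (inlet_true - c) - sink * c + source)
        t += step
        if t >= target - 1e-12:
            noise = rng.normal(0.0, params.noise_sd, size=2) if params.noise_sd > 0 else (0.0, 0.0)
            samples.append(
                SamplePair(
                    t_e=target,
                    c_in=max(0.0, inlet_true + noise[0]),
                    c_out=max(0.0, c + noise[1]),
                    n_replicates=3,
                    phase=Phase.REEMISSION if reemit else Phase.ADSORPTION,
                )
            )
            target = next(schedule, None)
    return ChamberTest(
        material_id=params.material_id,
        target_inlet_ppm=round(ugm3_to_ppm(params.inlet, fixed=True), 3),
        config=cfg,
        samples=tuple(samples),
    )


def breakthrough_midpoint(params: ColumnSimParams) -> float:
    """Mass-balance-centred logistic midpoint t₅₀ = capacity·m/(ρ_s·q_s), h."""
    return params.capacity * params.m / (params.rho_s * params.q_s)


def simulate_breakthrough(params: ColumnSimParams) -> BreakthroughTest:
    """Sigmoidal column breakthrough curve with mass-balance-consistent centre.

    The outlet/inlet ratio follows r(t) = 1/(1 + e^(−s·(t − t₅₀))); the area
    above the curve then equals the configured capacity to first order
    (within 1 % once s·t₅₀ ≥ 20).
    """
    t50 = breakthrough_midpoint(params)
    s = params.sharpness
    t_end = t50 + 10.0 / s
    times = np.linspace(0.0, t_end, params.n_points)[1:]
    ratios = expit(s * (times - t50))
    if params.ratio_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        ratios = np.clip(ratios + rng.normal(0.0, params.ratio_noise_sd, ratios.size), 0.0, 1.1)
    return BreakthroughTest(
        rho_s=params.rho_s,
        q_s=params.q_s,
        m=params.m,
        series=tuple((float(t), float(r)) for t, r in zip(times, ratios)),
    )
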