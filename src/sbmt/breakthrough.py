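"""Column breakthrough arithmetic and lifetime extrapolation.

A ground specimen packed in a tube is fed formaldehyde-spiked air until the
outlet reaches a set fraction of the inlet concentration (default 0.5 %, the
breakthrough time t_b). The capacity per sorbent mass is

    w_s = ρ_s · q_s · t_b / m            [μg/g]

(ρ_s inlet concentration μg/m³, q_s flow m³/h, m sorbent mass g). Published
versions of this formula carry a 1000 divisor, which expresses w_s in mg/g;
the package works in μg/g throughout so that the areal quantities stay in μg
(``sorption_capacity(..., milligrams=True)`` applies the divisor for
display). Scaled by the material's surface density ρ_A (g/m²) this gives the
areal saturation ρ_Aa = w_s·ρ_A (μg/m²). Dividing by the mass per area the
material actually removed over an accumulation window Δt_e in the chamber,
ρ_Ac = Σᵢ SB_m,i·Δt_e,i (right-endpoint rectangle sum), extrapolates the
service lifetime

    t_lt = (ρ_Aa / ρ_Ac) · Δt_e          [converted h → days].
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

HOURS_PER_DAY = 24.0
DEFAULT_THRESHOLD = 0.005


class BreakthroughTest(BaseModel):
    """One column run: inlet air, flow, sorbent mass, outlet/inlet ratio series."""

    rho_s: float = Field(gt=0, description="inlet HCHO concentration of spiked air, μg/m³")
    q_s: float = Field(gt=0, description="column air flow, m³/h")
    m: float = Field(gt=0, description="sorbent mass, g")
    series: tuple[tuple[float, float], ...] = Field(
        description="(time h, outlet/inlet ratio) pairs, time strictly increasing"
    )
    threshold: float = Field(DEFAULT_THRESHOLD, gt=0, lt=1)

    @model_validator(mode="after")
    def _check_series(self) -> "BreakthroughTest":
        if not self.series:
            raise ValueError("breakthrough series must be non-empty")
        times = [t for t, _ in self.series]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakthrough times must be strictly increasing")
        if any(not 0.0 <= r <= 1.1 for _, r in self.series):
            raise ValueError("outlet/inlet ratios must lie in [0, 1.1]")
        return self


class LifetimeEstimate(BaseModel):
    model_config = {"frozen": True}

    t_b: float = Field(description="breakthrough time, h")
    w_s: float = Field(description="sorption capacity, μg/g")
    rho_A: float = Field(description="material surface density, g/m²")
    rho_Aa: float = Field(description="areal saturation, μg/m²")
    rho_Ac: float = Field(description="cumulative sorbed mass per area, μg/m²")
    delta_te: float = Field(description="accumulation window, h")
    t_lt: float = Field(description="lifetime, days (inf if rho_Ac = 0)")


def breakthrough_time(test: BreakthroughTest) -> Optional[float]:
    """First time the outlet/inlet ratio reaches the threshold, h.

    Linearly interpolated between the bracketing sample points. Returns
    ``None`` when the column never breaks through within the series (a
    signal, not an error: the run simply ended early).
    """
    theta = test.threshold
    t0, r0 = test.series[0]
    if r0 >= theta:
        return t0
    for (ta, ra), (tb, rb) in zip(test.series, test.series[1:]):
        if rb >= theta:
            return ta + (theta - ra) * (tb - ta) / (rb - ra)
    return None


def sorption_capacity(
    test: BreakthroughTest, t_b: float | None = None, *, milligrams: bool = False
) -> float:
    """Sorption capacity w_s at breakthrough, μg/g (``milligrams`` → mg/g)."""
    if t_b is None:
        t_b = breakthrough_time(test)
    if t_b is None:
        raise ValueError("column did not break through; capacity undefined")
    if t_b < 0:
        raise ValueError("breakthrough time must be non-negative")
    w = test.rho_s * test.q_s * t_b / test.m
    return w / 1000.0 if milligrams else w


def integral_capacity(test: BreakthroughTest) -> float:
    """Full-curve capacity ∫(1 − ratio) dt · ρ_s q_s / m, μg/g.

    Trapezoidal integral over the recorded series; the threshold-free
    estimate of total uptake, used to audit the truncation bias of the
    breakthrough-time capacity.
    """
    t = np.array([p[0] for p in test.series])
    r = np.array([p[1] for p in test.series])
    return float(np.trapezoid(1.0 - r, t) * test.rho_s * test.q_s / test.m)


def areal_saturation(w_s: float, rho_A: float) -> float:
    """Areal saturation ρ_Aa = w_s × ρ_A, μg/m²."""
    if w_s < 0 or rho_A < 0:
        raise ValueError("capacity and surface density must be non-negative")
    return w_s * rho_A


def cumulative_sorption(
    metrics_series: Sequence[tuple[float, float]], *, rule: str = "rectangle"
) -> float:
    """Cumulative sorbed mass per area ρ_Ac = Σᵢ SB_m,i · Δt_e,i, μg/m².

    ``metrics_series`` is a sequence of (SB_m at t_e,i, t_e,i) pairs with
    strictly increasing t_e; the first interval runs from t_e = 0. The
    default right-endpoint rectangle rule applies each sampled flux to the
    interval ending at its sampling time (Δt_e,i = t_e,i − t_e,i−1);
    ``rule="trapezoid"`` is offered for smoother series.
    """
    if not metrics_series:
        raise ValueError("metrics series must be non-empty")
    fluxes = [f for f, _ in metrics_series]
    times = [t for _, t in metrics_series]
    if times[0] <= 0 or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("sampling times must be positive and strictly increasing")
    if rule == "rectangle":
        prev = [0.0] + times[:-1]
        return float(sum(f * (t - p) for f, t, p in zip(fluxes, times, prev)))
    if rule == "trapezoid":
        t = np.array([0.0] + times)
        f = np.array([fluxes[0]] + fluxes)
        return float(np.trapezoid(f, t))
    raise ValueError(f"unknown quadrature rule {rule!r}")


def lifetime_days(rho_Aa: float, rho_Ac: float, delta_te: float) -> float:
    """Service lifetime t_lt = (ρ_Aa / ρ_Ac) × Δt_e, converted h → days.

    A window over which the material removed nothing (ρ_Ac = 0) signals an
    unlimited lifetime; +inf is returned rather than raising.
    """
    if rho_Aa < 0 or rho_Ac < 0 or delta_te <= 0:
        raise ValueError("areal masses must be non-negative and the window positive")
    if rho_Ac == 0:
        return math.inf
    return (rho_Aa / rho_Ac) * delta_te / HOURS_PER_DAY


def lifetime_from_tests(
    column: BreakthroughTest,
    rho_A: float,
    metrics_series: Sequence[tuple[float, float]],
) -> LifetimeEstimate:
    """Full breakthrough → lifetime pipeline for one material."""
    t_b = breakthrough_time(column)
    if t_b is None:
        raise ValueError("column did not break through; lifetime undefined")
    w_s = sorption_capacity(column, t_b)
    rho_Aa = areal_saturation(w_s, rho_A)
    rho_Ac = cumulative_sorption(metrics_series)
    delta_te = metrics_series[-1][1]
    return LifetimeEstimate(
        t_b=t_b,
        w_s=w_s,
        rho_A=rho_A,
        rho_Aa=rho_Aa,
        rho_Ac=rho_Ac,
        delta_te=delta_te,
        t_lt=lifetime_days(rho_Aa, rho_Ac, delta_te),
    )
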