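# Methods

## Chamber test and sorption metrics

The experimental unit is a 99-L stainless-steel chamber ventilated at
n = 0.5 h⁻¹ (Q_v = 0.0495 m³/h) holding one 0.2 m × 0.2 m specimen face
(edges sealed, A = 0.04 m²), fed formaldehyde-spiked air at a constant
0.1 or 0.2 ppm inlet. Samples are inlet/outlet pairs at scheduled elapsed
times: every 2 h to 12 h, then 24 h and 72 h, after which the inlet switches
to clean air and re-emission is monitored.

All metrics assume steady state in a well-mixed chamber. The package
averages inlet and outlet concentrations over every adsorption-phase
sampling point with t_e ≥ 12 h (the protocol's equilibration allowance;
both window edges configurable) and applies

    SB_m    = (C_in − C_out) · Q_v / A
    SB_v,eq = (C_in / C_out − 1) · Q_v / A      (≡ SB_m / C_out)
    SB_r    = 100 · (C_in − C_out) / C_in
    ACH_eq  = SB_v,eq · L

Fluxes are signed: a specimen that re-emits more than it removes yields a
negative SB_m and a `net_emitter` flag, never a clipped zero.

Two loading-factor conventions coexist in chamber work: the geometric
A/V = 0.404 m²/m³ and the nominal 0.4 m²/m³ quoted in test reports. The
chamber model uses A/V by default; report-shaped outputs use the nominal
0.4 (`nominal_loading`), which is what reproduces the published
equivalent-ACH figures (0.33, 0.50, 0.57 h⁻¹).

ppm ↔ μg/m³ conversion defaults to the ideal gas law at the test
temperature (M = 30.03 g/mol); a fixed-molar-volume mode (24.62 L/mol,
under which 0.2 ppm ↔ 244 μg/m³) matches the rounding convention of the
published tables.

### Re-emission rate

No standard formula exists for the clean-air-phase emission rate; the
package uses the chamber mass balance solved for a pure surface source,
ER = mean re-emission C_out × Q_v/A (μg → mg). Samples within 12 h of the
clean-air switch (six chamber time constants at 0.5 h⁻¹) are excluded —
they still see adsorption-phase gas flushing out of the chamber, which
would inflate ER by far more than the 1 % closure the estimator otherwise
achieves. If no sample survives the settling window all re-emission
samples are used.

## Breakthrough capacity and lifetime

Breakthrough time t_b is the first time the column outlet/inlet ratio
reaches the threshold (default 0.5 % as in the reference protocol; 5 % is
the wider field convention and is a parameter), linearly interpolated
between bracketing samples — series are coarsely sampled and no standard
interpolation rule exists. A column that never reaches the threshold
returns `None` (a signal), not an error.

**Unit audit for w_s.** With ρ_s in μg/m³, q_s in m³/h, t_b in h and m in
g, ρ_s·q_s·t_b/m is in μg/g. The traditional statement of this formula
divides by 1000, i.e. expresses w_s in mg/g. The package keeps μg/g
internally so that ρ_Aa = w_s·ρ_A (g/m²) lands in μg/m², commensurate with
ρ_Ac = Σ SB_m·Δt (μg/m²), and the lifetime ratio is dimensionless;
`sorption_capacity(..., milligrams=True)` applies the 1000 for display.

ρ_Ac uses right-endpoint rectangles (the sampled flux applies to the
interval ending at its sampling time, first interval from t = 0), matching
the Δt_e,i = t_e,i − t_e,i−1 definition; a trapezoid option exists for
smoother series. The accumulation window Δt_e in t_lt = (ρ_Aa/ρ_Ac)·Δt_e
is the window over which ρ_Ac was summed.

The published ~333-day (0.9-year) siding lifetime rests on long-term
laboratory series that are not printed and is therefore **not** a
reproduction target. The stage is validated by simulator closure instead: a
siding-like scenario (v_d = 1.44 m/h at 122 μg/m³ inlet, 6300 g/m² board =
9 mm at 700 kg/m³, capacity chosen so the true lifetime is 333 days)
recovers the configured capacity within 5 % and lifetime within 2 %.

## Dwelling concentration and cancer risk

The model dwelling is one well-mixed zone: 14 m² floor, 45 m² walls,
42 m³, 0.5 h⁻¹ ventilation, mixing factor K = 0.5. The steady
concentration is C_steady = ER·Area/(ACH·VOL·K); the emitting Area
defaults to the floor (14 m²), which is the convention under which every
published dwelling concentration back-calculates exactly. Two caveats are
inherited deliberately from the reference assessment and flagged here:
K divides the denominator (so a mixing penalty *raises* the predicted
concentration — the opposite of the concentration-multiplier convention),
and the chamber inlet concentration stands in for the unmitigated indoor
level in risk-reduction calculations. Outdoor HCHO is omitted.

Risk uses the standard EPA chronic-daily-intake kernel
CDI = C·IR·ET·EF·ED·AF/(BW·AT) with potency factor 2.0 × 10⁻²
(mg/kg/day)⁻¹; some published statements of the kernel omit ET and EF, but
the package includes them for dimensional correctness and lets the
calibration absorb them (below). Risk reduction applies the same kernel to
(C_unmitigated − C_steady) and equals the difference of risks exactly, by
linearity.

### Calibrated exposure profiles

The individual exposure-factor values behind the reference risk table are
not published; only the per-concentration product is identifiable. The
default profiles fix ET = 14 h/day (time-use surveys), AF = 1, PF = 0.02,
lifetime exposure (EF = 365 d/y, ED = 70 y, AT = 25550 d), body weights of
65 kg (male) and 55 kg (female), and solve the inhalation rate so the unit
risk equals the through-origin least-squares slope of the published
(C_steady, risk) pairs: 2.416678 × 10⁻⁶ (male) and 2.042072 × 10⁻⁶
(female) per μg/m³. These slopes reproduce every male risk cell exactly at
the printed precision; the female cells carry independent rounding and one
cell differs in the last digit from any single slope. Every factor is
overridable in configuration; the calibrated IRs (≈0.56 and ≈0.40 m³/h)
are fitted products, not asserted survey values.

### Monte Carlo extension

`monte_carlo_risk` propagates exposure-factor uncertainty: each factor is
a point mass or a frozen scipy.stats distribution, all draws flow from one
explicit seed, and with only point masses the mean equals the
deterministic risk exactly with zero SD (the degenerate check the
deterministic pipeline is audited against).

## Synthetic data generator

The chamber simulator integrates the well-mixed balance with a linear
(deposition-velocity) sink,

    dC/dt = n·(C_in − C) − L·v_d·C,

in closed form. The linear sink is the minimal model consistent with a
constant adsorption rate and gives the exact identity SB_v,eq = v_d at
steady state, the basis of all parameter-recovery tests; SB_r then equals
100·L·v_d/(n + L·v_d). A saturating (half-saturation) variant exists for
stress tests only. The chamber starts at the inlet concentration (the
protocol pre-flushes with spiked air before inserting the specimen).
During re-emission the sink is off and the specimen is a constant areal
source, so the mass balance inverts exactly to the configured ER.
Measurement noise is Gaussian per sampling point, truncated at zero, SD
defaulting to 8 μg/m³ (mid-range of the replicate SDs in the reference
chamber data); all randomness flows from one explicit seed.

Column curves are logistic in time with midpoint t₅₀ = capacity·m/(ρ_s·q_s),
which makes the area above the curve equal the configured capacity to
first order (within 1 % once sharpness·t₅₀ ≥ 20). The 0.5 % threshold
truncates ≈ln(199)/sharpness hours of uptake, so closure scenarios use
sharpness·t₅₀ ≳ 100: the capacity-closure column uses sharpness 0.05 h⁻¹
with t₅₀ ≈ 10⁴ h, the lifetime-closure column sharpness 1.0 h⁻¹ (a ~10-h
transition on a ~700-h run).

What the generator does *not* emulate: temperature/RH dependence of
sorption, Langmuir saturation during the adsorption window, drifting inlet
concentration, or autocorrelated instrument noise. Passing closure tests
therefore demonstrates estimator correctness under the stated model, not
robustness to those real-world effects.

The noisy parameter-recovery experiment uses 200 replicates sampling the
steady window every 4 h from 24–72 h (13 points). The window-mean ratio
estimator has a second-order bias of order σ²/μ² ≈ 10⁻³, and the denser
window keeps that bias well below one standard error of the replicate
mean; sparser windows (3 points) do not.

## Tolerances for reproducing the published tables

Declared once, applied by `reproduce_study` and the test suite:

| quantity | tolerance |
|---|---|
| empty-chamber recoveries | exact after integer rounding |
| dwelling C_steady | exact after 1-decimal rounding |
| SB_m, SB_v,eq, SB_r (all 10 conditions) | 1 % + display half-ULP + propagated input half-ULP |
| named headline cells (124.9, 168.0, 0.83, 1.26, 1.44, 40.1 %, 53.8 %) | plain ±1 % |
| equivalent ACH (0.33, 0.50, 0.57) | ±0.01 after 2-decimal rounding |
| risks per sex | 1 % + 0.05 (×10⁻⁶ scale); male cells also exact after 1-decimal rounding |
| risk reductions | 1 % + 0.5 (×10⁻⁶ scale) |

The propagated input term is needed because the published concentration
means are printed rounded (inlet to 1 decimal, outlet to integer): a ±0.5
μg/m³ outlet rounding alone moves a small flux by ±0.62 μg/(m²·h), ~1.4 %
of the smallest printed SB_m. The typed fixture records carry the
1-decimal inlet concentrations, the best available estimate of the
laboratory means.

## Numerical and degenerate-input choices

- C_out = 0 makes SB_v,eq undefined → error naming the sample; C_in = 0
  makes SB_r and recovery undefined → error.
- ρ_Ac = 0 yields an infinite lifetime (signal), not an exception.
- Breakthrough threshold never reached → `None`, distinct from errors.
- Empty record files parse to an empty list with a warning; missing
  mandatory columns and non-monotone sampling times are hard errors naming
  the row.
- All concentrations are stored in μg/m³; ppm appears only at the
  boundary. Stored metric values are full precision; rounding is a
  rendering concern.
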