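"""Concentration unit conversions for formaldehyde.

Everything inside the package works in μg/m³; ppm appears only at the
boundary (regulatory target levels, report headers). Two conversion modes
are provided:

* ``ideal_gas`` (default) — molar volume scaled from 22.414 L/mol at 0 °C
  by the test temperature, with M(HCHO) = 30.03 g/mol.
* ``fixed`` — a pinned molar volume of 24.62 L/mol, under which
  0.2 ppm ↔ 244 μg/m³. Chamber-test reports in this field are commonly
  stated with that rounding, so the fixed mode is used when reproducing
  published tables.
"""

from __future__ import annotations

M_HCHO = 30.03
"""Molar mass of formaldehyde, g/mol."""

MOLAR_VOLUME_STP = 22.414
"""Ideal-gas molar volume at 0 °C and 1 atm, L/mol."""

FIXED_MOLAR_VOLUME = 24.62
"""Pinned molar volume (L/mol) reproducing the 0.2 ppm = 244 μg/m³ convention."""

_T0_K = 273.15


def molar_volume(temperature_c: float) -> float:
    """Ideal-gas molar volume (L/mol) at 1 atm and the given temperature (°C)."""
    if not -50.0 < temperature_c < 100.0:
        raise ValueError(f"temperature {temperature_c} °C outside supported range (-50, 100)")
    return MOLAR_VOLUME_STP * (temperature_c + _T0_K) / _T0_K


def ppm_to_ugm3(c_ppm: float, temperature_c: float = 25.0, *, fixed: bool = False) -> float:
    """Convert a formaldehyde mixing ratio (ppm) to mass concentration (μg/m³).

    Parameters
    ----------
    c_ppm
        Volume mixing ratio in parts per million. Must be non-negative.
    temperature_c
        Air temperature for the ideal-gas molar volume; ignored in fixed mode.
    fixed
        Use the pinned 24.62 L/mol molar volume instead of the ideal-gas law.
    """
    if c_ppm < 0:
        raise ValueError(f"concentration must be non-negative, got {c_ppm} ppm")
    v_m = FIXED_MOLAR_VOLUME if fixed else molar_volume(temperature_c)
    return c_ppm * 1000.0 * M_HCHO / v_m


def ugm3_to_ppm(c_ugm3: float, temperature_c: float = 25.0, *, fixed: bool = False) -> float:
    """Inverse of :func:`ppm_to_ugm3`; round-trips to 1e-9 relative."""
    if c_ugm3 < 0:
        raise ValueError(f"concentration must be non-negative, got {c_ugm3} μg/m³")
    v_m = FIXED_MOLAR_VOLUME if fixed else molar_volume(temperature_c)
    return c_ugm3 * v_m / (1000.0 * M_HCHO)
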