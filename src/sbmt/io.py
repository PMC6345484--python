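"""Reading and writing chamber records and run configuration.

Chamber records travel as delimited text with one row per (test, t_e):

    material_id, target_ppm, temp_c, rh_pct, t_e_h, phase,
    c_in_ugm3, c_out_ugm3, sd_in, sd_out, n_reps

Rows sharing (material_id, target_ppm, temp_c, rh_pct) form one test and
must be ordered by t_e within it. Unknown columns are preserved as test
metadata, so write ∘ read is the identity on canonical files.

Run configuration is a single YAML (or JSON) document with optional
``chamber``, ``qa_thresholds``, ``room`` and ``profiles`` sections mapping
straight onto the corresponding pydantic models.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .chamber import ChamberConfig, ChamberTest, Phase, QARecord, QAThresholds, SamplePair
from .risk import ExposureProfile, RoomScenario, default_profiles

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "material_id", "target_ppm", "temp_c", "rh_pct",
    "t_e_h", "phase", "c_in_ugm3", "c_out_ugm3",
]
OPTIONAL_COLUMNS = ["sd_in", "sd_out", "n_reps"]
QA_COLUMNS = {
    "qa_background_hcho": "background_hcho",
    "qa_background_tvoc": "background_tvoc",
    "qa_recovery": "empty_chamber_recovery",
    "qa_r2": "calibration_r2",
    "qa_outlet_flow_fraction": "outlet_flow_fraction",
}
_KEY = ["material_id", "target_ppm", "temp_c", "rh_pct"]


def read_chamber_tests(
    path: str | Path,
    base_config: ChamberConfig | None = None,
    *,
    delimiter: str = ",",
) -> list[ChamberTest]:
    """Parse a chamber-record CSV into ChamberTest objects.

    ``base_config`` supplies the chamber geometry (volume, ventilation,
    specimen area); per-row temperature and RH override its condition
    fields. An empty file yields an empty list with a warning.
    """
    base = base_config or ChamberConfig()
    try:
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("chamber record file %s is empty", path)
        return []
    if df.empty:
        logger.warning("chamber record file %s has no rows", path)
        return []
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    extra_cols = [
        c for c in df.columns
        if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS and c not in QA_COLUMNS
    ]

    tests: list[ChamberTest] = []
    for key, group in df.groupby(_KEY, sort=False):
        material_id, ppm, temp, rh = key
        t_prev = -math.inf
        samples = []
        for row in group.itertuples():
            if row.t_e_h <= t_prev:
                raise ValueError(
                    f"{path}: non-monotone t_e at row {row.Index} (test {material_id})"
                )
            t_prev = row.t_e_h
            sd_in = getattr(row, "sd_in", None)
            sd_out = getattr(row, "sd_out", None)
            samples.append(
                SamplePair(
                    t_e=float(row.t_e_h),
                    c_in=float(row.c_in_ugm3),
                    c_out=float(row.c_out_ugm3),
                    sd_in=None if sd_in is None or pd.isna(sd_in) else float(sd_in),
                    sd_out=None if sd_out is None or pd.isna(sd_out) else float(sd_out),
                    n_replicates=int(getattr(row, "n_reps", 1) or 1),
                    phase=Phase(row.phase),
                )
            )
        meta = {
            c: str(group[c].iloc[0]) for c in extra_cols if group[c].nunique(dropna=False) == 1
        }
        cfg = base.model_copy(
            update={"temperature": float(temp), "relative_humidity": float(rh)}
        )
        qa_fields = {
            field: float(group[col].iloc[0])
            for col, field in QA_COLUMNS.items()
            if col in group.columns and not pd.isna(group[col].iloc[0])
        }
        tests.append(
            ChamberTest(
                material_id=str(material_id),
                target_inlet_ppm=float(ppm),
                config=cfg,
                samples=tuple(samples),
                qa=QARecord(**qa_fields),
                meta=meta,
            )
        )
    return tests


def write_chamber_tests(
    tests: Iterable[ChamberTest], path: str | Path, *, delimiter: str = ","
) -> None:
    """Write tests in the canonical chamber-record dialect (lossless)."""
    rows = []
    for t in tests:
        for s in t.samples:
            row = {
                "material_id": t.material_id,
                "target_ppm": t.target_inlet_ppm,
                "temp_c": t.config.temperature,
                "rh_pct": t.config.relative_humidity,
                "t_e_h": s.t_e,
                "phase": s.phase.value,
                "c_in_ugm3": s.c_in,
                "c_out_ugm3": s.c_out,
                "sd_in": s.sd_in,
                "sd_out": s.sd_out,
                "n_reps": s.n_replicates,
            }
            row.update({col: getattr(t.qa, field) for col, field in QA_COLUMNS.items()})
            row.update(t.meta)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


class RunConfig(BaseModel):
    """Structured configuration for a pipeline run."""

    chamber: ChamberConfig = Field(default_factory=ChamberConfig)
    qa_thresholds: QAThresholds = Field(default_factory=QAThresholds)
    room: RoomScenario = Field(default_factory=RoomScenario)
    profiles: dict[str, ExposureProfile] = Field(default_factory=default_profiles)
    nominal_loading: float = Field(0.4, gt=0, description="L for equivalent-ACH reports")
    window_start: float = Field(12.0, ge=0, description="steady-state window start, h")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration; absent sections take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
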