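"""Patient records, cohorts, and cohort-table I/O.

A :class:`PatientRecord` bundles one subject's ipsilateral-lung DVH with the
clinical covariates used by the risk analysis (age, chemotherapy cycles,
surgery type, stage) and the radiation-induced lung injury (RILI) outcome
graded 0-5 per RTOG. The binary outcome is grade >= 1.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import (
    DIFFERENTIAL,
    DoseVolumeHistogram,
    DvhDialect,
    _as_differential,
    max_dose,
    mean_dose,
    read_dvh,
    volume_at_dose,
    write_dvh,
)

#: cohort bundles store DVHs differentially: lossless for any histogram,
#: since the cumulative->differential midpoint re-binning is one-way
COHORT_DIALECT = DvhDialect(mode=DIFFERENTIAL)
from .errors import EmptyInputError, MalformedInputError, ParameterError

SURGERY_TYPES = ("breast_conserving", "modified_radical")
STAGES = ("I", "II", "III")

#: dose thresholds (Gy) of the standard Vx battery
VX_LEVELS = (5, 10, 15, 20, 25, 30, 35, 40, 45)


@dataclass
class PatientRecord:
    patient_id: str
    dvh: DoseVolumeHistogram
    age_years: int
    chemo_cycles: int
    surgery: str
    stage: str
    rili_grade: int

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ParameterError("age_years must be positive")
        if self.chemo_cycles < 0:
            raise ParameterError("chemo_cycles must be nonnegative")
        if self.surgery not in SURGERY_TYPES:
            raise ParameterError(f"surgery must be one of {SURGERY_TYPES}")
        if self.stage not in STAGES:
            raise ParameterError(f"stage must be one of {STAGES}")
        if not 0 <= self.rili_grade <= 5:
            raise ParameterError("rili_grade must be an integer in 0..5")

    @property
    def rili_binary(self) -> int:
        """1 iff any-grade injury (RTOG grade >= 1)."""
        return int(self.rili_grade >= 1)

    def v(self, threshold_gy: float) -> float:
        """Vx in percent: share of lung volume receiving >= ``threshold_gy``."""
        return 100.0 * volume_at_dose(self.dvh, threshold_gy)

    def vx_table(self) -> dict[int, float]:
        """The V5..V45 battery in percent, monotone nonincreasing in x."""
        return {x: self.v(x) for x in VX_LEVELS}

    @property
    def mean_dose_gy(self) -> float:
        return mean_dose(self.dvh)

    @property
    def max_dose_gy(self) -> float:
        return max_dose(self.dvh)


@dataclass
class Cohort:
    records: list[PatientRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise MalformedInputError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def require_nonempty(self) -> None:
        if not self.records:
            raise EmptyInputError(f"cohort {self.label!r} is empty")

    def outcomes(self) -> np.ndarray:
        return np.array([r.rili_binary for r in self.records], dtype=float)

    @property
    def n_events(self) -> int:
        return int(self.outcomes().sum())

    def to_frame(self) -> pd.DataFrame:
        """Covariate + dosimetry table, one row per patient (Vx in percent)."""
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "age": r.age_years,
                "chemo_cycles": r.chemo_cycles,
                "surgery": r.surgery,
                "stage": r.stage,
                "rili_grade": r.rili_grade,
                "rili_binary": r.rili_binary,
                "mean_dose_gy": r.mean_dose_gy,
                "max_dose_gy": r.max_dose_gy,
            }
            row.update({f"v{x}": val for x, val in r.vx_table().items()})
            rows.append(row)
        return pd.DataFrame(rows)


def write_cohort(
    cohort: Cohort, out_dir: str | Path, dialect: DvhDialect = COHORT_DIALECT
) -> Path:
    """Write ``cohort.csv`` plus per-patient DVH CSVs under ``out_dir/dvh/``.

    Returns the cohort-table path. The layout is exactly what
    :func:`read_cohort` expects back; DVHs are stored in differential mode
    so the round trip loses nothing but sub-ulp percent scaling.
    """
    out_dir = Path(out_dir)
    dvh_dir = out_dir / "dvh"
    dvh_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort:
        rel = Path("dvh") / f"{r.patient_id}.csv"
        h = _as_differential(r.dvh) if dialect.mode == DIFFERENTIAL else r.dvh
        (out_dir / rel).write_text(write_dvh(h, dialect))
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age_years,
                "chemo_cycles": r.chemo_cycles,
                "surgery": r.surgery,
                "stage": r.stage,
                "rili_grade": r.rili_grade,
                "dvh_path": rel.as_posix(),
            }
        )
    table = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return table


def read_cohort(
    table_path: str | Path,
    dialect: DvhDialect = COHORT_DIALECT,
    label: str = "",
) -> Cohort:
    """Read a cohort table CSV; DVH paths are resolved relative to the table."""
    table_path = Path(table_path)
    df = pd.read_csv(table_path)
    required = {"patient_id", "age", "chemo_cycles", "surgery", "stage", "rili_grade", "dvh_path"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(f"cohort table lacks columns {sorted(missing)}")
    base = table_path.parent
    records = []
    for row in df.itertuples(index=False):
        dvh = read_dvh((base / row.dvh_path).read_text(), dialect)
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                dvh=dvh,
                age_years=int(row.age),
                chemo_cycles=int(row.chemo_cycles),
                surgery=str(row.surgery),
                stage=str(row.stage),
                rili_grade=int(row.rili_grade),
            )
        )
    return Cohort(records, label=label or table_path.stem)
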