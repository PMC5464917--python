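"""Dose-volume histogram (DVH) container, parsing and dosimetric summaries.

A DVH describes how dose is distributed over an organ's volume. In
*cumulative* mode ``volumes[i]`` is the fraction of the organ receiving at
least ``doses_gy[i]``; in *differential* mode it is the fraction receiving a
dose in the bin centred (by convention) at ``doses_gy[i]``. Volumes are
stored internally as fractions in [0, 1]; percentages appear only at I/O
boundaries.
"""
from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyInputError,
    MalformedInputError,
    ModeError,
    RangeError,
)

CUMULATIVE = "cumulative"
DIFFERENTIAL = "differential"

#: zero-volume tolerance used when locating the maximum delivered dose
_VOL_EPS = 1e-9


@dataclass(frozen=True)
class DvhDialect:
    """Describes the on-disk convention of a DVH text file.

    Planning systems export DVHs inconsistently; the dialect makes the
    contract explicit. The default is the package's canonical format:
    comma-separated, header row ``dose_gy,volume_pct``, cumulative mode,
    volumes in percent.
    """

    delimiter: str = ","
    percent: bool = True
    header: bool = True
    mode: str = CUMULATIVE


DEFAULT_DIALECT = DvhDialect()


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """A binned dose-vs-volume-fraction curve for one organ.

    Invariants (enforced at construction):

    * ``doses_gy`` strictly increasing, nonnegative, finite;
    * all ``volumes`` in [0, 1];
    * cumulative mode: volumes nonincreasing; if the lowest bin is 0 Gy its
      volume is 1 within 1e-6 (the whole organ receives at least no dose);
    * differential mode: volumes sum to at most 1 (equal to 1 for a
      histogram that accounts for the whole organ).
    """

    doses_gy: np.ndarray
    volumes: np.ndarray
    mode: str = CUMULATIVE
    organ_label: str = "ipsilateral_lung"
    total_volume_cc: float | None = None

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses_gy, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        if doses.ndim != 1 or vols.ndim != 1:
            raise MalformedInputError("doses and volumes must be 1-D")
        if doses.size == 0:
            raise EmptyInputError("histogram has no bins")
        if doses.size != vols.size:
            raise MalformedInputError("doses and volumes differ in length")
        if not (np.all(np.isfinite(doses)) and np.all(np.isfinite(vols))):
            raise MalformedInputError("non-finite dose or volume")
        if doses[0] < 0:
            raise RangeError("negative dose bin")
        if doses.size > 1 and not np.all(np.diff(doses) > 0):
            raise MalformedInputError("doses must be strictly increasing")
        if np.any(vols < -1e-9) or np.any(vols > 1 + 1e-9):
            raise RangeError("volume fraction outside [0, 1]")
        vols = np.clip(vols, 0.0, 1.0)
        if self.mode == CUMULATIVE:
            if np.any(np.diff(vols) > 1e-9):
                raise MalformedInputError(
                    "cumulative volumes must be nonincreasing in dose"
                )
            if doses[0] == 0.0 and abs(vols[0] - 1.0) > 1e-6:
                raise MalformedInputError(
                    "cumulative volume at 0 Gy must be 1 (whole organ)"
                )
        elif self.mode == DIFFERENTIAL:
            s = float(vols.sum())
            if s <= 0:
                raise MalformedInputError("differential histogram carries no mass")
            if s > 1 + 1e-6:
                raise MalformedInputError(
                    f"differential volumes sum to {s:.6g} > 1"
                )
        else:
            raise ModeError(f"unknown DVH mode {self.mode!r}")
        doses.flags.writeable = False
        vols.flags.writeable = False
        object.__setattr__(self, "doses_gy", doses)
        object.__setattr__(self, "volumes", vols)

    def __len__(self) -> int:
        return int(self.doses_gy.size)


def to_differential(h: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a cumulative DVH to differential bins.

    Bin ``i < N-1`` gets mass ``cum[i] - cum[i+1]`` at the midpoint of the
    two bounding cumulative doses; the last bin keeps its cumulative tail at
    its own dose. The total differential mass equals the cumulative volume
    at the first bin.
    """
    if h.mode != CUMULATIVE:
        raise ModeError("to_differential expects a cumulative histogram")
    d, c = h.doses_gy, h.volumes
    if len(h) == 1:
        return DoseVolumeHistogram(
            d.copy(), c.copy(), DIFFERENTIAL, h.organ_label, h.total_volume_cc
        )
    mids = 0.5 * (d[:-1] + d[1:])
    masses = np.maximum(c[:-1] - c[1:], 0.0)  # clip float noise
    doses = np.append(mids, d[-1])
    vols = np.append(masses, c[-1])
    return DoseVolumeHistogram(doses, vols, DIFFERENTIAL, h.organ_label, h.total_volume_cc)


def to_cumulative(h: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a differential DVH to cumulative (reversed running sum)."""
    if h.mode != DIFFERENTIAL:
        raise ModeError("to_cumulative expects a differential histogram")
    cum = np.minimum(np.cumsum(h.volumes[::-1])[::-1], 1.0)
    return DoseVolumeHistogram(
        h.doses_gy.copy(), cum, CUMULATIVE, h.organ_label, h.total_volume_cc
    )


def _as_differential(h: DoseVolumeHistogram) -> DoseVolumeHistogram:
    return h if h.mode == DIFFERENTIAL else to_differential(h)


def _as_cumulative(h: DoseVolumeHistogram) -> DoseVolumeHistogram:
    return h if h.mode == CUMULATIVE else to_cumulative(h)


def volume_at_dose(h: DoseVolumeHistogram, threshold_gy: float) -> float:
    """Fraction of the organ receiving at least ``threshold_gy``.

    Linear interpolation on the cumulative curve; V(0) = 1 and the curve is
    taken as 0 beyond the last bin. Nonincreasing in the threshold.
    """
    if threshold_gy < 0:
        raise RangeError("dose threshold must be nonnegative")
    c = _as_cumulative(h)
    x, y = c.doses_gy, c.volumes
    if x[0] > 0:  # anchor the whole organ at zero dose
        x = np.concatenate(([0.0], x))
        y = np.concatenate(([1.0], y))
    return float(np.interp(threshold_gy, x, y, right=0.0))


def mean_dose(h: DoseVolumeHistogram) -> float:
    """Volume-weighted mean organ dose in Gy (MLD for a lung DVH)."""
    d = _as_differential(h)
    return float(np.dot(d.volumes, d.doses_gy))


def max_dose(h: DoseVolumeHistogram) -> float:
    """Highest bin dose carrying nonzero volume (> 1e-9), in Gy."""
    d = _as_differential(h)
    nz = d.doses_gy[d.volumes > _VOL_EPS]
    return float(nz[-1]) if nz.size else 0.0


def read_dvh(
    stream,
    dialect: DvhDialect = DEFAULT_DIALECT,
    organ_label: str = "ipsilateral_lung",
    total_volume_cc: float | None = None,
) -> DoseVolumeHistogram:
    """Parse a two-column delimited DVH text (dose Gy, volume) per ``dialect``.

    Percent volumes are rescaled to fractions; the result is a validated
    histogram in the dialect's declared mode.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.strip() for ln in stream.read().splitlines()]
    lines = [ln for ln in lines if ln]
    if dialect.header:
        if not lines:
            raise EmptyInputError("empty DVH stream")
        lines = lines[1:]
    if not lines:
        raise EmptyInputError("DVH stream has no data rows")
    doses, vols = [], []
    for ln in lines:
        parts = ln.split(dialect.delimiter)
        if len(parts) != 2:
            raise MalformedInputError(f"expected two columns, got {ln!r}")
        try:
            dose, vol = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise MalformedInputError(f"non-numeric DVH row {ln!r}") from exc
        doses.append(dose)
        vols.append(vol)
    vols_arr = np.asarray(vols, dtype=float)
    hi = 100.0 if dialect.percent else 1.0
    if np.any(vols_arr < 0) or np.any(vols_arr > hi + 1e-9):
        raise RangeError(f"volume outside [0, {hi:g}]")
    if dialect.percent:
        vols_arr = vols_arr / 100.0
    return DoseVolumeHistogram(
        np.asarray(doses, dtype=float), vols_arr, dialect.mode, organ_label, total_volume_cc
    )


def write_dvh(h: DoseVolumeHistogram, dialect: DvhDialect = DEFAULT_DIALECT) -> str:
    """Serialize a DVH as delimited text; round-trips bit-exactly via ``read_dvh``."""
    if h.mode != dialect.mode:
        raise ModeError(
            f"histogram mode {h.mode!r} does not match dialect mode {dialect.mode!r}"
        )
    scale = 100.0 if dialect.percent else 1.0
    out = []
    if dialect.header:
        unit = "volume_pct" if dialect.percent else "volume_fraction"
        out.append(f"dose_gy{dialect.delimiter}{unit}")
    for dose, vol in zip(h.doses_gy, h.volumes):
        out.append(f"{float(dose)!r}{dialect.delimiter}{float(vol) * scale!r}")
    return "\n".join(out) + "\n"
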