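"""Steady-state fluorescence emission anisotropy from polarized intensities.

One instrument observation consists of four polarized intensity channels
(``i_vv``, ``i_vh``, ``i_hv``, ``i_hh``): the first subscript is the
orientation of the excitation polarizer, the second that of the emission
polarizer. The anisotropy is

    r = (R_v - R_h) / (R_v + 2 R_h)

with ``R_v = i_vv / i_vh`` and ``R_h = i_hv / i_hh``; ``R_h`` is the
instrument calibration (G) factor correcting for the polarization bias of
the detection path. Only intensity *ratios* enter the math, so units are
arbitrary and never interconverted.

Physically admissible anisotropies lie in [-0.2, 0.4]. Values outside
this interval are flagged but retained: downstream regression weighting,
not this module, decides inclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidReadingError

#: Default excitation wavelength set (nm): excitation maxima of the
#: anthroyloxy fluorophore.
DEFAULT_WAVELENGTHS: tuple[float, ...] = (319.0, 333.0, 347.0, 367.0, 381.0)

#: Physically admissible anisotropy range for a planar fluorophore.
R_MIN, R_MAX = -0.2, 0.4

#: Column order of the polarized-reading CSV dialect.
READING_COLUMNS = (
    "time_s",
    "temperature_c",
    "excitation_nm",
    "i_vv",
    "i_vh",
    "i_hv",
    "i_hh",
    "probe_id",
    "condition_id",
    "replicate_id",
)


@dataclass(frozen=True)
class PolarizedReading:
    """One spectrofluorometer observation: four channels plus metadata."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float
    excitation_nm: float
    temperature_c: float
    time_s: float = 0.0
    probe_id: str = ""
    condition_id: str = ""
    replicate_id: str = ""

    def channels(self) -> dict[str, float]:
        return {
            "i_vv": self.i_vv,
            "i_vh": self.i_vh,
            "i_hv": self.i_hv,
            "i_hh": self.i_hh,
        }


@dataclass(frozen=True)
class AnisotropyPoint:
    """A single anisotropy value with its acquisition metadata."""

    r: float
    excitation_nm: float
    temperature_c: float
    time_s: float = 0.0
    probe_id: str = ""
    condition_id: str = ""
    replicate_id: str = ""

    @property
    def in_range(self) -> bool:
        """True when r lies in the physically admissible [-0.2, 0.4]."""
        return R_MIN <= self.r <= R_MAX


@dataclass
class FlagReport:
    """Collects out-of-range points and processing warnings of a batch."""

    out_of_range: list[AnisotropyPoint] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_flags(self) -> int:
        return len(self.out_of_range)


def compute_anisotropy(reading: PolarizedReading) -> AnisotropyPoint:
    """Convert one polarized reading into an anisotropy point.

    Raises
    ------
    InvalidReadingError
        If any intensity channel is nonpositive; the error names the
        offending channel.
    """
    for name, value in reading.channels().items():
        if not value > 0:
            raise InvalidReadingError(
                f"channel {name} must be strictly positive, got {value!r}",
                channel=name,
            )
    r_v = reading.i_vv / reading.i_vh
    r_h = reading.i_hv / reading.i_hh
    r = (r_v - r_h) / (r_v + 2.0 * r_h)
    return AnisotropyPoint(
        r=r,
        excitation_nm=reading.excitation_nm,
        temperature_c=reading.temperature_c,
        time_s=reading.time_s,
        probe_id=reading.probe_id,
        condition_id=reading.condition_id,
        replicate_id=reading.replicate_id,
    )


def batch_anisotropy(
    readings: Sequence[PolarizedReading],
) -> tuple[list[AnisotropyPoint], FlagReport]:
    """Order-preserving elementwise anisotropy over a sequence of readings.

    Out-of-range anisotropies are flagged in the returned
    :class:`FlagReport` but kept in the output sequence. An empty input
    yields an empty output plus a warning in the report.
    """
    report = FlagReport()
    if len(readings) == 0:
        report.warnings.append("empty input: no readings to convert")
        return [], report
    points = []
    for reading in readings:
        point = compute_anisotropy(reading)
        if not point.in_range:
            report.out_of_range.append(point)
        points.append(point)
    return points, report


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def readings_to_frame(readings: Iterable[PolarizedReading]) -> pd.DataFrame:
    rows = [
        {
            "time_s": rd.time_s,
            "temperature_c": rd.temperature_c,
            "excitation_nm": rd.excitation_nm,
            "i_vv": rd.i_vv,
            "i_vh": rd.i_vh,
            "i_hv": rd.i_hv,
            "i_hh": rd.i_hh,
            "probe_id": rd.probe_id,
            "condition_id": rd.condition_id,
            "replicate_id": rd.replicate_id,
        }
        for rd in readings
    ]
    return pd.DataFrame(rows, columns=list(READING_COLUMNS))


def frame_to_readings(frame: pd.DataFrame) -> list[PolarizedReading]:
    missing = set(READING_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidReadingError(
            f"reading table is missing columns: {sorted(missing)}"
        )
    return [
        PolarizedReading(
            i_vv=float(row.i_vv),
            i_vh=float(row.i_vh),
            i_hv=float(row.i_hv),
            i_hh=float(row.i_hh),
            excitation_nm=float(row.excitation_nm),
            temperature_c=float(row.temperature_c),
            time_s=float(row.time_s),
            probe_id=str(row.probe_id),
            condition_id=str(row.condition_id),
            replicate_id=str(row.replicate_id),
        )
        for row in frame.itertuples(index=False)
    ]


def write_readings(readings: Iterable[PolarizedReading], path) -> None:
    """Write readings as CSV in the package dialect, one reading per row.

    Floats are written in shortest round-trip representation so that
    write -> read reproduces every field losslessly.
    """
    readings_to_frame(readings).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def read_readings(path) -> list[PolarizedReading]:
    """Read a polarized-reading CSV written by :func:`write_readings`."""
    return frame_to_readings(pd.read_csv(path, float_precision="round_trip"))


def points_to_frame(points: Iterable[AnisotropyPoint]) -> pd.DataFrame:
    rows = [
        {
            "time_s": p.time_s,
            "temperature_c": p.temperature_c,
            "excitation_nm": p.excitation_nm,
            "r": p.r,
            "in_range": p.in_range,
            "probe_id": p.probe_id,
            "condition_id": p.condition_id,
            "replicate_id": p.replicate_id,
        }
        for p in points
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "time_s",
            "temperature_c",
            "excitation_nm",
            "r",
            "in_range",
            "probe_id",
            "condition_id",
            "replicate_id",
        ],
    )
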