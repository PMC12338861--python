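"""Excited-state lifetimes and zero-time anisotropies per probe/wavelength.

The decomposition needs, for every probe, excitation wavelength and
temperature, the mean excited-state lifetime tau_F (ns) and the zero-time
(fundamental) anisotropy r_o. These are *inputs*, interpolated linearly in
temperature between anchor measurements — typically supplied at a few
anchor temperatures per (probe, wavelength). Queries beyond the outermost
anchors are linearly extrapolated and flagged; the flag propagates into
downstream decomposition diagnostics.

The bundled :func:`default_photophysics` table is synthetic: values are in
plausible ranges (tau_F 4-12 ns, r_o spanning -0.1..0.3 across 319-381 nm)
but are NOT literature values. Real analyses must supply their own table.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .errors import PhotophysicsLookupError, ValidationError

#: Probe labels and the carbon index of the anthroyloxy attachment, which
#: serves as the transversal depth coordinate (interface -> bilayer center).
PROBE_POSITIONS: dict[str, int] = {
    "2-AS": 2,
    "7-AS": 7,
    "9-AS": 9,
    "12-AS": 12,
    "16-AP": 16,
}

TABLE_COLUMNS = ("probe_id", "temperature_c", "excitation_nm", "tau_f_ns", "r_o")

RoMode = Literal["interpolate", "fixed"]


@dataclass(frozen=True)
class ProbeSpec:
    """A depth probe: label plus attachment carbon index."""

    probe_id: str
    position_n: int


@dataclass(frozen=True)
class PhotophysicsResult:
    """Resolved (tau_F, r_o) for one query, with extrapolation flag."""

    tau_f_ns: float
    r_o: float
    extrapolated: bool


def _validate_row(row: pd.Series, idx: int) -> None:
    if not row.tau_f_ns > 0:
        raise ValidationError(
            f"row {idx}: tau_f_ns must be > 0, got {row.tau_f_ns!r}"
        )
    if not -0.2 <= row.r_o <= 0.4:
        raise ValidationError(
            f"row {idx}: r_o must lie in [-0.2, 0.4], got {row.r_o!r}"
        )


class ProbePhotophysics:
    """Anchor table of (tau_F, r_o) per probe, wavelength and temperature.

    Parameters
    ----------
    table:
        Long-format frame with columns probe_id, temperature_c,
        excitation_nm, tau_f_ns, r_o. Validated on construction;
        violations are reported with row numbers.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(TABLE_COLUMNS) - set(table.columns)
        if missing:
            raise ValidationError(
                f"photophysics table is missing columns: {sorted(missing)}"
            )
        table = table.loc[:, list(TABLE_COLUMNS)].copy()
        table["probe_id"] = table["probe_id"].astype(str)
        for col in ("temperature_c", "excitation_nm", "tau_f_ns", "r_o"):
            table[col] = table[col].astype(float)
        for idx, row in enumerate(table.itertuples(index=False)):
            _validate_row(row, idx)
        dup = table.duplicated(["probe_id", "excitation_nm", "temperature_c"])
        if dup.any():
            raise ValidationError(
                f"duplicate anchors at rows {list(table.index[dup])}"
            )
        self.table = table.sort_values(
            ["probe_id", "excitation_nm", "temperature_c"]
        ).reset_index(drop=True)
        # index: (probe, wavelength) -> sorted anchor arrays
        self._anchors: dict[tuple[str, float], tuple[list, list, list]] = {}
        for (probe, wl), grp in self.table.groupby(["probe_id", "excitation_nm"]):
            self._anchors[(probe, float(wl))] = (
                grp["temperature_c"].tolist(),
                grp["tau_f_ns"].tolist(),
                grp["r_o"].tolist(),
            )

    @property
    def probes(self) -> list[str]:
        return sorted(self.table["probe_id"].unique())

    def wavelengths(self, probe_id: str) -> list[float]:
        return sorted(
            {wl for (p, wl) in self._anchors if p == probe_id}
        )

    def get(
        self,
        probe_id: str,
        excitation_nm: float,
        temperature_c: float,
        r_o_mode: RoMode = "interpolate",
    ) -> PhotophysicsResult:
        """Resolve (tau_F, r_o) at a temperature by linear interpolation.

        Exact at anchor temperatures; linear between bracketing anchors;
        linear continuation beyond the outermost anchors, flagged as
        extrapolated. With ``r_o_mode="fixed"`` r_o is taken from the
        anchor nearest in temperature instead of interpolated.
        """
        key = (str(probe_id), float(excitation_nm))
        if key not in self._anchors:
            raise PhotophysicsLookupError(
                f"no photophysics anchors for probe {probe_id!r} "
                f"at {excitation_nm} nm"
            )
        temps, taus, ros = self._anchors[key]
        t = float(temperature_c)
        if len(temps) == 1:
            if t == temps[0]:
                return PhotophysicsResult(taus[0], ros[0], False)
            raise ValidationError(
                f"single anchor at {temps[0]} degC for probe {probe_id!r} "
                f"at {excitation_nm} nm: cannot interpolate to {t} degC"
            )
        extrapolated = t < temps[0] or t > temps[-1]
        # bracketing segment (clamped to the outer segments when outside)
        j = bisect_left(temps, t)
        j = min(max(j, 1), len(temps) - 1)
        t0, t1 = temps[j - 1], temps[j]
        frac = (t - t0) / (t1 - t0)
        tau = taus[j - 1] + frac * (taus[j] - taus[j - 1])
        if r_o_mode == "fixed":
            nearest = min(range(len(temps)), key=lambda i: abs(temps[i] - t))
            r_o = ros[nearest]
        else:
            r_o = ros[j - 1] + frac * (ros[j] - ros[j - 1])
        return PhotophysicsResult(tau, r_o, extrapolated)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def get_photophysics(
    table: ProbePhotophysics,
    probe_id: str,
    excitation_nm: float,
    temperature_c: float,
    r_o_mode: RoMode = "interpolate",
) -> PhotophysicsResult:
    """Functional alias for :meth:`ProbePhotophysics.get`."""
    return table.get(probe_id, excitation_nm, temperature_c, r_o_mode)


def load_photophysics(path) -> ProbePhotophysics:
    """Load and validate a photophysics anchor table from CSV."""
    return ProbePhotophysics(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Synthetic default table (for tests and simulations only)
# ---------------------------------------------------------------------------

#: Synthetic r_o per wavelength at the middle anchor. Chosen to span the
#: plausible -0.1..0.3 range and to give good leverage in the X regressor.
_DEFAULT_RO = {319.0: 0.30, 333.0: 0.22, 347.0: 0.15, 367.0: 0.08, 381.0: -0.12}

#: Synthetic lifetime (ns) per probe at 21 degC; decreases with temperature.
_DEFAULT_TAU21 = {"2-AS": 8.6, "7-AS": 9.4, "9-AS": 9.8, "12-AS": 10.5, "16-AP": 11.2}

_ANCHOR_TEMPS = (21.0, 37.0, 47.0)
_TAU_SCALE = {21.0: 1.0, 37.0: 0.84, 47.0: 0.72}
_RO_SHIFT = {21.0: 0.004, 37.0: 0.0, 47.0: -0.004}


def default_photophysics() -> ProbePhotophysics:
    """Synthetic anchor table: 5 probes x 5 wavelengths x 3 temperatures.

    Clearly-labeled synthetic stand-in for a user-supplied table; values
    are plausible for anthroyloxy probes but are not measurements.
    """
    rows = []
    for probe in PROBE_POSITIONS:
        for wl, ro in _DEFAULT_RO.items():
            for t in _ANCHOR_TEMPS:
                rows.append(
                    {
                        "probe_id": probe,
                        "temperature_c": t,
                        "excitation_nm": wl,
                        "tau_f_ns": _DEFAULT_TAU21[probe] * _TAU_SCALE[t],
                        "r_o": ro + _RO_SHIFT[t] * (1.0 if ro >= 0 else -1.0),
                    }
                )
    return ProbePhotophysics(pd.DataFrame(rows))
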