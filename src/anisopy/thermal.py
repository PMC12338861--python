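"""Heating-curve analysis and depth x temperature fluidity gradients.

A heating curve is a continuous anisotropy recording of one probe in one
condition while the cuvette temperature ramps slowly (default 12 degC/h,
10 -> 52 degC) and the excitation wavelength alternates through the
configured set. The pipeline is:

1. :func:`bin_heating_curve` — group readings into temperature windows;
2. :func:`windowed_decompositions` — pool replicate curves per window and
   run the multi-wavelength decomposition in each;
3. :func:`smooth_profiles` — local linear regression over temperature
   producing continuous R_op(T), R_ip(T);
4. :func:`build_gradient` — evaluate each probe's profile on the 5 degC
   grid and arrange by attachment carbon (depth coordinate);
5. :func:`compare_gradients` — cell-wise fold changes between conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .anisotropy import AnisotropyPoint
from .decomposition import Decomposition, decompose_wavelength_set
from .errors import (
    GridMismatchError,
    InsufficientDataError,
    ValidationError,
)
from .photophysics import PROBE_POSITIONS, ProbePhotophysics, RoMode

Mode = Literal["op", "ip"]

#: Default reporting grid: 10..50 degC in 5 degC steps.
GRID_TEMPERATURES: tuple[float, ...] = tuple(float(t) for t in range(10, 51, 5))

#: Tolerance (degC) for temperature back-steps due to sensor jitter.
JITTER_TOLERANCE_C = 0.5


@dataclass
class HeatingCurve:
    """Time-ordered anisotropy points of one (probe, condition, replicate)."""

    points: list[AnisotropyPoint]
    ramp_rate_c_per_h: float = 12.0
    t_start_c: float = 10.0
    t_end_c: float = 52.0

    def __post_init__(self):
        if not self.points:
            raise ValidationError("heating curve has no points")
        times = [p.time_s for p in self.points]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("points must be time-ordered")
        temps = [p.temperature_c for p in self.points]
        drops = [
            a - b for a, b in zip(temps, temps[1:]) if a - b > JITTER_TOLERANCE_C
        ]
        if drops:
            raise ValidationError(
                f"temperature decreases by up to {max(drops):.3f} degC, "
                f"more than the {JITTER_TOLERANCE_C} degC jitter tolerance"
            )
        if len({p.excitation_nm for p in self.points}) < 2:
            raise ValidationError("curve needs >= 2 distinct wavelengths")

    @property
    def probe_id(self) -> str:
        return self.points[0].probe_id

    @property
    def condition_id(self) -> str:
        return self.points[0].condition_id


@dataclass
class TemperatureWindow:
    """Readings of one temperature bin, grouped by wavelength."""

    index: int
    center_c: float
    points: list[AnisotropyPoint]
    flagged: bool  # fewer than 2 wavelengths present

    @property
    def wavelengths(self) -> list[float]:
        return sorted({p.excitation_nm for p in self.points})


def bin_heating_curve(
    curve: HeatingCurve, window_c: float = 2.0
) -> list[TemperatureWindow]:
    """Partition a curve into fixed-width temperature windows.

    Bin edges start at ``curve.t_start_c``; each returned window is
    centered on the mean temperature of its members. Windows with fewer
    than two wavelengths are flagged.
    """
    if not window_c > 0:
        raise ValidationError(f"window_c must be > 0, got {window_c!r}")
    bins: dict[int, list[AnisotropyPoint]] = {}
    for p in curve.points:
        k = int(math.floor((p.temperature_c - curve.t_start_c) / window_c))
        bins.setdefault(k, []).append(p)
    windows = []
    for k in sorted(bins):
        pts = bins[k]
        n_wl = len({p.excitation_nm for p in pts})
        windows.append(
            TemperatureWindow(
                index=k,
                center_c=float(np.mean([p.temperature_c for p in pts])),
                points=pts,
                flagged=n_wl < 2,
            )
        )
    return windows


def windowed_decompositions(
    curves: Sequence[HeatingCurve],
    photophysics: ProbePhotophysics,
    *,
    window_c: float = 2.0,
    weighting: str = "ivar",
    r_o_mode: RoMode = "interpolate",
) -> list[Decomposition]:
    """Pool replicate curves per temperature window and decompose each.

    All curves must share one (probe, condition). Pooling all replicates
    into one per-window regression (rather than averaging per-replicate
    fits) uses the whole dataset in a single fit per window. Windows with
    fewer than two wavelengths are skipped.

    For inverse-variance weighting the per-measurement Var(r) of each
    wavelength is pooled across *all* windows of the curve set before
    being handed to the per-window fits: replicate scatter within one
    window has only a few degrees of freedom, and weights built from it
    are noisy enough to visibly inflate estimator variance and distort
    CI coverage.
    """
    if not curves:
        raise InsufficientDataError("no heating curves supplied")
    keys = {(c.probe_id, c.condition_id) for c in curves}
    if len(keys) > 1:
        raise ValidationError(
            f"curves mix (probe, condition) groups: {sorted(keys)}"
        )
    pooled: dict[int, list[AnisotropyPoint]] = {}
    for curve in curves:
        for w in bin_heating_curve(curve, window_c):
            pooled.setdefault(w.index, []).extend(w.points)

    r_variance: dict[float, float] | None = None
    if weighting == "ivar":
        ss: dict[float, float] = {}
        dof: dict[float, int] = {}
        for pts in pooled.values():
            by_wl: dict[float, list[float]] = {}
            for p in pts:
                by_wl.setdefault(float(p.excitation_nm), []).append(p.r)
            for wl, rs in by_wl.items():
                if len(rs) >= 2:
                    ss[wl] = ss.get(wl, 0.0) + float(
                        np.var(rs, ddof=1)
                    ) * (len(rs) - 1)
                    dof[wl] = dof.get(wl, 0) + len(rs) - 1
        if ss and all(v > 0 for v in ss.values()):
            r_variance = {wl: ss[wl] / dof[wl] for wl in ss}

    out = []
    for k in sorted(pooled):
        pts = pooled[k]
        if len({p.excitation_nm for p in pts}) < 2:
            continue
        out.append(
            decompose_wavelength_set(
                pts,
                photophysics,
                weighting=weighting,
                r_o_mode=r_o_mode,
                r_variance=r_variance,
            )
        )
    if not out:
        raise InsufficientDataError("no window had >= 2 wavelengths")
    return out


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    a = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return a**3


def _local_arrhenius(
    t: np.ndarray,
    y: np.ndarray,
    t0: float,
    bandwidth: float,
    y_se: np.ndarray | None = None,
) -> tuple[float, float]:
    """Local linear fit of log(rate) on 1/T_K around t0.

    Thermally activated rates are linear in these coordinates, so the
    local fit is unbiased for Arrhenius-type truth at any bandwidth,
    which permits the wide default kernel. The tricube kernel distance
    is measured in degC. Returns (rate, se) back on the MHz scale.

    The reported variance is the larger of the residual-based estimate
    and the propagation of the supplied per-window standard errors
    through the smoother's equivalent kernel; the residual route alone
    undercovers at this few-windows scale.
    """
    h = bandwidth
    w = _tricube((t - t0) / h)
    # widen adaptively until at least 3 points carry weight
    while np.count_nonzero(w) < 3 and h < 10 * bandwidth:
        h *= 1.5
        w = _tricube((t - t0) / h)
    if np.count_nonzero(w) < 2:
        return math.nan, math.nan
    z = 1.0 / (t + 273.15) - 1.0 / (t0 + 273.15)
    ly = np.log(y)
    sw = w.sum()
    m_z = (w * z).sum() / sw
    szz = (w * (z - m_z) ** 2).sum()
    m_y = (w * ly).sum() / sw
    if szz <= 0:
        est = m_y
        kernel = w / sw
        resid = ly - est
        dof = max(np.count_nonzero(w) - 1, 1)
        s2 = (w * resid**2).sum() / dof
        var = s2 / sw
    else:
        slope = (w * (z - m_z) * (ly - m_y)).sum() / szz
        est = m_y - slope * m_z  # value at z = 0
        # equivalent kernel of the intercept estimate
        kernel = w * (1.0 / sw - m_z * (z - m_z) / szz)
        resid = ly - (est + slope * z)
        dof = max(np.count_nonzero(w) - 2, 1)
        s2 = (w * resid**2).sum() / dof
        var = s2 * (1.0 / sw + m_z**2 / szz)
    if y_se is not None:
        var_known = float((kernel**2 * (y_se / y) ** 2).sum())
        var = max(var, var_known)
    rate = float(math.exp(est))
    return rate, rate * float(math.sqrt(var))


#: Evaluation is allowed to extend this far (degC) beyond the outermost
#: window centers, so the 10 degC grid row is reachable from windows
#: whose first center sits slightly above the ramp start.
SPAN_MARGIN_C = 2.0


@dataclass
class RateProfile:
    """A continuous R(T) curve smoothed from windowed decompositions."""

    temperatures: np.ndarray
    rates_mhz: np.ndarray
    bandwidth_c: float
    t_min: float
    t_max: float
    ses_mhz: np.ndarray | None = None
    extrapolation_temps: np.ndarray = field(
        default_factory=lambda: np.array([])
    )

    def __call__(self, temperature_c: float) -> tuple[float, float]:
        """Evaluate (rate_mhz, se_mhz) at a temperature inside the span."""
        if not self.t_min <= temperature_c <= self.t_max:
            raise ValidationError(
                f"T={temperature_c} outside profile span "
                f"[{self.t_min}, {self.t_max}]"
            )
        return _local_arrhenius(
            self.temperatures,
            self.rates_mhz,
            temperature_c,
            self.bandwidth_c,
            y_se=self.ses_mhz,
        )

    def flagged_at(self, temperature_c: float) -> bool:
        """True when nearby windows carried a photophysics extrapolation flag."""
        if self.extrapolation_temps.size == 0:
            return False
        return bool(
            np.any(
                np.abs(self.extrapolation_temps - temperature_c)
                <= self.bandwidth_c
            )
        )


@dataclass
class ProbeProfiles:
    """Smoothed out-of-plane and in-plane profiles of one probe."""

    probe_id: str
    op: RateProfile
    ip: RateProfile

    def get(self, mode: Mode) -> RateProfile:
        return self.op if mode == "op" else self.ip


def smooth_profiles(
    decomps: Sequence[Decomposition],
    *,
    bandwidth_c: float = 12.0,
) -> ProbeProfiles:
    """Smooth pooled windowed decompositions into continuous profiles.

    Requires at least 3 windows spanning at least 15 degC. Windows with
    nonpositive rate estimates are excluded from the corresponding
    profile (the log-scale smoother cannot use them).
    """
    decomps = sorted(decomps, key=lambda d: d.temperature_c)
    if len(decomps) < 3:
        raise InsufficientDataError(
            f"need >= 3 windows to smooth, got {len(decomps)}"
        )
    t = np.array([d.temperature_c for d in decomps])
    span = float(t.max() - t.min())
    if span < 15.0:
        raise InsufficientDataError(
            f"windows span only {span:.1f} degC; need >= 15 degC"
        )
    probe_id = decomps[0].probe_id
    flagged = np.array(
        [d.temperature_c for d in decomps if d.extrapolation_flag]
    )

    def _profile(rates: np.ndarray, cis: np.ndarray) -> RateProfile:
        ok = rates > 0
        if np.count_nonzero(ok) < 3:
            raise InsufficientDataError(
                "fewer than 3 windows with positive rate estimates"
            )
        if not ok.all():
            warnings.warn(
                f"{np.count_nonzero(~ok)} window(s) with nonpositive rate "
                "excluded from smoothing",
                stacklevel=3,
            )
        ses = cis[ok] / 1.96
        return RateProfile(
            t[ok],
            rates[ok],
            bandwidth_c=bandwidth_c,
            t_min=float(t[ok].min()) - SPAN_MARGIN_C,
            t_max=float(t[ok].max()) + SPAN_MARGIN_C,
            ses_mhz=ses if np.all(np.isfinite(ses)) else None,
            extrapolation_temps=flagged,
        )

    op = _profile(
        np.array([d.r_op_mhz for d in decomps]),
        np.array([d.ci95_op for d in decomps]),
    )
    ip = _profile(
        np.array([d.r_ip_mhz for d in decomps]),
        np.array([d.ci95_ip for d in decomps]),
    )
    return ProbeProfiles(probe_id=probe_id, op=op, ip=ip)


# ---------------------------------------------------------------------------
# Gradient surfaces
# ---------------------------------------------------------------------------

SURFACE_COLUMNS = (
    "mode",
    "condition_id",
    "position_n",
    "temperature_c",
    "rate_mhz",
    "ci95",
    "flag",
)


@dataclass
class GradientSurface:
    """R values on the probe-position x temperature grid (one mode)."""

    mode: Mode
    condition_id: str
    cells: pd.DataFrame  # position_n, temperature_c, rate_mhz, ci95, flag

    def __post_init__(self):
        missing = {"position_n", "temperature_c", "rate_mhz", "ci95", "flag"} - set(
            self.cells.columns
        )
        if missing:
            raise ValidationError(f"surface missing columns {sorted(missing)}")
        self.cells = self.cells.sort_values(
            ["position_n", "temperature_c"]
        ).reset_index(drop=True)

    @property
    def positions(self) -> list[int]:
        return sorted(self.cells["position_n"].unique())

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.cells["temperature_c"].unique())

    def pivot(self) -> pd.DataFrame:
        return self.cells.pivot(
            index="position_n", columns="temperature_c", values="rate_mhz"
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out.insert(0, "condition_id", self.condition_id)
        out.insert(0, "mode", self.mode)
        return out[list(SURFACE_COLUMNS)]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GradientSurface":
        modes = frame["mode"].unique()
        conds = frame["condition_id"].unique()
        if len(modes) != 1 or len(conds) != 1:
            raise ValidationError(
                "surface frame must hold exactly one (mode, condition)"
            )
        return cls(
            mode=str(modes[0]),
            condition_id=str(conds[0]),
            cells=frame.drop(columns=["mode", "condition_id"]).copy(),
        )

    @classmethod
    def from_csv(cls, path) -> "GradientSurface":
        return cls.from_frame(pd.read_csv(path))


def build_gradient(
    profiles: Iterable[ProbeProfiles],
    mode: Mode,
    *,
    condition_id: str = "",
    grid_temperatures: Sequence[float] = GRID_TEMPERATURES,
    positions: dict[str, int] | None = None,
) -> GradientSurface:
    """Evaluate smoothed profiles on the grid and arrange by depth.

    When ``positions`` is given explicitly, probes declared there but
    absent from ``profiles`` leave explicit NaN gap rows and emit a
    warning; with the default position map only the supplied probes
    appear. Grid cells outside a profile's temperature span are left as
    NaN gaps with a flag.
    """
    declared = positions is not None
    positions = dict(positions if declared else PROBE_POSITIONS)
    profiles = list(profiles)
    if len(profiles) < 1:
        raise InsufficientDataError("no profiles supplied")
    have = {p.probe_id for p in profiles}
    missing = (set(positions) - have) if declared else set()
    if missing:
        warnings.warn(
            f"no profile for probes {sorted(missing)}; surface has gaps",
            stacklevel=2,
        )
    rows = []
    for pp in profiles:
        if pp.probe_id not in positions:
            raise ValidationError(
                f"unknown probe {pp.probe_id!r}: no depth position assigned"
            )
        prof = pp.get(mode)
        for t in grid_temperatures:
            if prof.t_min <= t <= prof.t_max:
                est, se = prof(t)
                ci = 1.96 * se
                flag = prof.flagged_at(t)
            else:
                est, ci, flag = math.nan, math.nan, True
            rows.append(
                {
                    "position_n": positions[pp.probe_id],
                    "temperature_c": float(t),
                    "rate_mhz": est,
                    "ci95": ci,
                    "flag": flag,
                }
            )
    for probe in sorted(missing):
        for t in grid_temperatures:
            rows.append(
                {
                    "position_n": positions[probe],
                    "temperature_c": float(t),
                    "rate_mhz": math.nan,
                    "ci95": math.nan,
                    "flag": True,
                }
            )
    return GradientSurface(
        mode=mode, condition_id=condition_id, cells=pd.DataFrame(rows)
    )


@dataclass
class GradientComparison:
    """Cell-wise fold changes between two surfaces of the same mode."""

    mode: Mode
    condition_a: str
    condition_b: str
    cells: pd.DataFrame  # position_n, temperature_c, fold, ci95, flag
    log_fold_threshold: float = math.log(1.5)

    @property
    def exceeding(self) -> pd.DataFrame:
        """Cells where |log fold| exceeds the threshold."""
        mask = np.abs(np.log(self.cells["fold"])) > self.log_fold_threshold
        return self.cells[mask]

    def fold_vs_temperature(self) -> pd.Series:
        """Mean fold per grid temperature (across positions)."""
        return self.cells.groupby("temperature_c")["fold"].mean()

    def monotone_increasing(self, rtol: float = 0.05) -> bool:
        """True when the mean fold is nondecreasing with temperature."""
        f = self.fold_vs_temperature().to_numpy()
        return bool(np.all(np.diff(f) >= -rtol * f[:-1]))

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out.insert(0, "condition_b", self.condition_b)
        out.insert(0, "condition_a", self.condition_a)
        out.insert(0, "mode", self.mode)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_gradients(
    a: GradientSurface,
    b: GradientSurface,
    *,
    log_fold_threshold: float = math.log(1.5),
) -> GradientComparison:
    """Cell-wise ratio a/b with delta-method CI propagation.

    Ratios are defined only where both cells hold finite positive rates.
    """
    if a.mode != b.mode:
        raise GridMismatchError(f"mode mismatch: {a.mode!r} vs {b.mode!r}")
    merged = a.cells.merge(
        b.cells,
        on=["position_n", "temperature_c"],
        how="outer",
        suffixes=("_a", "_b"),
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        raise GridMismatchError(
            "surfaces are defined on different (position, temperature) grids"
        )
    ok = (
        np.isfinite(merged["rate_mhz_a"])
        & np.isfinite(merged["rate_mhz_b"])
        & (merged["rate_mhz_a"] > 0)
        & (merged["rate_mhz_b"] > 0)
    )
    m = merged[ok]
    fold = m["rate_mhz_a"] / m["rate_mhz_b"]
    rel = np.sqrt(
        (m["ci95_a"] / m["rate_mhz_a"]) ** 2
        + (m["ci95_b"] / m["rate_mhz_b"]) ** 2
    )
    cells = pd.DataFrame(
        {
            "position_n": m["position_n"].to_numpy(),
            "temperature_c": m["temperature_c"].to_numpy(),
            "fold": fold.to_numpy(),
            "ci95": (fold * rel).to_numpy(),
            "flag": (m["flag_a"] | m["flag_b"]).to_numpy(),
        }
    )
    return GradientComparison(
        mode=a.mode,
        condition_a=a.condition_id,
        condition_b=b.condition_id,
        cells=cells,
        log_fold_threshold=log_fold_threshold,
    )
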