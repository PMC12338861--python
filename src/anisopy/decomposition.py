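"""Decomposition of multi-wavelength anisotropy into rotational rates.

For a planar fluorophore rotating slowly relative to its excited-state
lifetime, the steady-state anisotropy r measured at several excitation
wavelengths (each with its own fundamental anisotropy r_o and lifetime
tau_F) can be linearized as

    Y = R_ip * X + R_op

with

    X = (10 r_o - 1) / (5 r_o + 1)
    Y = 5 r_o (r_o / r - 1) / (2 tau_F (5 r_o + 1))        [ns^-1]

so that a weighted linear regression of Y on X across wavelengths yields
the in-plane rotation rate R_ip (slope) and the out-of-plane rotation rate
R_op (intercept). Both are carried internally in ns^-1 and reported in MHz
(x1000). The rotational correlation time is phi = 1/(6 R).

The linearization rests on cos^2(alpha) = (5 r_o + 1)/3, the inverse of
r_o = (3 cos^2(alpha) - 1)/5, where alpha is the angle between absorption
and emission transition dipoles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .anisotropy import AnisotropyPoint
from .errors import (
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
    SingularityError,
    ValidationError,
)
from .photophysics import ProbePhotophysics, RoMode

#: ns^-1 -> MHz
NS_INV_TO_MHZ = 1000.0


def cos_sq_alpha(r_o: float) -> float:
    """cos^2 of the absorption/emission dipole angle from r_o.

    Inverts r_o = (3 cos^2(alpha) - 1)/5. Maps [-0.2, 0.4] onto [0, 1].
    """
    if not -0.2 <= r_o <= 0.4:
        raise DomainError(
            f"r_o must lie in [-0.2, 0.4] for a planar rotor, got {r_o!r}"
        )
    return (5.0 * r_o + 1.0) / 3.0


def xy_regressor(r_o: float) -> float:
    """The dimensionless regressor X = (10 r_o - 1)/(5 r_o + 1)."""
    denom = 5.0 * r_o + 1.0
    if denom == 0.0:
        raise SingularityError("X undefined at r_o = -0.2 (5 r_o + 1 = 0)")
    return (10.0 * r_o - 1.0) / denom


@dataclass(frozen=True)
class XYPoint:
    """One transformed observation on the Y = R_ip X + R_op line.

    ``y`` is in ns^-1. ``r`` and ``r_o`` are kept for diagnostics.
    """

    x: float
    y: float
    weight: float = 1.0
    excitation_nm: float = math.nan
    r: float = math.nan
    r_o: float = math.nan

    def __post_init__(self):
        if self.weight < 0:
            raise ValidationError(f"weight must be >= 0, got {self.weight!r}")
        if not math.isfinite(self.y):
            raise ValidationError(f"y must be finite, got {self.y!r}")


def weber_transform(
    r: float,
    r_o: float,
    tau_f_ns: float,
    *,
    weight: float = 1.0,
    excitation_nm: float = math.nan,
) -> XYPoint:
    """Map one anisotropy measurement to an (X, Y) point.

    Raises
    ------
    SingularityError
        If r = 0 (Y has a pole) or r_o = -0.2 (X and Y have a pole).
    DomainError
        If r_o is outside [-0.2, 0.4], tau_F is nonpositive, or r and
        r_o differ in sign (the ratio r_o/r is then unphysical).
    """
    if r == 0:
        raise SingularityError("r = 0: Y undefined (fully depolarized)")
    if not tau_f_ns > 0:
        raise DomainError(f"tau_f_ns must be > 0, got {tau_f_ns!r}")
    cos_sq_alpha(r_o)  # domain check on r_o
    if 5.0 * r_o + 1.0 == 0.0:
        raise SingularityError("r_o = -0.2: denominator 5 r_o + 1 vanishes")
    if r * r_o < 0:
        raise DomainError(
            f"r ({r!r}) and r_o ({r_o!r}) must have the same sign"
        )
    x = xy_regressor(r_o)
    y = 5.0 * r_o * (r_o / r - 1.0) / (2.0 * tau_f_ns * (5.0 * r_o + 1.0))
    return XYPoint(
        x=x, y=y, weight=weight, excitation_nm=excitation_nm, r=r, r_o=r_o
    )


@dataclass
class Decomposition:
    """Weighted-regression estimate of (R_op, R_ip) at one temperature."""

    r_op_mhz: float
    r_ip_mhz: float
    ci95_op: float
    ci95_ip: float
    n_points: int
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    extrapolation_flag: bool = False
    temperature_c: float = math.nan
    probe_id: str = ""
    condition_id: str = ""

    @property
    def phi_op_ns(self) -> float:
        return correlation_time(self.r_op_mhz)

    @property
    def phi_ip_ns(self) -> float:
        return correlation_time(self.r_ip_mhz)


def fit_rotation_rates(
    points: Sequence[XYPoint],
    *,
    temperature_c: float = math.nan,
    probe_id: str = "",
    condition_id: str = "",
    extrapolation_flag: bool = False,
    scale_mode: str = "estimated",
) -> Decomposition:
    """Weighted least squares of Y on X: slope -> R_ip, intercept -> R_op.

    95% confidence half-widths come from the t distribution with n-2
    degrees of freedom. With ``scale_mode="estimated"`` (default) the
    residual scale is estimated from the weighted residuals, so weights
    need only be proportional to inverse variances. With
    ``scale_mode="floored"`` — appropriate when the weights are true
    inverse variances — the residual scale factor is floored at 1, so
    CIs never shrink below the level implied by the weights themselves.
    """
    if len(points) < 2:
        raise InsufficientDataError(
            f"need >= 2 points for a line fit, got {len(points)}"
        )
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    w = np.array([p.weight for p in points], dtype=float)
    if np.any(w < 0):
        raise ValidationError("negative weights are not allowed")
    if not np.any(w > 0):
        raise ValidationError("all weights are zero")
    span = np.ptp(x[w > 0])
    if span <= 1e-12 * max(1.0, np.max(np.abs(x))):
        raise RankDeficiencyError(
            "all X values identical: slope and intercept are not separable"
        )
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (intercept + slope * x)
    n = len(points)
    dof = n - 2
    if dof > 0:
        s2 = (w * resid**2).sum() / dof
        if scale_mode == "floored":
            s2 = max(s2, 1.0)
        se_slope = math.sqrt(s2 / sxx)
        se_intercept = math.sqrt(s2 * (1.0 / sw + xbar**2 / sxx))
        tcrit = stats.t.ppf(0.975, dof)
        ci_ip = tcrit * se_slope
        ci_op = tcrit * se_intercept
    else:
        ci_ip = ci_op = math.inf
    sst = (w * (y - ybar) ** 2).sum()
    r_squared = 1.0 - (w * resid**2).sum() / sst if sst > 0 else 1.0

    return Decomposition(
        r_op_mhz=intercept * NS_INV_TO_MHZ,
        r_ip_mhz=slope * NS_INV_TO_MHZ,
        ci95_op=ci_op * NS_INV_TO_MHZ,
        ci95_ip=ci_ip * NS_INV_TO_MHZ,
        n_points=n,
        r_squared=float(r_squared),
        residuals=resid,
        extrapolation_flag=extrapolation_flag,
        temperature_c=temperature_c,
        probe_id=probe_id,
        condition_id=condition_id,
    )


def correlation_time(rate_mhz: float) -> float:
    """Rotational correlation time phi = 1/(6 R), in ns, from R in MHz."""
    if not rate_mhz > 0:
        raise DomainError(f"rate must be > 0 MHz, got {rate_mhz!r}")
    return 1e3 / (6.0 * rate_mhz)


def _delta_dy_dr(r: float, r_o: float, tau_f_ns: float) -> float:
    """dY/dr for propagating Var(r) to Var(Y)."""
    return -5.0 * r_o**2 / (2.0 * tau_f_ns * (5.0 * r_o + 1.0) * r**2)


def decompose_wavelength_set(
    points: Iterable[AnisotropyPoint],
    photophysics: ProbePhotophysics,
    *,
    weighting: str = "ivar",
    r_o_mode: RoMode = "interpolate",
    temperature_c: float | None = None,
    r_variance: dict[float, float] | None = None,
) -> Decomposition:
    """Full single-temperature decomposition across the wavelength set.

    Composes photophysics lookup -> (X, Y) transform -> weighted fit for
    a group of anisotropy points sharing one (probe, condition) at one
    nominal temperature (multiple wavelengths, optionally replicated).

    Weighting ``"ivar"`` averages r per wavelength across replicates,
    transforms the mean, and weights each wavelength by the inverse
    variance of its Y value, with Var(Y) propagated from the replicate
    scatter of r by the delta method; CIs then use the floored residual
    scale (see :func:`fit_rotation_rates`). This stabilizes the
    regression against the strongly heteroscedastic Y noise across
    wavelengths. When ``r_variance`` supplies an externally estimated
    per-measurement Var(r) per wavelength (e.g. pooled over many
    windows, see :func:`anisopy.thermal.windowed_decompositions`), it
    replaces the noisy within-group scatter in the weights. Without
    ``r_variance`` the fit falls back to an unweighted per-point fit
    whenever any wavelength lacks replicate scatter. ``"none"`` is
    always unweighted per-point.

    Extrapolation flags from the photophysics lookups propagate into the
    result.
    """
    points = list(points)
    if not points:
        raise InsufficientDataError("no anisotropy points supplied")
    probe_ids = {p.probe_id for p in points}
    if len(probe_ids) > 1:
        raise ValidationError(
            f"points mix probes {sorted(probe_ids)}; decompose one probe "
            "at a time"
        )
    probe_id = points[0].probe_id
    condition_id = points[0].condition_id
    if temperature_c is None:
        temperature_c = float(np.mean([p.temperature_c for p in points]))

    by_wl: dict[float, list[AnisotropyPoint]] = {}
    for p in points:
        by_wl.setdefault(float(p.excitation_nm), []).append(p)
    if len(by_wl) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct wavelengths, got {sorted(by_wl)}"
        )

    if weighting == "ivar" and r_variance is not None:
        use_ivar = all(
            r_variance.get(wl, 0.0) > 0 for wl in by_wl
        )
    else:
        use_ivar = weighting == "ivar" and all(
            len(grp) >= 2 and np.var([p.r for p in grp], ddof=1) > 0
            for grp in by_wl.values()
        )

    xy: list[XYPoint] = []
    extrapolated = False
    if use_ivar:
        for wl, grp in sorted(by_wl.items()):
            rs = np.array([p.r for p in grp])
            ph = photophysics.get(probe_id, wl, temperature_c, r_o_mode)
            extrapolated = extrapolated or ph.extrapolated
            r_mean = float(np.mean(rs))
            if r_variance is not None:
                var_mean = r_variance[wl] / len(rs)
            else:
                var_mean = float(np.var(rs, ddof=1)) / len(rs)
            dydr = _delta_dy_dr(r_mean, ph.r_o, ph.tau_f_ns)
            xy.append(
                weber_transform(
                    r_mean,
                    ph.r_o,
                    ph.tau_f_ns,
                    weight=1.0 / (var_mean * dydr**2),
                    excitation_nm=wl,
                )
            )
    else:
        for wl, grp in sorted(by_wl.items()):
            for p in grp:
                ph = photophysics.get(probe_id, wl, p.temperature_c, r_o_mode)
                extrapolated = extrapolated or ph.extrapolated
                xy.append(
                    weber_transform(
                        p.r, ph.r_o, ph.tau_f_ns, excitation_nm=wl
                    )
                )
    return fit_rotation_rates(
        xy,
        temperature_c=temperature_c,
        probe_id=probe_id,
        condition_id=condition_id,
        extrapolation_flag=extrapolated,
        scale_mode="floored" if use_ivar else "estimated",
    )


def decompositions_to_frame(decomps: Iterable[Decomposition]):
    """Long-format result table in the package CSV dialect."""
    import pandas as pd

    rows = []
    for d in decomps:
        rows.append(
            {
                "probe_id": d.probe_id,
                "condition_id": d.condition_id,
                "temperature_c": d.temperature_c,
                "r_op_mhz": d.r_op_mhz,
                "ci95_op": d.ci95_op,
                "r_ip_mhz": d.r_ip_mhz,
                "ci95_ip": d.ci95_ip,
                "phi_op_ns": correlation_time(d.r_op_mhz)
                if d.r_op_mhz > 0
                else math.nan,
                "phi_ip_ns": correlation_time(d.r_ip_mhz)
                if d.r_ip_mhz > 0
                else math.nan,
                "n_points": d.n_points,
                "r_squared": d.r_squared,
                "extrapolation_flag": d.extrapolation_flag,
            }
        )
    return pd.DataFrame(rows)
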