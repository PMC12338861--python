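"""Forward simulation of the spectrofluorometer experiment.

Ground-truth rotational-rate surfaces (Arrhenius in temperature, per probe
and rotation mode) are inverted to anisotropies, which are then rendered
as four polarized intensity channels with instrument calibration factor
and noise — so every pipeline stage is testable without external data.

Scenario parameters are synthetic stand-ins chosen so rates near 37 degC
fall in the 10-60 MHz range typical of anthroyloxy probes in membranes;
they are not literature values.
"""

from __future__ import annotations

import json
import math
import zlib
from pathlib import Path
from typing import Annotated, Literal, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .anisotropy import (
    DEFAULT_WAVELENGTHS,
    PolarizedReading,
    write_readings,
)
from .errors import ScenarioError
from .photophysics import ProbePhotophysics, default_photophysics

KELVIN_OFFSET = 273.15
_T_REF_K = 37.0 + KELVIN_OFFSET


# ---------------------------------------------------------------------------
# Ground-truth rate laws
# ---------------------------------------------------------------------------

class ArrheniusLaw(BaseModel):
    """R(T) = rate37 * exp(E/k * (1/T_ref - 1/T_K)), rates in MHz."""

    kind: Literal["arrhenius"] = "arrhenius"
    rate37_mhz: float = Field(gt=0)
    e_over_k: float = Field(default=3600.0, ge=0, description="E/k_B in K")

    def rate_mhz(self, temperature_c: float) -> float:
        t_k = temperature_c + KELVIN_OFFSET
        return self.rate37_mhz * math.exp(
            self.e_over_k * (1.0 / _T_REF_K - 1.0 / t_k)
        )


class TanhFold(BaseModel):
    """Smooth saturating fold profile rising from ``low`` to ``high``."""

    low: float = Field(gt=0)
    high: float = Field(gt=0)
    midpoint_c: float = 27.0
    width_c: float = Field(default=8.0, gt=0)

    def fold(self, temperature_c: float) -> float:
        return self.low + 0.5 * (self.high - self.low) * (
            1.0 + math.tanh((temperature_c - self.midpoint_c) / self.width_c)
        )


class ScaledLaw(BaseModel):
    """A base Arrhenius law multiplied by a temperature-dependent fold."""

    kind: Literal["scaled"] = "scaled"
    base: ArrheniusLaw
    fold: TanhFold

    def rate_mhz(self, temperature_c: float) -> float:
        return self.base.rate_mhz(temperature_c) * self.fold.fold(temperature_c)


RateLaw = Annotated[Union[ArrheniusLaw, ScaledLaw], Field(discriminator="kind")]


class ProbeTruth(BaseModel):
    """Ground-truth out-of-plane and in-plane rate laws of one probe."""

    op: RateLaw
    ip: RateLaw

    def rates_mhz(self, temperature_c: float) -> tuple[float, float]:
        return self.op.rate_mhz(temperature_c), self.ip.rate_mhz(temperature_c)


class NoiseModel(BaseModel):
    kind: Literal["gaussian", "poisson", "none"] = "gaussian"
    sigma_rel: float = Field(default=0.01, ge=0)
    temp_jitter_sd_c: float = Field(default=0.02, ge=0)


class Ramp(BaseModel):
    rate_c_per_h: float = Field(default=12.0, gt=0)
    t_start_c: float = 10.0
    t_end_c: float = 52.0

    @model_validator(mode="after")
    def _ordered(self):
        if not self.t_end_c > self.t_start_c:
            raise ValueError("t_end_c must exceed t_start_c")
        return self

    @property
    def duration_s(self) -> float:
        return (self.t_end_c - self.t_start_c) / self.rate_c_per_h * 3600.0

    def temperature(self, time_s: float) -> float:
        return self.t_start_c + self.rate_c_per_h * time_s / 3600.0


class SyntheticScenario(BaseModel):
    """Complete ground-truth + instrument description of one condition."""

    condition_id: str
    truths: dict[str, ProbeTruth]
    membrane_like: bool = True
    g_factor: float | dict[float, float] = Field(default=1.0)
    intensity_scale: float = Field(default=1e5, gt=0)
    noise: NoiseModel = NoiseModel()
    ramp: Ramp = Ramp()
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    n_measurements: int = Field(default=130, ge=2)
    cadence: Literal["cycle", "burst"] = "cycle"
    seed: int = 0

    @field_validator("wavelengths")
    @classmethod
    def _nonempty(cls, v):
        if len(v) == 0:
            raise ValueError("wavelength set must be nonempty")
        return v

    @model_validator(mode="after")
    def _membrane_invariant(self):
        # membrane-like scenarios must have R_ip >= R_op everywhere
        if self.membrane_like:
            for probe, truth in self.truths.items():
                for t in np.linspace(self.ramp.t_start_c, self.ramp.t_end_c, 43):
                    op, ip = truth.rates_mhz(float(t))
                    if ip < op * (1 - 1e-9):
                        raise ValueError(
                            f"membrane-like scenario requires R_ip >= R_op; "
                            f"violated for {probe} at {t:.1f} degC"
                        )
        return self

    def g_at(self, excitation_nm: float) -> float:
        if isinstance(self.g_factor, dict):
            return self.g_factor[float(excitation_nm)]
        return self.g_factor

    def run_seed(self, probe_id: str, replicate_id: str) -> list[int]:
        return [
            self.seed,
            zlib.crc32(self.condition_id.encode()),
            zlib.crc32(probe_id.encode()),
            zlib.crc32(replicate_id.encode()),
        ]


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def anisotropy_from_truth(
    r_op_mhz: float, r_ip_mhz: float, r_o: float, tau_f_ns: float
) -> float:
    """Invert the linear decomposition: ground-truth rates -> anisotropy.

    Computes X from r_o, Y = R_ip X + R_op (in ns^-1) and then
    r = r_o / (1 + 2 tau_F (5 r_o + 1) Y / (5 r_o)).
    """
    if 5.0 * r_o + 1.0 <= 0.0:
        raise ScenarioError(f"r_o = {r_o} is at/beyond the X pole (-0.2)")
    if r_o == 0:
        raise ScenarioError("r_o = 0 gives no depolarization signal")
    x = (10.0 * r_o - 1.0) / (5.0 * r_o + 1.0)
    y_ns = (r_ip_mhz * x + r_op_mhz) / 1000.0
    denom = 1.0 + 2.0 * tau_f_ns * (5.0 * r_o + 1.0) * y_ns / (5.0 * r_o)
    r = r_o / denom
    if not (r * r_o > 0 and abs(r) <= abs(r_o)):
        raise ScenarioError(
            f"parameters imply r = {r:.4g} outside (0, r_o]; "
            f"(r_o={r_o}, tau={tau_f_ns}, R_op={r_op_mhz}, R_ip={r_ip_mhz})"
        )
    return r


def channels_from_anisotropy(
    r: float, intensity_scale: float = 1e5, g_factor: float = 1.0
) -> tuple[float, float, float, float]:
    """Noiseless polarized channels reproducing anisotropy r exactly.

    Emits i_vv/i_vh = g (1 + 2r)/(1 - r) and i_hv/i_hh = g, so that the
    anisotropy computation returns r to machine precision.
    """
    if not -0.2 < r < 0.4:
        raise ScenarioError(f"r must lie in (-0.2, 0.4), got {r!r}")
    if not g_factor > 0:
        raise ScenarioError(f"g_factor must be > 0, got {g_factor!r}")
    s = intensity_scale
    i_vh = s
    i_vv = s * g_factor * (1.0 + 2.0 * r) / (1.0 - r)
    i_hh = s
    i_hv = s * g_factor
    return i_vv, i_vh, i_hv, i_hh


def _apply_noise(
    channels: tuple[float, float, float, float],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    ch = np.asarray(channels, dtype=float)
    if noise.kind == "none" or (
        noise.kind == "gaussian" and noise.sigma_rel == 0
    ):
        return tuple(ch)
    if noise.kind == "gaussian":
        ch = ch * (1.0 + noise.sigma_rel * rng.standard_normal(4))
        ch = np.maximum(ch, 1e-12)
    elif noise.kind == "poisson":
        ch = np.maximum(rng.poisson(ch).astype(float), 1.0)
    return tuple(ch)


def simulate_run(
    scenario: SyntheticScenario,
    probe_id: str,
    replicate_id: str = "r1",
    photophysics: ProbePhotophysics | None = None,
) -> list[PolarizedReading]:
    """Simulate one heating-curve run of one probe in one condition.

    Readings are time-ordered along the ramp with wavelengths cycling
    (``cadence="cycle"``: one wavelength per time point) or measured in
    bursts (``cadence="burst"``: the full wavelength set at a single
    temperature per time point). The run is fully determined by the
    scenario seed plus (condition, probe, replicate) labels.
    """
    if probe_id not in scenario.truths:
        raise ScenarioError(f"no ground truth for probe {probe_id!r}")
    photophysics = photophysics or default_photophysics()
    truth = scenario.truths[probe_id]
    rng = np.random.default_rng(scenario.run_seed(probe_id, replicate_id))
    ramp, noise = scenario.ramp, scenario.noise
    wavelengths = scenario.wavelengths

    schedule: list[tuple[float, float]] = []  # (time_s, excitation_nm)
    if scenario.cadence == "cycle":
        times = np.linspace(0.0, ramp.duration_s, scenario.n_measurements)
        for i, t in enumerate(times):
            schedule.append((float(t), wavelengths[i % len(wavelengths)]))
    else:
        n_bursts = max(scenario.n_measurements // len(wavelengths), 1)
        times = np.linspace(0.0, ramp.duration_s, n_bursts)
        for t in times:
            for wl in wavelengths:
                schedule.append((float(t), wl))

    readings: list[PolarizedReading] = []
    jitter_by_time: dict[float, float] = {}
    for time_s, wl in schedule:
        if time_s not in jitter_by_time:
            jitter_by_time[time_s] = (
                noise.temp_jitter_sd_c * rng.standard_normal()
                if noise.temp_jitter_sd_c > 0
                else 0.0
            )
        temp_c = ramp.temperature(time_s) + jitter_by_time[time_s]
        ph = photophysics.get(probe_id, wl, temp_c)
        r_op, r_ip = truth.rates_mhz(temp_c)
        r = anisotropy_from_truth(r_op, r_ip, ph.r_o, ph.tau_f_ns)
        channels = channels_from_anisotropy(
            r, scenario.intensity_scale, scenario.g_at(wl)
        )
        i_vv, i_vh, i_hv, i_hh = _apply_noise(channels, noise, rng)
        readings.append(
            PolarizedReading(
                i_vv=i_vv,
                i_vh=i_vh,
                i_hv=i_hv,
                i_hh=i_hh,
                excitation_nm=wl,
                temperature_c=temp_c,
                time_s=time_s,
                probe_id=probe_id,
                condition_id=scenario.condition_id,
                replicate_id=replicate_id,
            )
        )
    return readings


def make_study(
    scenarios: Sequence[SyntheticScenario],
    out_dir,
    n_replicates: int = 3,
    photophysics: ProbePhotophysics | None = None,
) -> dict:
    """Simulate a full study and write one CSV per run plus a manifest.

    The manifest (JSON) records every run file, its seed derivation, and
    the scenarios' ground-truth parameters, sufficient to reproduce the
    study byte for byte.
    """
    if len(scenarios) == 0:
        raise ScenarioError("need at least one scenario")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    photophysics = photophysics or default_photophysics()
    runs = []
    for scenario in scenarios:
        for probe_id in scenario.truths:
            for rep in range(1, n_replicates + 1):
                replicate_id = f"r{rep}"
                readings = simulate_run(
                    scenario, probe_id, replicate_id, photophysics
                )
                fname = (
                    f"{scenario.condition_id}_{probe_id}_{replicate_id}.csv"
                )
                write_readings(readings, out_dir / fname)
                runs.append(
                    {
                        "file": fname,
                        "condition_id": scenario.condition_id,
                        "probe_id": probe_id,
                        "replicate_id": replicate_id,
                        "seed": scenario.run_seed(probe_id, replicate_id),
                        "n_readings": len(readings),
                    }
                )
    manifest = {
        "runs": runs,
        "n_replicates": n_replicates,
        "scenarios": [s.model_dump() for s in scenarios],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Stock scenarios
# ---------------------------------------------------------------------------

#: Synthetic rates at 37 degC (MHz): U-shaped depth profile with maxima at
#: the interface (n=2) and bilayer center (n=16), minimum around n=7-9.
_SENSITIVE_OP = {"2-AS": 30.0, "7-AS": 12.0, "9-AS": 10.0, "12-AS": 14.0, "16-AP": 40.0}
_SENSITIVE_IP = {"2-AS": 37.5, "7-AS": 15.0, "9-AS": 12.5, "12-AS": 17.5, "16-AP": 50.0}
#: Resistant-like condition: flatter out-of-plane depth gradient, in-plane
#: rates close to the sensitive condition except near the bilayer center.
_RESISTANT_OP = {"2-AS": 28.0, "7-AS": 14.0, "9-AS": 12.0, "12-AS": 15.0, "16-AP": 24.0}
_RESISTANT_IP = {"2-AS": 36.0, "7-AS": 16.0, "9-AS": 14.0, "12-AS": 18.0, "16-AP": 27.0}


def _truths(op: dict, ip: dict, e_over_k: float = 3600.0):
    return {
        probe: ProbeTruth(
            op=ArrheniusLaw(rate37_mhz=op[probe], e_over_k=e_over_k),
            ip=ArrheniusLaw(rate37_mhz=ip[probe], e_over_k=e_over_k),
        )
        for probe in op
    }


def sensitive_like_scenario(seed: int = 0, **kwargs) -> SyntheticScenario:
    """Steep depth-gradient condition (drug-sensitive-like membrane)."""
    return SyntheticScenario(
        condition_id=kwargs.pop("condition_id", "sensitive"),
        truths=_truths(_SENSITIVE_OP, _SENSITIVE_IP),
        seed=seed,
        **kwargs,
    )


def resistant_like_scenario(seed: int = 0, **kwargs) -> SyntheticScenario:
    """Flattened depth-gradient condition (resistant-like membrane)."""
    return SyntheticScenario(
        condition_id=kwargs.pop("condition_id", "resistant"),
        truths=_truths(_RESISTANT_OP, _RESISTANT_IP),
        seed=seed,
        **kwargs,
    )


def modulator_pair_scenarios(
    seed: int = 0, probe_id: str = "2-AS", **kwargs
) -> tuple[SyntheticScenario, SyntheticScenario]:
    """Control vs fluidity-modulator pair for one probe.

    The modulated condition multiplies both rate laws by a saturating
    fold profile rising from 1.2x at low temperature to 2.4x above
    ~40 degC.
    """
    base_op = ArrheniusLaw(rate37_mhz=_RESISTANT_OP[probe_id])
    base_ip = ArrheniusLaw(rate37_mhz=_RESISTANT_IP[probe_id])
    fold = TanhFold(low=1.2, high=2.4, midpoint_c=27.0, width_c=8.0)
    control = SyntheticScenario(
        condition_id="control",
        truths={probe_id: ProbeTruth(op=base_op, ip=base_ip)},
        seed=seed,
        **kwargs,
    )
    modulated = SyntheticScenario(
        condition_id="modulated",
        truths={
            probe_id: ProbeTruth(
                op=ScaledLaw(base=base_op, fold=fold),
                ip=ScaledLaw(base=base_ip, fold=fold),
            )
        },
        seed=seed + 1,
        **kwargs,
    )
    return control, modulated


def load_scenario(path) -> SyntheticScenario:
    """Parse and validate a scenario JSON file."""
    with open(path) as fh:
        data = json.load(fh)
    return SyntheticScenario.model_validate(data)
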