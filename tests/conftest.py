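import pytest

from anisopy import (
    HeatingCurve,
    batch_anisotropy,
    default_photophysics,
    sensitive_like_scenario,
    simulate_run,
)


@pytest.fixture(scope="session")
def photophysics():
    return default_photophysics()


@pytest.fixture(scope="session")
def noiseless_kwargs():
    return {"noise": {"kind": "none", "temp_jitter_sd_c": 0.0}}


@pytest.fixture(scope="session")
def default_run(photophysics):
    """One default-noise simulated heating run of 2-AS."""
    scenario = sensitive_like_scenario(seed=11)
    return simulate_run(scenario, "2-AS", "r1", photophysics)


@pytest.fixture()
def triplicate_curves(photophysics):
    """Factory: three replicate heating curves for one probe."""

    def make(scenario, probe_id="2-AS"):
        curves = []
        for rep in ("r1", "r2", "r3"):
            points, _ = batch_anisotropy(
                simulate_run(scenario, probe_id, rep, photophysics)
            )
            curves.append(
                HeatingCurve(sorted(points, key=lambda p: p.time_s))
            )
        return curves

    return make
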