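import math

import numpy as np
import pandas as pd
import pytest

from anisopy import (
    AnisotropyPoint,
    ArrheniusLaw,
    GradientSurface,
    GridMismatchError,
    HeatingCurve,
    InsufficientDataError,
    ValidationError,
    batch_anisotropy,
    bin_heating_curve,
    build_gradient,
    compare_gradients,
    modulator_pair_scenarios,
    sensitive_like_scenario,
    simulate_run,
    smooth_profiles,
    windowed_decompositions,
)
from anisopy.thermal import GRID_TEMPERATURES

PROBE_BY_POSITION = {2: "2-AS", 7: "7-AS", 9: "9-AS", 12: "12-AS", 16: "16-AP"}


def point(t, wl=319.0, r=0.1, time_s=None, probe="2-AS", cond="c", rep="r1"):
    return AnisotropyPoint(
        r=r,
        excitation_nm=wl,
        temperature_c=t,
        time_s=t if time_s is None else time_s,
        probe_id=probe,
        condition_id=cond,
        replicate_id=rep,
    )


class TestHeatingCurve:
    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            HeatingCurve([])

    def test_unordered_time_rejected(self):
        pts = [point(10, time_s=5), point(11, wl=333.0, time_s=1)]
        with pytest.raises(ValidationError, match="time-ordered"):
            HeatingCurve(pts)

    def test_temperature_drop_beyond_jitter_rejected(self):
        pts = [
            point(20, time_s=0),
            point(19.0, wl=333.0, time_s=1),  # 1 degC drop > 0.5 tolerance
        ]
        with pytest.raises(ValidationError, match="decreases"):
            HeatingCurve(pts)

    def test_jitter_sized_drop_tolerated(self):
        pts = [point(20, time_s=0), point(19.9, wl=333.0, time_s=1)]
        assert HeatingCurve(pts).probe_id == "2-AS"

    def test_single_wavelength_rejected(self):
        pts = [point(10 + k, time_s=k) for k in range(5)]
        with pytest.raises(ValidationError, match="wavelength"):
            HeatingCurve(pts)


class TestBinHeatingCurve:
    def test_default_run_points_per_10c_interval(self, photophysics):
        # protocol shape: 23-43 anisotropy points per 10 degC interval
        scenario = sensitive_like_scenario(seed=3)
        points, _ = batch_anisotropy(
            simulate_run(scenario, "2-AS", "r1", photophysics)
        )
        curve = HeatingCurve(sorted(points, key=lambda p: p.time_s))
        for window in bin_heating_curve(curve, window_c=10.0):
            if window.center_c < 48.0:  # last partial interval excluded
                assert 23 <= len(window.points) <= 43

    def test_single_temperature_single_window(self):
        curve = HeatingCurve(
            [point(20.0, wl=wl, time_s=k) for k, wl in enumerate((319.0, 333.0))]
        )
        windows = bin_heating_curve(curve, window_c=2.0)
        assert len(windows) == 1
        assert windows[0].center_c == pytest.approx(20.0)

    def test_window_membership_matches_brute_force(self):
        rng = np.random.default_rng(0)
        temps = np.sort(rng.uniform(10, 52, size=200))
        pts = [
            point(float(t), wl=(319.0, 333.0)[k % 2], time_s=k)
            for k, t in enumerate(temps)
        ]
        curve = HeatingCurve(pts)
        windows = bin_heating_curve(curve, window_c=3.0)
        # oracle: direct partition by temperature
        expected = {}
        for p in pts:
            expected.setdefault(int(math.floor((p.temperature_c - 10.0) / 3.0)), []).append(p)
        assert {w.index: w.points for w in windows} == expected

    def test_window_centers_are_member_means(self):
        curve = HeatingCurve(
            [point(t, wl=(319.0, 333.0)[k % 2], time_s=k) for k, t in enumerate((10.2, 10.8, 11.4))]
        )
        (window,) = bin_heating_curve(curve, window_c=2.0)
        assert window.center_c == pytest.approx(np.mean([10.2, 10.8, 11.4]))

    def test_window_with_single_wavelength_flagged(self):
        pts = [point(10.5, time_s=0), point(13.5, wl=333.0, time_s=1)]
        windows = bin_heating_curve(HeatingCurve(pts), window_c=2.0)
        assert all(w.flagged for w in windows)

    def test_bad_window_width(self):
        curve = HeatingCurve([point(10, time_s=0), point(11, wl=333.0, time_s=1)])
        with pytest.raises(ValidationError):
            bin_heating_curve(curve, window_c=0.0)


class TestWindowedDecompositions:
    def test_mixed_groups_rejected(self, photophysics, triplicate_curves):
        scenario = sensitive_like_scenario(seed=1)
        a = triplicate_curves(scenario, "2-AS")[0]
        b = triplicate_curves(scenario, "9-AS")[0]
        with pytest.raises(ValidationError, match="mix"):
            windowed_decompositions([a, b], photophysics)

    def test_no_curves(self, photophysics):
        with pytest.raises(InsufficientDataError):
            windowed_decompositions([], photophysics)

    def test_pooling_three_replicates(self, photophysics, triplicate_curves):
        scenario = sensitive_like_scenario(seed=1)
        curves = triplicate_curves(scenario)
        pooled = windowed_decompositions(curves, photophysics)
        single = windowed_decompositions(curves[:1], photophysics)
        # pooling three replicates tightens the typical confidence interval
        assert np.median([d.ci95_op for d in pooled]) < np.median(
            [d.ci95_op for d in single]
        )

    def test_extrapolation_flag_above_anchor_range(
        self, photophysics, triplicate_curves
    ):
        scenario = sensitive_like_scenario(seed=1)
        decomps = windowed_decompositions(
            triplicate_curves(scenario), photophysics
        )
        hot = [d for d in decomps if d.temperature_c > 48.0]
        cold = [d for d in decomps if 25.0 < d.temperature_c < 45.0]
        assert hot and all(d.extrapolation_flag for d in hot)
        assert cold and not any(d.extrapolation_flag for d in cold)


def arrhenius_decomps(rate37_op, rate37_ip, e_over_k=3600.0, n=21, ci=0.1):
    """Noise-free windowed 'decompositions' on exact Arrhenius curves."""
    from anisopy.decomposition import Decomposition

    op = ArrheniusLaw(rate37_mhz=rate37_op, e_over_k=e_over_k)
    ip = ArrheniusLaw(rate37_mhz=rate37_ip, e_over_k=e_over_k)
    out = []
    for t in np.linspace(10.5, 51.5, n):
        out.append(
            Decomposition(
                r_op_mhz=op.rate_mhz(float(t)),
                r_ip_mhz=ip.rate_mhz(float(t)),
                ci95_op=ci,
                ci95_ip=ci,
                n_points=5,
                r_squared=1.0,
                residuals=np.array([]),
                temperature_c=float(t),
                probe_id="2-AS",
            )
        )
    return out


class TestSmoothProfiles:
    def test_noiseless_monotone_profile_within_1pct(self):
        decomps = arrhenius_decomps(30.0, 37.5)
        profiles = smooth_profiles(decomps)
        op = ArrheniusLaw(rate37_mhz=30.0, e_over_k=3600.0)
        for t in GRID_TEMPERATURES:
            est, _ = profiles.op(t)
            assert est == pytest.approx(op.rate_mhz(t), rel=0.01)

    def test_constant_profile_reproduced(self):
        decomps = arrhenius_decomps(25.0, 25.0, e_over_k=0.0)
        profiles = smooth_profiles(decomps)
        for t in GRID_TEMPERATURES:
            est, _ = profiles.ip(t)
            assert est == pytest.approx(25.0, rel=1e-9)

    def test_pooled_beats_single_replicate(
        self, photophysics, triplicate_curves
    ):
        scenario = sensitive_like_scenario(seed=1)
        curves = triplicate_curves(scenario)
        truth = scenario.truths["2-AS"].op

        def rmse(profile):
            errs = [
                profile(t)[0] - truth.rate_mhz(t) for t in GRID_TEMPERATURES
            ]
            return float(np.sqrt(np.mean(np.square(errs))))

        pooled = smooth_profiles(windowed_decompositions(curves, photophysics))
        singles = [
            smooth_profiles(windowed_decompositions([c], photophysics))
            for c in curves
        ]
        assert rmse(pooled.op) < min(rmse(s.op) for s in singles)

    def test_too_few_windows(self):
        with pytest.raises(InsufficientDataError):
            smooth_profiles(arrhenius_decomps(30.0, 37.5, n=2))

    def test_span_too_short(self):
        from anisopy.decomposition import Decomposition

        decomps = [
            Decomposition(
                r_op_mhz=30.0,
                r_ip_mhz=35.0,
                ci95_op=0.1,
                ci95_ip=0.1,
                n_points=5,
                r_squared=1.0,
                residuals=np.array([]),
                temperature_c=t,
            )
            for t in (20.0, 25.0, 30.0)
        ]
        with pytest.raises(InsufficientDataError, match="span"):
            smooth_profiles(decomps)

    def test_evaluation_outside_span_rejected(self):
        profiles = smooth_profiles(arrhenius_decomps(30.0, 37.5))
        with pytest.raises(ValidationError, match="span"):
            profiles.op(60.0)

    def test_monotone_for_arrhenius_truth(self):
        profiles = smooth_profiles(arrhenius_decomps(30.0, 37.5))
        values = [profiles.op(t)[0] for t in GRID_TEMPERATURES]
        assert all(b > a for a, b in zip(values, values[1:]))


def study_profiles(scenario, photophysics, triplicate_curves):
    profiles = []
    for probe in scenario.truths:
        curves = triplicate_curves(scenario, probe)
        profiles.append(
            smooth_profiles(windowed_decompositions(curves, photophysics))
        )
    return profiles


@pytest.fixture(scope="module")
def sensitive_surfaces(photophysics):
    scenario = sensitive_like_scenario(seed=7)
    profiles = []
    for probe in scenario.truths:
        curves = []
        for rep in ("r1", "r2", "r3"):
            pts, _ = batch_anisotropy(
                simulate_run(scenario, probe, rep, photophysics)
            )
            curves.append(HeatingCurve(sorted(pts, key=lambda p: p.time_s)))
        profiles.append(
            smooth_profiles(windowed_decompositions(curves, photophysics))
        )
    return scenario, {
        mode: build_gradient(profiles, mode, condition_id="sensitive")
        for mode in ("op", "ip")
    }


class TestBuildGradient:
    def test_grid_temperatures_exact(self, sensitive_surfaces):
        _, surfaces = sensitive_surfaces
        for surface in surfaces.values():
            assert surface.temperatures == [float(t) for t in range(10, 51, 5)]

    def test_u_shape_minimum_at_7_or_9(self, sensitive_surfaces):
        _, surfaces = sensitive_surfaces
        pivot = surfaces["op"].pivot()
        for t in pivot.columns:
            assert pivot[t].idxmin() in (7, 9)
            assert pivot[t].idxmax() in (2, 16)

    def test_rip_above_rop_diagnostic(self, sensitive_surfaces):
        # membrane-like ground truth preserves R_ip > R_op through the
        # pipeline: strictly in the vast majority of cells, and within
        # the combined CIs everywhere (noise can cross near-degenerate
        # low-rate cells)
        _, surfaces = sensitive_surfaces
        ip = surfaces["ip"].cells.set_index(["position_n", "temperature_c"])
        op = surfaces["op"].cells.set_index(["position_n", "temperature_c"])
        gap = ip.rate_mhz - op.rate_mhz
        slack = ip.ci95 + op.ci95
        assert (gap > 0).mean() >= 0.9
        assert (gap > -slack).all()

    def test_rates_increase_with_temperature(self, sensitive_surfaces):
        _, surfaces = sensitive_surfaces
        pivot = surfaces["op"].pivot()
        diffs = np.diff(pivot.to_numpy(), axis=1)
        assert (diffs > 0).all()

    def test_single_probe_gives_single_row(self):
        profiles = smooth_profiles(arrhenius_decomps(30.0, 37.5))
        surface = build_gradient([profiles], "op")
        assert surface.positions == [2]
        assert len(surface.cells) == len(GRID_TEMPERATURES)

    def test_declared_missing_probe_leaves_gaps_and_warns(self):
        profiles = smooth_profiles(arrhenius_decomps(30.0, 37.5))
        with pytest.warns(UserWarning, match="gaps"):
            surface = build_gradient(
                [profiles], "op", positions={"2-AS": 2, "9-AS": 9}
            )
        assert surface.positions == [2, 9]
        gap = surface.cells[surface.cells.position_n == 9]
        assert gap.rate_mhz.isna().all() and gap.flag.all()

    def test_unknown_probe_rejected(self):
        profiles = smooth_profiles(arrhenius_decomps(30.0, 37.5))
        profiles.probe_id = "mystery"
        with pytest.raises(ValidationError, match="mystery"):
            build_gradient([profiles], "op")

    def test_csv_round_trip(self, sensitive_surfaces, tmp_path):
        _, surfaces = sensitive_surfaces
        path = tmp_path / "surface.csv"
        surfaces["op"].to_csv(path)
        back = GradientSurface.from_csv(path)
        assert back.mode == "op" and back.condition_id == "sensitive"
        pd.testing.assert_frame_equal(
            back.cells, surfaces["op"].cells, atol=1e-9
        )


class TestCompareGradients:
    def make_surface(self, values, mode="op", condition="a", ci=0.5):
        rows = [
            {
                "position_n": n,
                "temperature_c": t,
                "rate_mhz": v,
                "ci95": ci,
                "flag": False,
            }
            for (n, t), v in values.items()
        ]
        return GradientSurface(
            mode=mode, condition_id=condition, cells=pd.DataFrame(rows)
        )

    def test_identity_comparison(self):
        values = {(n, t): 20.0 + n + t for n in (2, 9) for t in (10.0, 20.0)}
        a = self.make_surface(values, condition="a")
        b = self.make_surface(values, condition="b")
        comparison = compare_gradients(a, b)
        assert np.allclose(comparison.cells.fold, 1.0)

    def test_empty_cell_absent_from_ratio(self):
        values = {(2, 10.0): 20.0, (2, 15.0): 25.0}
        a = self.make_surface(values)
        b_values = dict(values)
        b_values[(2, 15.0)] = math.nan
        b = self.make_surface(b_values, condition="b")
        comparison = compare_gradients(a, b)
        assert len(comparison.cells) == 1
        assert comparison.cells.temperature_c.tolist() == [10.0]

    def test_mode_mismatch(self):
        a = self.make_surface({(2, 10.0): 20.0}, mode="op")
        b = self.make_surface({(2, 10.0): 20.0}, mode="ip")
        with pytest.raises(GridMismatchError):
            compare_gradients(a, b)

    def test_grid_mismatch(self):
        a = self.make_surface({(2, 10.0): 20.0, (2, 15.0): 22.0})
        b = self.make_surface({(2, 10.0): 20.0})
        with pytest.raises(GridMismatchError):
            compare_gradients(a, b)

    def test_exceeding_threshold_summary(self):
        a = self.make_surface({(2, 10.0): 40.0, (2, 15.0): 21.0})
        b = self.make_surface({(2, 10.0): 20.0, (2, 15.0): 20.0}, condition="b")
        comparison = compare_gradients(a, b)
        assert len(comparison.exceeding) == 1
        assert comparison.exceeding.iloc[0].temperature_c == 10.0

    def test_modulator_fold_recovered_within_ci(
        self, photophysics, triplicate_curves
    ):
        control, modulated = modulator_pair_scenarios(seed=4)
        surfaces = {}
        for scenario in (control, modulated):
            profile = smooth_profiles(
                windowed_decompositions(
                    triplicate_curves(scenario), photophysics
                )
            )
            surfaces[scenario.condition_id] = {
                mode: build_gradient(
                    [profile], mode, condition_id=scenario.condition_id
                )
                for mode in ("op", "ip")
            }
        for mode in ("op", "ip"):
            comparison = compare_gradients(
                surfaces["modulated"][mode], surfaces["control"][mode]
            )
            truth_op = modulated.truths["2-AS"]
            base_op = control.truths["2-AS"]
            for row in comparison.cells.itertuples():
                truth_fold = getattr(truth_op, mode).rate_mhz(
                    row.temperature_c
                ) / getattr(base_op, mode).rate_mhz(row.temperature_c)
                assert abs(row.fold - truth_fold) <= row.ci95
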