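"""Tube-axis and helix fitting from 3D filament point traces."""

import math

import numpy as np
import pytest

from tubecoat import (
    FilamentTrace,
    FittingError,
    HelixParams,
    InsufficientExtentError,
    TubeModel,
    ValidationError,
    dataset_from_traces,
    fit_tube_axis,
    helix_from_trace,
    read_traces_csv,
    read_xyz,
    simulate_helix_trace,
    write_traces_csv,
)

Z_TUBE = TubeModel(axis_point=np.zeros(3), axis_direction=np.array([0.0, 0.0, 1.0]), radius_r=20.0)


def rigid_transform(points, seed=0):
    """A reproducible random rotation + translation."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    return points @ q.T + t, q, t


class TestFitTubeAxis:
    def test_noiseless_cylinder_recovered(self):
        trace = simulate_helix_trace(HelixParams(20.0, 8.0), n_points=120)
        tube = fit_tube_axis(trace)
        assert tube.radius_r == pytest.approx(20.0, abs=1e-6)
        assert abs(tube.axis_direction @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-6)
        assert tube.rms_residual < 1e-6

    def test_noisy_cylinder_radius_within_2_percent(self):
        trace = simulate_helix_trace(
            HelixParams(20.0, 8.0), n_points=200, noise_sd=0.5, seed=99
        )
        tube = fit_tube_axis(trace)
        assert tube.radius_r == pytest.approx(20.0, rel=0.02)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 10, 20)])
        with pytest.raises(FittingError):
            fit_tube_axis(FilamentTrace(points=pts))

    def test_too_few_points_rejected(self):
        trace = simulate_helix_trace(HelixParams(20.0, 8.0), n_points=6)
        with pytest.raises(FittingError):
            fit_tube_axis(FilamentTrace(points=trace.points[:8]))

    def test_rotated_cylinder_recovered(self):
        trace = simulate_helix_trace(HelixParams(15.0, 10.0), n_points=100)
        moved, _, _ = rigid_transform(trace.points, seed=4)
        tube = fit_tube_axis(FilamentTrace(points=moved))
        assert tube.radius_r == pytest.approx(15.0, abs=1e-6)


class TestHelixFromTrace:
    def test_noiseless_round_trip(self):
        trace = simulate_helix_trace(HelixParams(20.0, 10.0), n_points=60)
        fit = helix_from_trace(trace, Z_TUBE)
        assert fit.helix_angle_deg == pytest.approx(math.degrees(math.atan(0.5)), abs=1e-9)
        assert fit.params.reduced_pitch_h == pytest.approx(10.0, abs=1e-9)
        assert fit.handedness == "right"

    def test_left_handed_helix(self):
        trace = simulate_helix_trace(HelixParams(20.0, -10.0), n_points=60)
        fit = helix_from_trace(trace, Z_TUBE)
        assert fit.handedness == "left"
        assert fit.helix_angle_deg == pytest.approx(math.degrees(math.atan(0.5)), abs=1e-9)

    def test_ring_reports_undefined_handedness(self):
        trace = simulate_helix_trace(HelixParams(20.0, 0.0), n_points=40)
        fit = helix_from_trace(trace, Z_TUBE)
        assert fit.helix_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert fit.handedness == "ring"

    def test_noisy_recovery(self):
        r, theta = 15.0, 60.0
        h = r * math.tan(math.radians(theta))
        trace = simulate_helix_trace(
            HelixParams(r, h), n_points=50, noise_sd=0.5, seed=7
        )
        tube = fit_tube_axis(trace)
        fit = helix_from_trace(trace, tube)
        assert fit.helix_angle_deg == pytest.approx(theta, abs=1.0)
        assert fit.params.radius_r == pytest.approx(r, rel=0.02)

    def test_rigid_invariance(self):
        """theta and r are unchanged when points and tube move rigidly together."""
        trace = simulate_helix_trace(HelixParams(18.0, 12.0), n_points=80)
        fit0 = helix_from_trace(trace, fit_tube_axis(trace))
        moved, _, _ = rigid_transform(trace.points, seed=11)
        trace2 = FilamentTrace(points=moved)
        fit1 = helix_from_trace(trace2, fit_tube_axis(trace2))
        assert fit1.helix_angle_deg == pytest.approx(fit0.helix_angle_deg, abs=1e-8)
        assert fit1.params.radius_r == pytest.approx(fit0.params.radius_r, abs=1e-8)
        assert fit1.handedness == fit0.handedness

    def test_point_order_reversal_invariance(self):
        trace = simulate_helix_trace(HelixParams(18.0, 12.0), n_points=80)
        fit0 = helix_from_trace(trace, Z_TUBE_18 := TubeModel(
            axis_point=np.zeros(3), axis_direction=np.array([0.0, 0.0, 1.0]), radius_r=18.0))
        rev = FilamentTrace(points=trace.points[::-1])
        fit1 = helix_from_trace(rev, Z_TUBE_18)
        assert fit1.helix_angle_deg == pytest.approx(fit0.helix_angle_deg, abs=1e-9)
        assert fit1.handedness == fit0.handedness

    def test_axis_flip_does_not_change_handedness(self):
        trace = simulate_helix_trace(HelixParams(20.0, 10.0), n_points=60)
        flipped = TubeModel(axis_point=np.zeros(3),
                            axis_direction=np.array([0.0, 0.0, -1.0]), radius_r=20.0)
        assert helix_from_trace(trace, flipped).handedness == "right"

    def test_insufficient_azimuthal_extent(self):
        # ~20 degrees of azimuth only
        r = 20.0
        phi = np.linspace(0, math.radians(20), 12)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), 3 * phi])
        with pytest.raises(InsufficientExtentError):
            helix_from_trace(FilamentTrace(points=pts), Z_TUBE)

    def test_filament_radius_source(self):
        # filament points at rho = 22 around a tube fitted at r = 20
        trace = simulate_helix_trace(HelixParams(22.0, 11.0), n_points=60)
        fit_tube = helix_from_trace(trace, Z_TUBE, radius_source="tube")
        fit_fil = helix_from_trace(trace, Z_TUBE, radius_source="filament")
        assert fit_tube.params.radius_r == pytest.approx(20.0)
        assert fit_fil.params.radius_r == pytest.approx(22.0, abs=1e-9)
        assert fit_fil.filament_radius_nm == pytest.approx(22.0, abs=1e-9)


class TestDatasetFromTraces:
    def _make_traces(self, radii_angles, n_points=60, noise=0.0, seed=None):
        traces = []
        for i, (r, theta) in enumerate(radii_angles):
            h = r * math.tan(math.radians(theta))
            for f in range(2):
                tr = simulate_helix_trace(
                    HelixParams(r, h), n_points=n_points, noise_sd=noise,
                    seed=None if seed is None else seed + 10 * i + f,
                    tube_id=f"tube_{i}", filament_id=f"fil_{f}",
                    phase0=f * math.pi,
                )
                traces.append(tr)
        return traces

    def test_noiseless_records_match_truth(self):
        conditions = [(20.0, 50.0), (35.0, 35.0), (55.0, 15.0)]
        ds, report = dataset_from_traces(self._make_traces(conditions))
        assert len(ds) == 6
        assert report.n_used == 6 and not report.skipped
        for (r, theta) in conditions:
            sel = np.isclose(ds.radii, r, rtol=1e-6)
            assert sel.sum() == 2
            np.testing.assert_allclose(ds.angles[sel], theta, atol=1e-6)

    def test_short_trace_skipped_and_reported(self):
        traces = self._make_traces([(20.0, 50.0), (35.0, 35.0), (55.0, 15.0)])
        # truncate one filament below the 6-point minimum
        traces[3] = FilamentTrace(points=traces[3].points[:5],
                                  tube_id=traces[3].tube_id,
                                  filament_id=traces[3].filament_id)
        ds, report = dataset_from_traces(traces)
        assert len(ds) == 5
        assert report.n_used == 5
        assert len(report.skipped) == 1
        assert report.skipped[0][0] == "tube_1"

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            dataset_from_traces([])


class TestFullPipelineRoundTrip:
    def test_traces_to_spontaneous_curvature(self):
        """Generator -> trace measurement -> elastic fit recovers the
        generating spontaneous curvature within 10% (50 tubes, 0.5 nm
        positional noise)."""
        from tubecoat import SimulationConfig, curvature_only_params, fit_spontaneous
        from tubecoat.simulate import simulate_tube_traces

        kappa0_true = 1.0 / 68.0
        cfg = SimulationConfig(seed=99, n_tubes=50, kappa0_true=kappa0_true,
                               trace_point_noise_sd=0.5)
        ds, report = dataset_from_traces(simulate_tube_traces(cfg))
        assert report.n_used >= 45  # a rare degenerate trace may be skipped
        fit = fit_spontaneous(ds, curvature_only_params(0.02))
        assert abs(fit.params.kappa0 - kappa0_true) / kappa0_true < 0.10

    def test_coats_to_spontaneous_curvature(self):
        """Multi-filament coats simulated on tubes across 15-70 nm from a
        kappa0 = 0.02 1/nm model feed the full pipeline back to that value."""
        from tubecoat import (
            LatticeSpec,
            analytic_angle,
            curvature_only_params,
            fit_spontaneous,
            simulate_coat_point_cloud,
        )

        kappa0_true = 0.02
        traces = []
        for i, r in enumerate(np.arange(15.0, 71.0, 5.0)):
            theta = float(analytic_angle(r, kappa0_true))
            spec = LatticeSpec(radius_r=float(r), helix_angle_theta=theta,
                               subunit_spacing=7.0, n_subunits=40, n_filaments=2)
            traces.extend(
                simulate_coat_point_cloud(spec, noise_sd=0.3, seed=i, tube_id=f"tube_{i}")
            )
        ds, report = dataset_from_traces(traces)
        assert report.n_used >= 20
        fit = fit_spontaneous(ds, curvature_only_params(0.05))
        assert abs(fit.params.kappa0 - kappa0_true) / kappa0_true < 0.10


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path):
        traces = [
            simulate_helix_trace(HelixParams(20.0, 10.0), n_points=20,
                                 tube_id="t0", filament_id="f0"),
            simulate_helix_trace(HelixParams(30.0, 5.0), n_points=15,
                                 tube_id="t0", filament_id="f1"),
        ]
        path = tmp_path / "traces.csv"
        write_traces_csv(traces, path)
        back = read_traces_csv(path)
        assert len(back) == 2
        by_id = {t.filament_id: t for t in back}
        np.testing.assert_allclose(by_id["f0"].points, traces[0].points, atol=1e-9)
        np.testing.assert_allclose(by_id["f1"].points, traces[1].points, atol=1e-9)

    def test_xyz_reader(self, tmp_path):
        pts = simulate_helix_trace(HelixParams(20.0, 10.0), n_points=12).points
        path = tmp_path / "fil01.xyz"
        path.write_text("# comment\n" + "\n".join(
            f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in pts))
        tr = read_xyz(path, tube_id="t9")
        assert tr.filament_id == "fil01"
        np.testing.assert_allclose(tr.points, pts, atol=1e-6)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValidationError):
            read_traces_csv(path)
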