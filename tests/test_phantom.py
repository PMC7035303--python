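"""Vessel phantom construction, cross-section flux, and gated reconstruction."""

import numpy as np
import pytest

from flowpulse import (
    BoundaryError,
    ConfigurationError,
    FlowWaveform,
    ReconstructionError,
    ValidationError,
    WaveformParams,
    build_phantom,
    compute_metrics,
    compute_pi,
    cross_section_flow,
    curved_tube,
    extract_centerline_flow,
    gated_reconstruction,
    generate_waveform,
    straight_tube,
    waveform_function,
)
from flowpulse.phantom import VesselPhantom, draw_rr_sequence


def constant_waveform(q=5.0, n=20, rr=1.0):
    t = np.arange(n) / n * rr
    return FlowWaveform(t, np.full(n, q), rr)


@pytest.fixture(scope="module")
def straight_field():
    phantom = straight_tube(radius=2.0, voxel_size=0.5, length=5.0)
    waveform = generate_waveform(WaveformParams(mean_flow=3.0, pulse_amplitude=3.0), 20)
    return phantom, waveform, build_phantom(phantom, waveform)


class TestGenerateWaveform:
    def test_zero_amplitude_is_constant(self):
        params = WaveformParams(pulse_amplitude=0.0, noise_sd=0.0)
        wf = generate_waveform(params, 50)
        assert np.allclose(wf.flow_rates, params.mean_flow)

    def test_deterministic_given_seed(self):
        params = WaveformParams(noise_sd=0.5, seed=9)
        a = generate_waveform(params, 20)
        b = generate_waveform(params, 20)
        assert np.array_equal(a.flow_rates, b.flow_rates)

    def test_amplitude_calibrates_dense_pi(self):
        # unit peak-to-peak pulse shape: PI = amplitude / mean at dense sampling
        params = WaveformParams(mean_flow=4.0, pulse_amplitude=4.0)
        wf = generate_waveform(params, 2000)
        assert compute_pi(wf) == pytest.approx(1.0, abs=0.01)

    def test_cycle_mean_matches_mean_flow(self):
        params = WaveformParams(mean_flow=4.4, dicrotic_amplitude=1.0)
        wf = generate_waveform(params, 200)
        assert compute_metrics(wf).mean_flow == pytest.approx(4.4, rel=1e-4)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            WaveformParams(mean_flow=-1.0)
        with pytest.raises(ValidationError):
            WaveformParams(peak_width=1.5)


class TestPhantomGeometry:
    def test_unresolvable_lumen_rejected(self):
        with pytest.raises(ValidationError):
            straight_tube(radius=0.7, voxel_size=0.5)

    def test_centerline_margin_enforced(self):
        pts = np.column_stack([np.full(5, 1.0), np.full(5, 1.0), np.arange(5) * 0.5 + 2])
        with pytest.raises(ValidationError):
            VesselPhantom(pts, radius=2.0, voxel_size=0.5, grid_shape=(8, 8, 16))

    def test_centerline_spacing_enforced(self):
        pts = np.column_stack([np.full(3, 4.0), np.full(3, 4.0), [3.0, 4.5, 6.0]])
        with pytest.raises(ValidationError):
            VesselPhantom(pts, radius=1.5, voxel_size=0.5, grid_shape=(16, 16, 20))


class TestBuildPhantom:
    def test_apex_velocity_is_poiseuille_peak(self, straight_field):
        phantom, waveform, field = straight_field
        mid = phantom.centerline_points[len(phantom.centerline_points) // 2]
        idx = tuple(int(c / phantom.voxel_size) for c in mid)
        vz = field.velocities[2][idx]
        q_peak = waveform.flow_rates.max()
        expected = 2 * q_peak / (np.pi * phantom.radius**2) * 100.0  # cm/s
        assert vz.max() == pytest.approx(expected, rel=1e-9)

    def test_no_slip_outside_lumen(self, straight_field):
        phantom, _, field = straight_field
        mid = phantom.centerline_points[len(phantom.centerline_points) // 2]
        ix = int((mid[0] + phantom.radius + 0.3) / phantom.voxel_size)
        iy = int(mid[1] / phantom.voxel_size)
        iz = int(mid[2] / phantom.voxel_size)
        assert np.all(field.velocities[:, ix, iy, iz, :] == 0.0)

    def test_transverse_components_vanish_for_straight_tube(self, straight_field):
        _, _, field = straight_field
        assert np.abs(field.velocities[0]).max() == 0.0
        assert np.abs(field.velocities[1]).max() == 0.0

    def test_venc_violation_raises_unless_aliasing(self):
        phantom = straight_tube(radius=2.0, voxel_size=0.5, length=5.0)
        waveform = constant_waveform(q=10.0)  # peak 159 cm/s
        with pytest.raises(ConfigurationError):
            build_phantom(phantom, waveform, venc=110.0)
        field = build_phantom(phantom, waveform, venc=110.0, aliasing=True)
        assert np.all(field.velocities < 110.0)
        assert np.all(field.velocities >= -110.0)


class TestCrossSectionFlow:
    def test_constant_flow_recovered_within_discretization(self):
        phantom = straight_tube(radius=2.0, voxel_size=0.5, length=5.0)
        field = build_phantom(phantom, constant_waveform(q=5.0))
        tans = phantom.tangents()
        for i in (2, 5, 8):
            q = cross_section_flow(field, phantom.centerline_points[i], tans[i], 0)
            assert q == pytest.approx(5.0, rel=0.03)

    def test_zero_flow_phase_gives_zero(self, straight_field):
        phantom, waveform, _ = straight_field
        wf0 = waveform.with_flow(np.zeros_like(waveform.flow_rates))
        field0 = build_phantom(phantom, wf0)
        q = cross_section_flow(field0, phantom.centerline_points[4], phantom.tangents()[4], 3)
        assert q == 0.0

    def test_linearity_in_waveform(self, straight_field):
        phantom, waveform, field = straight_field
        doubled = build_phantom(
            phantom, waveform.with_flow(2 * waveform.flow_rates), venc=250.0
        )
        pt, tan = phantom.centerline_points[4], phantom.tangents()[4]
        for phase in (0, 7, 13):
            assert cross_section_flow(doubled, pt, tan, phase) == pytest.approx(
                2 * cross_section_flow(field, pt, tan, phase), rel=1e-12, abs=1e-15
            )

    def test_point_outside_grid_raises(self, straight_field):
        _, _, field = straight_field
        with pytest.raises(BoundaryError):
            cross_section_flow(field, [100.0, 0.0, 0.0], [0, 0, 1], 0)


class TestExtractCenterlineFlow:
    def test_six_voxel_average_matches_single_voxel_for_straight_tube(self, straight_field):
        phantom, _, field = straight_field
        wf6 = extract_centerline_flow(field, phantom, start_voxel=2)
        single = np.array(
            [
                cross_section_flow(field, phantom.centerline_points[4], phantom.tangents()[4], p)
                for p in range(field.n_phases)
            ]
        )
        assert np.allclose(wf6.flow_rates, single, rtol=0.01)

    def test_too_few_voxels_raises(self, straight_field):
        phantom, _, field = straight_field
        with pytest.raises(ValidationError):
            extract_centerline_flow(field, phantom, start_voxel=len(phantom.centerline_points) - 3)

    def test_curved_tube_agrees_with_straight(self):
        waveform = generate_waveform(WaveformParams(mean_flow=3.0, pulse_amplitude=3.0), 20)
        straight = straight_tube(radius=2.0, voxel_size=0.5, length=5.0)
        curved = curved_tube(radius=2.0, voxel_size=0.5, curvature_radius=20.0)
        f_s = build_phantom(straight, waveform)
        f_c = build_phantom(curved, waveform)
        wf_s = extract_centerline_flow(f_s, straight, start_voxel=2)
        mid = len(curved.centerline_points) // 2
        wf_c = extract_centerline_flow(f_c, curved, start_voxel=mid - 3)
        m_s, m_c = compute_metrics(wf_s), compute_metrics(wf_c)
        assert m_c.mean_flow == pytest.approx(m_s.mean_flow, rel=0.05)
        assert m_c.pi_raw == pytest.approx(m_s.pi_raw, rel=0.05)
        assert m_c.fvp_raw == pytest.approx(m_s.fvp_raw, rel=0.05)


class TestGatedReconstruction:
    def test_constant_waveform_reconstructs_constant(self):
        wf = gated_reconstruction(lambda t: np.full_like(np.asarray(t, float), 4.0), [0.9] * 10)
        assert np.allclose(wf.flow_rates, 4.0)
        assert wf.n_samples == 20

    def test_sinusoid_reconstruction_accuracy(self):
        rr = 1.0
        f = lambda t: 5.0 + 2.0 * np.sin(2 * np.pi * np.asarray(t, float) / rr)
        wf = gated_reconstruction(f, [rr] * 40, samples_per_cycle=2000, seed=5)
        err = np.abs(wf.flow_rates - f(wf.times))
        assert err.max() < 0.01 * (f(wf.times).max() - f(wf.times).min())

    def test_deterministic_given_seed(self):
        f = waveform_function(WaveformParams())
        rr = [0.9] * 10
        a = gated_reconstruction(f, rr, seed=3)
        b = gated_reconstruction(f, rr, seed=3)
        assert np.array_equal(a.flow_rates, b.flow_rates)

    def test_narrow_peak_is_blunted(self):
        params = WaveformParams(peak_width=0.05)
        dense_pi = compute_pi(generate_waveform(params, 2000))
        gated = gated_reconstruction(
            waveform_function(params), draw_rr_sequence(params, 30, seed=1), seed=2
        )
        assert compute_pi(gated) < dense_pi

    def test_sparse_sampling_raises_on_empty_bins(self):
        with pytest.raises(ReconstructionError):
            gated_reconstruction(lambda t: np.ones_like(np.asarray(t, float)),
                                 [0.9], n_phases=20, samples_per_cycle=5, seed=0)

    def test_rr_sequence_validated(self):
        with pytest.raises(ValidationError):
            gated_reconstruction(lambda t: t, [])


class TestFlowConservation:
    def test_flux_constant_along_straight_tube(self, straight_field):
        phantom, waveform, field = straight_field
        tans = phantom.tangents()
        pts = phantom.centerline_points
        for i in range(2, 8):
            for p in range(0, field.n_phases, 4):
                q = cross_section_flow(field, pts[i], tans[i], p)
                assert q == pytest.approx(waveform.flow_rates[p], rel=0.03)

    def test_refinement_shrinks_error(self):
        waveform = constant_waveform(q=5.0, n=5)
        errs = {}
        for h in (0.5, 0.25):
            phantom = straight_tube(radius=2.0, voxel_size=h, length=3.0)
            field = build_phantom(phantom, waveform)
            mid = len(phantom.centerline_points) // 2
            q = cross_section_flow(
                field, phantom.centerline_points[mid], phantom.tangents()[mid], 0
            )
            errs[h] = abs(q - 5.0) / 5.0
        assert errs[0.25] <= 0.6 * errs[0.5]
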