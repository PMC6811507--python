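"""Phantom generator: analytic truth, encoding model, noise, study design."""
import math

import numpy as np
import pytest

from cvrflow import phantom
from cvrflow.phantom import (
    AcquisitionSpec,
    Condition,
    StudySpec,
    VesselSpec,
    add_background_phase,
    add_noise,
    build_velocity_field,
    encode_phase,
    simulate_cvr_study,
    straight_tube,
    y_bifurcation,
)


class TestVesselSpec:
    def test_analytic_poiseuille_flux(self):
        vs = VesselSpec("MCA_L", [[0, 0, 0], [0, 0, 1]], radius=0.15,
                        mean_velocity=30.0)
        assert vs.csa == pytest.approx(0.0707, abs=5e-4)
        assert vs.flow == pytest.approx(127.2, abs=0.1)  # vbar * pi R^2 * 60

    @pytest.mark.parametrize(
        "kw",
        [
            dict(radius=0.0),
            dict(radius=-1.0),
            dict(centerline=[[0, 0, 0]]),
            dict(centerline=[[0, 0, 0], [0, 0, 0]]),
            dict(mean_velocity=-5.0),
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        base = dict(label="BA", centerline=[[0, 0, 0], [0, 0, 1]],
                    radius=0.1, mean_velocity=20.0)
        base.update(kw)
        with pytest.raises(ValueError):
            VesselSpec(**base)


class TestBuildVelocityField:
    def test_zero_mean_velocity_gives_zero_field(self):
        vs, acq = straight_tube(vbar=0.0)
        vol = build_velocity_field([vs], acq)
        assert np.all(vol.velocity == 0.0)

    def test_peak_velocity_is_twice_mean(self):
        vs, acq = straight_tube(radius=0.15, vbar=30.0, direction=(0, 0, 1))
        vol = build_velocity_field([vs], acq)
        # box-averaging over voxels depresses the apex by ~(vbar/3)(h/R)^2
        assert vol.speed().max() == pytest.approx(60.0, rel=0.05)

    def test_vessel_leaving_grid_rejected(self):
        vs = VesselSpec("BA", [[0.5, 0.5, -1.0], [0.5, 0.5, 3.0]],
                        radius=0.1, mean_velocity=20.0)
        acq = AcquisitionSpec(grid_shape=(32, 32, 32))
        with pytest.raises(ValueError, match="exits the grid"):
            build_velocity_field([vs], acq)

    def test_overlapping_unrelated_vessels_rejected(self):
        acq = AcquisitionSpec(grid_shape=(32, 32, 32))
        a = VesselSpec("ICA_L", [[0.5, 0.5, 0.3], [0.5, 0.5, 0.8]], 0.1, 20.0)
        b = VesselSpec("ICA_R", [[0.52, 0.5, 0.3], [0.52, 0.5, 0.8]], 0.1, 20.0)
        with pytest.raises(ValueError, match="overlap"):
            build_velocity_field([a, b], acq)

    def test_bifurcation_truth_conserves_mass(self):
        vessels, acq, truth = y_bifurcation(split=(0.6, 0.4))
        assert truth["BA"] == pytest.approx(truth["MCA_L"] + truth["MCA_R"])
        assert truth["MCA_L"] / truth["BA"] == pytest.approx(0.6)

    def test_finer_grid_reduces_field_error(self):
        """Decoded-field partial-volume error shrinks with resolution."""
        errs = []
        for vpr in (2.0, 4.0):
            vox = 0.15 / vpr
            acq = AcquisitionSpec(voxel_size=vox,
                                  grid_shape=(int(10 * vpr),) * 2 + (32,))
            vs, acq = straight_tube(radius=0.15, vbar=30.0, acq=acq,
                                    direction=(0, 0, 1))
            vol = build_velocity_field([vs], acq)
            # compare axial velocity to the analytic profile at voxel centers
            ext = (np.array(acq.grid_shape) - 1) * acq.voxel_size
            x = np.arange(acq.grid_shape[0]) * acq.voxel_size - ext[0] / 2
            y = np.arange(acq.grid_shape[1]) * acq.voxel_size - ext[1] / 2
            rr = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
            analytic = np.where(rr <= 0.15, 60.0 * (1 - (rr / 0.15) ** 2), 0.0)
            mid = vol.velocity[2, :, :, acq.grid_shape[2] // 2, 0]
            core = rr < 0.15 - vox  # away from the partial-volume rim
            errs.append(np.abs(mid - analytic)[core].max())
        assert errs[1] < errs[0]
        # analytic partial-volume bound: box averaging a parabola biases it
        # by (h^2/24)|lap v| = (vbar/3)(h/R)^2 per voxel
        bound = 1.5 * (30.0 / 3.0) * (1.0 / 4.0) ** 2
        assert errs[1] < bound


class TestPhaseEncoding:
    def test_wrap_arithmetic(self):
        acq = AcquisitionSpec(grid_shape=(2, 2, 2), venc=80.0)
        for v_true, v_expected in [(0.0, 0.0), (79.0, 79.0), (100.0, -60.0),
                                   (-100.0, 60.0)]:
            vol = phantom.VelocityVolume(
                velocity=np.full((3, 2, 2, 2), v_true),
                magnitude=np.ones((2, 2, 2)),
                voxel_size=acq.voxel_size, venc=80.0,
            )
            dec = encode_phase(vol, acq).decode()
            assert dec.velocity[0, 0, 0, 0, 0] == pytest.approx(v_expected)

    def test_noise_free_roundtrip_below_venc(self):
        vs, acq = straight_tube(radius=0.12, vbar=25.0)
        vol = build_velocity_field([vs], acq)
        dec = encode_phase(vol, acq).decode()
        assert np.allclose(dec.velocity, vol.velocity, atol=1e-9)
        assert np.allclose(dec.magnitude, vol.magnitude, atol=1e-12)


class TestNoise:
    def test_infinite_snr_is_identity(self):
        vs, acq = straight_tube()
        enc = encode_phase(build_velocity_field([vs], acq), acq)
        out = add_noise(enc, np.inf, 0)
        assert np.array_equal(out.signal, enc.signal)

    def test_fixed_seed_reproducible(self):
        vs, acq = straight_tube()
        enc = encode_phase(build_velocity_field([vs], acq), acq)
        a = add_noise(enc, 20.0, 42)
        b = add_noise(enc, 20.0, 42)
        c = add_noise(enc, 20.0, 43)
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_velocity_noise_matches_propagation(self):
        """Monte-Carlo check of sigma_v = venc / (pi * snr * A) at A = 1."""
        n = 10_000
        snr, venc = 20.0, 80.0
        vol = phantom.VelocityVolume(
            velocity=np.zeros((3, n, 1, 1)),
            magnitude=np.ones((n, 1, 1)),
            voxel_size=0.1, venc=venc,
        )
        acq = AcquisitionSpec(grid_shape=(n, 1, 1), venc=venc, snr=snr,
                              tissue_magnitude=1.0)
        noisy = add_noise(encode_phase(vol, acq), snr, 123).decode()
        predicted = venc / (math.pi * snr)
        measured = noisy.velocity[0].std()
        assert measured == pytest.approx(predicted, rel=0.10)


class TestBackgroundPhase:
    def test_zero_coefficients_identity(self):
        vs, acq = straight_tube()
        enc = encode_phase(build_velocity_field([vs], acq), acq)
        out = add_background_phase(enc, np.zeros((3, 4)))
        assert np.allclose(out.signal, enc.signal)

    def test_constant_offset_shifts_decoded_velocity(self):
        vs, acq = straight_tube(vbar=0.0)
        enc = encode_phase(build_velocity_field([vs], acq), acq)
        coeffs = np.zeros((3, 4))
        coeffs[0, 0] = 0.1  # radians
        dec = add_background_phase(enc, coeffs).decode()
        expected = 80.0 * 0.1 / math.pi  # 2.546 cm/s
        assert np.allclose(dec.velocity[0], expected, atol=1e-9)
        assert np.allclose(dec.velocity[1], 0.0, atol=1e-9)

    def test_linear_ramp_produces_plane(self):
        vs, acq = straight_tube(vbar=0.0)
        enc = encode_phase(build_velocity_field([vs], acq), acq)
        coeffs = np.zeros((3, 4))
        coeffs[1, 1] = 0.05  # radians per cm along x
        dec = add_background_phase(enc, coeffs).decode()
        v = dec.velocity[1, :, :, :, 0]
        x = np.arange(v.shape[0]) * acq.voxel_size
        fit = np.polyfit(x, v.mean(axis=(1, 2)), 1)
        assert fit[0] == pytest.approx(80.0 * 0.05 / math.pi, rel=1e-6)
        resid = v - (80.0 / math.pi) * 0.05 * x[:, None, None]
        assert np.abs(resid).max() < 1e-9


class TestStudySimulation:
    def test_truth_cvc_lies_exactly_on_programmed_line(self, study_data):
        truth, study = study_data.truth, study_data.study
        cvc = truth.cvc(study.conditions)
        e0 = study.conditions[0].etco2
        for cond in study.conditions:
            for vessel, slope in study.vessel_slopes.items():
                expected = cvc[study.conditions[0].label][vessel] + slope * (
                    cond.etco2 - e0
                )
                assert cvc[cond.label][vessel] == pytest.approx(expected)
            expected_g = cvc[study.conditions[0].label]["global"] + (
                truth.global_slope * (cond.etco2 - e0)
            )
            assert cvc[cond.label]["global"] == pytest.approx(expected_g)

    def test_global_flow_is_sum_of_feeders(self, study_data):
        truth = study_data.truth
        for cond, flows in truth.flow.items():
            assert truth.global_flow[cond] == pytest.approx(
                flows["ICA_L"] + flows["ICA_R"] + flows["BA"]
            )

    def test_mca_dilation_scales_csa_at_top_condition(self, study_data):
        truth = study_data.truth
        base = truth.csa["normocapnia"]["MCA_L"]
        top = truth.csa["co2_6pct"]["MCA_L"]
        assert base == pytest.approx(0.069, abs=5e-4)
        assert top / base == pytest.approx(1.0435, rel=1e-9)
        assert top == pytest.approx(0.0720, abs=5e-4)

    def test_seed_changes_noise_not_truth(self):
        acq = phantom.default_acquisition(snr=20.0)
        a = simulate_cvr_study(phantom.default_study(seed=1), acq)
        b = simulate_cvr_study(phantom.default_study(seed=2), acq)
        assert a.truth.to_dict() == b.truth.to_dict()
        sa = a.volumes[0]["normocapnia"].signal
        sb = b.volumes[0]["normocapnia"].signal
        assert not np.array_equal(sa, sb)

    def test_requires_distinct_etco2(self):
        conds = [Condition("a", 40.0, 95.0), Condition("b", 40.0, 95.0)]
        with pytest.raises(ValueError, match="distinct ETCO2"):
            StudySpec(
                conditions=conds,
                vessel_slopes=dict.fromkeys(phantom.VESSEL_LABELS, 5.0),
                baseline_flows=dict.fromkeys(phantom.VESSEL_LABELS, 100.0),
            )


def test_samples_per_heartbeat_matches_protocol():
    assert phantom.samples_per_heartbeat(7.8, 60.0) == 128


def test_cohort_tables_have_programmed_slopes():
    df = phantom.simulate_cvc_tables(50, slope_mean=25.0, slope_sd=0.0,
                                     noise_sd=0.0, seed=0)
    fits = df.groupby("subject").apply(
        lambda g: np.polyfit(g["etco2"], g["cvc"], 1)[0], include_groups=False
    )
    assert np.allclose(fits, 25.0)
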