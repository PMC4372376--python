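"""Reconstruction tests: carrier estimation, demodulation, unwrapping,
background flattening, simulated DIC, and the end-to-end oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from necroscope import phantoms, recon
from necroscope.recon import PhaseImage, WrappedPhase

from conftest import BIN_CARRIER_256, gaussian_bump


def wrap(x):
    return np.angle(np.exp(1j * np.asarray(x)))


class TestEstimateCarrier:
    def test_known_carrier_recovered(self):
        holo = phantoms.render_hologram(np.zeros((256, 256)), carrier=(0.25, 0.0), noise_sd=0)
        fx, fy = recon.estimate_carrier(holo.intensity)
        assert abs(fx - 0.25) < 0.002
        assert abs(fy - 0.0) < 0.002

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="no carrier"):
            recon.estimate_carrier(np.ones((128, 128)))

    def test_diagonal_carrier_with_noise(self):
        holo = phantoms.render_hologram(
            np.zeros((256, 256)), carrier=(0.18, 0.18), noise_sd=0.02, rng=1
        )
        fx, fy = recon.estimate_carrier(holo.intensity)
        assert abs(fx - 0.18) < 0.005
        assert abs(fy - 0.18) < 0.005


class TestSidebandFilter:
    def test_radius_positive(self):
        with pytest.raises(ValueError, match="radius"):
            recon.SidebandFilter(center=(0.3, 0.0), radius=0.0)

    def test_circle_must_exclude_dc(self):
        with pytest.raises(ValueError, match="DC"):
            recon.SidebandFilter(center=(0.1, 0.0), radius=0.2)


class TestDemodulate:
    def test_flat_phase_constant(self):
        holo = phantoms.render_hologram(
            np.zeros((256, 256)), carrier=BIN_CARRIER_256, noise_sd=0
        )
        wp = recon.demodulate(holo.intensity, recon.design_filter(holo.carrier))
        assert np.ptp(wp.values) < 1e-6

    def test_unwrapped_ground_truth_no_wrapping(self):
        phi = gaussian_bump(peak=2.5, sigma=30)
        holo = phantoms.render_hologram(phi, carrier=BIN_CARRIER_256, noise_sd=0)
        wp = recon.demodulate(holo.intensity, recon.design_filter(holo.carrier))
        err = wp.values - phi
        err -= np.median(err)
        assert np.sqrt((err**2).mean()) < 1e-3

    def test_phase_invariant_to_object_amplitude(self):
        phi = gaussian_bump(peak=1.5, sigma=30)
        wps = []
        for a_o in (0.5, 1.0):
            holo = phantoms.render_hologram(
                phi, carrier=BIN_CARRIER_256, amps=(a_o, 1.0), noise_sd=0
            )
            wps.append(recon.demodulate(holo.intensity, recon.design_filter(holo.carrier)))
        diff = wrap(wps[0].values - wps[1].values)
        assert np.abs(diff - np.median(diff)).max() < 1e-6

    def test_clipped_filter_warns(self):
        holo = phantoms.render_hologram(np.zeros((64, 64)), carrier=(0.31, 0.31), noise_sd=0)
        filt = recon.SidebandFilter(center=(0.31, 0.31), radius=0.25)
        with pytest.warns(UserWarning, match="clipped"):
            recon.demodulate(holo.intensity, filt)


class TestUnwrapPhase:
    def test_linear_ramp_6pi(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        truth = 6 * np.pi * xx / 127
        wp = WrappedPhase(values=wrap(truth), amplitude=np.ones_like(truth))
        out = recon.unwrap_phase(wp).values
        err = out - truth
        err -= err.flat[0]
        assert np.abs(err).max() < 1e-3

    def test_already_continuous_is_identity_up_to_constant(self):
        phi = gaussian_bump(shape=(96, 96), peak=2.0, sigma=15)
        wp = WrappedPhase(values=wrap(phi), amplitude=np.ones_like(phi))
        out = recon.unwrap_phase(wp).values
        diff = out - phi
        assert np.ptp(diff) < 1e-9

    def test_all_zero_amplitude_raises(self):
        wp = WrappedPhase(values=np.zeros((16, 16)), amplitude=np.zeros((16, 16)))
        with pytest.raises(ValueError, match="no reliable seed"):
            recon.unwrap_phase(wp)

    def test_full_chain_peak_recovery_with_noise(self):
        phi = gaussian_bump(peak=8.0, sigma=25)
        holo = phantoms.render_hologram(phi, carrier=BIN_CARRIER_256, rng=3)  # 1% noise
        wp = recon.demodulate(holo.intensity, recon.design_filter(holo.carrier))
        out = recon.unwrap_phase(wp)
        flat = recon.flatten_background(out)
        assert flat.values.max() == pytest.approx(8.0, abs=0.05)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=10, deadline=None)
    def test_wrap_invariance_property(self, seed):
        # unwrap(wrap(phi)) - phi is one global 2 pi multiple everywhere
        rng = np.random.default_rng(seed)
        phi = gaussian_bump(
            shape=(64, 64),
            peak=float(rng.uniform(1, 12)),
            sigma=float(rng.uniform(8, 15)),
        )
        wp = WrappedPhase(values=wrap(phi), amplitude=np.ones_like(phi))
        out = recon.unwrap_phase(wp, remove_offset=False).values
        diff = out - phi
        assert np.ptp(diff) < 1e-6
        k = diff.flat[0] / (2 * np.pi)
        assert abs(k - round(k)) < 1e-6


class TestFlattenBackground:
    def test_pure_plane_annihilated(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        plane = 0.02 * yy - 0.01 * xx + 0.5
        out = recon.flatten_background(PhaseImage(plane)).values
        assert np.abs(out).max() < 1e-9

    def test_zero_image_unchanged(self):
        out = recon.flatten_background(PhaseImage(np.zeros((64, 64)))).values
        assert np.allclose(out, 0.0)

    def test_tilted_phantom_mass_recovered(self, calib):
        from necroscope import quant

        phi = gaussian_bump(peak=6.0, sigma=20)
        true_mass = phi[phi >= 0.21].sum() * calib.kappa
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        tilted = phi + 0.01 * xx
        flat = recon.flatten_background(PhaseImage(tilted))
        mask = quant.segment_cells(flat.values)
        meas = quant.measure_cells(
            mask, quant.phase_to_mass_density(flat.values, calib), calib
        )
        assert len(meas) == 1
        assert meas[0].dry_mass == pytest.approx(true_mass, rel=0.005)

    def test_background_median_zero(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0.3, 0.01, (128, 128))
        out = recon.flatten_background(PhaseImage(img)).values
        # background median is zeroed on the robustly-selected background
        # subset; over all pixels it is zero to within the selection effect
        assert abs(np.median(out)) < 1e-5

    def test_excessive_mask_raises(self):
        mask = np.ones((64, 64), dtype=bool)
        mask[0, 0] = False
        with pytest.raises(ValueError, match="90%"):
            recon.flatten_background(PhaseImage(np.zeros((64, 64))), exclude_mask=mask)


class TestSimulatedDIC:
    def test_constant_phase_gives_bias(self):
        out = recon.simulated_dic(PhaseImage(np.full((32, 32), 1.7)), axis="col", bias=0.4)
        assert np.allclose(out, 0.4)

    def test_ramp_gives_constant_slope_plus_bias(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        out = recon.simulated_dic(PhaseImage(0.05 * xx), axis="col", bias=0.1)
        assert np.allclose(out, 0.15)
        out_r = recon.simulated_dic(PhaseImage(0.03 * yy), axis="row", bias=0.0)
        assert np.allclose(out_r, 0.03)

    def test_symmetric_bump_antisymmetric_response(self):
        phi = gaussian_bump(shape=(65, 65), peak=3.0, sigma=8, center=(32, 32))
        out = recon.simulated_dic(PhaseImage(phi), axis="col", bias=0.2)
        # forward difference of a symmetric profile sums to ~0 over a
        # symmetric window; the bias contributes bias * count
        window = out[32, 2:-3]
        assert window.sum() == pytest.approx(0.2 * len(window), abs=1e-6)

    def test_shape_preserved(self, bump_256):
        assert recon.simulated_dic(PhaseImage(bump_256), axis="row").shape == (256, 256)


class TestEndToEnd:
    @pytest.mark.parametrize("peak", [4.0, 8.0, 12.0])
    def test_noiseless_round_trip_rms(self, peak):
        phi = gaussian_bump(peak=peak, sigma=40)
        holo = phantoms.render_hologram(phi, carrier=BIN_CARRIER_256, noise_sd=0)
        out = recon.reconstruct(holo.intensity, carrier=holo.carrier)
        err = out.values - phi
        err -= np.median(err)
        assert np.sqrt((err**2).mean()) < 1e-2

    def test_phantom_round_trip_rms(self, calib):
        spec = phantoms.PhantomSpec(
            image_shape=(256, 256), cell_count=1, n_frames=4, seed=2
        )
        cell = phantoms.make_cell_phantom(spec, (128, 128), phantoms.Fate.NO_CHANGE, seed=4)
        canvas = np.zeros(spec.image_shape)
        cell.add_to(canvas, 0)
        holo = phantoms.render_hologram(canvas, carrier=BIN_CARRIER_256, noise_sd=0)
        out = recon.reconstruct(holo.intensity, carrier=holo.carrier)
        err = out.values - canvas
        err -= np.median(err)
        assert np.sqrt((err**2).mean()) < 1e-2

    def test_carrier_direction_invariance(self):
        phi = gaussian_bump(peak=6.0, sigma=30)
        # all bin-aligned so border wraparound does not enter the comparison
        recons = []
        for carrier in [(80 / 256, 0.0), (56 / 256, 56 / 256), (0.0, 80 / 256)]:
            holo = phantoms.render_hologram(phi, carrier=carrier, noise_sd=0)
            recons.append(recon.reconstruct(holo.intensity, carrier=carrier).values)
        for other in recons[1:]:
            assert np.sqrt(((recons[0] - other) ** 2).mean()) < 1e-2

    def test_estimated_carrier_round_trip(self):
        # the full auto path: carrier estimated from the data, not given
        phi = gaussian_bump(peak=7.0, sigma=30)
        holo = phantoms.render_hologram(phi, carrier=BIN_CARRIER_256, noise_sd=0)
        out = recon.reconstruct(holo.intensity)
        err = out.values - phi
        err -= np.median(err)
        assert np.sqrt((err**2).mean()) < 1e-2
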