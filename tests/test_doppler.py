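"""Doppler velocimetry: spectra, Gaussian fits, validation, velocities."""

import numpy as np
import pytest

from vascuflow.doppler import (REASON_EMPTY, compute_dps, fit_dps,
                               spectral_moments, to_velocities,
                               validate_voxels, VelocityField)
from vascuflow.octsim import MModeVolume, simulate_mmode, simulate_mmode_voxels


def single_voxel_dps(vz, vt, protocol, calibration, n_avg=3, n_rep=1, seed=0,
                     highpass=True, **sim_kw):
    """DPS of one (replicated) simulated voxel, protocol-style averaged."""
    rng = np.random.default_rng(seed)
    vols = [
        MModeVolume(
            simulate_mmode_voxels([vz] * n_rep, [vt] * n_rep, protocol,
                                  calibration, rng=rng, **sim_kw)
            .reshape(1, 1, n_rep, protocol.n_ascans),
            protocol, calibration)
        for _ in range(n_avg)
    ]
    dps = compute_dps(vols, calibration, highpass=highpass)
    if n_rep > 1:  # pool replicate voxels into one averaged spectrum
        pooled = dps.spectra.mean(axis=0, keepdims=True)
        dps.spectra = pooled
        dps.indices = np.array([[0, 0, 0]])
        dps.shape = (1, 1, 1)
        dps.d_max = pooled.max(axis=1).reshape(1, 1, 1)
    return dps


class TestComputeDps:
    def test_highpass_removes_constant_series(self, protocol, calibration):
        data = np.full((1, 1, 1, protocol.n_ascans), 3.0 + 4.0j, np.complex64)
        vol = MModeVolume(data, protocol, calibration)
        dps = compute_dps(vol, calibration)
        in_power = np.abs(data[0, 0, 0]) ** 2
        assert dps.spectra.sum() < 1e-3 * in_power.sum()

    def test_pure_tone_peak_position(self, protocol, calibration):
        t = np.arange(protocol.n_ascans) / protocol.ascan_rate
        data = np.exp(2j * np.pi * 5000.0 * t).astype(np.complex64)
        vol = MModeVolume(data.reshape(1, 1, 1, -1), protocol, calibration)
        dps = compute_dps(vol, calibration)
        peak = dps.freqs[np.argmax(dps.spectra[0])]
        assert abs(peak - 5000.0) <= dps.bin_width

    def test_simulated_moments_match_ground_truth(self, protocol, calibration):
        mu0, s0 = 2000.0, 500.0
        vz = calibration.v_z_from_shift(mu0)
        vt = calibration.v_transverse_from_sigma(s0)
        dps = single_voxel_dps(vz, vt, protocol, calibration, n_rep=100,
                               noise_amplitude=0.0, seed=4)
        # noiseless input: no floor to subtract; deconvolve the record window
        mu, s = spectral_moments(dps.spectra[0], dps.freqs, dps.sample_rate,
                                 subtract_floor=False,
                                 resolution=dps.resolution)
        assert mu == pytest.approx(mu0, rel=0.05)
        assert s == pytest.approx(s0, rel=0.05)

    def test_pad_shorter_than_series_rejected(self, protocol, calibration):
        from dataclasses import replace

        bad = replace(calibration, n_pad=128)
        data = np.zeros((1, 1, 1, protocol.n_ascans), np.complex64)
        vol = MModeVolume(data, protocol, calibration)
        with pytest.raises(ValueError, match="n_pad"):
            compute_dps(vol, bad)


class TestFitDps:
    def test_noiseless_gaussian_recovered_exactly(self, protocol, calibration):
        # model fits itself: synthetic spectrum, no noise
        from vascuflow.doppler import DopplerSpectraVolume

        n_pad = calibration.n_pad
        freqs = np.fft.fftshift(np.fft.fftfreq(n_pad, 1 / protocol.ascan_rate))
        spec = 1.0 * np.exp(-((freqs - 1000.0) ** 2) / (2 * 500.0**2))
        dps = DopplerSpectraVolume(
            spectra=spec[None, :].astype(np.float32),
            indices=np.array([[0, 0, 0]]), shape=(1, 1, 1), freqs=freqs,
            sample_rate=protocol.ascan_rate,
            d_max=np.ones((1, 1, 1)), stop_band=0.0, resolution=0.0)
        fits = fit_dps(dps)
        assert fits.mu[0, 0, 0] == pytest.approx(1000.0, abs=1.0)
        assert fits.sigma[0, 0, 0] == pytest.approx(500.0, rel=1e-3)
        assert fits.offset[0, 0, 0] == pytest.approx(0.0, abs=1e-3)

    def test_artery_like_spectrum_recovery(self, protocol, calibration):
        # values of the printed artery example: mu 2119 Hz, sigma 3817 Hz
        mu0, s0 = 2119.0, 3817.0
        vz = calibration.v_z_from_shift(mu0)
        vt = calibration.v_transverse_from_sigma(s0)
        dps = single_voxel_dps(vz, vt, protocol, calibration, n_rep=64,
                               noise_amplitude=0.1, seed=2)
        fits = fit_dps(dps)
        assert fits.mu[0, 0, 0] == pytest.approx(mu0, rel=0.05)
        assert fits.sigma[0, 0, 0] == pytest.approx(s0, rel=0.05)

    def test_flat_noise_spectrum_invalid(self, protocol, calibration):
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(20):
            ts = (rng.standard_normal((1, protocol.n_ascans))
                  + 1j * rng.standard_normal((1, protocol.n_ascans)))
            vol = MModeVolume(ts.reshape(1, 1, 1, -1), protocol, calibration)
            dps = compute_dps(vol, calibration)
            fits = fit_dps(dps)
            validate_voxels(fits, dps, adaptive_dmax=False)
            r2s.append(fits.r2[0, 0, 0])
            assert not fits.valid[0, 0, 0]
        assert np.median(r2s) < 0.5

    def test_all_zero_spectrum_flagged(self, protocol, calibration):
        data = np.zeros((1, 1, 1, protocol.n_ascans), np.complex64)
        vol = MModeVolume(data, protocol, calibration)
        dps = compute_dps(vol, calibration)
        fits = fit_dps(dps)
        assert not fits.valid[0, 0, 0]
        assert fits.reason[0, 0, 0] == REASON_EMPTY

    def test_sigma_monotone_in_transverse_speed(self, protocol, calibration):
        # fixed noise; increasing v_t strictly increases fitted sigma
        vts = np.linspace(1.0, 20.0, 10)
        sigmas = []
        for i, vt in enumerate(vts):
            dps = single_voxel_dps(0.8, vt, protocol, calibration, n_rep=48,
                                   noise_amplitude=0.1, seed=100)
            fits = fit_dps(dps)
            sigmas.append(float(fits.sigma[0, 0, 0]))
        assert np.all(np.diff(sigmas) > 0)

    def test_fit_agrees_with_moments_on_clean_input(self, protocol, calibration):
        # oracle equivalence: noiseless voxel, fitted (mu, sigma) vs moments
        mu0, s0 = 3000.0, 800.0
        vz = calibration.v_z_from_shift(mu0)
        vt = calibration.v_transverse_from_sigma(s0)
        dps = single_voxel_dps(vz, vt, protocol, calibration, n_rep=200,
                               noise_amplitude=0.0, seed=8)
        mu_m, s_m = spectral_moments(dps.spectra[0], dps.freqs, dps.sample_rate)
        fits = fit_dps(dps)
        res = protocol.ascan_rate / protocol.n_ascans
        assert abs(fits.mu[0, 0, 0] - mu_m) <= res
        assert abs(fits.sigma[0, 0, 0] - s_m) <= max(res, 0.1 * s_m)


class TestValidation:
    def test_flow_vs_static_classification(self, protocol, calibration):
        # half flow, half static voxels; classification accuracy >= 95%
        n = 40
        rng = np.random.default_rng(5)
        vz = rng.uniform(0.8, 3.0, n)
        vt = rng.uniform(1.0, 8.0, n)
        vols = []
        for _ in range(protocol.n_volumes):
            flow_ts = simulate_mmode_voxels(vz, vt, protocol, calibration,
                                            noise_amplitude=0.1, rng=rng)
            static_ts = simulate_mmode_voxels(
                np.zeros(n), np.zeros(n), protocol, calibration,
                dynamic_amplitude=0.0, static_amplitude=1.0,
                noise_amplitude=0.1, rng=rng)
            data = np.concatenate([flow_ts, static_ts]).reshape(1, 1, 2 * n, -1)
            vols.append(MModeVolume(data.astype(np.complex64), protocol,
                                    calibration))
        dps = compute_dps(vols, calibration)
        fits = fit_dps(dps)
        valid = validate_voxels(fits, dps)
        truth = np.zeros((1, 1, 2 * n), bool)
        truth[0, 0, :n] = True
        acc = (valid == truth).mean()
        assert acc >= 0.95


class TestVelocities:
    def test_transverse_worked_example(self, calibration):
        # sigma = 3817 Hz with the default kappa -> 12.2 mm/s
        assert calibration.v_transverse_from_sigma(3817.0) == \
            pytest.approx(12.2, abs=0.05)

    def test_axial_closed_form(self, calibration):
        # v_z = lambda0 mu / (2 n): mu = 2119 Hz -> ~1.05 mm/s
        assert calibration.v_z_from_shift(2119.0) == pytest.approx(1.0475, abs=0.002)

    def test_total_velocity_euclidean(self):
        shape = (1, 1, 1)
        from vascuflow.doppler import DopplerFitVolume
        from vascuflow.octsim import SystemCalibration

        cal = SystemCalibration()
        mu = np.full(shape, cal.doppler_shift(3.0))
        sigma = np.full(shape, cal.sigma_from_v_transverse(4.0))
        fits = DopplerFitVolume(
            amplitude=np.ones(shape), mu=mu, sigma=sigma,
            offset=np.zeros(shape), r2=np.ones(shape),
            valid=np.ones(shape, bool), reason=np.zeros(shape, np.uint8),
            aliased=np.zeros(shape, bool), sample_rate=23000.0)
        vel = to_velocities(fits, cal)
        assert vel.v_tot[0, 0, 0] == pytest.approx(5.0, rel=1e-9)

    def test_euclidean_identity_enforced(self):
        shape = (2, 2, 2)
        with pytest.raises(ValueError, match="Euclidean"):
            VelocityField(v_z=np.full(shape, 3.0),
                          v_transverse=np.full(shape, 4.0),
                          v_tot=np.full(shape, 6.0),
                          valid=np.ones(shape, bool))
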