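"""Synthetic OCT acquisitions: M-mode Doppler time series and repeated B-scans.

The Doppler signal model is the one the velocimetry stage assumes: at a
perfused voxel the dynamic scatterer signal is a complex Gaussian process
whose one-sided power spectrum is Gaussian with mean equal to the Doppler
shift f_D = 2 n v_z / lambda0 and standard deviation sigma = v_t / kappa,
where v_z is the axial velocity (positive toward increasing depth, mapping
to positive f_D) and v_t the transverse speed.  Static tissue and
partial-volume scatterers contribute a constant-phase component that
produces the DC peak; complex white noise sets the SNR.  Doppler shifts
beyond the Nyquist band fold back (aliasing is reproduced, not hidden).

Synthesis shapes complex white noise in the frequency domain with the
target spectral envelope (including +/- f_s replicas, so wrapped spectra
have the correct circular statistics) and inverse transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "SystemCalibration",
    "MModeVolume",
    "BScanSeries",
    "simulate_mmode",
    "simulate_mmode_voxels",
    "simulate_bscan_series",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scan protocol parameters.

    Doppler (M-mode) default: 23 kHz A-scan rate, 250 repeated A-scans per
    lateral position, 4 um lateral pixels, 3 volumes for averaging.
    Angiography default: 46 kHz A-scan rate, 8 repeated B-scans, 2 um pixels.
    """

    ascan_rate: float = 23_000.0  # Hz
    n_ascans: int = 250  # M-mode repeats per position
    bscan_repeats: int = 8
    pixel_size: float = 4.0  # um lateral
    n_volumes: int = 3  # Doppler volumes acquired for averaging

    def __post_init__(self):
        if self.ascan_rate <= 0:
            raise ValueError("ascan_rate must be positive")
        if self.n_ascans < 2:
            raise ValueError("need at least 2 A-scans per position")
        if self.bscan_repeats < 1 or self.n_volumes < 1:
            raise ValueError("repeat counts must be >= 1")

    @classmethod
    def doppler_default(cls) -> "AcquisitionProtocol":
        return cls()

    @classmethod
    def octa_default(cls) -> "AcquisitionProtocol":
        return cls(ascan_rate=46_000.0, pixel_size=2.0)


@dataclass(frozen=True)
class SystemCalibration:
    """System constants tying spectra to velocities.

    kappa converts the Doppler spectral width to transverse speed,
    v_t [um/s] = kappa * sigma [Hz]; its default 3.196 um is fixed by the
    system's worked calibration point (sigma = 3817 Hz <-> 12.2 mm/s).
    """

    wavelength: float = 1315e-9  # m, center wavelength
    refractive_index: float = 1.33
    kappa: float = 3.196  # um per Hz of sigma
    highpass_cutoff: float = 270.0  # Hz
    n_pad: int = 4096  # zero-padded FFT length

    def __post_init__(self):
        for name in ("wavelength", "refractive_index", "kappa",
                     "highpass_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_pad < 2:
            raise ValueError("n_pad must be >= 2")

    # velocity <-> spectrum conversions (velocities in mm/s)
    def doppler_shift(self, v_z_mm_s):
        """f_D = 2 n v_z / lambda0 (Hz), signed."""
        return 2.0 * self.refractive_index * np.asarray(v_z_mm_s) * 1e-3 / self.wavelength

    def v_z_from_shift(self, mu_hz):
        return np.asarray(mu_hz) * self.wavelength / (2.0 * self.refractive_index) * 1e3

    def sigma_from_v_transverse(self, v_t_mm_s):
        """sigma = v_t / kappa (Hz)."""
        return np.asarray(v_t_mm_s) * 1e3 / self.kappa

    def v_transverse_from_sigma(self, sigma_hz):
        return self.kappa * np.asarray(sigma_hz) * 1e-3


@dataclass
class MModeVolume:
    """Complex M-mode samples indexed [z, x, y, t]."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    calibration: SystemCalibration
    aliased: np.ndarray | None = None  # bool volume: |f_D| beyond Nyquist

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("M-mode data must be [z, x, y, t]")
        if self.data.shape[-1] != self.protocol.n_ascans:
            raise ValueError("time length must equal protocol n_ascans")
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("non-finite samples")


@dataclass
class BScanSeries:
    """Complex repeated B-scans indexed [repeat, z, x, y]."""

    data: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("B-scan series must be [repeat, z, x, y]")
        if self.data.shape[0] != self.protocol.bscan_repeats:
            raise ValueError("repeat count must equal protocol bscan_repeats")


def _wrap_frequency(f, fs):
    """Fold frequency into (-fs/2, fs/2]."""
    w = (np.asarray(f, float) + fs / 2) % fs - fs / 2
    return np.where(w == -fs / 2, fs / 2, w)


def simulate_mmode_voxels(
    v_z,
    v_t,
    protocol: AcquisitionProtocol,
    calibration: SystemCalibration,
    *,
    dynamic_amplitude=1.0,
    static_amplitude=0.0,
    noise_amplitude=0.1,
    rng=None,
):
    """Simulate M-mode time series for a batch of voxels.

    Parameters are broadcastable over the batch: ``v_z``/``v_t`` in mm/s,
    amplitudes in linear units (RMS of each component).  Returns a complex
    array of shape (n_voxels, n_ascans).
    """
    rng = np.random.default_rng(rng)
    v_z = np.atleast_1d(np.asarray(v_z, float))
    v_t = np.atleast_1d(np.asarray(v_t, float))
    n = len(v_z)
    nt = protocol.n_ascans
    fs = protocol.ascan_rate
    a_d = np.broadcast_to(np.asarray(dynamic_amplitude, float), (n,))
    a_s = np.broadcast_to(np.asarray(static_amplitude, float), (n,))
    a_n = np.broadcast_to(np.asarray(noise_amplitude, float), (n,))

    f_d = calibration.doppler_shift(v_z)
    f_d_wrapped = _wrap_frequency(f_d, fs)
    sigma = calibration.sigma_from_v_transverse(np.abs(v_t))

    f = np.fft.fftfreq(nt, d=1.0 / fs)  # (nt,)
    out = np.zeros((n, nt), dtype=np.complex128)

    narrow = sigma < fs / nt / 4  # effectively a pure tone
    if np.any(narrow):
        t = np.arange(nt) / fs
        ph = rng.uniform(0, 2 * np.pi, size=int(narrow.sum()))
        out[narrow] = (
            a_d[narrow, None]
            * np.exp(1j * (2 * np.pi * f_d_wrapped[narrow, None] * t[None, :]
                           + ph[:, None]))
        )
    broad = ~narrow
    if np.any(broad):
        # Gaussian envelope with +/- fs replicas: correct wrapped statistics.
        fd_b = f_d_wrapped[broad, None]
        s_b = sigma[broad, None]
        env = np.zeros((int(broad.sum()), nt))
        for m in (-1, 0, 1):
            env += np.exp(-((f[None, :] - fd_b + m * fs) ** 2) / (2 * s_b**2))
        env /= env.sum(axis=1, keepdims=True)  # unit total power
        w = (rng.standard_normal(env.shape) + 1j * rng.standard_normal(env.shape))
        spec = np.sqrt(env / 2.0) * w
        x = np.fft.ifft(spec, axis=1) * nt  # per-sample variance = sum(env) = 1
        out[broad] = a_d[broad, None] * x

    # static (constant-phase) component and complex white noise
    phi0 = rng.uniform(0, 2 * np.pi, size=n)
    out += a_s[:, None] * np.exp(1j * phi0)[:, None]
    out += a_n[:, None] / np.sqrt(2) * (
        rng.standard_normal((n, nt)) + 1j * rng.standard_normal((n, nt))
    )
    return out


def simulate_mmode(
    mask,
    velocity,
    protocol: AcquisitionProtocol | None = None,
    calibration: SystemCalibration | None = None,
    *,
    dynamic_amplitude: float = 1.0,
    static_amplitude: float = 1.0,
    static_fraction_in_vessel: float = 0.0,
    noise_amplitude: float = 0.1,
    seed: int | None = 0,
) -> MModeVolume:
    """Simulate a full M-mode Doppler volume from a rasterized velocity field.

    ``mask`` is a :class:`~vascuflow.volumes.SegmentationMask` (or bool
    array); ``velocity`` the (3, nz, nx, ny) field in mm/s from the
    rasterizer.  Foreground voxels receive the dynamic flow signal (plus a
    configurable partial-volume static component); background voxels are
    static tissue.  Voxels whose Doppler shift exceeds the Nyquist band are
    simulated with wrap-around and flagged in ``aliased``.
    """
    protocol = protocol or AcquisitionProtocol.doppler_default()
    calibration = calibration or SystemCalibration()
    m = np.asarray(getattr(mask, "data", mask), dtype=bool)
    vel = np.asarray(velocity, float)
    if vel.shape != (3,) + m.shape:
        raise ValueError("velocity must be (3,) + mask.shape")
    rng = np.random.default_rng(seed)
    nt = protocol.n_ascans
    shape = m.shape
    data = np.zeros(shape + (nt,), dtype=np.complex64)

    v_z = vel[0][m]
    v_t = np.sqrt(vel[1][m] ** 2 + vel[2][m] ** 2)
    fg = simulate_mmode_voxels(
        v_z, v_t, protocol, calibration,
        dynamic_amplitude=dynamic_amplitude,
        static_amplitude=static_fraction_in_vessel * static_amplitude,
        noise_amplitude=noise_amplitude, rng=rng,
    )
    data[m] = fg.astype(np.complex64)

    n_bg = int((~m).sum())
    if n_bg:
        phi0 = rng.uniform(0, 2 * np.pi, size=n_bg)
        bg = static_amplitude * np.exp(1j * phi0)[:, None] * np.ones((1, nt))
        bg = bg + noise_amplitude / np.sqrt(2) * (
            rng.standard_normal((n_bg, nt)) + 1j * rng.standard_normal((n_bg, nt))
        )
        data[~m] = bg.astype(np.complex64)

    f_d = calibration.doppler_shift(vel[0])
    aliased = np.abs(f_d) > protocol.ascan_rate / 2
    aliased &= m
    return MModeVolume(data=data, protocol=protocol, calibration=calibration,
                       aliased=aliased)


def simulate_bscan_series(
    mask,
    velocity,
    protocol: AcquisitionProtocol | None = None,
    *,
    signal_amplitude: float = 1.0,
    noise_amplitude: float = 0.05,
    decorrelation_speed: float = 1.0,
    seed: int | None = 0,
) -> BScanSeries:
    """Simulate repeated B-scans for angiography.

    Perfused voxels decorrelate between repeats following an AR(1) process
    with correlation exp(-speed / decorrelation_speed); static voxels repeat
    up to additive noise.  ``decorrelation_speed`` (mm/s) sets how fast
    contrast saturates with speed.
    """
    protocol = protocol or AcquisitionProtocol.octa_default()
    m = np.asarray(getattr(mask, "data", mask), dtype=bool)
    vel = np.asarray(velocity, float)
    if vel.shape != (3,) + m.shape:
        raise ValueError("velocity must be (3,) + mask.shape")
    rng = np.random.default_rng(seed)
    n_rep = protocol.bscan_repeats
    speed = np.sqrt((vel**2).sum(axis=0))
    rho = np.where(m, np.exp(-speed / decorrelation_speed), 1.0)

    base = signal_amplitude / np.sqrt(2) * (
        rng.standard_normal(m.shape) + 1j * rng.standard_normal(m.shape)
    )
    data = np.empty((n_rep,) + m.shape, dtype=np.complex64)
    cur = base
    for r in range(n_rep):
        if r > 0:
            w = (rng.standard_normal(m.shape) + 1j * rng.standard_normal(m.shape))
            cur = rho * cur + np.sqrt(np.clip(1 - rho**2, 0, 1)) * (
                signal_amplitude / np.sqrt(2) * w
            )
        noise = noise_amplitude / np.sqrt(2) * (
            rng.standard_normal(m.shape) + 1j * rng.standard_normal(m.shape)
        )
        data[r] = (cur + noise).astype(np.complex64)
    return BScanSeries(data=data, protocol=protocol)
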