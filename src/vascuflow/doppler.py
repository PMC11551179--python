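"""High-sensitivity Doppler velocimetry from M-mode OCT time series.

Per-voxel processing follows the joint spectral and time domain approach:
the repeated A-scans at each position form a time series, which is
high-pass filtered (zero-phase projection removing modes below 270 Hz) to
suppress the DC peak from static and partial-volume scatterers, Fourier
transformed with zero padding to 4096 samples, and converted to a Doppler
power spectrum (DPS).  A Gaussian with constant offset,

    G(f) = A exp(-(f - mu)^2 / (2 sigma^2)) + c,

evaluated circularly on the wrapped frequency axis (the +/- f_s replica
terms matter once sigma becomes comparable to the Nyquist band) is fit to
each DPS by nonlinear least squares, initialised from circular spectral
moments.  mu is the fit's peak position and sigma its standard deviation.
Velocities follow as v_z = lambda0 mu / (2n) (signed; positive toward
increasing depth), v_transv = kappa sigma, and
v_tot = sqrt(v_transv^2 + v_z^2).

Voxel validation combines the goodness of fit R^2, physical bounds on
sigma, and an adaptive per-depth-slice Otsu threshold on the Doppler
spectrum maximum D_max, which rejects residual static-tissue voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu

from .octsim import MModeVolume, SystemCalibration

__all__ = [
    "DopplerSpectraVolume",
    "DopplerFitVolume",
    "VelocityField",
    "compute_dps",
    "spectral_moments",
    "fit_dps",
    "validate_voxels",
    "to_velocities",
]

# reason codes for invalid fits
REASON_OK = 0
REASON_EMPTY = 1  # all-zero / no power
REASON_NO_CONVERGE = 2
REASON_LOW_R2 = 3
REASON_SIGMA_BOUNDS = 4
REASON_LOW_DMAX = 5


@dataclass
class DopplerSpectraVolume:
    """Doppler power spectra for a set of voxels.

    ``spectra`` holds one zero-padded power spectrum per selected voxel
    (fftshifted axis spanning the Nyquist band); ``indices`` the (z, x, y)
    voxel index of each row; ``shape`` the full volume shape.  ``d_max`` is
    the per-voxel spectral maximum over the full volume (NaN where not
    computed), the angiogram-like surrogate used for registration and
    adaptive thresholding.
    """

    spectra: np.ndarray  # (n, n_pad) float32, >= 0
    indices: np.ndarray  # (n, 3) int
    shape: tuple[int, int, int]
    freqs: np.ndarray  # (n_pad,) Hz, symmetric about 0
    sample_rate: float
    d_max: np.ndarray  # full volume
    stop_band: float = 0.0  # Hz; |f| below this was zeroed by the high-pass
    resolution: float = 0.0  # Hz; intrinsic (unpadded) bin width fs/n_t

    @property
    def bin_width(self) -> float:
        """Width of the interpolated (zero-padded) frequency bins."""
        return float(self.freqs[1] - self.freqs[0])

    def fit_band(self) -> np.ndarray:
        """Frequency bins usable for fitting (outside the notched band)."""
        if self.stop_band <= 0:
            return np.ones_like(self.freqs, dtype=bool)
        return np.abs(self.freqs) >= self.stop_band + self.resolution


@dataclass
class DopplerFitVolume:
    """Per-voxel modified-Gaussian fit parameters as full-volume maps."""

    amplitude: np.ndarray
    mu: np.ndarray  # Hz, signed
    sigma: np.ndarray  # Hz, >= 0
    offset: np.ndarray
    r2: np.ndarray
    valid: np.ndarray  # bool
    reason: np.ndarray  # uint8 reason codes
    aliased: np.ndarray  # |mu| beyond 0.45 fs
    sample_rate: float


@dataclass
class VelocityField:
    """Per-voxel velocities (mm/s): signed axial, transverse, total."""

    v_z: np.ndarray
    v_transverse: np.ndarray
    v_tot: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        ok = self.valid
        if ok.any():
            expected = np.sqrt(self.v_z[ok] ** 2 + self.v_transverse[ok] ** 2)
            if not np.allclose(self.v_tot[ok], expected, rtol=1e-12, atol=1e-12):
                raise ValueError("v_tot must equal the Euclidean norm of components")


def highpass_filter(ts: np.ndarray, fs: float, cutoff: float):
    """Zero-phase high-pass along axis -1 by Fourier-mode projection.

    Removes the discrete Fourier modes of the record whose frequency lies
    below the cutoff (the DC bin and its neighbours).  On short M-mode
    records (250 samples) this is exact and artifact-free, unlike an IIR
    filtfilt whose edge transients leave a spectral ridge just above the
    cutoff; it suppresses the static (constant-phase) component completely
    while preserving the spectral mean of the flow signal.
    """
    nt = ts.shape[-1]
    f = np.fft.fftfreq(nt, d=1.0 / fs)
    spec = np.fft.fft(ts, axis=-1)
    spec[..., np.abs(f) < cutoff] = 0.0
    return np.fft.ifft(spec, axis=-1)


def compute_dps(
    mmode: MModeVolume | list[MModeVolume],
    calibration: SystemCalibration | None = None,
    mask=None,
    highpass: bool = True,
) -> DopplerSpectraVolume:
    """Compute per-voxel Doppler power spectra from M-mode data.

    When several volumes are passed (the protocol acquires three for
    averaging) their power spectra are averaged voxel-wise before fitting.
    ``mask`` restricts spectra to selected voxels (e.g. the segmentation
    foreground); ``d_max`` is still computed for those voxels only.
    Disabling ``highpass`` reproduces the raw, DC-dominated spectra.
    """
    volumes = mmode if isinstance(mmode, (list, tuple)) else [mmode]
    first = volumes[0]
    calibration = calibration or first.calibration
    n_pad = calibration.n_pad
    nt = first.protocol.n_ascans
    fs = first.protocol.ascan_rate
    if n_pad < nt:
        raise ValueError(f"n_pad ({n_pad}) must be >= time-series length ({nt})")
    shape = first.data.shape[:3]

    if mask is None:
        m = np.ones(shape, dtype=bool)
    else:
        m = np.asarray(getattr(mask, "data", mask), dtype=bool)
        if m.shape != shape:
            raise ValueError("mask shape mismatch")
    idx = np.argwhere(m)

    power = np.zeros((len(idx), n_pad), dtype=np.float64)
    for vol in volumes:
        if vol.data.shape != first.data.shape:
            raise ValueError("volumes to average must share a shape")
        ts = np.asarray(vol.data[m], dtype=np.complex128)
        if highpass:
            ts = highpass_filter(ts, fs, calibration.highpass_cutoff)
        spec = np.fft.fftshift(np.fft.fft(ts, n=n_pad, axis=-1), axes=-1)
        power += np.abs(spec) ** 2
    power /= len(volumes)

    freqs = np.fft.fftshift(np.fft.fftfreq(n_pad, d=1.0 / fs))
    d_max = np.full(shape, np.nan, dtype=np.float32)
    d_max[m] = power.max(axis=1)
    return DopplerSpectraVolume(
        spectra=power.astype(np.float32), indices=idx, shape=tuple(shape),
        freqs=freqs, sample_rate=fs, d_max=d_max,
        stop_band=calibration.highpass_cutoff if highpass else 0.0,
        resolution=fs / nt,
    )


def spectral_moments(power, freqs, fs, subtract_floor: bool = True,
                     resolution: float | None = None):
    """Circular spectral mean and standard deviation (Hz).

    Treats the wrapped frequency axis as a circle so broad or aliased
    spectra get meaningful moments.  ``power`` may be (n_pad,) or
    (n, n_pad).  The median spectral level is removed as a noise-floor
    estimate when ``subtract_floor``.  When ``resolution`` (the intrinsic
    bin width f_s / n_t) is given, the finite-record window broadening is
    deconvolved exactly: circular resultants multiply under convolution,
    so dividing by the window's resultant removes the bias.
    """
    p = np.atleast_2d(np.asarray(power, float)).copy()
    if subtract_floor:
        p -= np.median(p, axis=1, keepdims=True)
        p = np.clip(p, 0.0, None)
    tot = p.sum(axis=1)
    tot[tot == 0] = np.nan
    theta = 2 * np.pi * freqs / fs
    z = (p * np.exp(1j * theta)).sum(axis=1) / tot
    if resolution is not None and resolution > 0:
        nt = int(round(fs / resolution))
        x = np.pi * freqs / fs
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (np.sin(nt * x) / (nt * np.sin(x))) ** 2
        w[~np.isfinite(w)] = 1.0
        r_w = float((w * np.exp(1j * theta)).sum().real / w.sum())
        z = z / max(r_w, 1e-6)
    mu = np.angle(z) * fs / (2 * np.pi)
    # circular std mapped back to Hz; guard |z| -> 0 (flat spectrum)
    r = np.clip(np.abs(z), 1e-12, 1.0)
    sigma = np.sqrt(-2.0 * np.log(r)) * fs / (2 * np.pi)
    if np.ndim(power) == 1:
        return float(mu[0]), float(sigma[0])
    return mu, sigma


def _wrapped_gaussian(f, a, mu, sigma, c, fs):
    g = np.zeros_like(f)
    for m in (-1.0, 0.0, 1.0):
        g += np.exp(-((f - mu + m * fs) ** 2) / (2.0 * sigma**2))
    return a * g + c


class _SpectrumModel:
    """Window-convolved wrapped Gaussian with analytic Jacobian.

    Operates on a (possibly decimated) circular frequency grid; the model
    and its parameter derivatives share one batched FFT convolution.
    """

    def __init__(self, freqs, fs, nt=None, band=None):
        self.f = np.asarray(freqs, float)
        self.fs = fs
        self.band = np.ones(len(self.f), bool) if band is None else band
        if nt:
            fshift = np.fft.ifftshift(self.f)
            x = np.pi * fshift / fs
            with np.errstate(divide="ignore", invalid="ignore"):
                w = (np.sin(nt * x) / (nt * np.sin(x))) ** 2
            w[~np.isfinite(w)] = 1.0
            w /= w.sum()
            self.wfft = np.fft.rfft(w)
        else:
            self.wfft = None

    def _convolve(self, rows):
        if self.wfft is None:
            return rows
        return np.fft.irfft(np.fft.rfft(rows, axis=-1) * self.wfft,
                            n=rows.shape[-1], axis=-1)

    def _parts(self, mu, sigma):
        """(G, dG/dmu, dG/dsigma) summed over wrap replicas."""
        f = self.f
        g = np.zeros_like(f)
        dmu = np.zeros_like(f)
        dsig = np.zeros_like(f)
        inv_s2 = 1.0 / (sigma * sigma)
        for m in (-1.0, 0.0, 1.0):
            x = f - mu + m * self.fs
            e = np.exp(-0.5 * x * x * inv_s2)
            g += e
            dmu += e * x * inv_s2
            dsig += e * x * x * inv_s2 / sigma
        return g, dmu, dsig

    def value(self, a, mu, sigma, c):
        g = self._convolve(self._parts(mu, sigma)[0][None, :])[0]
        return (a * g + c)[self.band]

    def value_and_jac(self, a, mu, sigma, c, free_offset):
        g, dmu, dsig = self._parts(mu, sigma)
        conv = self._convolve(np.vstack([g, dmu, dsig]))
        val = (a * conv[0] + c)[self.band]
        cols = [conv[0][self.band], a * conv[1][self.band],
                a * conv[2][self.band]]
        if free_offset:
            cols.append(np.ones(int(self.band.sum())))
        return val, np.column_stack(cols)


def fit_dps(
    dps: DopplerSpectraVolume,
    max_nfev: int = 200,
    noise_floor: float | np.ndarray | None = None,
    fit_stride: int = 4,
) -> DopplerFitVolume:
    """Fit the offset Gaussian to every Doppler spectrum.

    Fits are independent per voxel, initialised from circular spectral
    moments, bounded to the Nyquist band, and evaluated with wrap replicas.
    Voxels whose fit fails to converge (or has no power) come back with
    ``valid=False`` and a reason code, never an exception.

    ``noise_floor`` optionally pins the offset c to a known spectral noise
    level (scalar or per-voxel array aligned with ``dps.indices``), e.g.
    from a dark calibration or from static-tissue voxels.  Once the
    spectral width approaches the Nyquist band (sigma above roughly f_s/4),
    the wrapped Gaussian is degenerate with its offset up to the first
    circular harmonic, and only a pinned floor keeps sigma identifiable.
    """
    if not np.all(np.isfinite(dps.spectra)):
        raise ValueError("spectra must be finite")
    n, n_pad = dps.spectra.shape
    fs = dps.sample_rate
    df = dps.bin_width
    # decimate the heavily oversampled padded grid for fitting speed
    stride = max(int(fit_stride), 1)
    if dps.resolution > 0:
        stride = min(stride, max(int(dps.resolution // df) // 4, 1))
    freqs_r = dps.freqs[::stride]
    band = dps.fit_band()[::stride]
    spectra_r = dps.spectra[:, ::stride]
    f = freqs_r[band]
    nt = int(round(fs / dps.resolution)) if dps.resolution > 0 else None
    model = _SpectrumModel(freqs_r, fs, nt=nt, band=band)
    model_full = model.value

    shape = dps.shape
    full = lambda fill: np.full(shape, fill, dtype=np.float32)
    out = DopplerFitVolume(
        amplitude=full(np.nan), mu=full(np.nan), sigma=full(np.nan),
        offset=full(np.nan), r2=full(np.nan),
        valid=np.zeros(shape, bool), reason=np.full(shape, REASON_EMPTY, np.uint8),
        aliased=np.zeros(shape, bool), sample_rate=fs,
    )

    if noise_floor is not None:
        floors = np.broadcast_to(np.asarray(noise_floor, float).ravel(), (n,))
    mu0s, s0s = spectral_moments(spectra_r[:, band], f, fs)
    min_sigma = df * stride / 4
    for i in range(n):
        z, x, y = dps.indices[i]
        p = spectra_r[i, band].astype(float)
        pmax = p.max()
        if not pmax > 0:
            continue
        floor = float(np.median(p)) if noise_floor is None else float(floors[i])
        a0 = max(pmax - floor, 1e-12 * max(pmax, 1.0))
        mu0 = mu0s[i] if np.isfinite(mu0s[i]) else 0.0
        s0 = np.clip(s0s[i] if np.isfinite(s0s[i]) else 10 * df,
                     2 * df, 0.45 * fs)
        scale = pmax
        mu_peak = float(f[np.argmax(p)])
        free_offset = noise_floor is None
        cfix = max(floor, 0.0)

        if free_offset:

            def resid(q):
                return (model_full(q[0], q[1], q[2], q[3]) - p) / scale

            def jac(q):
                _, J = model.value_and_jac(q[0], q[1], q[2], q[3], True)
                return J / scale

            inits = [np.array([a0, mu0, s0, cfix]),
                     np.array([a0, mu_peak, max(4 * df, 2 * fs / 250), cfix]),
                     np.array([2 * a0, mu0, 0.35 * fs, max(p.min(), 0.0)])]
            bounds = ([0.0, -fs / 2, min_sigma, 0.0],
                      [np.inf, fs / 2, fs, np.inf])
        else:

            def resid(q):
                return (model_full(q[0], q[1], q[2], cfix) - p) / scale

            def jac(q):
                _, J = model.value_and_jac(q[0], q[1], q[2], cfix, False)
                return J / scale

            inits = [np.array([a0, mu0, s0]),
                     np.array([a0, mu_peak, max(4 * df, 2 * fs / 250)]),
                     np.array([2 * a0, mu0, 0.35 * fs]),
                     np.array([4 * a0, mu0, 0.6 * fs])]
            bounds = ([0.0, -fs / 2, min_sigma], [np.inf, fs / 2, fs])
        # Multi-start: spectral-moment init, plus peak-based narrow and
        # broad inits (broad wrapped spectra have a shallow local minimum
        # at small sigma + large offset).
        sol = None
        ss_tot = float(((p - p.mean()) ** 2).sum())
        for k, x0 in enumerate(inits):
            try:
                cand = least_squares(resid, x0, jac=jac, bounds=bounds,
                                     max_nfev=max_nfev, method="trf")
            except Exception:
                continue
            if sol is None or cand.cost < sol.cost:
                sol = cand
            if k == 0:
                # alternates only rescue degenerate landings: near-flat
                # R^2, a sigma stuck at a bound, or a near-Nyquist width
                r2_first = 1.0 - 2.0 * sol.cost * scale**2 / ss_tot \
                    if ss_tot > 0 else -np.inf
                s_first = sol.x[2]
                suspicious = (r2_first < 0.3 or s_first <= 2 * min_sigma
                              or s_first > 0.22 * fs)
                if not suspicious:
                    break
        if sol is None:
            out.reason[z, x, y] = REASON_NO_CONVERGE
            continue
        if free_offset:
            a, mu, sigma, c = sol.x
        else:
            a, mu, sigma = sol.x
            c = cfix
        fitted = model_full(a, mu, sigma, c)
        ss_res = float(((fitted - p) ** 2).sum())
        ss_tot = float(((p - p.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
        out.amplitude[z, x, y] = a
        out.mu[z, x, y] = mu
        out.sigma[z, x, y] = sigma
        out.offset[z, x, y] = c
        out.r2[z, x, y] = r2
        out.valid[z, x, y] = sigma > 0 and np.isfinite(r2)
        out.reason[z, x, y] = REASON_OK if out.valid[z, x, y] else REASON_NO_CONVERGE
        out.aliased[z, x, y] = abs(mu) > 0.45 * fs
    return out


def validate_voxels(
    fits: DopplerFitVolume,
    dps: DopplerSpectraVolume,
    r2_min: float = 0.6,
    sigma_bounds: tuple[float, float] | None = None,
    adaptive_dmax: bool = True,
) -> np.ndarray:
    """Validity mask: good fit, physical sigma, and D_max above threshold.

    The D_max threshold is adaptive per depth slice (Otsu on log D_max),
    which tracks the depth-dependent intensity roll-off and rejects
    residual static-tissue voxels.  Returns the boolean mask and updates
    ``fits.valid``/``fits.reason`` in place.

    The R^2 of a correct fit to an M-volume-averaged speckle periodogram
    is bounded near M/(M+1) (the periodogram of a Gaussian process has
    100%/sqrt(M) multiplicative noise), i.e. ~0.75 for the three-volume
    protocol; the default threshold sits below that.  Disable
    ``adaptive_dmax`` when fitting only inside a segmentation mask (the
    intensity distribution is then unimodal and Otsu would split it).
    """
    fs = fits.sample_rate
    if sigma_bounds is None:
        sigma_bounds = (dps.bin_width / 2, 0.5 * fs)
    ok = fits.valid.copy()

    low_r2 = ok & ~(fits.r2 >= r2_min)
    fits.reason[low_r2] = REASON_LOW_R2
    ok &= fits.r2 >= r2_min

    bad_sigma = ok & ~((fits.sigma >= sigma_bounds[0]) & (fits.sigma <= sigma_bounds[1]))
    fits.reason[bad_sigma] = REASON_SIGMA_BOUNDS
    ok &= (fits.sigma >= sigma_bounds[0]) & (fits.sigma <= sigma_bounds[1])

    if adaptive_dmax:
        d = dps.d_max
        for z in range(d.shape[0]):
            vals = d[z][np.isfinite(d[z]) & (d[z] > 0)]
            if vals.size < 2 or np.ptp(np.log10(vals)) < 1e-6:
                continue
            thr = 10 ** threshold_otsu(np.log10(vals))
            low = ok[z] & ~(d[z] >= thr)
            fits.reason[z][low] = REASON_LOW_DMAX
            ok[z] &= d[z] >= thr
    fits.valid = ok
    return ok


def to_velocities(
    fits: DopplerFitVolume,
    calibration: SystemCalibration,
    valid: np.ndarray | None = None,
) -> VelocityField:
    """Convert fitted (mu, sigma) maps to axial/transverse/total velocities."""
    ok = fits.valid if valid is None else np.asarray(valid, bool)
    v_z = np.where(ok, calibration.v_z_from_shift(fits.mu), np.nan)
    v_t = np.where(ok, calibration.v_transverse_from_sigma(fits.sigma), np.nan)
    v_tot = np.sqrt(v_z**2 + v_t**2)
    return VelocityField(v_z=v_z, v_transverse=v_t, v_tot=v_tot, valid=ok)
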