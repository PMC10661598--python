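"""Synthetic spatio-temporal encoder and calibration dictionary.

The physical system relays photoacoustic waves from a water volume
through a right-angle prism and a long cylindrical fused-silica pipe to
a single-element transducer. Multipath propagation inside the pipe
scrambles each source position into a unique temporal signature, which
is what makes a single trace invertible into a 3-D image once the
system has been calibrated voxel by voxel with a point absorber.

This module emulates that calibration phenomenologically. Each voxel's
impulse response is composed of

* a time-of-flight delay (water path to the pipe entrance plus the
  fixed pipe transit),
* the band-limited transducer pulse,
* a voxel-specific pseudorandom reverberation coda with an exponential
  envelope (the scrambling),
* a solid-angle aperture weight limited by the water/silica critical
  angle, and
* Gaussian lateral mixing between neighbouring columns, imposing the
  finite lateral resolution of the relay.

Calibration measurement noise and shot averaging are applied last, so
the resulting dictionary has the statistical character of a measured
one while remaining exactly reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .core_model import AcousticParams, MeasuredSignal, VolumeGrid

__all__ = [
    "EncoderConfig",
    "CalibrationDictionary",
    "transducer_pulse",
    "critical_angle",
    "time_of_flight",
    "aperture_weight",
    "scramble_coda",
    "build_dictionary",
    "lateral_mix",
    "add_noise",
    "pulse_energy_correct",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


@dataclass(frozen=True)
class EncoderConfig:
    """Parameters of the synthetic encoder and calibration protocol.

    coda_len:
        Length (samples) of the pseudorandom reverberation tail appended
        behind the direct arrival. Longer codas make the dictionary
        columns more incoherent.
    coda_decay_tau:
        Time constant (s) of the coda's exponential envelope.
    lateral_fwhm_mm:
        FWHM of the Gaussian in-plane mixing kernel; this sets the
        lateral resolution the relay can support.
    calib_snr_db:
        SNR (dB, per column) of each simulated calibration shot;
        ``None`` or ``inf`` gives a noiseless calibration.
    n_avg:
        Number of averaged shots per calibration point.
    seed:
        Base RNG seed; every coda and noise draw derives from it.
    """

    coda_len: int = 1500
    coda_decay_tau: float = 100e-6
    lateral_fwhm_mm: float = 2.5
    calib_snr_db: Optional[float] = 40.0
    n_avg: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coda_len < 0:
            raise ValueError("coda_len must be >= 0")
        if self.lateral_fwhm_mm < 0:
            raise ValueError("lateral_fwhm_mm must be >= 0")
        if self.n_avg < 1:
            raise ValueError("n_avg must be >= 1")


@dataclass
class CalibrationDictionary:
    """Per-voxel impulse-response dictionary K (T x N).

    Column ``k_i`` is the calibrated single-shot response of voxel ``i``
    (linear-index order of ``grid``). ``column_norms`` is populated once
    :meth:`normalized` has been applied and stores the original
    Euclidean norms so intensities can be mapped back to physical scale.
    """

    columns: np.ndarray
    grid: VolumeGrid
    params: AcousticParams
    encoder: EncoderConfig
    column_norms: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("dictionary must be a 2-D (T, N) array")
        if self.columns.shape[1] != self.grid.n_voxels:
            raise ValueError(
                f"dictionary has {self.columns.shape[1]} columns but grid has "
                f"{self.grid.n_voxels} voxels"
            )
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("dictionary entries must be finite")

    @property
    def n_samples(self) -> int:
        return self.columns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.columns.shape[1]

    def normalized(self) -> "CalibrationDictionary":
        """Unit-norm columns; zero columns are left untouched (norm kept as 1)."""
        norms = np.linalg.norm(self.columns, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        return CalibrationDictionary(
            self.columns / safe, self.grid, self.params, self.encoder,
            column_norms=norms,
        )


def transducer_pulse(params: AcousticParams) -> np.ndarray:
    """Band-limited detection pulse: Gaussian-envelope cosine at ``f_c``.

    The envelope width is set so the -6 dB full width of the pulse's
    power spectrum equals ``frac_bw_6db * f_c``. The returned waveform
    is unit-norm and symmetric about its centre sample.
    """
    nyquist_needed = 2.0 * params.f_c * (1.0 + params.frac_bw_6db / 2.0)
    if params.fs <= nyquist_needed:
        raise ValueError("sampling rate below Nyquist for the pulse band")
    # -6 dB on the power spectrum: exp(-w^2/sigma_f^2) = 10^-0.6
    half_width_factor = math.sqrt(0.6 * math.log(10.0))  # 1.17547
    sigma_f = params.frac_bw_6db * params.f_c / (2.0 * half_width_factor)
    sigma_t = 1.0 / (2.0 * math.pi * sigma_f)
    half = int(math.ceil(4.0 * sigma_t * params.fs))
    t = np.arange(-half, half + 1) / params.fs
    p = np.cos(2.0 * math.pi * params.f_c * t) * np.exp(-t**2 / (2.0 * sigma_t**2))
    return p / np.linalg.norm(p)


def critical_angle(params: AcousticParams) -> float:
    """Water-to-silica critical angle, ``arcsin(v_water / v_pipe)``, radians."""
    if params.v_water >= params.v_pipe:
        raise ValueError("no critical angle: v_water must be < v_pipe")
    return math.asin(params.v_water / params.v_pipe)


def time_of_flight(coord_mm, params: AcousticParams) -> float:
    """Arrival delay (s) of a source at ``coord_mm`` (grid frame, mm).

    Water path from the voxel to the centre of the pipe entrance
    aperture (the coordinate origin) plus the fixed pipe transit.
    """
    coord = np.asarray(coord_mm, dtype=float)
    if coord[2] < 0:
        raise ValueError(f"voxel {coord_mm} lies behind the pipe entrance plane")
    d = float(np.linalg.norm(coord)) * 1e-3  # m
    return d / params.v_water + params.pipe_length / params.v_pipe


def aperture_weight(coord_mm, params: AcousticParams) -> float:
    """Fraction of a source's forward hemisphere collected by the relay.

    Rays couple into the pipe only if they hit the entrance disk and
    arrive within the critical angle. For a source at distance ``d``
    from the entrance centre the accepted cone half-angle is
    ``min(theta_c, atan(pipe_radius / d))`` and the weight is the
    spherical-cap fraction ``(1 - cos(theta_eff)) / 2``. Off-axis
    sources use the same first-order rule with ``d`` the distance to
    the entrance centre.
    """
    coord = np.asarray(coord_mm, dtype=float)
    d = float(np.linalg.norm(coord)) * 1e-3
    if d <= 0:
        raise ValueError("source must be at positive distance from the entrance")
    theta_c = critical_angle(params)
    theta_eff = min(theta_c, math.atan(params.pipe_radius / d))
    return (1.0 - math.cos(theta_eff)) / 2.0


def _coda_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))


def scramble_coda(i: int, encoder: EncoderConfig, params: AcousticParams) -> np.ndarray:
    """Voxel-specific pseudorandom reverberation tail, unit-norm.

    Deterministic in ``(encoder.seed, i)``: the same voxel always gets
    the same coda, which is what lets the simulated calibration be
    reproduced exactly.
    """
    if encoder.coda_len < 1:
        raise ValueError("coda_len must be >= 1 to generate a coda")
    if encoder.coda_len == 1:
        return np.array([1.0])
    rng = _coda_rng(encoder.seed, i)
    coda = rng.standard_normal(encoder.coda_len)
    t = np.arange(encoder.coda_len) / params.fs
    coda *= np.exp(-t / encoder.coda_decay_tau)
    return coda / np.linalg.norm(coda)


def lateral_mix(K_raw: np.ndarray, grid: VolumeGrid, lateral_fwhm_mm: float) -> np.ndarray:
    """Mix dictionary columns of laterally neighbouring voxels.

    Applies a normalized Gaussian kernel of the given FWHM in the X-Y
    plane (per Z slice, per time sample); kernel weights for each voxel
    sum to 1 including at volume edges. FWHM 0 is the identity.
    """
    if lateral_fwhm_mm < 0:
        raise ValueError("lateral_fwhm_mm must be >= 0")
    if lateral_fwhm_mm == 0:
        return K_raw
    T = K_raw.shape[0]
    sig_x = lateral_fwhm_mm / (_FWHM_PER_SIGMA * grid.inc_mm[0])
    sig_y = lateral_fwhm_mm / (_FWHM_PER_SIGMA * grid.inc_mm[1])
    # (T, nz, ny, nx) view: linear index is X fastest, Z slowest.
    arr = K_raw.reshape(T, grid.nz, grid.ny, grid.nx)
    mixed = gaussian_filter(arr, sigma=(0, 0, sig_y, sig_x), mode="constant")
    # renormalize edge kernels so every voxel's weights sum to 1
    wsum = gaussian_filter(np.ones((grid.ny, grid.nx)), sigma=(sig_y, sig_x),
                           mode="constant")
    mixed /= wsum[None, None, :, :]
    return mixed.reshape(T, grid.n_voxels)


def add_noise(signal, snr_db: Optional[float], rng: np.random.Generator) -> MeasuredSignal:
    """Add white Gaussian noise at the requested SNR (power ratio, dB)."""
    if isinstance(signal, MeasuredSignal):
        samples, fs, energy = signal.samples, signal.fs, signal.pulse_energy
    else:
        raise TypeError("add_noise expects a MeasuredSignal")
    if snr_db is None or math.isinf(snr_db):
        return MeasuredSignal(samples.copy(), fs, energy)
    power = float(np.mean(samples**2))
    if power == 0.0:
        raise ValueError("cannot set a finite SNR on a zero-power signal")
    sigma = math.sqrt(power * 10.0 ** (-snr_db / 10.0))
    noisy = samples + rng.normal(0.0, sigma, size=samples.shape)
    return MeasuredSignal(noisy, fs, energy)


def pulse_energy_correct(y: MeasuredSignal, E_meas: float, E_ref: float = 1.0) -> MeasuredSignal:
    """Rescale a trace for laser pulse-energy fluctuation.

    The photodiode reading ``E_meas`` of the firing pulse is used to
    normalize amplitudes to the reference energy ``E_ref``.
    """
    if E_meas <= 0:
        raise ValueError(f"measured pulse energy must be positive, got {E_meas}")
    return MeasuredSignal(y.samples * (E_ref / E_meas), y.fs, pulse_energy=E_ref)


def build_dictionary(grid: VolumeGrid, params: AcousticParams,
                     encoder: EncoderConfig) -> CalibrationDictionary:
    """Simulate the pointwise calibration scan of the imaging volume.

    Column ``i`` is built as
    ``aperture_weight_i * delay(tof_i)[pulse (*) coda_i]``, laterally
    mixed with the Gaussian kernel, then corrupted by the averaged
    calibration noise. Fully reproducible from ``encoder.seed``.
    """
    T = params.n_samples
    N = grid.n_voxels
    pulse = transducer_pulse(params)
    centers = grid.voxel_centers()

    if np.any(centers[:, 2] < 0):
        raise ValueError("grid extends behind the pipe entrance plane")
    dist_m = np.linalg.norm(centers, axis=1) * 1e-3
    tof = dist_m / params.v_water + params.pipe_length / params.v_pipe
    delays = np.rint(tof * params.fs).astype(int)
    bad = np.nonzero(delays >= T)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"time of flight of voxel {i} at {tuple(centers[i])} mm "
            f"({tof[i] * 1e6:.2f} us) exceeds the record length "
            f"({T / params.fs * 1e6:.2f} us)"
        )

    theta_c = critical_angle(params)
    theta_eff = np.minimum(theta_c, np.arctan(params.pipe_radius / dist_m))
    weights = (1.0 - np.cos(theta_eff)) / 2.0

    if encoder.coda_len <= 1:
        responses = np.broadcast_to(pulse, (N, pulse.size))
    else:
        codas = np.empty((N, encoder.coda_len))
        for i in range(N):
            codas[i] = scramble_coda(i, encoder, params)
        responses = fftconvolve(codas, pulse[None, :], axes=1)

    K = np.zeros((T, N))
    L = responses.shape[1]
    for i in range(N):
        d = delays[i]
        m = min(L, T - d)
        K[d:d + m, i] = responses[i, :m]
    K *= weights[None, :]

    K = lateral_mix(K, grid, encoder.lateral_fwhm_mm)

    if encoder.calib_snr_db is not None and not math.isinf(encoder.calib_snr_db):
        # averaging n_avg iid shots == one draw with std sigma/sqrt(n_avg)
        col_power = np.mean(K**2, axis=0)
        sigma = np.sqrt(col_power * 10.0 ** (-encoder.calib_snr_db / 10.0)
                        / encoder.n_avg)
        rng = np.random.default_rng(
            np.random.SeedSequence(encoder.seed, spawn_key=(0, 1)))
        K += rng.standard_normal(K.shape) * sigma[None, :]

    return CalibrationDictionary(K, grid, params, encoder)
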