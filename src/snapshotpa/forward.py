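"""Linear single-shot measurement model.

One laser shot excites every absorber in the volume simultaneously;
the detector trace is the superposition of the per-voxel calibrated
responses weighted by the voxel intensities, ``y = K x``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core_model import MeasuredSignal, VolumeImage
from .encoder_sim import CalibrationDictionary, add_noise

__all__ = ["synthesize", "residual_norm"]


def _as_matrix(K) -> np.ndarray:
    if isinstance(K, CalibrationDictionary):
        return K.columns
    return np.asarray(K, dtype=float)


def _as_vector(x) -> np.ndarray:
    if isinstance(x, VolumeImage):
        return x.values
    return np.asarray(x, dtype=float).ravel()


def synthesize(K, x, snr_db: Optional[float] = None,
               rng: Optional[np.random.Generator] = None,
               fs: Optional[float] = None) -> MeasuredSignal:
    """Synthesize the single-shot trace of an intensity volume.

    Parameters
    ----------
    K : CalibrationDictionary or (T, N) array
    x : VolumeImage or length-N vector
    snr_db : optional detector-referred SNR; ``None``/``inf`` is noiseless.
    rng : generator used for the noise draw (required when snr_db is finite).
    fs : sampling rate for a bare-matrix ``K`` (taken from the dictionary
        otherwise).
    """
    A = _as_matrix(K)
    v = _as_vector(x)
    if v.size != A.shape[1]:
        raise ValueError(f"x has {v.size} entries but K has {A.shape[1]} columns")
    if not np.all(np.isfinite(v)):
        raise ValueError("x must be finite")
    if fs is None:
        fs = K.params.fs if isinstance(K, CalibrationDictionary) else 1.0
    y = MeasuredSignal(A @ v, fs)
    if snr_db is None or np.isinf(snr_db):
        return y
    if rng is None:
        raise ValueError("rng is required for noisy synthesis")
    return add_noise(y, snr_db, rng)


def residual_norm(y, K, x) -> float:
    """Data-fidelity term ``0.5 * ||y - K x||^2`` (Euclidean)."""
    A = _as_matrix(K)
    yv = y.samples if isinstance(y, MeasuredSignal) else np.asarray(y, float).ravel()
    v = _as_vector(x)
    if v.size != A.shape[1] or yv.size != A.shape[0]:
        raise ValueError(
            f"dimension mismatch: y {yv.size}, K {A.shape}, x {v.size}")
    r = yv - A @ v
    return 0.5 * float(r @ r)
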