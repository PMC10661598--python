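"""Compressive 3-D reconstruction by TwIST with total-variation regularization.

The image is recovered as

    x_hat = argmin_x  1/2 ||y - K x||^2 + lam * TV(x)

with isotropic 3-D total variation, solved by the two-step iterative
shrinkage/thresholding scheme: each iterate combines the previous two
accepted iterates with a TV-denoised gradient step, and a monotone
safeguard falls back to a plain IST step whenever the two-step update
would increase the objective. The proximal TV step is a Chambolle-type
dual projection extended to 3-D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_model import MeasuredSignal, VolumeGrid, VolumeImage
from .encoder_sim import CalibrationDictionary
from .forward import residual_norm

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "tv_norm",
    "tv_denoise",
    "objective",
    "twist_reconstruct",
    "lambda_sweep",
    "suggest_lambda",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Solver settings.

    lam:
        Regularization weight; trades data fidelity against TV
        smoothness. Its scale refers to the column-normalized
        dictionary (normalization happens inside the solver).
    max_iter, tol:
        Outer iteration cap and relative objective-change stopping
        threshold.
    tv_inner_iter:
        Chambolle dual-projection iterations per proximal step.
    xi:
        Assumed smallest-to-largest squared-singular-value ratio of the
        normalized dictionary, from which the two-step parameters are
        derived; the monotone safeguard makes the solver robust to a
        poor guess.
    nonneg:
        Project each iterate onto x >= 0 (photoacoustic sources are
        nonnegative initial pressures).
    """

    lam: float = 0.0
    max_iter: int = 200
    tol: float = 1e-4
    tv_inner_iter: int = 10
    xi: float = 1e-2
    nonneg: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not (0 < self.xi <= 1):
            raise ValueError("xi must be in (0, 1]")


@dataclass
class ReconstructionResult:
    """Solution of one reconstruction."""

    values: np.ndarray
    grid: Optional[VolumeGrid]
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def image(self) -> VolumeImage:
        if self.grid is None:
            raise ValueError("no grid attached to this reconstruction")
        return VolumeImage(self.values, self.grid)


# ---------------------------------------------------------------------------
# total variation
# ---------------------------------------------------------------------------

def _as_volume(image) -> np.ndarray:
    if isinstance(image, VolumeImage):
        return image.as_array()
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D array or VolumeImage")
    return arr


def _grad(u: np.ndarray):
    """Forward differences with replicate boundary (last difference 0)."""
    gz = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx = np.zeros_like(u)
    gz[:-1, :, :] = u[1:, :, :] - u[:-1, :, :]
    gy[:, :-1, :] = u[:, 1:, :] - u[:, :-1, :]
    gx[:, :, :-1] = u[:, :, 1:] - u[:, :, :-1]
    return gz, gy, gx


def _div(pz: np.ndarray, py: np.ndarray, px: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_grad` (so <grad u, p> = -<u, div p>)."""
    d = np.zeros_like(pz)
    if d.shape[0] > 1:
        d[0, :, :] += pz[0, :, :]
        d[1:-1, :, :] += pz[1:-1, :, :] - pz[:-2, :, :]
        d[-1, :, :] += -pz[-2, :, :]
    if d.shape[1] > 1:
        d[:, 0, :] += py[:, 0, :]
        d[:, 1:-1, :] += py[:, 1:-1, :] - py[:, :-2, :]
        d[:, -1, :] += -py[:, -2, :]
    if d.shape[2] > 1:
        d[:, :, 0] += px[:, :, 0]
        d[:, :, 1:-1] += px[:, :, 1:-1] - px[:, :, :-2]
        d[:, :, -1] += -px[:, :, -2]
    return d


def tv_norm(image) -> float:
    """Isotropic 3-D total variation.

    Sum over voxels of ``sqrt(dx^2 + dy^2 + dz^2)`` with forward
    differences and replicate (Neumann) boundary.
    """
    u = _as_volume(image)
    gz, gy, gx = _grad(u)
    return float(np.sum(np.sqrt(gx**2 + gy**2 + gz**2)))


def tv_denoise(image, lam: float, n_inner: int = 10):
    """Approximate proximal operator of ``lam * TV`` (Chambolle dual projection).

    Minimizes ``1/2 ||u - f||^2 + lam * TV(u)`` with a dual step of
    1/12 (the 3-D stability bound). ``lam = 0`` returns the input.
    Returns the same type as the input (array or VolumeImage).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    f = _as_volume(image)
    if lam == 0 or n_inner == 0:
        out = f.copy()
    else:
        tau = 1.0 / 12.0
        pz = np.zeros_like(f)
        py = np.zeros_like(f)
        px = np.zeros_like(f)
        f_over_lam = f / lam
        for _ in range(n_inner):
            gz, gy, gx = _grad(_div(pz, py, px) - f_over_lam)
            mag = np.sqrt(gx**2 + gy**2 + gz**2)
            denom = 1.0 + tau * mag
            pz = (pz + tau * gz) / denom
            py = (py + tau * gy) / denom
            px = (px + tau * gx) / denom
        out = f - lam * _div(pz, py, px)
    if isinstance(image, VolumeImage):
        return VolumeImage.from_array(out, image.grid)
    return out


# ---------------------------------------------------------------------------
# objective and solver
# ---------------------------------------------------------------------------

def _matrix_and_shape(K, x=None):
    if isinstance(K, CalibrationDictionary):
        g = K.grid
        return K.columns, (g.nz, g.ny, g.nx), g
    A = np.asarray(K, dtype=float)
    if isinstance(x, VolumeImage):
        g = x.grid
        return A, (g.nz, g.ny, g.nx), g
    return A, (1, 1, A.shape[1]), None


def objective(y, K, x, lam: float) -> float:
    """Full objective ``1/2 ||y - K x||^2 + lam * TV(x)``."""
    A, shape, _ = _matrix_and_shape(K, x)
    v = x.values if isinstance(x, VolumeImage) else np.asarray(x, float).ravel()
    return residual_norm(y, A, v) + lam * tv_norm(v.reshape(shape))


def suggest_lambda(y, K, frac: float = 0.05) -> float:
    """Heuristic scale for ``lam``: ``frac * max |K~^T y|`` with unit-norm
    columns, the level at which the regularizer starts competing with the
    strongest data-fit gradient."""
    A, _, _ = _matrix_and_shape(K)
    yv = y.samples if isinstance(y, MeasuredSignal) else np.asarray(y, float).ravel()
    norms = np.linalg.norm(A, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return float(frac * np.max(np.abs((A.T @ yv) / norms)))


def _twist_params(xi: float):
    rho = (1.0 - math.sqrt(xi)) / (1.0 + math.sqrt(xi))
    alpha = 2.0 / (1.0 + math.sqrt(1.0 - rho**2))
    beta = 2.0 * alpha / (1.0 + math.sqrt(xi))
    return alpha, beta


def _spectral_norm_sq(A: np.ndarray, n_iter: int = 30) -> float:
    """Largest squared singular value by deterministic power iteration."""
    v = np.ones(A.shape[1]) / math.sqrt(A.shape[1])
    s = 1.0
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        s = float(np.linalg.norm(w))
        if s == 0.0:
            return 1.0
        v = w / s
    return s


def twist_reconstruct(y, K, cfg: ReconstructionConfig) -> ReconstructionResult:
    """Reconstruct a volume from a single-shot trace.

    The dictionary is column-normalized internally and the stored
    column norms are folded back into the returned intensities, so
    ``cfg.lam`` has a scale independent of the encoder's absolute
    sensitivity. Deterministic: zero initialization, no randomness.
    """
    A_raw, shape, grid = _matrix_and_shape(K)
    yv = y.samples if isinstance(y, MeasuredSignal) else np.asarray(y, float).ravel()
    if not np.all(np.isfinite(yv)):
        raise ValueError("y must be finite")
    if yv.size != A_raw.shape[0]:
        raise ValueError(f"y has {yv.size} samples but K has {A_raw.shape[0]} rows")

    norms = np.linalg.norm(A_raw, axis=0)
    safe_norms = np.where(norms > 0, norms, 1.0)
    A = A_raw / safe_norms

    L = max(_spectral_norm_sq(A), 1e-12)
    lam_prox = cfg.lam / L
    alpha, beta = _twist_params(cfg.xi)

    def prox(v: np.ndarray) -> np.ndarray:
        u = tv_denoise(v.reshape(shape), lam_prox, cfg.tv_inner_iter).ravel()
        if cfg.nonneg:
            u = np.maximum(u, 0.0)
        return u

    def fval(v: np.ndarray, Av: np.ndarray) -> float:
        r = yv - Av
        return 0.5 * float(r @ r) + cfg.lam * tv_norm(v.reshape(shape))

    x = np.zeros(A.shape[1])
    Ax = np.zeros(A.shape[0])
    f_cur = fval(x, Ax)
    trace = [f_cur]
    x_prev = None
    Ax_prev = None
    converged = False
    n_iter = 0

    for t in range(cfg.max_iter):
        n_iter = t + 1
        grad = A.T @ (yv - Ax)
        gamma = prox(x + grad / L)
        Agamma = A @ gamma

        restart = False
        if x_prev is not None:
            cand = (1.0 - alpha) * x_prev + (alpha - beta) * x + beta * gamma
            if cfg.nonneg:
                cand = np.maximum(cand, 0.0)
                Acand = A @ cand
            else:
                Acand = (1.0 - alpha) * Ax_prev + (alpha - beta) * Ax + beta * Agamma
            f_cand = fval(cand, Acand)
            if f_cand > f_cur:  # monotone safeguard: plain IST, restart memory
                cand, Acand, f_cand = gamma, Agamma, fval(gamma, Agamma)
                restart = True
        else:
            cand, Acand, f_cand = gamma, Agamma, fval(gamma, Agamma)

        if f_cand > f_cur:
            # even the IST step would increase the objective (inexact prox);
            # keep the current iterate and stop
            converged = True
            break

        x_prev, Ax_prev = (None, None) if restart else (x, Ax)
        rel_change = abs(f_cur - f_cand) / max(f_cur, 1e-300)
        x, Ax, f_cur = cand, Acand, f_cand
        trace.append(f_cur)
        if rel_change < cfg.tol:
            converged = True
            break

    # fold the column norms back into physical intensity units
    x_out = x / safe_norms
    return ReconstructionResult(values=x_out, grid=grid,
                                objective_trace=trace, n_iter=n_iter,
                                converged=converged)


@dataclass
class SweepEntry:
    lam: float
    residual: float
    tv: float
    result: ReconstructionResult


def lambda_sweep(y, K, lam_list, cfg: ReconstructionConfig) -> list:
    """Reconstruct at each regularization weight and report the trade-off.

    Returns one :class:`SweepEntry` per lam with the data-fidelity
    residual and TV of the solution; larger lam gives smoother images
    (lower TV) at the price of a larger residual.
    """
    lams = list(lam_list)
    if not lams:
        raise ValueError("lam_list must be nonempty")
    if any(b < a for a, b in zip(lams, lams[1:])):
        raise ValueError("lam_list must be sorted ascending")
    out = []
    for lam in lams:
        res = twist_reconstruct(y, K, ReconstructionConfig(
            lam=lam, max_iter=cfg.max_iter, tol=cfg.tol,
            tv_inner_iter=cfg.tv_inner_iter, xi=cfg.xi,
            nonneg=cfg.nonneg, seed=cfg.seed))
        A, shape, _ = _matrix_and_shape(K)
        out.append(SweepEntry(
            lam=lam,
            residual=residual_norm(y, A, res.values),
            tv=tv_norm(res.values.reshape(shape)),
            result=res,
        ))
    return out
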