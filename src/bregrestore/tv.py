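"""Discrete total-variation calculus and the Chambolle projection denoiser.

The discrete gradient uses forward differences with Neumann boundaries
(zero difference past the last row/column); the divergence is its exact
negative adjoint, so ``<grad u, p> = -<u, div p>`` holds to machine
precision.  The isotropic TV norm is ``sum_x |grad u(x)|_2``.

``chambolle_denoise`` solves the ROF sub-problem

    min_g  TV(g) + (w / 2) ||g - f||^2

by the dual fixed-point (projection) iteration on a vector field p:

    eta = grad(div p - w f),   p <- (p + tau eta) / (1 + tau |eta|)

with the classical step ``tau = 1/8`` guaranteeing convergence, and output
``g = f - (1/w) div p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .degradation import as_image

__all__ = [
    "VectorField",
    "DenoiseInfo",
    "grad",
    "div",
    "tv_norm",
    "rof_objective",
    "chambolle_denoise",
]


@dataclass
class VectorField:
    """Pixelwise 2-vector field: the two forward-difference components."""

    px: np.ndarray
    py: np.ndarray

    def __post_init__(self):
        self.px = np.asarray(self.px, dtype=float)
        self.py = np.asarray(self.py, dtype=float)
        if self.px.shape != self.py.shape:
            raise ValueError("px and py must share a shape")
        if not (np.all(np.isfinite(self.px)) and np.all(np.isfinite(self.py))):
            raise ValueError("vector field contains non-finite values")

    @classmethod
    def zeros(cls, shape) -> "VectorField":
        return cls(np.zeros(shape), np.zeros(shape))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.px, self.py)


def grad(u: np.ndarray) -> VectorField:
    """Forward-difference gradient with Neumann (zero) last-row/column."""
    u = as_image(u)
    px = np.zeros_like(u)
    py = np.zeros_like(u)
    px[:-1, :] = u[1:, :] - u[:-1, :]
    py[:, :-1] = u[:, 1:] - u[:, :-1]
    return VectorField(px, py)


def div(p: VectorField) -> np.ndarray:
    """Discrete divergence, the exact negative adjoint of :func:`grad`."""
    px, py = p.px, p.py
    out = np.zeros_like(px)
    # backward difference of px along rows, with boundary rows taken one-sided
    out[0, :] += px[0, :]
    out[1:-1, :] += px[1:-1, :] - px[:-2, :]
    out[-1, :] += -px[-2, :]
    out[:, 0] += py[:, 0]
    out[:, 1:-1] += py[:, 1:-1] - py[:, :-2]
    out[:, -1] += -py[:, -2]
    return out


def tv_norm(u: np.ndarray) -> float:
    """Isotropic total variation ``sum_x sqrt(dx^2 + dy^2)``."""
    return float(grad(u).magnitude().sum())


def rof_objective(g: np.ndarray, f: np.ndarray, reg_weight: float) -> float:
    """ROF energy ``TV(g) + (reg_weight/2) ||g - f||^2``."""
    return tv_norm(g) + 0.5 * reg_weight * float(np.sum((g - f) ** 2))


@dataclass
class DenoiseInfo:
    """Run metadata of a projection denoise: convergence flag and histories."""

    converged: bool
    iterations: int
    energy_history: list[float] = field(default_factory=list)


def chambolle_denoise(
    f: np.ndarray,
    reg_weight: float,
    step: float = 0.125,
    tol: float = 1e-4,
    max_iter: int = 100,
    full_output: bool = False,
    p0: VectorField | None = None,
):
    """TV denoising by Chambolle's dual projection iteration.

    Parameters
    ----------
    f : 2-D array
        Noisy input image.
    reg_weight : float
        Fidelity weight ``w`` in ``TV(g) + (w/2)||g - f||^2``; larger values
        keep the output closer to ``f``.
    step : float
        Dual step size; must not exceed 1/8, the classical sufficient
        condition for convergence of the projection iteration.
    tol : float
        Stop when the max-norm of the dual-variable update falls below this.
    max_iter : int
        Iteration cap; hitting it flags ``converged=False`` in the info.
    full_output : bool
        If true, return ``(g, DenoiseInfo)`` with the per-iteration ROF
        energy history; otherwise just ``g``.
    p0 : VectorField, optional
        Warm-start dual variable; defaults to zero for reproducibility.
    """
    f = as_image(f)
    if reg_weight <= 0:
        raise ValueError(f"reg_weight must be positive, got {reg_weight}")
    if step <= 0 or step > 0.125:
        raise ValueError(f"step must lie in (0, 1/8], got {step}")

    p = VectorField.zeros(f.shape) if p0 is None else VectorField(p0.px.copy(), p0.py.copy())
    inv_w = 1.0 / reg_weight
    converged = False
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = grad(div(p) - f * reg_weight)
        denom = 1.0 + step * eta.magnitude()
        px_new = (p.px + step * eta.px) / denom
        py_new = (p.py + step * eta.py) / denom
        delta = max(
            np.abs(px_new - p.px).max(initial=0.0),
            np.abs(py_new - p.py).max(initial=0.0),
        )
        p = VectorField(px_new, py_new)
        if full_output:
            history.append(rof_objective(f - inv_w * div(p), f, reg_weight))
        if delta < tol:
            converged = True
            break

    g = f - inv_w * div(p)
    if full_output:
        return g, DenoiseInfo(converged=converged, iterations=it, energy_history=history)
    return g
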