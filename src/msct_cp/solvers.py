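"""Preconditioned fixed-point iterations for material decomposition.

All solvers are instances of the generic update

    X_{k+1} = X_k - omega * Q_k H'[X_k]* (H(X_k) - Y_H),

optionally alternated with the orthogonal projection onto the nonnegative
cone.  The four variants differ in the preconditioner Q_k:

* ``landweber``     — Q_k = identity (plain nonlinear gradient descent);
* ``gauss_newton``  — Q_k = (H'[X_k]* H'[X_k])^{-1}, assembled densely;
  a small-scale baseline only (guarded at Nx*M <= 4096);
* ``cp_full``       — channel preconditioning with the exact per-ray
  Jacobian: X_{k+1} = X_k - omega * A^T pinv(Phi'[A X_k])(H(X_k) - Y_H);
* ``cp_fast``       — derivative-free: the per-ray Jacobian is frozen at
  zero, pinv(Phi'[0]) R = -R (U^+)^T, so the update needs only one forward
  evaluation per step:  X_{k+1} = X_k + omega * A^T (H(X_k) - Y_H) (U^+)^T.

The sign of the cp_fast update carries the minus of Phi'[0] = -(.)U^T; this
makes its first step from X_0 = 0 coincide with cp_full's and makes the
update a descent direction for D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .derivatives import (
    ChannelMatrix,
    build_channel_matrix,
    channel_precondition,
    gradient_D,
    _ray_jacobians,
    _ray_state,
)
from .forward import forward_H, lsq_objective, _image_values
from .model import SpectralModel
from .projector import ProjectorPair, adjoint_multichannel, apply_multichannel

VARIANTS = ("landweber", "gauss_newton", "cp_full", "cp_fast")

GAUSS_NEWTON_MAX_UNKNOWNS = 4096

__all__ = [
    "SolverConfig",
    "SolverTrace",
    "DivergenceError",
    "project_nonnegative",
    "landweber_step",
    "gauss_newton_step",
    "cp_full_step",
    "cp_fast_step",
    "auto_step_size",
    "step_cost_estimate",
    "run_solver",
]


class DivergenceError(RuntimeError):
    """Iteration produced a non-finite or exploding iterate.

    Carries the partial ``trace`` accumulated before the abort; try a
    smaller step size.
    """

    def __init__(self, msg: str, trace: "SolverTrace" = None):
        super().__init__(msg)
        self.trace = trace


@dataclass
class SolverConfig:
    """Configuration of one reconstruction run (also the config-file schema)."""

    variant: str = "cp_fast"
    step_size: object = "auto"  # positive float, or "auto" for 1/norm estimate
    max_iterations: int = 500
    positivity: bool = True
    stop_tolerance: float = 1e-6
    seed: int = 0
    track_error_against: Optional[np.ndarray] = None
    backtracking: bool = False
    store_iterates: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.step_size != "auto":
            self.step_size = float(self.step_size)
            if self.step_size <= 0:
                raise ValueError("step_size must be positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.track_error_against is not None:
            self.track_error_against = _image_values(self.track_error_against)


@dataclass
class SolverTrace:
    """Per-iteration history of a solver run.

    Entry k corresponds to iterate X_{k+1} (the state after update k+1).
    ``best_index`` selects the iterate with minimal relative error when a
    ground truth was supplied, else with minimal objective.
    """

    objective: list = field(default_factory=list)
    rel_error: Optional[list] = None
    step_sizes: list = field(default_factory=list)
    iterates: Optional[list] = None
    best_index: int = -1
    best_iterate: Optional[np.ndarray] = None
    omega: float = np.nan
    converged: bool = False

    def __len__(self) -> int:
        return len(self.objective)

    def to_dataframe(self):
        import pandas as pd

        d = {
            "iteration": np.arange(1, len(self.objective) + 1),
            "objective": self.objective,
            "step_size": self.step_sizes,
        }
        if self.rel_error is not None:
            d["rel_error"] = self.rel_error
        return pd.DataFrame(d)


def project_nonnegative(X: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the cone of nonnegative images."""
    return np.maximum(_image_values(X), 0.0)


def _residual(model, P, X, Y_H):
    return forward_H(model, P, X) - Y_H


def landweber_step(X, model, P, Y_H, omega: float) -> np.ndarray:
    """One gradient step with identity preconditioner."""
    X = _image_values(X)
    X_new = X - omega * gradient_D(model, P, X, Y_H)
    if not np.all(np.isfinite(X_new)):
        raise DivergenceError("non-finite Landweber iterate; reduce the step size")
    return X_new


def _dense_normal_operator(model, P: ProjectorPair, X) -> np.ndarray:
    """Dense (Nx*M)^2 matrix of H'[X]* H'[X], material-major ordering."""
    m, Pv, Fv = _ray_state(model, apply_multichannel(P, _image_values(X)))
    J = _ray_jacobians(m, Pv, Fv)  # (Ny, B, M)
    G = np.einsum("ibm,ibn->imn", J, J)  # (Ny, M, M)
    A = P.matrix.toarray()
    Nx, M = P.geometry.n_pixels, model.n_materials
    N = np.empty((M * Nx, M * Nx))
    for a in range(M):
        for b in range(a, M):
            blk = A.T @ (G[:, a, b][:, None] * A)
            N[a * Nx:(a + 1) * Nx, b * Nx:(b + 1) * Nx] = blk
            if b != a:
                N[b * Nx:(b + 1) * Nx, a * Nx:(a + 1) * Nx] = blk.T
    return N


def gauss_newton_step(X, model, P, Y_H, omega: float = 1.0) -> np.ndarray:
    """One damped Gauss-Newton update via dense normal-equation assembly.

    Small-scale baseline: refuses problems with more than
    ``GAUSS_NEWTON_MAX_UNKNOWNS`` unknowns.
    """
    X = _image_values(X)
    Nx, M = X.shape
    if Nx * M > GAUSS_NEWTON_MAX_UNKNOWNS:
        raise ValueError(
            f"Gauss-Newton baseline limited to {GAUSS_NEWTON_MAX_UNKNOWNS} "
            f"unknowns; got {Nx * M}"
        )
    g = gradient_D(model, P, X, Y_H)
    N = _dense_normal_operator(model, P, X)
    try:
        delta = np.linalg.solve(N, g.T.reshape(-1))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular Gauss-Newton normal operator: {e}")
    return X - omega * delta.reshape(M, Nx).T


def cp_full_step(X, model, P, Y_H, omega: float) -> np.ndarray:
    """Channel-preconditioned gradient step with the exact per-ray Jacobian."""
    X = _image_values(X)
    Z = apply_multichannel(P, X)
    R = forward_H(model, P, X) - Y_H
    zeta = channel_precondition(model, Z, R)
    X_new = X - omega * adjoint_multichannel(P, zeta)
    if not np.all(np.isfinite(X_new)):
        raise DivergenceError("non-finite cp_full iterate; reduce the step size")
    return X_new


def cp_fast_step(X, model, P, Y_H, omega: float, C: ChannelMatrix) -> np.ndarray:
    """Derivative-free channel-preconditioned step.

    Uses the zero linearization's pseudoinverse, computed once before the
    iteration: pinv(Phi'[0]) R = -R (U^+)^T, hence the plus sign.
    """
    X = _image_values(X)
    R = forward_H(model, P, X) - Y_H
    X_new = X + omega * adjoint_multichannel(P, R @ C.pinv.T)
    if not np.all(np.isfinite(X_new)):
        raise DivergenceError("non-finite cp_fast iterate; reduce the step size")
    return X_new


def step_cost_estimate(variant: str, geometry, model: SpectralModel) -> float:
    """Floating-point operation count proxy for one iterative update.

    Counts the dominant dense work (the sparse Radon products are common to
    all variants and omitted): every variant evaluates the forward model
    once per step (Ny*E*(M+B) flops); cp_full additionally assembles per-ray
    B x M Jacobians and solves Ny small M x M normal systems; gauss_newton
    assembles and solves a dense (Nx*M)^2 system.
    """
    Ny, Nx = geometry.n_rays, geometry.n_pixels
    E, M, B = model.n_energies, model.n_materials, model.n_bins
    forward = Ny * E * (M + B)
    if variant == "cp_fast":
        return forward + Ny * B * M
    if variant == "landweber":
        return 2 * forward + Ny * B * M
    if variant == "cp_full":
        return 2 * forward + Ny * (B * E * M + B * M * M + M**3)
    if variant == "gauss_newton":
        return 2 * forward + Ny * (B * E * M) + M * M * Ny * Nx + (Nx * M) ** 3 / 3
    raise ValueError(f"unknown variant {variant!r}")


def _power_iteration(op, shape, n_iter: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape)
    x /= np.linalg.norm(x)
    rho = 0.0
    for _ in range(n_iter):
        z = op(x)
        nz = np.linalg.norm(z)
        if nz == 0.0:
            raise RuntimeError("power iteration failed to grow: zero operator")
        x = z / nz
        rho = nz
    return float(rho)


def auto_step_size(
    model: SpectralModel,
    P: ProjectorPair,
    C: Optional[ChannelMatrix],
    variant: str,
    *,
    n_iter: int = 50,
    seed: int = 0,
) -> float:
    """Step size omega = 1 / rho with rho a power-iteration estimate of the
    spectral norm of the preconditioned linearized normal operator at X = 0.

    * landweber: xi -> A^T (A xi U^T U), so rho ~ ||A||^2 ||U||^2;
    * cp_full / cp_fast: the channel part cancels at zero (pinv(Phi'[0])
      Phi'[0] = id), leaving xi -> A^T A xi per channel, rho ~ ||A||^2;
    * gauss_newton: the preconditioner is the full inverse, omega = 1.
    """
    if variant == "gauss_newton":
        return 1.0
    if C is None:
        C = build_channel_matrix(model)
    M = model.n_materials
    shape = (P.geometry.n_pixels, M)
    UtU = C.U.T @ C.U

    if variant == "landweber":
        def op(xi):
            return adjoint_multichannel(P, apply_multichannel(P, xi) @ UtU)
    elif variant in ("cp_full", "cp_fast"):
        def op(xi):
            return adjoint_multichannel(P, apply_multichannel(P, xi))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    rho = _power_iteration(op, shape, n_iter, seed)
    return 1.0 / rho


def run_solver(
    model: SpectralModel,
    P: ProjectorPair,
    Y_H: np.ndarray,
    config: SolverConfig,
    X0: Optional[np.ndarray] = None,
):
    """Iterate a solver variant to reconstruct material images from log data.

    Returns ``(X_final, trace)``; the best iterate (minimal relative error if
    a ground truth is tracked, else minimal objective) is stored on the
    trace.  Fully deterministic given the configuration.
    """
    Y_H = np.asarray(Y_H, dtype=float)
    Nx, M = P.geometry.n_pixels, model.n_materials
    X = np.zeros((Nx, M)) if X0 is None else _image_values(X0).copy()
    if X.shape != (Nx, M):
        raise ValueError(f"X0 must have shape ({Nx}, {M}), got {X.shape}")

    C = build_channel_matrix(model)
    if config.step_size == "auto":
        omega = auto_step_size(model, P, C, config.variant, seed=config.seed)
    else:
        omega = float(config.step_size)

    trace = SolverTrace(
        rel_error=[] if config.track_error_against is not None else None,
        iterates=[] if config.store_iterates else None,
        omega=omega,
    )
    truth = config.track_error_against
    truth_norm = np.linalg.norm(truth) if truth is not None else None

    def do_step(Xk, w):
        if config.variant == "landweber":
            return landweber_step(Xk, model, P, Y_H, w)
        if config.variant == "gauss_newton":
            return gauss_newton_step(Xk, model, P, Y_H, w)
        if config.variant == "cp_full":
            return cp_full_step(Xk, model, P, Y_H, w)
        return cp_fast_step(Xk, model, P, Y_H, w, C)

    D_prev = lsq_objective(model, P, X, Y_H)
    D_init = max(D_prev, np.finfo(float).tiny)
    best_score = np.inf

    for k in range(config.max_iterations):
        w = omega
        X_new = do_step(X, w)
        if config.positivity:
            X_new = project_nonnegative(X_new)
        D_new = lsq_objective(model, P, X_new, Y_H)
        if config.backtracking:
            n_half = 0
            while D_new > D_prev and n_half < 20:
                w *= 0.5
                n_half += 1
                X_new = do_step(X, w)
                if config.positivity:
                    X_new = project_nonnegative(X_new)
                D_new = lsq_objective(model, P, X_new, Y_H)
            if D_new > D_prev:  # no descent found: reject, stay put
                X_new, D_new, w = X, D_prev, 0.0

        trace.objective.append(D_new)
        trace.step_sizes.append(w)
        if truth is not None:
            err = float(np.linalg.norm(X_new - truth) / truth_norm)
            trace.rel_error.append(err)
            score = err
        else:
            score = D_new
        if config.store_iterates:
            trace.iterates.append(X_new.copy())
        if score < best_score:
            best_score = score
            trace.best_index = k
            trace.best_iterate = X_new.copy()

        if not np.isfinite(D_new) or D_new > 1e6 * D_init:
            raise DivergenceError(
                f"objective exploded at iteration {k + 1} "
                f"(D={D_new:.3e} vs initial {D_init:.3e}); reduce the step size",
                trace=trace,
            )
        diff = np.linalg.norm(X_new - X)
        denom = np.linalg.norm(X)
        change = diff / denom if denom > 0 else (0.0 if diff == 0 else np.inf)
        X = X_new
        D_prev = D_new
        if change < config.stop_tolerance:
            trace.converged = True
            break

    return X, trace
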