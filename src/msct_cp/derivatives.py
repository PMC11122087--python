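"""Derivative calculus of the logarithmic forward model.

The model factorizes as H(X) = Phi(A X): a high-dimensional, ill-posed but
*linear* Radon part A acting on pixels, and a small, well-posed but
*nonlinear* channel map Phi acting independently on every ray.  All
derivatives inherit this structure:

    H'[X](xi)   = Phi'[A X](A xi)
    H'[X]*(eta) = A^T Phi'[A X]*(eta)
    grad D[X]   = H'[X]*(H(X) - Y_H)

Per ray i, Phi'[Z] is a small (B x M) Jacobian

    J_i[b, m] = - sum_e Sbar[b,e] P_i[e] M[e,m] / F_i[b],

with P_i = exp(-Z_i M^T) the ray's virtual energy transmission and
F_i = P_i Sbar^T its bin response.  At Z = 0 every J_i collapses to -U with
U[b, m] = <S_b, M_m> / <S_b, 1>, the matrix of spectrum-weighted mean
attenuations (zero linearization).

Channel preconditioning inverts only this per-ray mixing: Ny independent
M x M solves, never one coupled (Nx*M) x (Nx*M) system, so its cost is
linear in the number of rays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward import _guarded_exp, forward_H
from .model import SpectralModel
from .projector import ProjectorPair, adjoint_multichannel, apply_multichannel

logger = logging.getLogger(__name__)

#: rays are processed in blocks of this many to keep memory linear in Ny
RAY_BLOCK = 8192

__all__ = [
    "ChannelMatrix",
    "build_channel_matrix",
    "dH_apply",
    "dH_adjoint",
    "gradient_D",
    "dPhi_apply",
    "dPhi_adjoint",
    "channel_precondition",
]


@dataclass(frozen=True)
class ChannelMatrix:
    """Zero linearization U (B x M), its pseudoinverse and condition number."""

    U: np.ndarray
    pinv: np.ndarray  # (M, B), equals (U^T U)^{-1} U^T
    cond: float


def build_channel_matrix(model: SpectralModel, cond_limit: float = 1e12) -> ChannelMatrix:
    """Spectrum-weighted mean attenuations U[b,m] = <S_b, M_m> / <S_b, 1>.

    Requires B >= M and full column rank; a rank-deficient U (identical
    materials or degenerate spectra) raises with the measured condition
    number.
    """
    B, M = model.n_bins, model.n_materials
    if B < M:
        raise ValueError(f"need at least as many bins as materials (B={B} < M={M})")
    U = (model.spectra @ model.attenuations) / model.bin_totals[:, None]
    s = np.linalg.svd(U, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"channel matrix is rank deficient (condition number {cond:.3e}); "
            "materials are spectrally indistinguishable"
        )
    pinv = np.linalg.solve(U.T @ U, U.T)
    return ChannelMatrix(U=U, pinv=pinv, cond=cond)


def _ray_state(model: SpectralModel, Z: np.ndarray):
    """Per-ray transmission P = exp(-Z M^T) and bin response F = P Sbar^T."""
    m = model if model.is_normalized else model.normalized()
    Z = np.asarray(Z, dtype=float)
    P = _guarded_exp(Z @ m.attenuations.T)
    F = P @ m.spectra.T
    if np.any(F <= 0):
        raise FloatingPointError("vanishing bin response; attenuation overflow")
    return m, P, F


def dPhi_apply(model: SpectralModel, Z: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    """Directional derivative Phi'[Z](zeta), shape (Ny, B)."""
    m, P, F = _ray_state(model, Z)
    zeta = np.asarray(zeta, dtype=float)
    return -((P * (zeta @ m.attenuations.T)) @ m.spectra.T) / F


def dPhi_adjoint(model: SpectralModel, Z: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Adjoint Phi'[Z]*(eta), shape (Ny, M)."""
    m, P, F = _ray_state(model, Z)
    eta = np.asarray(eta, dtype=float)
    return -(P * ((eta / F) @ m.spectra)) @ m.attenuations


def dH_apply(model: SpectralModel, P: ProjectorPair, X, xi) -> np.ndarray:
    """Directional derivative H'[X](xi) = Phi'[A X](A xi), shape (Ny, B)."""
    from .forward import _image_values

    Z = apply_multichannel(P, _image_values(X))
    return dPhi_apply(model, Z, apply_multichannel(P, _image_values(xi)))


def dH_adjoint(model: SpectralModel, P: ProjectorPair, X, eta: np.ndarray) -> np.ndarray:
    """Adjoint H'[X]*(eta) = A^T Phi'[A X]*(eta), shape (Nx, M)."""
    from .forward import _image_values

    Z = apply_multichannel(P, _image_values(X))
    return adjoint_multichannel(P, dPhi_adjoint(model, Z, eta))


def gradient_D(model: SpectralModel, P: ProjectorPair, X, Y_H: np.ndarray) -> np.ndarray:
    """Gradient of the LSQ functional: H'[X]*(H(X) - Y_H), shape (Nx, M)."""
    R = forward_H(model, P, X) - np.asarray(Y_H, dtype=float)
    return dH_adjoint(model, P, X, R)


def _ray_jacobians(m: SpectralModel, P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Stack of per-ray Jacobians of Phi, shape (n_rays, B, M)."""
    # J[i,b,m] = -(sum_e Sbar[b,e] P[i,e] M[e,m]) / F[i,b]
    J = (P[:, None, :] * m.spectra[None, :, :]) @ m.attenuations
    J /= F[:, :, None]
    return -J


def channel_precondition(
    model: SpectralModel,
    Z: np.ndarray,
    R: np.ndarray,
    *,
    cond_limit: float = 1e12,
    damping: bool = False,
) -> np.ndarray:
    """Apply the pseudoinverse of the channel map: (Phi'[Z]* Phi'[Z])^{-1} Phi'[Z]*(R).

    Solves Ny independent M x M normal systems (one per ray), blocked so no
    intermediate exceeds O(Ny * B * E) memory.  Rays whose normal matrix has
    a condition number above ``cond_limit`` raise by default; with
    ``damping=True`` a diagonal shift of ``1e-10 * trace/M`` is added for
    those rays instead (count logged).

    Note Phi'[Z] carries a minus sign (attenuation decreases the response),
    so at Z = 0 this map reduces to R -> -R (U^+)^T.
    """
    m, P, F = _ray_state(model, Z)
    R = np.asarray(R, dtype=float)
    n_rays, M = Z.shape[0], m.n_materials
    if R.shape != (n_rays, m.n_bins):
        raise ValueError(f"expected residual of shape ({n_rays}, {m.n_bins}), got {R.shape}")
    out = np.empty((n_rays, M))
    n_damped = 0
    for lo in range(0, n_rays, RAY_BLOCK):
        hi = min(lo + RAY_BLOCK, n_rays)
        J = _ray_jacobians(m, P[lo:hi], F[lo:hi])
        G = np.einsum("ibm,ibn->imn", J, J)
        rhs = np.einsum("ibm,ib->im", J, R[lo:hi])
        ev = np.linalg.eigvalsh(G)
        with np.errstate(divide="ignore", invalid="ignore"):
            conds = ev[:, -1] / ev[:, 0]
        bad = ~np.isfinite(conds) | (conds > cond_limit)
        if np.any(bad):
            if not damping:
                raise np.linalg.LinAlgError(
                    f"{int(bad.sum())} ray(s) have ill-conditioned channel "
                    f"normal matrices (limit {cond_limit:g})"
                )
            n_damped += int(bad.sum())
            tr = np.trace(G[bad], axis1=1, axis2=2) / M
            G[bad] += (1e-10 * tr)[:, None, None] * np.eye(M)[None]
        out[lo:hi] = np.linalg.solve(G, rhs[:, :, None])[:, :, 0]
    if n_damped:
        logger.warning("damped %d ill-conditioned per-ray channel solves", n_damped)
    return out
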