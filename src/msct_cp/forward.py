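"""The nonlinear polychromatic forward model and its logarithmic form.

For a material image X (Nx x M) the detector model is

    F(X) = exp(-A X M^T) S^T          (Ny x B)

where A is the Radon matrix, M the (E x M) attenuation table and S the
(B x E) effective spectra.  Reconstruction works with the recalibrated
logarithmic model H(X) = log(F(X) / F(0)), which equals F under row-
normalized spectra followed by the pointwise logarithm, and with the least
squares functional D(X) = ||H(X) - Y_H||^2 / 2.  H factorizes as
H(X) = Phi(A X) where Phi acts ray-by-ray on the material sinogram only.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import MaterialImage, SpectralModel
from .projector import ProjectorPair, apply_multichannel

logger = logging.getLogger(__name__)

#: exponent clip threshold guarding exp() overflow
EXP_CLIP = 700.0

__all__ = [
    "forward_F",
    "forward_H",
    "normalize_spectra",
    "lsq_objective",
    "log_rescale_data",
    "phi_apply",
    "virtual_spectral_data",
    "F_zero_row",
]


def _image_values(X) -> np.ndarray:
    if isinstance(X, MaterialImage):
        return X.values
    return np.asarray(X, dtype=float)


def _guarded_exp(T: np.ndarray) -> np.ndarray:
    """exp(-T) with the exponent clipped at +/-EXP_CLIP (counted and logged)."""
    n_clip = int(np.count_nonzero(np.abs(T) > EXP_CLIP))
    if n_clip:
        logger.warning("clipped %d exponent entries at |%g|", n_clip, EXP_CLIP)
        T = np.clip(T, -EXP_CLIP, EXP_CLIP)
    return np.exp(-T)


def normalize_spectra(model: SpectralModel) -> SpectralModel:
    """Row-normalize the effective spectra to unit sum.

    Recalibration: dividing measurements by the zero-object measurement F(0)
    is the same as evaluating F with normalized spectra.
    """
    return model.normalized()


def F_zero_row(model: SpectralModel) -> np.ndarray:
    """One row of F(0): the bin totals (<S_1,1>, ..., <S_B,1>), shape (B,)."""
    return model.bin_totals


def forward_F(model: SpectralModel, P: ProjectorPair, X) -> np.ndarray:
    """Evaluate the detector model F(X) = exp(-A X M^T) S^T, shape (Ny, B)."""
    Z = apply_multichannel(P, _image_values(X))
    return _spectral_transmission(model, Z)


def _spectral_transmission(model: SpectralModel, Z: np.ndarray) -> np.ndarray:
    """exp(-Z M^T) S^T for a material sinogram Z (Ny, M) -> (Ny, B)."""
    T = Z @ model.attenuations.T
    out = _guarded_exp(T) @ model.spectra.T
    if not np.all(np.isfinite(out)):
        bad = np.flatnonzero(~np.all(np.isfinite(out), axis=1))
        raise FloatingPointError(
            f"non-finite forward model output at ray(s) {bad[:10].tolist()}"
        )
    return out


def forward_H(model: SpectralModel, P: ProjectorPair, X) -> np.ndarray:
    """Logarithmic forward model H(X) = log(F(X) / F(0)), shape (Ny, B).

    Evaluated with normalized spectra so that H(0) = 0 exactly.
    """
    Z = apply_multichannel(P, _image_values(X))
    return phi_apply(model, Z)


def phi_apply(model: SpectralModel, Z: np.ndarray) -> np.ndarray:
    """Channel nonlinearity Phi(Z) = log(exp(-Z M^T) Sbar^T), ray-wise.

    Satisfies H(X) = Phi(A X) exactly.  Computed as log F - log F(0) with
    F(0) evaluated by the same matrix product as F, so Phi(0) is exactly
    zero regardless of the spectra's normalization.
    """
    Z = np.asarray(Z, dtype=float)
    F = _spectral_transmission(model, Z)
    F0 = np.ones((1, model.n_energies)) @ model.spectra.T
    out = np.log(F) - np.log(F0)
    # a zero sinogram row has Phi = log(F0/F0) = 0 analytically; pin it so
    # Phi(0) = 0 holds exactly despite differing BLAS summation orders
    zero_rows = ~Z.any(axis=1)
    if zero_rows.any():
        out[zero_rows] = 0.0
    return out


def lsq_objective(model: SpectralModel, P: ProjectorPair, X, Y_H: np.ndarray) -> float:
    """Least squares data fit D(X) = ||H(X) - Y_H||_F^2 / 2."""
    Y_H = np.asarray(Y_H, dtype=float)
    R = forward_H(model, P, X)
    if R.shape != Y_H.shape:
        raise ValueError(f"shape mismatch: H(X) is {R.shape}, Y_H is {Y_H.shape}")
    R = R - Y_H
    return 0.5 * float(np.vdot(R, R).real)


def log_rescale_data(model: SpectralModel, Y: np.ndarray) -> np.ndarray:
    """Recalibrate measured data: Y_H = log(Y / F(0)), shape (Ny, B).

    Nonpositive entries (possible under Poisson noise) are floored at
    ``1e-12 * min_b <S_b, 1>``; the floored count is logged.  An error is
    raised only if flooring cannot produce positive entries.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != model.n_bins:
        raise ValueError(f"expected (Ny, {model.n_bins}) data, got {Y.shape}")
    floor = 1e-12 * float(model.bin_totals.min())
    if floor <= 0:
        raise ValueError("cannot floor data: spectra have zero total weight")
    n_floored = int(np.count_nonzero(Y < floor))
    if n_floored:
        logger.warning("floored %d nonpositive data entries at %g", n_floored, floor)
        Y = np.maximum(Y, floor)
    return np.log(Y / model.bin_totals[None, :])


def virtual_spectral_data(model: SpectralModel, P: ProjectorPair, X) -> np.ndarray:
    """Virtual spectrally resolved data Q_X = exp(-M (A X)^T), shape (E, Ny).

    Entries lie in (0, 1] whenever A X and the attenuations are nonnegative.
    """
    Z = apply_multichannel(P, _image_values(X))
    return _guarded_exp(model.attenuations @ Z.T)
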