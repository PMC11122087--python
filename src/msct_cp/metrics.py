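"""Reconstruction quality metrics."""

from __future__ import annotations

import numpy as np

from .forward import _image_values

__all__ = ["relative_error"]


def relative_error(X, X_star, per_material: bool = False):
    """Relative L2 reconstruction error ||X - X*|| / ||X*||.

    With ``per_material`` the error is reported per channel (each channel
    normalized by its own ground-truth norm).
    """
    X = _image_values(X)
    X_star = _image_values(X_star)
    if X.shape != X_star.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_star.shape}")
    if per_material:
        norms = np.linalg.norm(X_star, axis=0)
        if np.any(norms == 0):
            raise ValueError("a ground-truth channel has zero norm")
        return list(np.linalg.norm(X - X_star, axis=0) / norms)
    n = np.linalg.norm(X_star)
    if n == 0:
        raise ValueError("ground truth has zero norm")
    return float(np.linalg.norm(X - X_star) / n)
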