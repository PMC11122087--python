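"""Discrete parallel-beam Radon transform with an exactly matched adjoint.

The system matrix ``A`` is assembled explicitly as a sparse matrix whose
entries are the exact intersection lengths of each ray with each pixel
(Siddon-style ray tracing).  The adjoint is the literal transpose, so the
matched-pair identity ``<A x, y> = <x, A^T y>`` holds to machine precision —
a requirement for the derivative calculus built on top of it.  Unmatched
third-party backprojectors are deliberately not used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import Geometry

__all__ = ["ProjectorPair", "build_projector", "apply_multichannel", "adjoint_multichannel"]


@dataclass(frozen=True)
class ProjectorPair:
    """The discretized Radon transform A and its exact transpose.

    ``matrix`` has shape (Ny, Nx) with Ny = n_angles * n_detector_bins and
    Nx = n**2; all entries are nonnegative ray-pixel intersection lengths.
    """

    geometry: Geometry
    matrix: sp.csr_matrix

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Forward projection of one flattened image channel (Nx -> Ny)."""
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.size != self.geometry.n_pixels:
            raise ValueError(
                f"expected {self.geometry.n_pixels} pixels, got {x.size}"
            )
        return self.matrix @ x

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """Backprojection of one sinogram channel (Ny -> Nx), exact transpose."""
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.size != self.geometry.n_rays:
            raise ValueError(f"expected {self.geometry.n_rays} rays, got {y.size}")
        return self.matrix.T @ y

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    def norm_estimate(self, n_iter: int = 50, seed: int = 0) -> float:
        """Power-iteration estimate of the spectral norm of A."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.geometry.n_pixels)
        x /= np.linalg.norm(x)
        s = 0.0
        for _ in range(n_iter):
            z = self.adjoint(self.apply(x))
            nz = np.linalg.norm(z)
            if nz == 0.0:
                raise RuntimeError("power iteration hit the null space; zero operator?")
            x = z / nz
            s = nz
        return float(np.sqrt(s))


def _trace_ray(p0x, p0y, dx, dy, n, h):
    """Intersection of one line with the pixel grid [0, n*h]^2.

    The line is p(t) = (p0x, p0y) + t*(dx, dy).  Returns (pixel_indices,
    lengths) with flat index iy*n + ix.
    """
    # slab clipping against the grid bounding box
    tmin, tmax = -np.inf, np.inf
    for p0, d in ((p0x, dx), (p0y, dy)):
        if abs(d) < 1e-14:
            if p0 <= 0.0 or p0 >= n * h:
                return np.empty(0, dtype=np.int64), np.empty(0)
        else:
            t0, t1 = (0.0 - p0) / d, (n * h - p0) / d
            if t0 > t1:
                t0, t1 = t1, t0
            tmin, tmax = max(tmin, t0), min(tmax, t1)
    if not tmax - tmin > 1e-14 * h:
        return np.empty(0, dtype=np.int64), np.empty(0)

    crossings = [np.array([tmin, tmax])]
    for p0, d in ((p0x, dx), (p0y, dy)):
        if abs(d) >= 1e-14:
            t = (np.arange(1, n) * h - p0) / d
            crossings.append(t[(t > tmin) & (t < tmax)])
    ts = np.unique(np.concatenate(crossings))
    lengths = np.diff(ts)
    keep = lengths > 1e-12 * h
    if not np.any(keep):
        return np.empty(0, dtype=np.int64), np.empty(0)
    tmid = 0.5 * (ts[:-1] + ts[1:])[keep]
    lengths = lengths[keep]
    ix = np.clip(np.floor((p0x + tmid * dx) / h).astype(np.int64), 0, n - 1)
    iy = np.clip(np.floor((p0y + tmid * dy) / h).astype(np.int64), 0, n - 1)
    return iy * n + ix, lengths


def build_projector(geometry: Geometry) -> ProjectorPair:
    """Assemble the sparse Radon matrix for a parallel-beam geometry.

    Each ray ``(theta, r)`` has unit normal ``(cos theta, sin theta)`` at
    signed distance ``r`` from the image center and direction
    ``(-sin theta, cos theta)``.  Rays are ordered angle-major: row
    ``a * n_detector_bins + b``.  Deterministic given the geometry.
    """
    n = geometry.n_pixels_side
    h = geometry.pixel_size
    cx = cy = 0.5 * n * h
    offsets = geometry.detector_offsets
    rows, cols, vals = [], [], []
    for a, theta in enumerate(geometry.angles):
        nx_, ny_ = np.cos(theta), np.sin(theta)
        dx, dy = -ny_, nx_
        base = a * geometry.n_detector_bins
        for b, r in enumerate(offsets):
            idx, lens = _trace_ray(cx + r * nx_, cy + r * ny_, dx, dy, n, h)
            if idx.size:
                rows.append(np.full(idx.size, base + b, dtype=np.int64))
                cols.append(idx)
                vals.append(lens)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:  # pragma: no cover - geometry validation should prevent this
        rows = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    A = sp.csr_matrix(
        (vals, (rows, cols)), shape=(geometry.n_rays, geometry.n_pixels)
    )
    return ProjectorPair(geometry=geometry, matrix=A)


def apply_multichannel(P: ProjectorPair, X: np.ndarray) -> np.ndarray:
    """A applied per material channel: (Nx, M) -> (Ny, M)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != P.geometry.n_pixels:
        raise ValueError(
            f"expected shape ({P.geometry.n_pixels}, M), got {X.shape}"
        )
    return P.matrix @ X


def adjoint_multichannel(P: ProjectorPair, Z: np.ndarray) -> np.ndarray:
    """A^T applied per channel: (Ny, M) -> (Nx, M)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != P.geometry.n_rays:
        raise ValueError(f"expected shape ({P.geometry.n_rays}, M), got {Z.shape}")
    return P.matrix.T @ Z
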