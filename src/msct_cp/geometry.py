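"""Parallel-beam acquisition geometry.

The image is an ``n x n`` pixel grid; pixel ``(0, 0)`` sits at the lower-left
corner, pixel centers at half-integer grid coordinates, and all rotations are
about the image center.  A projection line is parametrized by its unit normal
``(cos theta, sin theta)`` and its signed distance ``r`` from the image
center; the detector coordinate ``r`` spans ``[-D/2, D/2]`` where
``D = n_detector_bins * detector_spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam geometry: image raster plus the set of projection lines.

    Parameters
    ----------
    n_pixels_side
        Image side length in pixels; the image has ``Nx = n**2`` unknowns
        per channel.
    angles
        Projection angles in radians, strictly increasing, all in ``[0, pi)``.
    n_detector_bins
        Number of detector elements per view; must be at least
        ``n_pixels_side`` so the object fits in the field of view.
    pixel_size
        Pixel edge length in (dimensionless) grid units.
    detector_spacing
        Distance between detector element centers, same units.
    """

    n_pixels_side: int
    angles: tuple = field(default=())
    n_detector_bins: int = 0
    pixel_size: float = 1.0
    detector_spacing: float = 1.0

    def __post_init__(self):
        if self.n_pixels_side < 2:
            raise ValueError("n_pixels_side must be >= 2")
        ang = np.asarray(self.angles, dtype=float)
        if ang.size == 0:
            raise ValueError("angle list must be non-empty")
        if np.any(ang < 0.0) or np.any(ang >= np.pi):
            raise ValueError("angles must lie in [0, pi)")
        if np.any(np.diff(ang) <= 0.0):
            raise ValueError("angles must be strictly increasing")
        if self.n_detector_bins < self.n_pixels_side:
            raise ValueError(
                "n_detector_bins must be >= n_pixels_side so the object "
                "fits in the detector field of view"
            )
        if self.pixel_size <= 0 or self.detector_spacing <= 0:
            raise ValueError("pixel_size and detector_spacing must be positive")
        object.__setattr__(self, "angles", tuple(float(a) for a in ang))

    @property
    def n_pixels(self) -> int:
        """Total pixel count Nx = n**2."""
        return self.n_pixels_side ** 2

    @property
    def n_rays(self) -> int:
        """Total line count Ny = |angles| * n_detector_bins."""
        return len(self.angles) * self.n_detector_bins

    @property
    def detector_offsets(self) -> np.ndarray:
        """Signed detector coordinates r (bin centers), spanning [-D/2, D/2]."""
        nb = self.n_detector_bins
        return (np.arange(nb) - (nb - 1) / 2.0) * self.detector_spacing

    def to_dict(self) -> dict:
        return {
            "n_pixels_side": self.n_pixels_side,
            "angles": list(self.angles),
            "n_detector_bins": self.n_detector_bins,
            "pixel_size": self.pixel_size,
            "detector_spacing": self.detector_spacing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(
            n_pixels_side=int(d["n_pixels_side"]),
            angles=tuple(d["angles"]),
            n_detector_bins=int(d["n_detector_bins"]),
            pixel_size=float(d.get("pixel_size", 1.0)),
            detector_spacing=float(d.get("detector_spacing", 1.0)),
        )


def default_geometry(n: int, *, unit_field_of_view: bool = True) -> Geometry:
    """Standard sampling for an ``n x n`` image.

    Uses ``ceil(pi/2 * n)`` views over ``[0, pi)`` and ``ceil(1.5 * n)``
    detector bins.  With ``unit_field_of_view`` the pixel size is ``1/n`` so
    the image occupies the unit square and line integrals of a unit-density
    object are O(1); otherwise pixels have unit edge length.
    """
    n_angles = int(np.ceil(np.pi / 2 * n))
    n_bins = int(np.ceil(1.5 * n))
    px = 1.0 / n if unit_field_of_view else 1.0
    angles = tuple(np.arange(n_angles) * np.pi / n_angles)
    return Geometry(
        n_pixels_side=n,
        angles=angles,
        n_detector_bins=n_bins,
        pixel_size=px,
        detector_spacing=px,
    )
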