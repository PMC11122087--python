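"""Containers for the spectral quantities and material images.

Conventions (row-major throughout): material images are ``(Nx, M)`` arrays,
multichannel sinograms ``(Ny, M)``, spectral data ``(Ny, B)``, attenuations
``(E, M)`` and effective spectra ``(B, E)``.  Energy integration is a plain
weighted sum over the ``E`` grid nodes — quadrature weights are absorbed into
the tabulated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


@dataclass
class MaterialImage:
    """Material density channels on the pixel grid.

    ``values`` has shape (Nx, M); column m is the flattened density map of
    material m (dimensionless fractions, conceptually in [0, 1] but no upper
    bound is enforced).  ``grid(n)`` reshapes a channel to (n, n) with row j
    counted from the bottom of the image.
    """

    values: np.ndarray
    names: Sequence[str] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MaterialImage.values must be (Nx, M)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MaterialImage contains non-finite entries")
        if not self.names:
            self.names = tuple(f"material_{m}" for m in range(self.values.shape[1]))
        elif len(self.names) != self.values.shape[1]:
            raise ValueError("one name per material channel required")

    @property
    def n_materials(self) -> int:
        return self.values.shape[1]

    def grid(self, n: int, channel: int = 0) -> np.ndarray:
        return self.values[:, channel].reshape(n, n)


@dataclass
class SpectralModel:
    """Discretized spectral quantities of the acquisition.

    energies : (E,) energy grid nodes in keV.
    attenuations : (E, M) per-material mass attenuation sampled on the grid.
    spectra : (B, E) effective spectrum per energy bin (source spectral
        density times detector bin sensitivity, quadrature weights absorbed);
        row b is the spectrum of bin b.
    family : optional parametric generator that produced the tables, kept so
        the same physics can be re-tabulated on a finer grid for
        inverse-crime-avoiding data simulation.
    """

    energies: np.ndarray
    attenuations: np.ndarray
    spectra: np.ndarray
    material_names: Sequence[str] = ()
    family: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float).reshape(-1)
        self.attenuations = np.asarray(self.attenuations, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        E = self.energies.size
        if E < 1:
            raise ValueError("need at least one energy node")
        if self.attenuations.shape[0] != E or self.attenuations.ndim != 2:
            raise ValueError("attenuations must be (E, M)")
        if self.spectra.ndim != 2 or self.spectra.shape[1] != E:
            raise ValueError("spectra must be (B, E)")
        if np.any(self.attenuations < 0) or np.any(self.spectra < 0):
            raise ValueError("attenuations and spectra must be nonnegative")
        if np.any(self.spectra.sum(axis=1) <= 0):
            raise ValueError("every spectrum row must have positive total weight")
        if not self.material_names:
            self.material_names = tuple(
                f"material_{m}" for m in range(self.attenuations.shape[1])
            )

    @property
    def n_energies(self) -> int:
        return self.energies.size

    @property
    def n_materials(self) -> int:
        return self.attenuations.shape[1]

    @property
    def n_bins(self) -> int:
        return self.spectra.shape[0]

    @property
    def bin_totals(self) -> np.ndarray:
        """<S_b, 1>: total weight of each bin's effective spectrum, (B,)."""
        return self.spectra.sum(axis=1)

    @property
    def is_normalized(self) -> bool:
        return bool(np.allclose(self.bin_totals, 1.0, rtol=0, atol=1e-13))

    def normalized(self) -> "SpectralModel":
        """Model with each spectrum row rescaled to unit sum (recalibration)."""
        S = self.spectra / self.bin_totals[:, None]
        return replace(self, spectra=S)
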