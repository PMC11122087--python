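"""Synthetic phantoms, spectra, attenuation curves, and noisy data.

Everything needed to exercise the method without an external dataset.  The
default configuration mirrors a three-material (water / iodine-like /
gadolinium-like contrast agent) acquisition with five energy bins on a
0-150 keV grid.  The attenuation and spectrum curves are parametric
stand-ins with the qualitative structure of the physical tables: a
photoelectric power-law decay plus a Compton floor per material, smoothed
K-edge steps for the contrast agents inside the spectral range, and
bell-shaped bin spectra under a bremsstrahlung-like envelope.

Noisy measurements are simulated with inverse-crime avoidance: the data are
generated from the same parametric physics tabulated on a *finer* energy
grid (default twice as many nodes) than the grid handed to the
reconstruction, then scaled to an expected photon count per ray and bin and
replaced by a Poisson draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .forward import forward_F
from .model import MaterialImage, SpectralModel
from .projector import ProjectorPair

__all__ = [
    "Primitive",
    "PhantomSpec",
    "AcquisitionSpec",
    "SpectralFamily",
    "make_phantom",
    "default_phantom_spec",
    "make_spectral_model",
    "simulate_data",
]

#: energies below this are outside the source window (spectra vanish there)
E_MIN_KEV = 18.0

#: master energy lattice size: curves are sampled once at e_max/N resolution
#: and aggregated into cells, so tabulations at different E share samples and
#: the total weight of every bin is exactly grid-independent
_MASTER_LATTICE = 4800


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Primitive:
    """One ellipse/disk in the unit field of view.

    center, radii are in field-of-view units (the image spans [0, 1]^2);
    ``rotation`` in radians; ``material`` is the channel index; ``density``
    the value written into that channel.
    """

    center: tuple
    radii: tuple
    material: int
    density: float
    rotation: float = 0.0
    kind: str = "ellipse"

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("densities must be nonnegative")
        cx, cy = self.center
        rx, ry = self.radii
        if rx <= 0 or ry <= 0:
            raise ValueError("radii must be positive")
        rmax = max(rx, ry)
        if not (0.0 <= cx - rmax and cx + rmax <= 1.0 and 0.0 <= cy - rmax and cy + rmax <= 1.0):
            raise ValueError("primitive does not fit in the unit field of view")


@dataclass
class PhantomSpec:
    """Grid size plus an ordered list of primitives (later ones win).

    ``supersample`` controls area-weighted rasterization: each pixel value is
    the mean over an s x s sub-grid, so partially covered edge pixels carry
    their coverage fraction (set 1 for binary rasterization).
    """

    n: int
    primitives: Sequence[Primitive] = field(default_factory=tuple)
    background_material: int = 0
    background_density: float = 0.0
    n_materials: int = 3
    jitter: float = 0.0  # optional random jitter of centers, FOV units
    supersample: int = 4


def default_phantom_spec(n: int, n_materials: int = 3) -> PhantomSpec:
    """Three-feature phantom: contrast-agent disks (left, middle) in a water
    ellipse, plus a denser water disk on the right."""
    prims = [
        Primitive(center=(0.5, 0.5), radii=(0.44, 0.38), material=0, density=0.9),
        Primitive(center=(0.30, 0.50), radii=(0.12, 0.12), material=min(1, n_materials - 1), density=1.0),
        Primitive(center=(0.50, 0.50), radii=(0.12, 0.12), material=min(2, n_materials - 1), density=1.0),
        Primitive(center=(0.70, 0.50), radii=(0.12, 0.12), material=0, density=1.0),
    ]
    return PhantomSpec(n=n, primitives=prims, n_materials=n_materials)


def make_phantom(spec: PhantomSpec, seed: int = 0) -> MaterialImage:
    """Rasterize a phantom spec to an (Nx, M) material image.

    A sample point belongs to the last primitive whose ellipse contains it
    (last-wins), so primitives separated by more than a pixel yield channels
    with disjoint support; pixel values are coverage-weighted averages over
    the supersampling grid.  Deterministic given the spec; the seed only
    drives the optional center jitter.
    """
    n, M, ss = spec.n, spec.n_materials, max(int(spec.supersample), 1)
    rng = np.random.default_rng(seed)
    nf = n * ss
    # sample points in field-of-view coordinates
    c = (np.arange(nf) + 0.5) / nf
    gx, gy = np.meshgrid(c, c)  # gy is the row (from the bottom), gx the column
    fine = np.zeros((nf, nf, M))
    if spec.background_density:
        fine[:, :, spec.background_material] = spec.background_density
    for prim in spec.primitives:
        if prim.material >= M:
            raise ValueError(f"material index {prim.material} out of range (M={M})")
        cx, cy = prim.center
        if spec.jitter:
            cx += rng.uniform(-spec.jitter, spec.jitter)
            cy += rng.uniform(-spec.jitter, spec.jitter)
        ct, st = np.cos(prim.rotation), np.sin(prim.rotation)
        u = (gx - cx) * ct + (gy - cy) * st
        v = -(gx - cx) * st + (gy - cy) * ct
        mask = (u / prim.radii[0]) ** 2 + (v / prim.radii[1]) ** 2 <= 1.0
        fine[mask, :] = 0.0
        fine[mask, prim.material] = prim.density
    X = fine.reshape(n, ss, n, ss, M).mean(axis=(1, 3)).reshape(n * n, M)
    return MaterialImage(values=X)


# ---------------------------------------------------------------------------
# spectral curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralFamily:
    """Parametric attenuation curves and bin spectra, tabulable at any E.

    Attenuation of material m:
        mu_m(e) = compton_m + photo_m * (60/e)^p * (1 + jump_m * s((e - edge_m)/w))
    with s a logistic sigmoid (smoothed K-edge of width ``edge_width`` keV).
    Bin b's effective spectrum is a Gaussian bell at ``bin_centers[b]`` under
    a bremsstrahlung-like envelope (e - E_MIN) * exp(-e / 45), zero below
    E_MIN_KEV.
    """

    e_max: float
    compton: tuple
    photo: tuple
    power: tuple
    edge_pos: tuple      # NaN = no K-edge
    edge_jump: tuple
    edge_width: float
    bin_centers: tuple
    bin_sigmas: tuple
    material_names: tuple

    @property
    def n_materials(self) -> int:
        return len(self.compton)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def attenuation(self, e: np.ndarray) -> np.ndarray:
        """mu(e), shape (len(e), M); e in keV.

        The power-law divergence is truncated below 10 keV — outside the
        source window (the spectra vanish below E_MIN_KEV), so the clamp
        only bounds the dynamic range of the exponentials.
        """
        e = np.maximum(np.asarray(e, dtype=float), 10.0)
        out = np.empty(e.shape + (self.n_materials,))
        for m in range(self.n_materials):
            base = self.photo[m] * (60.0 / e) ** self.power[m]
            if np.isfinite(self.edge_pos[m]):
                sig = 1.0 / (1.0 + np.exp(-(e - self.edge_pos[m]) / self.edge_width))
                base = base * (1.0 + self.edge_jump[m] * sig)
            out[..., m] = self.compton[m] + base
        return out

    def spectrum_density(self, e: np.ndarray) -> np.ndarray:
        """s_b(e), shape (B, len(e)); zero below E_MIN_KEV."""
        e = np.asarray(e, dtype=float)
        env = np.where(e > E_MIN_KEV, (e - E_MIN_KEV) / 30.0 * np.exp(-e / 45.0), 0.0)
        out = np.empty((self.n_bins,) + e.shape)
        for b in range(self.n_bins):
            bell = np.exp(-0.5 * ((e - self.bin_centers[b]) / self.bin_sigmas[b]) ** 2)
            out[b] = env * bell
        return out

    def tabulate(self, E: int) -> SpectralModel:
        """Tabulate on E uniform cells covering (0, e_max].

        Node k sits at the center of cell [k, k+1] * e_max / E; the tabulated
        spectrum value is the *integral* of s_b over the cell (quadrature
        weights absorbed) and the attenuation value the cell average of
        mu_m.  Both are aggregated from a fixed fine master lattice, so
        tabulations at different E describe the same physics at different
        fidelity and the total bin weight <S_b, 1> is grid-independent.
        """
        if not 1 <= E <= _MASTER_LATTICE:
            raise ValueError(f"E must be in [1, {_MASTER_LATTICE}]")
        de = self.e_max / E
        nodes = (np.arange(E) + 0.5) * de
        N = _MASTER_LATTICE
        e_fine = (np.arange(N) + 0.5) * (self.e_max / N)
        cell = np.minimum((e_fine // de).astype(np.int64), E - 1)
        counts = np.bincount(cell, minlength=E).astype(float)
        mu = self.attenuation(e_fine)  # (N, M)
        att = np.stack(
            [np.bincount(cell, weights=mu[:, m], minlength=E) / counts
             for m in range(self.n_materials)], axis=1)
        s = self.spectrum_density(e_fine)  # (B, N)
        spectra = np.stack(
            [np.bincount(cell, weights=s[b], minlength=E) * (self.e_max / N)
             for b in range(self.n_bins)], axis=0)
        return SpectralModel(
            energies=nodes,
            attenuations=att,
            spectra=spectra,
            material_names=self.material_names,
            family=self,
        )


_BASE_MATERIALS = [
    # name, compton, photo, power, edge position, edge jump
    ("water", 0.15, 0.25, 2.6, np.nan, 0.0),
    ("iodine_like", 0.10, 0.90, 2.6, 33.2, 4.0),
    ("gadolinium_like", 0.10, 0.70, 2.6, 50.2, 4.5),
]


def make_spectral_model(
    M: int = 3,
    B: int = 5,
    E: int = 150,
    e_max: float = 150.0,
    seed: int = 0,
    cond_limit: float = 1e6,
) -> SpectralModel:
    """Build a seeded parametric spectral model and tabulate it at E nodes.

    Requires B >= M.  The resulting zero-linearization matrix U must have a
    condition number below ``cond_limit``; otherwise the curves are redrawn
    with a fresh sub-seed (at most 10 attempts).
    """
    from .derivatives import build_channel_matrix

    if B < M:
        raise ValueError(f"need B >= M bins (got B={B}, M={M})")
    if E < 1:
        raise ValueError("E must be >= 1")
    rng = np.random.default_rng(seed)
    for _attempt in range(10):
        names, compton, photo, power, epos, ejump = [], [], [], [], [], []
        for m in range(M):
            if m < len(_BASE_MATERIALS):
                nm, c, a, p, ep, ej = _BASE_MATERIALS[m]
            else:  # extra materials: seeded K-edge variants
                nm = f"material_{m}"
                c = rng.uniform(0.05, 0.2)
                a = rng.uniform(0.3, 1.0)
                p = rng.uniform(2.2, 3.0)
                ep = rng.uniform(30.0, min(90.0, 0.6 * e_max))
                ej = rng.uniform(2.0, 6.0)
            names.append(nm)
            compton.append(c)
            photo.append(a)
            power.append(p)
            epos.append(ep)
            ejump.append(ej)
        lo, hi = max(25.0, E_MIN_KEV + 7.0), min(0.93 * e_max, e_max - 10.0)
        centers = np.linspace(lo, hi, B)
        spacing = (hi - lo) / max(B - 1, 1)
        centers = centers + rng.uniform(-0.02, 0.02, size=B) * spacing
        sigmas = np.full(B, 0.55 * spacing if B > 1 else 0.25 * (hi - lo))
        fam = SpectralFamily(
            e_max=float(e_max),
            compton=tuple(compton),
            photo=tuple(photo),
            power=tuple(power),
            edge_pos=tuple(epos),
            edge_jump=tuple(ejump),
            edge_width=4.0,
            bin_centers=tuple(centers),
            bin_sigmas=tuple(sigmas),
            material_names=tuple(names),
        )
        model = fam.tabulate(E)
        try:
            C = build_channel_matrix(model, cond_limit=cond_limit)
        except np.linalg.LinAlgError:
            continue
        if C.cond < cond_limit:
            return model
    raise RuntimeError(
        f"could not draw a spectral model with cond(U) < {cond_limit:g} in 10 attempts"
    )


# ---------------------------------------------------------------------------
# data simulation
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionSpec:
    """Photon budget and inverse-crime settings for data generation.

    photon_budget : expected photon count I0 per ray for a fully
        transmitting bin (mean of the Poisson draw is I0 * F(X)/<S_b,1>).
    E_data : energy nodes for the data-generation model; must be >= the
        reconstruction grid.  None means twice the reconstruction grid.
    noise : Poisson noise on/off (off = noiseless fine-grid data).
    """

    photon_budget: float = 1e6
    E_data: Optional[int] = None
    noise: bool = True

    def __post_init__(self):
        if self.photon_budget <= 0:
            raise ValueError("photon budget must be positive")


def simulate_data(
    X_star,
    model: SpectralModel,
    P: ProjectorPair,
    acq: AcquisitionSpec,
    seed: int = 0,
) -> np.ndarray:
    """Simulate multispectral measurements of a ground-truth image.

    The forward model is evaluated with the generating curve family
    re-tabulated on the (finer) ``E_data`` grid, scaled to expected counts
    ``I0 * F(X)/<S_b,1>`` per bin, replaced by Poisson draws, and rescaled
    back to the measurement scale.  Reproducible given the seed.
    """
    E_data = acq.E_data if acq.E_data is not None else 2 * model.n_energies
    if E_data < model.n_energies:
        raise ValueError("E_data must be at least the reconstruction energy grid size")
    if E_data == model.n_energies:
        data_model = model
    else:
        if model.family is None:
            raise ValueError(
                "model has no generating curve family; cannot re-tabulate on a finer grid"
            )
        data_model = model.family.tabulate(E_data)
    F = forward_F(data_model, P, X_star)
    if not acq.noise:
        return F
    totals = data_model.bin_totals
    lam = acq.photon_budget * F / totals[None, :]
    if np.any(lam > 2**63 / 4):
        raise OverflowError("expected photon counts overflow; reduce the photon budget")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return counts * (totals[None, :] / acq.photon_budget)
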