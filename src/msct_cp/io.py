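"""File round-tripping: CSV spectra, HDF5/TIFF arrays, traces, configs.

All float data round-trip bit-exactly in float64.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import MaterialImage, SpectralModel

__all__ = [
    "write_spectral_model_csv",
    "read_spectral_model_csv",
    "save_array_h5",
    "load_array_h5",
    "save_image_tiff",
    "load_image_tiff",
    "write_trace_csv",
    "load_config",
    "save_config",
]


def write_spectral_model_csv(model: SpectralModel, attenuation_path, spectra_path) -> None:
    """Write attenuation curves and spectra as CSV (energy_keV, one column each)."""
    att = pd.DataFrame(model.attenuations, columns=list(model.material_names))
    att.insert(0, "energy_keV", model.energies)
    att.to_csv(attenuation_path, index=False, float_format="%.17g")
    spec = pd.DataFrame(
        model.spectra.T, columns=[f"bin_{b}" for b in range(model.n_bins)]
    )
    spec.insert(0, "energy_keV", model.energies)
    spec.to_csv(spectra_path, index=False, float_format="%.17g")


def read_spectral_model_csv(attenuation_path, spectra_path) -> SpectralModel:
    att = pd.read_csv(attenuation_path, float_precision="round_trip")
    spec = pd.read_csv(spectra_path, float_precision="round_trip")
    e = att["energy_keV"].to_numpy()
    if not np.array_equal(e, spec["energy_keV"].to_numpy()):
        raise ValueError("attenuation and spectra CSVs use different energy grids")
    names = [c for c in att.columns if c != "energy_keV"]
    return SpectralModel(
        energies=e,
        attenuations=att[names].to_numpy(),
        spectra=spec.drop(columns="energy_keV").to_numpy().T,
        material_names=names,
    )


def save_array_h5(path, array: np.ndarray, names: Optional[Sequence[str]] = None, **attrs) -> None:
    """Store a channelled array (Nx x M or Ny x M/B) with named channels."""
    array = np.asarray(array, dtype=np.float64)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("values", data=array)
        if names is not None:
            ds.attrs["channel_names"] = [str(n) for n in names]
        for k, v in attrs.items():
            ds.attrs[k] = v


def load_array_h5(path):
    """Return (array, channel_names or None)."""
    with h5py.File(path, "r") as f:
        ds = f["values"]
        arr = ds[()]
        names = ds.attrs.get("channel_names")
        if names is not None:
            names = [str(n) for n in names]
    return arr, names


def save_image_tiff(path, image: MaterialImage, n: int) -> None:
    """Multi-page float64 TIFF, one page per material channel."""
    pages = np.stack([image.grid(n, m) for m in range(image.n_materials)])
    tifffile.imwrite(path, pages.astype(np.float64), photometric="minisblack")


def load_image_tiff(path) -> np.ndarray:
    """Return an (Nx, M) array from a multi-page TIFF."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return np.stack([p.reshape(-1) for p in pages], axis=1)


def write_trace_csv(path, trace) -> None:
    trace.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(path, cfg: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
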