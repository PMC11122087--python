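"""End-to-end runs: simulate -> recalibrate -> reconstruct -> evaluate.

A run is driven by a schema-validated config dict (YAML/JSON on disk) and
writes everything into one output directory: a copy of the config, the
ground truth, the data, the model tables, iterates, the trace CSV and the
metrics CSV.  Given the same config and seed, every stage is deterministic
and its outputs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .forward import log_rescale_data
from .geometry import Geometry, default_geometry
from .metrics import relative_error
from .model import MaterialImage
from .projector import build_projector
from .solvers import SolverConfig, run_solver
from .synthetic import (
    AcquisitionSpec,
    PhantomSpec,
    Primitive,
    default_phantom_spec,
    make_phantom,
    make_spectral_model,
    simulate_data,
)

__all__ = ["validate_config", "run_simulate", "run_reconstruct", "run_evaluate"]

_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "geometry": dict,
    "spectral_model": dict,
    "phantom": dict,
    "acquisition": dict,
    "solver": dict,
}
_SECTION_KEYS = {
    "geometry": {"n", "unit_field_of_view", "angles", "n_detector_bins",
                 "pixel_size", "detector_spacing"},
    "spectral_model": {"M", "B", "E", "e_max", "seed",
                       "attenuation_csv", "spectra_csv"},
    "phantom": {"default", "primitives", "background_material",
                "background_density", "n_materials", "jitter"},
    "acquisition": {"photon_budget", "E_data", "noise"},
    "solver": {"variant", "step_size", "max_iterations", "positivity",
               "stop_tolerance", "seed", "backtracking"},
}


def validate_config(cfg: dict) -> dict:
    """Check the run config against the schema; unknown keys are rejected."""
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("seed", "output_dir"):
        if key not in cfg:
            raise ValueError(f"config is missing required key {key!r}")
    for section, allowed in _SECTION_KEYS.items():
        sub = cfg.get(section, {})
        if not isinstance(sub, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ValueError(f"unknown keys in config section {section!r}: {sorted(bad)}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _build_geometry(cfg: dict) -> Geometry:
    g = cfg.get("geometry", {})
    if "angles" in g:
        return Geometry.from_dict(g | {"n_pixels_side": g["n"]})
    return default_geometry(int(g.get("n", 64)),
                            unit_field_of_view=bool(g.get("unit_field_of_view", True)))


def _build_model(cfg: dict):
    sm = cfg.get("spectral_model", {})
    if "attenuation_csv" in sm:
        return mio.read_spectral_model_csv(sm["attenuation_csv"], sm["spectra_csv"])
    return make_spectral_model(
        M=int(sm.get("M", 3)),
        B=int(sm.get("B", 5)),
        E=int(sm.get("E", 150)),
        e_max=float(sm.get("e_max", 150.0)),
        seed=int(sm.get("seed", cfg["seed"])),
    )


def _build_phantom_spec(cfg: dict, n: int) -> PhantomSpec:
    ph = cfg.get("phantom", {})
    M = int(ph.get("n_materials", cfg.get("spectral_model", {}).get("M", 3)))
    if ph.get("default", True) and "primitives" not in ph:
        spec = default_phantom_spec(n, n_materials=M)
    else:
        prims = [Primitive(**p) for p in ph.get("primitives", [])]
        spec = PhantomSpec(
            n=n,
            primitives=prims,
            background_material=int(ph.get("background_material", 0)),
            background_density=float(ph.get("background_density", 0.0)),
            n_materials=M,
            jitter=float(ph.get("jitter", 0.0)),
        )
    return spec


def _write_log(outdir: Path, cfg: dict, **extra) -> None:
    import msct_cp

    log = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "versions": {"msct_cp": msct_cp.__version__, "numpy": np.__version__},
    } | extra
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def run_simulate(cfg: dict, output_dir=None) -> Path:
    """Generate phantom, model tables, and (noisy) data into the run directory."""
    cfg = validate_config(cfg)
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    geom = _build_geometry(cfg)
    model = _build_model(cfg)
    P = build_projector(geom)
    spec = _build_phantom_spec(cfg, geom.n_pixels_side)
    truth = make_phantom(spec, seed=cfg["seed"])
    ac = cfg.get("acquisition", {})
    acq = AcquisitionSpec(
        photon_budget=float(ac.get("photon_budget", 1e6)),
        E_data=ac.get("E_data"),
        noise=bool(ac.get("noise", True)),
    )
    Y = simulate_data(truth, model, P, acq, seed=cfg["seed"])
    mio.save_config(outdir / "config.yaml", cfg)
    mio.write_spectral_model_csv(model, outdir / "attenuations.csv", outdir / "spectra.csv")
    mio.save_array_h5(outdir / "truth.h5", truth.values, names=model.material_names)
    mio.save_array_h5(outdir / "data.h5", Y, names=[f"bin_{b}" for b in range(model.n_bins)])
    _write_log(outdir, cfg, stage="simulate")
    return outdir


def run_reconstruct(cfg: dict, run_dir=None) -> Path:
    """Recalibrate the data of a simulated run and reconstruct."""
    cfg = validate_config(cfg)
    outdir = Path(run_dir or cfg["output_dir"])
    if not (outdir / "data.h5").exists():
        raise FileNotFoundError(f"no data.h5 in {outdir}; run simulate first")
    geom = _build_geometry(cfg)
    model = mio.read_spectral_model_csv(outdir / "attenuations.csv", outdir / "spectra.csv")
    P = build_projector(geom)
    Y, _ = mio.load_array_h5(outdir / "data.h5")
    Y_H = log_rescale_data(model, Y)

    truth = None
    if (outdir / "truth.h5").exists():
        truth, _ = mio.load_array_h5(outdir / "truth.h5")

    sv = cfg.get("solver", {})
    config = SolverConfig(
        variant=sv.get("variant", "cp_fast"),
        step_size=sv.get("step_size", "auto"),
        max_iterations=int(sv.get("max_iterations", 500)),
        positivity=bool(sv.get("positivity", True)),
        stop_tolerance=float(sv.get("stop_tolerance", 1e-6)),
        seed=int(sv.get("seed", cfg["seed"])),
        backtracking=bool(sv.get("backtracking", False)),
        track_error_against=truth,
    )
    X, trace = run_solver(model, P, Y_H, config)
    mio.save_array_h5(outdir / "recon.h5", X, names=model.material_names)
    if trace.best_iterate is not None:
        mio.save_array_h5(outdir / "recon_best.h5", trace.best_iterate,
                          names=model.material_names,
                          best_index=trace.best_index)
    mio.write_trace_csv(outdir / "trace.csv", trace)
    _write_log(outdir, cfg, stage="reconstruct", omega=trace.omega,
               n_iterations=len(trace), best_index=trace.best_index)
    return outdir


def run_evaluate(run_dir, recon_file="recon.h5", truth_file="truth.h5") -> Path:
    """Compare reconstructions against ground truth; write metrics.csv."""
    outdir = Path(run_dir)
    truth, names = mio.load_array_h5(outdir / truth_file)
    rows = []
    for fname in (recon_file, "recon_best.h5"):
        path = outdir / fname
        if not path.exists():
            continue
        X, _ = mio.load_array_h5(path)
        overall = relative_error(X, truth)
        per_mat = relative_error(X, truth, per_material=True)
        row = {"file": fname, "rel_error": overall}
        for nm, e in zip(names or range(len(per_mat)), per_mat):
            row[f"rel_error_{nm}"] = e
        rows.append(row)
    if not rows:
        raise FileNotFoundError(f"no reconstruction files found in {outdir}")
    pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False, float_format="%.17g")
    return outdir / "metrics.csv"
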