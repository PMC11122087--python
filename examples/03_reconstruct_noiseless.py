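"""Noiseless reconstruction: CP-fast vs CP-full vs Landweber.

Simulates noiseless data on a twice-finer energy grid than the
reconstruction model (inverse-crime avoidance), recalibrates, and runs three
solver variants with the automatic step size.  The relative L2 error against
the ground-truth phantom is printed every 50 iterations.
"""

import msct_cp as mc

n = 32
P = mc.build_projector(mc.default_geometry(n))
model = mc.make_spectral_model(M=3, B=5, E=20, e_max=150.0, seed=1)
truth = mc.make_phantom(mc.default_phantom_spec(n), seed=0)

Y = mc.simulate_data(truth, model, P, mc.AcquisitionSpec(E_data=40, noise=False), seed=0)
Y_H = mc.log_rescale_data(model, Y)

for variant in ("cp_fast", "cp_full", "landweber"):
    cfg = mc.SolverConfig(variant=variant, max_iterations=300,
                          track_error_against=truth.values, stop_tolerance=0)
    X, tr = mc.run_solver(model, P, Y_H, cfg)
    marks = ", ".join(f"{k + 1}: {tr.rel_error[k]:.3f}" for k in (49, 149, 299))
    print(f"{variant:10s} omega={tr.omega:.3g}  rel L2 error at iteration {marks}")

print("\nChannel preconditioning (cp_*) removes the material-mixing part of the")
print("ill-conditioning; the plain gradient (Landweber) barely moves in 300 steps.")
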