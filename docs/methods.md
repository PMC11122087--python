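# Methods

## Discrete model

All computations use the fully discrete formulation.  Images are `n×n`
pixel grids stored as `(Nx, M)` arrays (`Nx = n²`), sinograms as `(Ny, M)`,
spectral data as `(Ny, B)`.  The energy integral is a plain weighted sum
over `E` grid nodes; quadrature weights are absorbed into the tabulated
spectra, so `⟨S_b, 1⟩` is the total weight of bin `b` and the empty-scanner
measurement is `F(0)_ib = ⟨S_b, 1⟩`.

The logarithmic model is evaluated as `log F − log F(0)` with both terms
produced by the same matrix product, and rows with an exactly zero material
sinogram are pinned to `H = 0`; this makes the identity `H(0) = 0` hold in
exact arithmetic rather than to round-off.

### Projector

The Radon matrix is assembled explicitly (Siddon-style exact pixel–ray
intersection lengths) as a sparse CSR matrix; the adjoint is its literal
transpose.  Matched adjointness is a *requirement* of the derivative
calculus, so unmatched third-party backprojectors are never used inside the
iterations (they may appear in tests as references).  Conventions: pixel
`(0,0)` at the lower left, pixel centers at half-integers, rotation about
the image center, detector coordinate spanning `[−D/2, D/2]`.  The default
geometry uses `⌈πn/2⌉` views on `[0, π)` and `⌈1.5n⌉` detector bins, with
pixel size `1/n` so the object occupies the unit square and line integrals
of unit-density objects are O(1).

### Derivatives and channel preconditioning

`H` factorizes through the per-ray channel map `Φ`.  Per ray `i` the
Jacobian of `Φ` is the `B×M` matrix

    J_i[b,m] = − Σ_e S̄[b,e] P_i[e] M[e,m] / F_i[b],

with `P_i` the ray's virtual energy transmission and `F_i` its bin
response.  All derivative operators (`H′`, `H′*`, `∇D`, `Φ′`, `Φ′*`) are
implemented from this composite form and validated three ways: adjoint
identities on randomized instances, second-order central-difference decay,
and dense-Jacobian oracles at small size.

`channel_precondition` applies `(Φ′[Z]*Φ′[Z])⁻¹Φ′[Z]*` as `Ny` independent
symmetric `M×M` solves, blocked over rays (8192 per block) so peak memory
stays linear in `Ny`; no `(Nx·M)²` or `(Ny·M)²` object is ever formed.
Per-ray systems whose condition number exceeds `1e12` raise by default; an
opt-in damping mode adds `1e−10·trace/M` to the diagonal instead and logs
the affected count.

Sign convention: `Φ′` carries a minus (more material ⇒ smaller response), so
the pseudoinverse of `Φ′[0] = −(·)Uᵀ` applied to a residual `R` is
`−R(U‡)ᵀ`, and the derivative-free update reads
`X ← X + ω Aᵀ(H(X) − Y_H)(U‡)ᵀ`.  This is the unique convention under which
CP-full and CP-fast take identical first steps from `X₀ = 0` and both
descend on `D`; it is verified by the brute-force dense pseudoinverse
oracle and by objective monotonicity.

### Solvers

All four variants instantiate the generic preconditioned fixed-point update
with an optional nonnegativity projection after every step (on by default:
densities are physical fractions).  Defaults: `X₀ = 0` (which makes the
zero linearization exact at the start), at most 500 iterations, relative
iterate-change stopping at `1e−6`.

* Step size: constant `ω = 1/ρ̂`, with `ρ̂` estimated by 50 seeded power
  iterations on the linearized normal operator at zero — `Aᵀ(A · UᵀU)` for
  Landweber, `AᵀA` for the channel-preconditioned variants (the channel
  part cancels at zero).  This is the conservative half of the classical
  `(0, 2/ρ)` stability interval.
* Optional backtracking halves `ω` (≤ 20 times) until the objective
  decreases and rejects the step if no decrease is found, which keeps
  backtracked runs strictly monotone.  Gauss–Newton uses unit damping with
  this fallback; it exists purely as a small-scale baseline and refuses
  problems with more than 4096 unknowns (dense normal-operator assembly).
* Divergence guard: a non-finite objective, or growth beyond `1e6×` the
  initial objective, aborts with the partial trace attached.
* Exponent arguments are clipped at `|700|` (logged) to avoid overflow;
  measured data are floored at `1e−12·min_b⟨S_b,1⟩` before the logarithm
  (Poisson draws can be zero), with the floored count logged.
* Traces record objective, step size, and — when a ground truth is given —
  the relative L2 error per iteration, plus the best iterate (minimal error
  if a truth is tracked, else minimal objective).  Best-iterate selection
  emulates oracle early stopping, which is only available in simulation.

## Synthetic data

The generator emulates a three-material acquisition — water plus iodine-like
and gadolinium-like contrast agents — with `B = 5` bins and `E = 150`
uniform energy nodes on (0, 150] keV by default.

* **Attenuation curves**: `μ_m(e) = c_m + a_m (60/e)^{p} [1 + j_m σ((e−e_K)/w)]`
  — a Compton-like floor, a photoelectric power-law decay (`p = 2.6`), and
  for the contrast agents a K-edge step at 33.2 / 50.2 keV smoothed over
  `w = 4` keV (detector energy-resolution blur).  The divergence of the
  power law is truncated below 10 keV, outside the source window.
* **Spectra**: Gaussian bin sensitivities under a bremsstrahlung-like
  envelope `(e − 18)·exp(−e/45)` that vanishes below 18 keV; bin centers
  spread over 25–139.5 keV with a small seeded jitter.
* **Tabulation**: curves are sampled once on a fixed 4800-point master
  lattice and aggregated into cells (spectra: cell integrals; attenuations:
  cell averages), so tabulations at different `E` describe the same physics
  and every bin's total weight is exactly grid-independent.
* **Phantoms**: ellipse/disk primitives in the unit field of view,
  rasterized area-weighted (4× supersampling, last-wins overlap semantics).
  The default phantom is a water ellipse with one iodine-like, one
  gadolinium-like, and one denser water disk.
* **Noise**: expected counts `I₀·F(X★)/⟨S_b,1⟩` per ray and bin are replaced
  by Poisson draws and rescaled; the default photon budget is `I₀ = 10⁶`.
  Inverse-crime avoidance generates data from the same curve family
  re-tabulated on a twice-finer energy grid (`E_data = 2E`); an exact
  inverse-crime mode (`E_data = E`, noise off) exists for consistency tests.

The generator does **not** model detector physics beyond an effective
spectrum (no pile-up, scatter, or charge sharing), uses parametric curve
stand-ins rather than measured attenuation tables, and its phantoms are
geometric, not anatomical.  Passing tests therefore demonstrate the
correctness and behavior of the *algorithms* under controlled conditions,
not calibrated performance on clinical data.

## Study sizes and observed behavior

Desk-scale experiments use 64×64 pixels (101 views × 96 bins, `Ny = 9696`),
`M = 3`, `B = 5`, `E = 20` with `E_data = 40`; these sizes keep every run in
seconds-to-minutes while preserving the structure of the full-size problem.
At this scale the channel matrix has condition number ≈ 68, Poisson
reconstructions at `I₀ = 10⁶` reach best-iterate errors ≈ 0.065 (CP-full)
and ≈ 0.076 (CP-fast), and the objective is monotone under the automatic
step for all variants.

Two known limitations shape the noiseless results.  First, after channel
preconditioning the remaining iteration is an unaccelerated Landweber
scheme on the Radon part: per-mode contraction `(1 − σ²/‖A‖²)^k`, so
edge-dominated phantoms converge to ≈ 3% relative error in 500 iterations
and need ~2000 iterations to reach 1%.  Second, reconstructing on an
energy grid twice as coarse as the data-generation grid leaves a
systematic log-domain discrepancy concentrated in the lowest-energy bin
(where attenuation curves are steepest); after channel inversion this
yields a bias floor of a few percent at `E = 20` that shrinks quadratically
with the grid spacing.  Both effects are properties of the stated method
and study conditions rather than implementation artifacts; the acceptance
suite reports them as measured.
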