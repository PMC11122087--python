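"""Derivative calculus: adjoints, finite differences, zero linearization,
channel matrix and per-ray channel preconditioning."""

import tracemalloc

import numpy as np
import pytest

import msct_cp as mc
from msct_cp.model import SpectralModel
from msct_cp.synthetic import SpectralFamily


def rand_pair(rng, proj, model, scale=0.4):
    Nx, Ny = proj.geometry.n_pixels, proj.geometry.n_rays
    X = scale * rng.random((Nx, model.n_materials))
    xi = rng.standard_normal((Nx, model.n_materials))
    eta = rng.standard_normal((Ny, model.n_bins))
    return X, xi, eta


# ---------------------------------------------------------------------------
# channel matrix
# ---------------------------------------------------------------------------

def test_channel_matrix_scalar_weighted_mean():
    m = SpectralModel(energies=[30.0, 90.0], attenuations=[[1.0], [3.0]],
                      spectra=[[1.0, 1.0]])
    C = mc.build_channel_matrix(m)
    assert np.allclose(C.U, [[2.0]])  # (1+3)/2
    assert np.allclose(C.pinv, [[0.5]])


def test_channel_matrix_unit_material_column(model_small):
    att = model_small.attenuations.copy()
    att[:, 0] = 1.0
    m = SpectralModel(energies=model_small.energies, attenuations=att,
                      spectra=model_small.spectra)
    C = mc.build_channel_matrix(m)
    assert np.allclose(C.U[:, 0], 1.0, rtol=1e-14)


def test_channel_matrix_pseudoinverse(model_small):
    C = mc.build_channel_matrix(model_small)
    assert np.allclose(C.pinv @ C.U, np.eye(3), atol=1e-10)
    # independent normal-equation oracle
    U = (model_small.spectra @ model_small.attenuations) / model_small.bin_totals[:, None]
    oracle = np.linalg.inv(U.T @ U) @ U.T
    assert np.allclose(C.pinv, oracle, rtol=1e-8)


def test_channel_matrix_rejects_degenerate_materials(model_small):
    att = model_small.attenuations.copy()
    att[:, 2] = att[:, 1]  # two spectrally identical materials
    m = SpectralModel(energies=model_small.energies, attenuations=att,
                      spectra=model_small.spectra)
    with pytest.raises(np.linalg.LinAlgError, match="condition"):
        mc.build_channel_matrix(m)


def test_channel_matrix_requires_enough_bins():
    m = SpectralModel(energies=[30.0], attenuations=[[1.0, 2.0]],
                      spectra=[[1.0]])
    with pytest.raises(ValueError, match="bins"):
        mc.build_channel_matrix(m)


# ---------------------------------------------------------------------------
# derivatives of H
# ---------------------------------------------------------------------------

def test_dH_linear_in_direction(proj8, model_small):
    rng = np.random.default_rng(1)
    X, xi, _ = rand_pair(rng, proj8, model_small)
    assert np.all(mc.dH_apply(model_small, proj8, X, 0 * xi) == 0.0)
    out1 = mc.dH_apply(model_small, proj8, X, xi)
    out2 = mc.dH_apply(model_small, proj8, X, 2.0 * xi)
    assert np.allclose(out2, 2.0 * out1, rtol=1e-12)


def test_dH_central_difference_second_order(proj8, model_small):
    """Central FD error shrinks ~4x when h halves (second-order accuracy)."""
    rng = np.random.default_rng(2)
    X, xi, _ = rand_pair(rng, proj8, model_small)
    dH = mc.dH_apply(model_small, proj8, X, xi)
    errs = []
    for h in [1e-3, 5e-4, 2.5e-4]:
        fd = (mc.forward_H(model_small, proj8, X + h * xi)
              - mc.forward_H(model_small, proj8, X - h * xi)) / (2 * h)
        errs.append(np.linalg.norm(fd - dH))
    for e0, e1 in zip(errs, errs[1:]):
        assert 3.5 <= e0 / e1 <= 4.5


def test_dH_at_zero_equals_zero_linearization(proj8, model_small):
    rng = np.random.default_rng(3)
    _, xi, eta = rand_pair(rng, proj8, model_small)
    C = mc.build_channel_matrix(model_small)
    X0 = np.zeros((64, 3))
    lhs = mc.dH_apply(model_small, proj8, X0, xi)
    rhs = -mc.apply_multichannel(proj8, xi) @ C.U.T
    assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-14)
    # adjoint at zero: -A^T eta U
    lhs_a = mc.dH_adjoint(model_small, proj8, X0, eta)
    rhs_a = -mc.adjoint_multichannel(proj8, eta @ C.U)
    assert np.allclose(lhs_a, rhs_a, rtol=1e-12, atol=1e-14)


def test_dH_adjoint_identity_vs_dense_jacobian(proj8, model_small):
    """<H'[X] xi, eta> = <xi, H'[X]* eta>; H'[X]* matches the dense Jacobian
    assembled column by column from unit-vector directional derivatives."""
    rng = np.random.default_rng(4)
    X, xi, eta = rand_pair(rng, proj8, model_small)
    assert np.all(mc.dH_adjoint(model_small, proj8, X, 0 * eta) == 0.0)
    out = mc.dH_apply(model_small, proj8, X, xi)
    adj = mc.dH_adjoint(model_small, proj8, X, eta)
    defect = abs(np.vdot(out, eta) - np.vdot(xi, adj))
    assert defect <= 1e-10 * np.linalg.norm(out) * np.linalg.norm(eta)

    Nx, M = X.shape
    J = np.empty((out.size, Nx * M))
    for j in range(Nx * M):
        e = np.zeros(Nx * M)
        e[j] = 1.0
        J[:, j] = mc.dH_apply(model_small, proj8, X, e.reshape(Nx, M)).ravel()
    assert np.allclose(adj.ravel(), J.T @ eta.ravel(), rtol=1e-10, atol=1e-12)


def test_gradient_D(proj8, model_small):
    rng = np.random.default_rng(5)
    X, xi, _ = rand_pair(rng, proj8, model_small)
    H = mc.forward_H(model_small, proj8, X)
    assert np.all(mc.gradient_D(model_small, proj8, X, H) == 0.0)
    Y_H = H + 0.1 * rng.standard_normal(H.shape)
    g = mc.gradient_D(model_small, proj8, X, Y_H)
    # agrees with the adjoint applied to the residual
    assert np.allclose(g, mc.dH_adjoint(model_small, proj8, X, H - Y_H),
                       rtol=1e-14, atol=0)
    # directional central differences of the objective
    errs = []
    for h in [1e-3, 5e-4, 2.5e-4]:
        fd = (mc.lsq_objective(model_small, proj8, X + h * xi, Y_H)
              - mc.lsq_objective(model_small, proj8, X - h * xi, Y_H)) / (2 * h)
        errs.append(abs(fd - np.vdot(g, xi)))
    for e0, e1 in zip(errs, errs[1:]):
        assert 3.5 <= e0 / e1 <= 4.5


def test_linearization_consistency_at_zero(proj8, model_small):
    """||H(h xi) - h H'[0] xi|| / h -> 0 as h -> 0 (Taylor at zero)."""
    rng = np.random.default_rng(6)
    _, xi, _ = rand_pair(rng, proj8, model_small)
    d0 = mc.dH_apply(model_small, proj8, np.zeros((64, 3)), xi)
    rels = []
    for h in [1e-1, 1e-2, 1e-3]:
        rels.append(np.linalg.norm(mc.forward_H(model_small, proj8, h * xi) - h * d0) / h)
    assert rels[0] > rels[1] > rels[2]
    # the defect is O(h): one decade in h buys about one decade in defect
    assert rels[2] / rels[0] < 0.02


# ---------------------------------------------------------------------------
# derivatives of the channel map Phi
# ---------------------------------------------------------------------------

def test_dPhi_at_zero_and_chain_rule(proj8, model_small):
    rng = np.random.default_rng(7)
    X, xi, eta = rand_pair(rng, proj8, model_small)
    C = mc.build_channel_matrix(model_small)
    Ny = proj8.geometry.n_rays
    zeta = rng.standard_normal((Ny, 3))
    Z0 = np.zeros((Ny, 3))
    assert np.allclose(mc.dPhi_apply(model_small, Z0, zeta), -zeta @ C.U.T,
                       rtol=1e-12, atol=1e-14)
    assert np.allclose(mc.dPhi_adjoint(model_small, Z0, eta), -eta @ C.U,
                       rtol=1e-12, atol=1e-14)
    # chain rule: H'[X](xi) = Phi'[A X](A xi)
    Z = mc.apply_multichannel(proj8, X)
    lhs = mc.dH_apply(model_small, proj8, X, xi)
    rhs = mc.dPhi_apply(model_small, Z, mc.apply_multichannel(proj8, xi))
    assert np.allclose(lhs, rhs, rtol=1e-12)


def test_dPhi_matches_finite_differences_of_Phi(model_small):
    """Phi' is validated independently of H by central differences of Phi."""
    rng = np.random.default_rng(8)
    Z = 0.5 * rng.random((6, 3))
    zeta = rng.standard_normal((6, 3))
    d = mc.dPhi_apply(model_small, Z, zeta)
    errs = []
    for h in [1e-3, 5e-4, 2.5e-4]:
        fd = (mc.phi_apply(model_small, Z + h * zeta)
              - mc.phi_apply(model_small, Z - h * zeta)) / (2 * h)
        errs.append(np.linalg.norm(fd - d))
    for e0, e1 in zip(errs, errs[1:]):
        assert 3.5 <= e0 / e1 <= 4.5


def test_dPhi_adjoint_identity_vs_dense_jacobian(model_small):
    rng = np.random.default_rng(9)
    Ny, M, B = 5, 3, 5
    Z = 0.5 * rng.random((Ny, M))
    # dense Jacobian of Phi at Z from unit directions
    J = np.empty((Ny * B, Ny * M))
    for j in range(Ny * M):
        e = np.zeros(Ny * M)
        e[j] = 1.0
        J[:, j] = mc.dPhi_apply(model_small, Z, e.reshape(Ny, M)).ravel()
    for _ in range(20):
        zeta = rng.standard_normal((Ny, M))
        eta = rng.standard_normal((Ny, B))
        out = mc.dPhi_apply(model_small, Z, zeta)
        adj = mc.dPhi_adjoint(model_small, Z, eta)
        defect = abs(np.vdot(out, eta) - np.vdot(zeta, adj))
        assert defect <= 1e-10 * np.linalg.norm(out) * np.linalg.norm(eta)
        assert np.allclose(adj.ravel(), J.T @ eta.ravel(), rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# channel preconditioning
# ---------------------------------------------------------------------------

def test_channel_precondition_at_zero(model_small):
    rng = np.random.default_rng(10)
    C = mc.build_channel_matrix(model_small)
    R = rng.standard_normal((7, 5))
    out = mc.channel_precondition(model_small, np.zeros((7, 3)), R)
    # pinv of Phi'[0] = -(.)U^T carries the minus sign
    assert np.allclose(out, -R @ C.pinv.T, rtol=1e-10, atol=1e-13)


def test_channel_precondition_matches_dense_pseudoinverse(model_small):
    """Per-ray solves equal the brute-force stacked-Jacobian least squares."""
    rng = np.random.default_rng(11)
    Ny, M, B = 3, 3, 5
    Z = 0.4 * rng.random((Ny, M))
    R = rng.standard_normal((Ny, B))
    out = mc.channel_precondition(model_small, Z, R)
    J = np.empty((Ny * B, Ny * M))
    for j in range(Ny * M):
        e = np.zeros(Ny * M)
        e[j] = 1.0
        J[:, j] = mc.dPhi_apply(model_small, Z, e.reshape(Ny, M)).ravel()
    oracle = np.linalg.solve(J.T @ J, J.T @ R.ravel())
    assert np.allclose(out.ravel(), oracle, rtol=1e-8)


def test_channel_precondition_recovers_direction(model_small):
    rng = np.random.default_rng(12)
    Z = 0.4 * rng.random((11, 3))
    zeta = rng.standard_normal((11, 3))
    R = mc.dPhi_apply(model_small, Z, zeta)
    rec = mc.channel_precondition(model_small, Z, R)
    assert np.allclose(rec, zeta, rtol=1e-8)


def test_channel_precondition_linear_memory_in_rays(model_small):
    """Works at a ray count where any (Ny*M)^2 object would need ~3 TB."""
    rng = np.random.default_rng(13)
    Ny = 400_000
    Z = 0.4 * rng.random((Ny, 3))
    R = rng.standard_normal((Ny, 5))
    tracemalloc.start()
    out = mc.channel_precondition(model_small, Z, R)
    _, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()
    assert out.shape == (Ny, 3)
    assert peak < 500e6  # linear in Ny, far below any (Ny*M)^2 footprint


def test_adjoint_identities_randomized_instances():
    """Adjoint identity for A, H'[X], Phi'[Z] on 100 random geometries/models."""
    rng = np.random.default_rng(99)
    fam_model = mc.make_spectral_model(M=2, B=3, E=8, seed=3)
    for trial in range(100):
        n = int(rng.integers(2, 8))
        n_ang = int(rng.integers(1, 7))
        nb = int(rng.integers(n, 12))
        g = mc.Geometry(n_pixels_side=n,
                        angles=tuple(np.sort(rng.uniform(0, np.pi, n_ang))),
                        n_detector_bins=nb, pixel_size=1 / n, detector_spacing=1 / n)
        P = mc.build_projector(g)
        X = 0.5 * rng.random((g.n_pixels, 2))
        xi = rng.standard_normal((g.n_pixels, 2))
        eta = rng.standard_normal((g.n_rays, 3))
        out = mc.dH_apply(fam_model, P, X, xi)
        adj = mc.dH_adjoint(fam_model, P, X, eta)
        defect = abs(np.vdot(out, eta) - np.vdot(xi, adj))
        assert defect <= 1e-10 * max(np.linalg.norm(out) * np.linalg.norm(eta), 1e-300)
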