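import numpy as np
import pytest

from vistamrf.dictionary import TemporalBasis
from vistamrf.phantom import KSpaceDataset
from vistamrf.recon import (ReconConfig, SubspaceOperator, ToeplitzNormal,
                            llr_prox, mfi_weights, subspace_recon)


def make_instance(seed=0, nt=8, k=3, n=8, ns=150, n_coils=2):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-n / 2 + 0.1, n / 2 - 0.1, (nt, ns, 3))
    sens = (rng.standard_normal((n_coils, n, n, n))
            + 1j * rng.standard_normal((n_coils, n, n, n)))
    phi = np.linalg.qr(rng.standard_normal((nt, k)))[0]
    return rng, coords, sens, phi


class TestForwardOperator:
    def test_linearity(self):
        rng, coords, sens, phi = make_instance()
        op = SubspaceOperator(coords, (8, 8, 8), sens, phi,
                              dtype=np.complex128)
        x1 = rng.standard_normal((3, 8, 8, 8)) + 1j * rng.standard_normal((3, 8, 8, 8))
        x2 = rng.standard_normal((3, 8, 8, 8))
        assert np.abs(op.forward(np.zeros_like(x1))).max() == 0
        add_err = np.abs(op.forward(x1 + x2)
                         - (op.forward(x1) + op.forward(x2))).max()
        assert add_err < 1e-10 * np.abs(op.forward(x1)).max()

    def test_k_mismatch_rejected(self):
        _, coords, sens, phi = make_instance()
        op = SubspaceOperator(coords, (8, 8, 8), sens, phi)
        with pytest.raises(ValueError):
            op.forward(np.zeros((5, 8, 8, 8)))

    def test_mfi_off_equals_zero_b0(self):
        rng, coords, sens, phi = make_instance()
        t = np.arange(150) * 0.01
        op0 = SubspaceOperator(coords, (8, 8, 8), sens, phi,
                               sample_times_ms=t,
                               b0_map=np.zeros((8, 8, 8)), mfi_bins=4,
                               dtype=np.complex128)
        op = SubspaceOperator(coords, (8, 8, 8), sens, phi,
                              dtype=np.complex128)
        x = rng.standard_normal((3, 8, 8, 8)) + 0j
        assert np.abs(op0.forward(x) - op.forward(x)).max() < 1e-8

    def test_adjoint_and_gradient_consistency(self):
        """The numerical directional derivative of the weighted data term
        matches <A^H W (Ac - k), d>."""
        rng, coords, sens, phi = make_instance(seed=3)
        op = SubspaceOperator(coords, (8, 8, 8), sens, phi,
                              dtype=np.complex128)
        w = rng.uniform(0.5, 2.0, 150)
        c = rng.standard_normal((3, 8, 8, 8)) + 1j * rng.standard_normal((3, 8, 8, 8))
        d = rng.standard_normal((3, 8, 8, 8)) + 1j * rng.standard_normal((3, 8, 8, 8))
        k = op.forward(rng.standard_normal((3, 8, 8, 8)) + 0j)

        def f(x):
            r = op.forward(x) - k
            return 0.5 * np.sum(w[None, None, :] * np.abs(r) ** 2)

        grad = op.adjoint((op.forward(c) - k) * w[None, None, :])
        eps = 1e-6
        num = (f(c + eps * d) - f(c - eps * d)) / (2 * eps)
        ana = np.real(np.vdot(grad, d))
        assert abs(num - ana) / max(abs(num), 1e-12) < 1e-5

    def test_toeplitz_matches_explicit_normal(self):
        rng, coords, sens, phi = make_instance(seed=5)
        w = rng.uniform(0.5, 2.0, 150)
        op = SubspaceOperator(coords, (8, 8, 8), sens, phi,
                              oversamp=1.25, width=4, dtype=np.complex64)
        top = ToeplitzNormal(coords, (8, 8, 8), sens, phi, w,
                             oversamp=1.25, width=4)
        x = (rng.standard_normal((3, 8, 8, 8))
             + 1j * rng.standard_normal((3, 8, 8, 8))).astype(np.complex64)
        n1 = op.adjoint((op.forward(x) * w[None, None, :]).astype(np.complex64))
        n2 = top.apply(x)
        assert np.linalg.norm(n1 - n2) / np.linalg.norm(n1) < 2e-2


class TestMfiWeights:
    def test_unit_selector_at_bin_frequency(self):
        b0 = np.linspace(-40, 40, 27).reshape(3, 3, 3)
        t = np.arange(64) * 0.01
        coeffs, freqs, _ = mfi_weights(b0, t, 5)
        # the corner voxel frequency coincides with the first bin
        assert np.abs(coeffs[0, 0, 0] - np.eye(5)[0]).max() < 1e-8

    def test_error_monotone_in_bins(self):
        rng = np.random.default_rng(0)
        b0 = rng.uniform(-50, 50, (4, 4, 4))
        t = np.arange(128) * 0.01
        errs = [mfi_weights(b0, t, nb)[2] for nb in range(2, 13)]
        assert np.all(np.diff(errs) <= 1e-10)

    def test_zero_field_passthrough(self):
        coeffs, freqs, err = mfi_weights(np.zeros((2, 2, 2)),
                                         np.arange(10) * 0.01, 6)
        assert coeffs.shape[-1] == 1 and err == 0.0
        assert np.allclose(coeffs, 1.0)


class TestLlrProx:
    def test_zero_threshold_identity(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal((3, 8, 8, 8))
        assert np.array_equal(llr_prox(c, 0.0, 4), c)

    def test_single_block_matches_dense_svd(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal((4, 6, 6, 6)) + 1j * rng.standard_normal((4, 6, 6, 6))
        out = llr_prox(c, 0.3, 6)
        cas = c.reshape(4, -1).T
        u, s, vh = np.linalg.svd(cas, full_matrices=False)
        ref = (u * np.maximum(s - 0.3, 0.0)[None, :]) @ vh
        assert np.abs(out.reshape(4, -1).T - ref).max() < 1e-8

    @pytest.mark.parametrize("thresh", [0.05, 0.5, 5.0])
    def test_nuclear_norm_shrinks(self, thresh):
        from vistamrf.recon import _block_nuclear_norm

        rng = np.random.default_rng(2)
        c = rng.standard_normal((3, 8, 8, 8))
        out = llr_prox(c, thresh, 4, shift=(1, 2, 3))
        assert _block_nuclear_norm(out, 4, (1, 2, 3)) \
            <= _block_nuclear_norm(c, 4, (1, 2, 3)) + 1e-9

    def test_block_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            llr_prox(np.zeros((2, 4, 4, 4)), 0.1, 8)

    def test_shift_round_trip_preserves_shape(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal((2, 7, 9, 5))
        out = llr_prox(c, 1e9, 4, shift=(2, 1, 3))
        assert out.shape == c.shape
        # enormous threshold annihilates everything
        assert np.abs(out).max() < 1e-12


class TestSolver:
    @pytest.fixture(scope="class")
    def instance(self):
        rng, coords, sens, phi = make_instance(seed=7, nt=10, ns=200)
        op = SubspaceOperator(coords, (8, 8, 8), sens, phi,
                              dtype=np.complex128, oversamp=2.0, width=7)
        ct = rng.standard_normal((3, 8, 8, 8)) + 1j * rng.standard_normal((3, 8, 8, 8))
        y = op.forward(ct)
        kd = KSpaceDataset(samples=y.astype(np.complex64),
                           coords=(coords / 8).astype(np.float32),
                           matrix_size=8, fov_mm=220.0,
                           resolution_mm=220.0 / 8, dwell_us=10.0, te_ms=0.0,
                           noise_sigma=0.0, seed=0)
        basis = TemporalBasis(phi=phi, singular_values=np.ones(10), k=3,
                              energy_fraction=1.0)
        return op, kd, sens, basis, y

    def test_unregularized_solution_matches_dense_solve(self, instance):
        """lambda=0 on an 8^3 instance: FISTA converges to the explicit
        normal-equation solution (brute-force linear algebra oracle)."""
        op, kd, sens, basis, y = instance
        nvox = 3 * 8**3
        a = np.zeros((y.size, nvox), complex)
        e = np.zeros((3, 8, 8, 8), complex)
        for i in range(nvox):
            e.ravel()[i] = 1.0
            a[:, i] = op.forward(e).ravel()
            e.ravel()[i] = 0.0
        w = _recover_weights(kd)
        wt = np.tile(w, y.size // w.size)
        ref = np.linalg.solve((a.conj().T * wt[None, :]) @ a,
                              a.conj().T @ (y.ravel() * wt))
        cfg = ReconConfig(lambda_llr=0.0, n_iter=300, precond_degree=4,
                          backend="explicit", oversamp=2.0, width=7)
        res = subspace_recon(kd, sens, basis, cfg)
        rel = np.linalg.norm(res.c.ravel() - ref) / np.linalg.norm(ref)
        assert rel < 1e-4

    def test_deterministic(self, instance):
        _, kd, sens, basis, _ = instance
        cfg = ReconConfig(n_iter=3, backend="explicit", random_shift_seed=5,
                          oversamp=2.0, width=7)
        r1 = subspace_recon(kd, sens, basis, cfg)
        r2 = subspace_recon(kd, sens, basis, cfg)
        assert np.array_equal(r1.c, r2.c)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)

    def test_objective_decreases(self, instance):
        _, kd, sens, basis, _ = instance
        cfg = ReconConfig(n_iter=10, backend="explicit", oversamp=2.0,
                          width=7)
        res = subspace_recon(kd, sens, basis, cfg)
        assert res.meta["final_objective"] \
            <= res.meta["initial_objective"] + 1e-9

    def test_circulant_preconditioner_stable(self, instance):
        """The per-frequency kernel-inverse preconditioner (toeplitz
        backend) keeps FISTA stable and reduces the objective fast."""
        _, kd, sens, basis, _ = instance
        res = subspace_recon(kd, sens, basis, ReconConfig(
            lambda_llr=0.0, n_iter=15, backend="toeplitz",
            preconditioner="circulant", precond_delta=1e-3,
            oversamp=2.0, width=7))
        assert res.meta["preconditioner"] == "circulant"
        assert res.meta["final_objective"] \
            <= 0.1 * res.meta["initial_objective"]

    def test_circulant_requires_toeplitz(self, instance):
        _, kd, sens, basis, _ = instance
        with pytest.raises(ValueError):
            subspace_recon(kd, sens, basis, ReconConfig(
                backend="explicit", preconditioner="circulant",
                oversamp=2.0, width=7))

    def test_preconditioning_accelerates(self, instance):
        """The degree-4 polynomial-preconditioned run reaches (at 20
        iterations) at least the objective the plain run attains at 40."""
        _, kd, sens, basis, _ = instance
        plain = subspace_recon(kd, sens, basis, ReconConfig(
            lambda_llr=0.0, n_iter=40, precond_degree=0, backend="explicit",
            oversamp=2.0, width=7))
        pre = subspace_recon(kd, sens, basis, ReconConfig(
            lambda_llr=0.0, n_iter=20, precond_degree=4, backend="explicit",
            oversamp=2.0, width=7))
        assert pre.meta["final_objective"] \
            <= plain.meta["final_objective"] + 1e-9


def _recover_weights(kd):
    from vistamrf.trajectory import pipe_menon_dcf

    coords = kd.grid_coords().astype(np.float64)
    return pipe_menon_dcf(coords[0], (kd.matrix_size,) * 3, method="grid")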