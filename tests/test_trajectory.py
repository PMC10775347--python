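import numpy as np
import pytest

from vistamrf.trajectory import (design_spiral, pipe_menon_dcf,
                                 rotation_matrix, tgas_schedule)
from vistamrf.nufft import NufftPlan


class TestSpiral:
    def test_nyquist_radius(self):
        sp = design_spiral(220.0, 1.0)
        assert np.linalg.norm(sp.k_samples, axis=1).max() \
            == pytest.approx(0.5, rel=1e-3)
        assert sp.kmax == pytest.approx(0.5)

    @pytest.mark.parametrize("res,gmax,smax", [
        (1.0, 40.0, 100.0),      # 1 mm protocol gradient set
        (0.66, 60.0, 160.0),     # 0.66 mm protocol gradient set
        (220.0 / 32, 40.0, 100.0),
    ])
    def test_waveform_audit(self, res, gmax, smax):
        """The designed arm respects its own gradient and slew limits and
        reaches k_max within the readout window."""
        sp = design_spiral(220.0, res, gmax=gmax, smax=smax,
                           max_duration_ms=6.8)
        audit = sp.audit()
        assert audit["gradient_ok"] and audit["slew_ok"]
        assert audit["kmax_reached"]
        assert sp.duration_ms <= 6.8 + 1e-9

    def test_halving_slew_increases_duration(self):
        a = design_spiral(220.0, 220.0 / 32, smax=100.0,
                          max_duration_ms=60.0, pitch_factor=1.0)
        b = design_spiral(220.0, 220.0 / 32, smax=50.0,
                          max_duration_ms=60.0, pitch_factor=1.0)
        assert b.duration_ms > a.duration_ms

    def test_infeasible_reported(self):
        with pytest.raises(ValueError):
            design_spiral(220.0, 1.0, gmax=1.0, max_duration_ms=1.0)
        with pytest.raises(ValueError):
            design_spiral(220.0, 1.0, pitch_factor=1.0, max_duration_ms=6.8)

    def test_grid_coordinate_convention(self):
        """coordinate x matrix size = grid-index units, bounded by N/2."""
        sp = design_spiral(220.0, 220.0 / 32)
        g = sp.grid_coords(32)
        assert np.abs(g).max() <= 16.0 + 1e-9
        assert np.linalg.norm(g, axis=1).max() == pytest.approx(16.0,
                                                                rel=1e-3)


class TestTgas:
    def test_relative_rotation_is_increment(self):
        sch = tgas_schedule(1, 2, increment_deg=23.628)
        rel = sch.matrices[0, 1] @ sch.matrices[0, 0].T
        assert np.abs(rel - rotation_matrix(0, np.deg2rad(23.628))).max() \
            < 1e-10

    def test_rotations_orthonormal(self):
        sch = tgas_schedule(7, 12)
        m = sch.matrices.reshape(-1, 3, 3)
        assert np.abs(m @ m.transpose(0, 2, 1) - np.eye(3)).max() < 1e-10
        assert np.allclose(np.linalg.det(m), 1.0)

    def test_deterministic(self):
        a = tgas_schedule(5, 9)
        b = tgas_schedule(5, 9)
        assert np.array_equal(a.matrices, b.matrices)

    def test_coverage_vs_golden_means_oracle(self):
        """Spherical-cap discrepancy of the 480 readout normals stays
        within 0.1 of a golden-means point set (the uniformity oracle)."""
        sch = tgas_schedule(24, 20)
        pts = sch.normals().reshape(-1, 3)
        i = np.arange(480)
        z = 1 - 2 * (i + 0.5) / 480
        phi = 2 * np.pi * i * (np.sqrt(5) - 1) / 2
        oracle = np.stack([np.sqrt(1 - z**2) * np.cos(phi),
                           np.sqrt(1 - z**2) * np.sin(phi), z], axis=1)

        def cap_disc(p, seed=0, ncaps=2000):
            rng = np.random.default_rng(seed)
            c = rng.standard_normal((ncaps, 3))
            c /= np.linalg.norm(c, axis=1, keepdims=True)
            h = rng.uniform(-1, 1, ncaps)
            frac = (p @ c.T > h[None, :]).mean(axis=0)
            return np.abs(frac - (1 - h) / 2).max()

        assert cap_disc(pts) <= cap_disc(oracle) + 0.1


class TestPipeMenon:
    def test_uniform_cartesian_uniform_weights(self):
        n = 8
        g = np.stack(np.meshgrid(*[np.arange(n) - n // 2] * 3,
                                 indexing="ij"), -1).reshape(-1, 3).astype(float)
        w = pipe_menon_dcf(g, (n, n, n))
        assert w.max() / w.min() < 1.01

    def test_duplicates_get_half_weight(self):
        pts = np.array([[0., 0., 0.], [0., 0., 0.], [3., 0., 0.],
                        [-3., 1., 2.], [0., -3., 1.], [2., 2., -2.]])
        w = pipe_menon_dcf(pts, (16, 16, 16))
        assert w[0] == pytest.approx(w[1])
        assert w[0] / w[2] == pytest.approx(0.5, abs=0.025)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-3, 3, (150, 3))
        rot = rotation_matrix(1, 0.7) @ rotation_matrix(0, 0.3)
        w1 = pipe_menon_dcf(pts, (16, 16, 16))
        w2 = pipe_menon_dcf(pts @ rot.T, (16, 16, 16))
        assert np.abs(w1 - w2).max() < 1e-6

    def test_positive_and_empty_rejected(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-7, 7, (500, 3))
        w = pipe_menon_dcf(pts, (16, 16, 16))
        assert np.all(w > 0)
        with pytest.raises(ValueError):
            pipe_menon_dcf(np.empty((0, 3)), (16, 16, 16))

    def test_weighted_adjoint_sharpens_psf(self):
        """On the designed spiral-projection set, DCF weighting improves
        the point-spread peak-to-sidelobe ratio of the adjoint."""
        from vistamrf.trajectory import design_spiral, tgas_schedule

        n = 32
        sp = design_spiral(220.0, 220.0 / n, gmax=10.0, smax=50.0,
                           max_duration_ms=8.0, pitch_factor=3.0)
        sch = tgas_schedule(8, 1)
        arm = sp.grid_coords(n)
        arm3 = np.concatenate([arm, np.zeros((len(arm), 1))], 1)
        coords = np.concatenate([arm3 @ sch.matrices[g, 0].T
                                 for g in range(8)])
        w = pipe_menon_dcf(coords, (n, n, n), method="grid")
        plan = NufftPlan((n, n, n), coords)
        delta = np.zeros((n, n, n))
        delta[n // 2, n // 2, n // 2] = 1.0
        s = plan.forward(delta)

        def peak_to_sidelobe(img):
            a = np.abs(img)
            peak = a[n // 2, n // 2, n // 2]
            a = a.copy()
            a[n // 2 - 1:n // 2 + 2, n // 2 - 1:n // 2 + 2,
              n // 2 - 1:n // 2 + 2] = 0
            return peak / a.max()

        psf_w = plan.adjoint(s * w)
        psf_u = plan.adjoint(s)
        assert peak_to_sidelobe(psf_w) > peak_to_sidelobe(psf_u)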