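import numpy as np
import pytest

from vistamrf.epg import MYELIN_WATER, batch_simulate
from vistamrf.phantom import (LABEL_WM, PhantomConfig, make_coil_sensitivities,
                              make_phantom, sample_kspace, voxel_timeseries)
from vistamrf.protocol import SequenceProtocol
from vistamrf.trajectory import design_spiral, tgas_schedule


@pytest.fixture(scope="module")
def short_protocol():
    """Structurally complete but short protocol to keep forward tests fast."""
    return SequenceProtocol(n_vista_blocks=2, n_vista_timepoints_per_block=4,
                            n_mrf_timepoints=12, mrf_inversion_index=6,
                            fa_train=np.full(20, 30.0))


class TestPhantom:
    def test_deterministic(self):
        a = make_phantom((16, 16, 16), seed=5)
        b = make_phantom((16, 16, 16), seed=5)
        for f in ("tissue_label", "t1_map", "mwf_map", "b0_map", "b1_map"):
            assert np.array_equal(getattr(a, f), getattr(b, f))
        c = make_phantom((16, 16, 16), seed=6)
        assert not np.array_equal(a.mwf_map, c.mwf_map)

    def test_mwf_range_and_support(self):
        ph = make_phantom((24, 24, 24), seed=1)
        assert np.all(ph.mwf_map >= 0) and np.all(ph.mwf_map <= 1)
        assert np.all(ph.mwf_map[ph.tissue_label != LABEL_WM] == 0)
        wm_mwf = ph.mwf_map[ph.tissue_label == LABEL_WM]
        assert wm_mwf.min() >= 0.05 - 1e-9 and wm_mwf.max() <= 0.18 + 1e-9

    def test_volume_fractions_match_geometry(self):
        """Voxel counts reproduce the analytic ellipsoid volume fractions
        within 2 percentage points (64^3 discretization)."""
        ph = make_phantom((64, 64, 64), seed=2)
        expected = PhantomConfig().expected_fractions()
        tot = ph.tissue_label.size
        measured = {
            "background": np.mean(ph.tissue_label == 0),
            "csf": np.mean(ph.tissue_label == 1),
            "gm": np.mean(ph.tissue_label == 2),
            "wm": np.mean(ph.tissue_label == 3),
        }
        for key, exp in expected.items():
            assert measured[key] == pytest.approx(exp, abs=0.02), key

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_phantom((8, 8, 8))

    def test_coil_sos_positive_inside(self):
        ph = make_phantom((16, 16, 16), seed=0)
        sens = make_coil_sensitivities((16, 16, 16), 8, seed=0)
        sos = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
        assert np.all(sos[ph.mask] > 0)
        assert sos.max() == pytest.approx(1.0)


class TestVoxelTimeseries:
    def test_two_pool_mixture_properties(self, short_protocol):
        ph = make_phantom((16, 16, 16), seed=3)
        ts = voxel_timeseries(ph, short_protocol)
        assert np.all(ts[~ph.mask] == 0)
        # pick a WM voxel and verify the mixture identity pointwise
        idx = np.argwhere(ph.tissue_label == LABEL_WM)[0]
        i, j, k = idx
        b1 = ph.b1_map[i, j, k]
        mwf = ph.mwf_map[i, j, k]
        pd = ph.pd_map[i, j, k]
        s_tis = batch_simulate(short_protocol, [ph.t1_map[i, j, k]],
                               [ph.t2_map[i, j, k]], [b1])[0]
        s_my = batch_simulate(short_protocol, [MYELIN_WATER.t1],
                              [MYELIN_WATER.t2], [b1])[0]
        expected = pd * (mwf * s_my + (1 - mwf) * s_tis)
        assert np.allclose(ts[i, j, k], expected, atol=1e-6)

    def test_mwf_limits(self, short_protocol):
        """mwf=0 gives the pure tissue pool; mwf=1 the pure myelin pool."""
        ph = make_phantom((16, 16, 16), seed=3)
        for value in (0.0, 1.0):
            mwf = np.where(ph.tissue_label == LABEL_WM, value, 0.0)
            ph2 = type(ph)(shape=ph.shape, tissue_label=ph.tissue_label,
                           t1_map=ph.t1_map, t2_map=ph.t2_map,
                           pd_map=ph.pd_map, mwf_map=mwf, b0_map=ph.b0_map,
                           b1_map=ph.b1_map, seed=ph.seed, config=ph.config)
            ts = voxel_timeseries(ph2, short_protocol)
            idx = np.argwhere(ph.tissue_label == LABEL_WM)[0]
            i, j, k = idx
            if value == 0.0:
                ref = batch_simulate(short_protocol, [ph.t1_map[i, j, k]],
                                     [ph.t2_map[i, j, k]],
                                     [ph.b1_map[i, j, k]])[0]
            else:
                ref = batch_simulate(short_protocol, [MYELIN_WATER.t1],
                                     [MYELIN_WATER.t2],
                                     [ph.b1_map[i, j, k]])[0]
            assert np.allclose(ts[i, j, k], ph.pd_map[i, j, k] * ref,
                               atol=1e-6)


class TestSampleKspace:
    @pytest.fixture(scope="class")
    def setup(self, short_protocol):
        n = 16
        ph = make_phantom((n, n, n), seed=4)
        ts = voxel_timeseries(ph, short_protocol)
        sens = make_coil_sensitivities((n, n, n), 3, seed=4)
        spiral = design_spiral(220.0, 220.0 / n, gmax=10.0, smax=50.0,
                               max_duration_ms=8.0, pitch_factor=3.0,
                               dwell_us=40.0)
        schedule = tgas_schedule(2, short_protocol.n_timepoints)
        return ph, ts, sens, spiral, schedule

    def test_noise_determinism(self, setup):
        ph, ts, sens, spiral, schedule = setup
        a = sample_kspace(ts, schedule, spiral, sens, noise_sigma=0.5, seed=9)
        b = sample_kspace(ts, schedule, spiral, sens, noise_sigma=0.5, seed=9)
        assert np.array_equal(a.samples, b.samples)
        c = sample_kspace(ts, schedule, spiral, sens, noise_sigma=0.5,
                          seed=10)
        assert not np.array_equal(a.samples, c.samples)

    def test_delta_object_flat_magnitude(self, short_protocol):
        """A centered point object with flat sensitivity has constant
        k-space magnitude along the whole readout."""
        n = 16
        ts = np.zeros((n, n, n, short_protocol.n_timepoints),
                      dtype=np.float32)
        ts[n // 2, n // 2, n // 2, :] = 1.0
        sens = np.ones((1, n, n, n), dtype=complex)
        spiral = design_spiral(220.0, 220.0 / n, gmax=10.0, smax=50.0,
                               max_duration_ms=8.0, pitch_factor=3.0,
                               dwell_us=40.0)
        schedule = tgas_schedule(1, short_protocol.n_timepoints)
        kd = sample_kspace(ts, schedule, spiral, sens, noise_sigma=0.0)
        mag = np.abs(kd.samples[0, 0])
        assert mag.max() - mag.min() < 1e-3

    def test_off_resonance_matches_brute_force(self, short_protocol):
        """Per-dwell off-resonance phase accrual agrees with a direct DFT
        with explicit per-sample demodulation."""
        n = 16
        rng = np.random.default_rng(2)
        ph = make_phantom((n, n, n), seed=4)
        ts = voxel_timeseries(ph, short_protocol)[..., :2]
        sens = np.ones((1, n, n, n), dtype=complex)
        spiral = design_spiral(220.0, 220.0 / n, gmax=10.0, smax=50.0,
                               max_duration_ms=8.0, pitch_factor=3.0,
                               dwell_us=80.0)
        schedule = tgas_schedule(1, 2)
        b0 = rng.uniform(-40, 40, (n, n, n))
        kd = sample_kspace(ts, schedule, spiral, sens, b0_map=b0,
                           noise_sigma=0.0)
        arm = spiral.grid_coords(n)
        arm3 = np.concatenate([arm, np.zeros((len(arm), 1))], 1)
        coords = arm3 @ schedule.matrices[0, 0].T
        r = np.arange(n) - n // 2
        t_samp = np.arange(len(arm3)) * spiral.dwell_us * 1e-3
        ref = np.zeros(len(coords), complex)
        x = ts[..., 0].astype(complex)
        for j, k in enumerate(coords):
            ph_b0 = np.exp(2j * np.pi * b0 * t_samp[j] * 1e-3)
            phase = np.exp(-2j * np.pi * (k[0] * r[:, None, None]
                                          + k[1] * r[None, :, None]
                                          + k[2] * r[None, None, :]) / n)
            ref[j] = np.sum(x * ph_b0 * phase)
        rel = np.linalg.norm(kd.samples[0, 0] - ref) / np.linalg.norm(ref)
        assert rel < 1e-3

    def test_shape_validation(self, setup, short_protocol):
        ph, ts, sens, spiral, schedule = setup
        with pytest.raises(ValueError):
            sample_kspace(ts, tgas_schedule(1, 2), spiral, sens)
        with pytest.raises(ValueError):
            sample_kspace(ts, schedule, spiral, sens[:, :8])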