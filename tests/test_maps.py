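import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vistamrf.maps import (MyelinReference, compute_mwf, dir_null_times,
                           fit_maps, myelin_reference, synthesize_contrast)
from vistamrf.recon import CoefficientMaps


def coeff_volume_from_atom(dictionary, basis, atom_index, shape, scale=1.0):
    """Project a homogeneous noiseless atom volume onto the basis."""
    c_vec = basis.phi.T @ (scale * dictionary.atoms[atom_index])
    c = np.broadcast_to(c_vec[:, None, None, None],
                        (basis.k,) + shape).copy()
    return CoefficientMaps(c=c, basis_hash="test",
                           objective_trace=np.array([]))


class TestFitMaps:
    def test_noiseless_atom_recovered_everywhere(self, tiny_dictionary,
                                                 tiny_basis):
        i = tiny_dictionary.n_atoms // 3
        shape = (5, 5, 5)
        coeffs = coeff_volume_from_atom(tiny_dictionary, tiny_basis, i, shape)
        b1 = np.full(shape, tiny_dictionary.b1[i])
        q = fit_maps(coeffs, tiny_basis, tiny_dictionary, b1_map=b1,
                     mask=np.ones(shape, bool))
        assert np.all(q.t1_map == tiny_dictionary.t1[i])
        assert np.all(q.t2_map == tiny_dictionary.t2[i])
        # vista image equals the subspace-projected atom's first time point
        proj = tiny_basis.phi @ (tiny_basis.phi.T @ tiny_dictionary.atoms[i])
        assert np.allclose(q.vista_image,
                           proj[tiny_dictionary.protocol.vista_index],
                           rtol=1e-6)

    def test_pd_scale_equivariance(self, tiny_dictionary, tiny_basis):
        i = 7
        shape = (4, 4, 4)
        b1 = np.full(shape, tiny_dictionary.b1[i])
        mask = np.ones(shape, bool)
        q1 = fit_maps(coeff_volume_from_atom(tiny_dictionary, tiny_basis, i,
                                             shape, 1.0),
                      tiny_basis, tiny_dictionary, b1, mask=mask)
        q3 = fit_maps(coeff_volume_from_atom(tiny_dictionary, tiny_basis, i,
                                             shape, 3.0),
                      tiny_basis, tiny_dictionary, b1, mask=mask)
        assert np.allclose(q3.pd_map, 3.0 * q1.pd_map, rtol=1e-10)
        assert np.array_equal(q3.t1_map, q1.t1_map)
        assert np.array_equal(q3.t2_map, q1.t2_map)

    def test_missing_b1_warns_and_uses_unity(self, tiny_dictionary,
                                             tiny_basis, caplog):
        import logging

        i = int(np.flatnonzero(tiny_dictionary.b1 == 1.0)[0])
        coeffs = coeff_volume_from_atom(tiny_dictionary, tiny_basis, i,
                                        (3, 3, 3))
        with caplog.at_level(logging.WARNING):
            q = fit_maps(coeffs, tiny_basis, tiny_dictionary,
                         mask=np.ones((3, 3, 3), bool))
        assert "B1" in caplog.text
        assert np.all(q.b1_map_used == 1.0)
        assert np.all(q.t1_map == tiny_dictionary.t1[i])


class TestMyelinReference:
    def test_reference_in_unit_interval(self, protocol):
        ref = myelin_reference(protocol, np.arange(0.70, 1.21, 0.05))
        assert np.all(ref.s_myelin > 0) and np.all(ref.s_myelin < 1)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            MyelinReference(b1_values=np.array([1.0]),
                            s_myelin=np.array([-0.1]))


class TestComputeMwf:
    def setup_method(self):
        self.ref = MyelinReference(b1_values=np.array([1.0]),
                                   s_myelin=np.array([0.35]))

    def test_zero_vista_zero_mwf(self):
        mwf = compute_mwf(np.zeros((4, 4, 4)), np.ones((4, 4, 4)), self.ref,
                          np.ones((4, 4, 4)))
        assert np.all(mwf == 0)

    def test_pure_myelin_voxel_unity(self):
        pd = np.full((3, 3, 3), 0.8)
        vista = pd * 0.35
        mwf = compute_mwf(vista, pd, self.ref, np.ones((3, 3, 3)))
        assert np.allclose(mwf, 1.0)

    def test_low_pd_floored_to_zero(self):
        pd = np.ones((4, 4, 4))
        pd[0, 0, 0] = 1e-5
        vista = 0.1 * np.ones((4, 4, 4))
        mwf = compute_mwf(vista, pd, self.ref, np.ones((4, 4, 4)))
        assert mwf[0, 0, 0] == 0.0
        assert np.all(mwf.ravel()[1:] > 0)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           mwf_true=st.floats(min_value=0.0, max_value=1.0))
    def test_scale_invariance(self, scale, mwf_true):
        """Rescaling pd and vista together leaves the MWF unchanged."""
        pd = np.full((2, 2, 2), 0.9)
        vista = pd * 0.35 * mwf_true
        a = compute_mwf(vista, pd, self.ref, np.ones((2, 2, 2)))
        b = compute_mwf(scale * vista, scale * pd, self.ref,
                        np.ones((2, 2, 2)))
        assert np.allclose(a, b, atol=1e-12)
        assert np.allclose(a, mwf_true, atol=1e-9)


class TestSyntheticContrast:
    t1 = np.array([[[750.0, 1300.0, 4000.0]]])
    t2 = np.array([[[60.0, 75.0, 2000.0]]])
    pd = np.array([[[0.77, 0.86, 1.0]]])

    def test_flair_nulls_csf(self):
        img = synthesize_contrast(self.t1, self.t2, self.pd, "flair",
                                  ti=4000.0 * np.log(2.0), te=0.0)
        assert abs(img[0, 0, 2]) < 1e-6 * self.pd[0, 0, 2]
        assert abs(img[0, 0, 0]) > 0.01  # WM not nulled

    def test_t2w_decreasing_in_te(self):
        sig = [synthesize_contrast(self.t1, self.t2, self.pd, "t2w",
                                   tr=4000.0, te=te)[0, 0, 0]
               for te in (20.0, 60.0, 120.0, 200.0)]
        assert np.all(np.diff(sig) < 0)

    def test_dir_nulls_both_targets(self):
        """TIs from the module's own root solver suppress both targeted
        tissues (CSF and WM) below 1e-4 x pd."""
        ti1, ti2 = dir_null_times(4000.0, 750.0)
        img = synthesize_contrast(self.t1, self.t2, self.pd, "dir",
                                  ti1=ti1, ti2=ti2, te=0.0)
        assert abs(img[0, 0, 2]) < 1e-4 * self.pd[0, 0, 2]
        assert abs(img[0, 0, 0]) < 1e-4 * self.pd[0, 0, 0]
        assert abs(img[0, 0, 1]) > 1e-3  # GM survives

    def test_background_stays_zero(self):
        t1 = np.array([[[0.0, 750.0]]])
        img = synthesize_contrast(t1, np.array([[[0.0, 60.0]]]),
                                  np.array([[[0.0, 0.77]]]), "t1w")
        assert img[0, 0, 0] == 0.0 and img[0, 0, 1] != 0.0

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            synthesize_contrast(self.t1, self.t2, self.pd, "stir")

    def test_mprage_wm_gm_contrast(self):
        img = synthesize_contrast(self.t1, self.t2, self.pd, "mprage",
                                  ti=1100.0, te=3.0, flip_deg=9.0)
        assert img[0, 0, 0] > img[0, 0, 1]  # WM brighter than GM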