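"""Dense-CRF energies and mean-field inference."""

import itertools

import numpy as np
import pytest

from dualpath3d import LabelVolume, Volume3D
from dualpath3d.crf import (CRFParams, ResourceGuardError, _flatten_features,
                            _kernel_matrix, gibbs_energy, mean_field_infer,
                            pairwise_kernel, probs_from_labels, refine,
                            unary_from_probs)


class TestUnary:
    def test_certain_class_has_zero_energy(self):
        p = np.zeros((2, 1, 1, 1))
        p[0] = 1.0
        u = unary_from_probs(p)
        assert u[0, 0, 0, 0] == 0.0
        assert u[1, 0, 0, 0] > 20  # floored log

    def test_uniform_probs_equal_energies(self):
        p = np.full((3, 2, 2, 2), 1 / 3)
        u = unary_from_probs(p)
        np.testing.assert_allclose(u, np.log(3), atol=1e-12)

    def test_direct_arithmetic(self):
        p = np.array([0.7, 0.2, 0.1]).reshape(3, 1, 1, 1)
        u = unary_from_probs(p)
        np.testing.assert_allclose(u.ravel(),
                                   [-np.log(0.7), -np.log(0.2), -np.log(0.1)])


class TestPairwiseKernel:
    PARAMS = CRFParams(w1=1.0, w2=1.0, theta_alpha=1.0, theta_beta=1.0,
                       theta_gamma=1.0)

    def test_coincident_features(self):
        k = pairwise_kernel(((0, 0, 0), 0.5), ((0, 0, 0), 0.5), self.PARAMS)
        assert k == pytest.approx(2.0)

    def test_distant_pair_decays_to_zero(self):
        k = pairwise_kernel(((0, 0, 0), 0.0), ((1000, 0, 0), 0.0), self.PARAMS)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_unit_offset_value(self):
        k = pairwise_kernel(((0, 0, 0), 0.0), ((1, 0, 0), 0.0), self.PARAMS)
        assert k == pytest.approx(2 * np.exp(-0.5))

    def test_symmetry(self, rng):
        for _ in range(20):
            fi = (tuple(rng.uniform(0, 5, 3)), float(rng.normal()))
            fj = (tuple(rng.uniform(0, 5, 3)), float(rng.normal()))
            params = CRFParams(w1=float(rng.uniform(0, 2)), w2=float(rng.uniform(0, 2)),
                               theta_alpha=1.3, theta_beta=0.7, theta_gamma=2.1)
            assert pairwise_kernel(fi, fj, params) == \
                pytest.approx(pairwise_kernel(fj, fi, params))

    def test_zero_bandwidth_limit(self):
        params = CRFParams(w1=1.0, w2=0.0, theta_alpha=0.0, theta_beta=1.0)
        assert pairwise_kernel(((0, 0, 0), 0.0), ((1, 0, 0), 0.0), params) == 0.0
        assert pairwise_kernel(((0, 0, 0), 0.0), ((0, 0, 0), 0.0), params) == 1.0


class TestGibbsEnergy:
    def test_zero_pairwise_weights_sum_of_unaries(self, rng):
        img = Volume3D(rng.normal(size=(2, 2, 2)).astype(np.float32))
        u = rng.uniform(0, 2, size=(2, 2, 2, 2))
        lab = rng.integers(0, 2, size=(2, 2, 2)).astype(np.int16)
        params = CRFParams(w1=0, w2=0)
        flat = lab.ravel()
        expected = u.reshape(2, -1)[flat, np.arange(8)].sum()
        assert gibbs_energy(lab, u, img, params) == pytest.approx(expected)

    def test_uniform_labels_no_potts_penalty(self, rng):
        img = Volume3D(rng.normal(size=(2, 2, 2)).astype(np.float32))
        u = rng.uniform(0, 2, size=(2, 2, 2, 2))
        lab = np.ones((2, 2, 2), dtype=np.int16)
        params = CRFParams(w1=1.0, w2=1.0)
        expected = u[1].sum()
        assert gibbs_energy(lab, u, img, params) == pytest.approx(expected)

    def test_two_voxel_enumeration_by_hand(self):
        # 2x1x1 instance: energies for all four labelings from the formula
        img = Volume3D(np.array([0.0, 1.0]).reshape(2, 1, 1).astype(np.float32))
        u = np.array([[1.0, 2.0], [3.0, 0.5]]).reshape(2, 2, 1, 1)
        params = CRFParams(w1=0.5, w2=0.25, theta_alpha=2.0, theta_beta=1.0,
                           theta_gamma=1.0)
        k01 = (0.5 * np.exp(-1 / (2 * 4) - 1 / 2) + 0.25 * np.exp(-1 / 2))
        for l0, l1 in itertools.product(range(2), repeat=2):
            lab = np.array([l0, l1], dtype=np.int16).reshape(2, 1, 1)
            expected = u[l0, 0, 0, 0] + u[l1, 1, 0, 0] + (k01 if l0 != l1 else 0.0)
            assert gibbs_energy(lab, u, img, params) == pytest.approx(expected)

    def test_resource_guard(self):
        img = Volume3D(np.zeros((20, 20, 20), dtype=np.float32))
        u = np.zeros((2, 20, 20, 20))
        with pytest.raises(ResourceGuardError):
            gibbs_energy(np.zeros((20, 20, 20), dtype=np.int16), u, img, CRFParams())


def brute_force_minimum(unary, img, params):
    """Exhaustive enumeration oracle over all labelings (vectorized)."""
    L = unary.shape[0]
    n = img.data.size
    pos, inten = _flatten_features(img)
    K = _kernel_matrix(pos, inten, params)
    u = unary.reshape(L, -1).T
    assigns = np.array(list(itertools.product(range(L), repeat=n)), dtype=np.int8)
    e = u[np.arange(n), assigns].sum(axis=1)
    iu, ju = np.triu_indices(n, k=1)
    e = e + (assigns[:, iu] != assigns[:, ju]) @ K[iu, ju]
    return float(e.min()), np.asarray(e)


class TestMeanField:
    def test_no_coupling_returns_unary_argmin(self, rng):
        img = Volume3D(rng.normal(size=(3, 2, 2)).astype(np.float32))
        u = rng.uniform(0, 3, size=(3, 3, 2, 2))
        lab, q = mean_field_infer(u, img, CRFParams(w1=0, w2=0), method="exact")
        np.testing.assert_array_equal(lab.data, u.argmin(axis=0))
        np.testing.assert_allclose(q.sum(axis=0), 1.0, atol=1e-9)

    def test_2x2_grid_matches_enumeration(self, rng):
        img = Volume3D(rng.normal(size=(2, 2, 1)).astype(np.float32))
        probs = rng.dirichlet((3, 3), size=4).T.reshape(2, 2, 2, 1)
        u = unary_from_probs(probs)
        params = CRFParams(w1=0.3, w2=0.2, theta_alpha=1.5, theta_beta=1.0,
                           theta_gamma=1.5, n_iters=10, n_labels=2)
        lab, _ = mean_field_infer(u, img, params, method="exact")
        best, _ = brute_force_minimum(u, img, params)
        assert gibbs_energy(lab.data, u, img, params) == pytest.approx(best)

    def test_dissenting_voxel_flipped_and_energy_drops(self):
        # a weak-unary dissenter inside a uniform region is absorbed
        shape = (3, 3, 1)
        img = Volume3D(np.zeros(shape, dtype=np.float32))
        probs = np.full((2,) + shape, 0.0)
        probs[0] = 0.6
        probs[1] = 0.4
        probs[0, 1, 1, 0], probs[1, 1, 1, 0] = 0.45, 0.55  # dissenter
        u = unary_from_probs(probs)
        params = CRFParams(w1=0.0, w2=0.5, theta_gamma=1.5, n_iters=10, n_labels=2)
        lab, _ = mean_field_infer(u, img, params, method="exact")
        assert lab.data[1, 1, 0] == 0
        dissent = np.zeros(shape, dtype=np.int16)
        dissent[1, 1, 0] = 1
        assert gibbs_energy(lab.data, u, img, params) < \
            gibbs_energy(dissent, u, img, params)

    def test_intensity_shift_invariance(self, rng):
        # constant intensity offset leaves the appearance kernel unchanged
        base = rng.normal(size=(2, 2, 2)).astype(np.float32)
        probs = rng.dirichlet((2, 2, 2), size=8).T.reshape(3, 2, 2, 2)
        u = unary_from_probs(probs)
        params = CRFParams(w1=0.4, w2=0.2, n_iters=5)
        lab1, q1 = mean_field_infer(u, Volume3D(base), params, method="exact")
        lab2, q2 = mean_field_infer(u, Volume3D(base + 100.0), params, method="exact")
        np.testing.assert_array_equal(lab1.data, lab2.data)
        # float32 storage of the shifted image leaves ~1e-7 rounding residue
        np.testing.assert_allclose(q1, q2, atol=1e-5)

    def test_exact_method_guard(self):
        img = Volume3D(np.zeros((30, 30, 30), dtype=np.float32))
        u = np.zeros((2, 30, 30, 30))
        with pytest.raises(ResourceGuardError):
            mean_field_infer(u, img, CRFParams(), method="exact")

    def test_misaligned_unary_rejected(self):
        img = Volume3D(np.zeros((3, 3, 3), dtype=np.float32))
        with pytest.raises(ValueError):
            mean_field_infer(np.zeros((2, 2, 2, 2)), img, CRFParams())


class TestFilterApproximation:
    def test_filter_agrees_with_exact_on_small_structured_volume(self, rng):
        # both inference routes should restore an obvious speckle
        shape = (9, 9, 9)
        img = Volume3D(np.zeros(shape, dtype=np.float32))
        lab = np.zeros(shape, dtype=np.int16)
        lab[4, 4, 4] = 1  # lone dissenter
        probs = probs_from_labels(LabelVolume(lab), n_classes=2, confidence=0.8)
        u = unary_from_probs(probs)
        params = CRFParams(w1=0.02, w2=0.04, n_iters=5, n_labels=2)
        lab_e, _ = mean_field_infer(u, img, params, method="exact")
        lab_f, _ = mean_field_infer(u, img, params, method="filter")
        assert lab_e.data[4, 4, 4] == 0
        assert lab_f.data[4, 4, 4] == 0
        agreement = (lab_e.data == lab_f.data).mean()
        assert agreement > 0.97

    def test_refine_marginals_normalized(self, preprocessed_phantom):
        img, labels = preprocessed_phantom
        probs = probs_from_labels(labels, confidence=0.9)
        out, q = refine(probs, img, method="filter")
        np.testing.assert_allclose(q.sum(axis=0), 1.0, atol=1e-6)
        assert out.shape == img.shape


def test_probs_from_labels_confidence():
    lab = LabelVolume(np.array([[[0, 1, 2]]], dtype=np.int16))
    p = probs_from_labels(lab, confidence=0.9)
    np.testing.assert_allclose(p.data[:, 0, 0, 0], [0.9, 0.05, 0.05])
    np.testing.assert_allclose(p.data.sum(axis=0), 1.0)
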