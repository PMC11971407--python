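"""Angle-embedding kernel, statevector oracle, gate decomposition,
feature-map baseline kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qscreen.kernel import (GramMatrix, QuantumCircuit, SingleQubitGate,
                            feature_overlap, featuremap_gram, gram_matrix,
                            kernel_value, kernel_value_statevector, ry,
                            statevector_simulate, verify_ry_decomposition,
                            z_featuremap_kernel, zz_featuremap_kernel)


class TestFeatureOverlap:
    @pytest.mark.parametrize("delta,expected", [
        (0.0, 1.0), (np.pi, 0.0), (np.pi / 2, 0.5), (-np.pi / 2, 0.5),
    ])
    def test_reference_angles(self, delta, expected):
        assert feature_overlap(delta) == pytest.approx(expected, abs=1e-12)

    def test_matches_statevector(self, rng):
        for delta in rng.uniform(-10, 10, 50):
            circ = QuantumCircuit(1)
            circ.add(SingleQubitGate("RY", delta), 0)
            amp = statevector_simulate(circ)
            assert feature_overlap(delta) == pytest.approx(
                float(np.abs(amp[0]) ** 2), abs=1e-12)


class TestKernelValue:
    def test_self_similarity_is_one(self, rng):
        a = rng.standard_normal(6)
        w = rng.dirichlet(np.ones(6))
        assert kernel_value(a, a, w) == pytest.approx(1.0, abs=1e-12)

    def test_two_feature_half(self):
        assert kernel_value(np.array([0.0, 0.0]), np.array([0.0, np.pi]),
                            np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_matches_per_qubit_statevector_oracle(self, rng):
        for _ in range(20):
            a = rng.uniform(-np.pi, np.pi, 15)
            b = rng.uniform(-np.pi, np.pi, 15)
            w = rng.dirichlet(np.ones(15))
            assert kernel_value(a, b, w) == pytest.approx(
                kernel_value_statevector(a, b, w), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_value(np.zeros(3), np.zeros(4), np.full(3, 1 / 3))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_bounds_and_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        a, b = rng.uniform(-8, 8, n), rng.uniform(-8, 8, n)
        w = rng.dirichlet(np.ones(n))
        k = kernel_value(a, b, w)
        assert 0.0 <= k <= 1.0 + 1e-12
        perm = rng.permutation(n)
        assert kernel_value(a[perm], b[perm], w[perm]) == pytest.approx(
            k, abs=1e-12)


class TestGramMatrix:
    def test_single_row_unit(self):
        g = gram_matrix(np.array([[0.3, -0.4]]), np.array([[0.3, -0.4]]),
                        np.array([0.6, 0.4]))
        np.testing.assert_allclose(g.values, [[1.0]])

    def test_train_gram_valid_up_to_n200(self, rng):
        X = rng.uniform(-np.pi, np.pi, (200, 13))
        w = rng.dirichlet(np.ones(13))
        g = gram_matrix(X, X, w)
        g.validate_train()  # symmetry, unit diagonal, PSD

    def test_cross_gram_transpose_symmetry(self, rng):
        A = rng.standard_normal((7, 5))
        B = rng.standard_normal((4, 5))
        w = rng.dirichlet(np.ones(5))
        kab = gram_matrix(A, B, w).values
        kba = gram_matrix(B, A, w).values
        np.testing.assert_allclose(kab, kba.T, atol=1e-14)

    def test_shape_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GramMatrix(np.ones((2, 2)), ["a"], ["b", "c"])


class TestStatevectorSimulate:
    def test_hadamard(self):
        circ = QuantumCircuit(1).add(SingleQubitGate("H"), 0)
        np.testing.assert_allclose(statevector_simulate(circ),
                                   [1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_bell_state(self):
        circ = QuantumCircuit(2)
        circ.add(SingleQubitGate("H"), 0)
        circ.add(SingleQubitGate("X"), 1, control=0)
        state = statevector_simulate(circ)
        np.testing.assert_allclose(
            state, [1 / np.sqrt(2), 0, 0, 1 / np.sqrt(2)], atol=1e-12)

    def test_product_circuit_equals_kron_of_2x2(self, rng):
        gates = []
        per_qubit = []
        circ = QuantumCircuit(4)
        for q in range(4):
            g1 = SingleQubitGate("RY", float(rng.uniform(-np.pi, np.pi)))
            g2 = SingleQubitGate("RZ", float(rng.uniform(-np.pi, np.pi)))
            circ.add(g1, q).add(g2, q)
            per_qubit.append(g2.matrix @ g1.matrix @ np.array([1, 0]))
        expect = per_qubit[0]
        for v in per_qubit[1:]:
            expect = np.kron(expect, v)
        np.testing.assert_allclose(statevector_simulate(circ), expect,
                                   atol=1e-12)

    def test_norm_preserved(self, rng):
        circ = QuantumCircuit(3)
        for q in range(3):
            circ.add(SingleQubitGate("H"), q)
            circ.add(SingleQubitGate("P", float(rng.uniform(0, 7))), q)
        circ.add(SingleQubitGate("X"), 2, control=0)
        assert np.linalg.norm(statevector_simulate(circ)) == pytest.approx(
            1.0, abs=1e-12)

    def test_out_of_range_qubit_rejected(self):
        with pytest.raises(ValueError):
            QuantumCircuit(2).add(SingleQubitGate("H"), 5)


class TestRyDecomposition:
    def test_exact_ry_at_zero(self):
        rep = verify_ry_decomposition(0.0)
        assert rep["p0_exact_ry"] == pytest.approx(1.0)

    def test_canonical_zsx_equals_ry_up_to_phase(self, rng):
        for theta in rng.uniform(-2 * np.pi, 2 * np.pi, 100):
            rep = verify_ry_decomposition(float(theta))
            assert rep["canonical_max_deviation"] <= 1e-12

    def test_printed_sequence_is_complement_and_flagged(self):
        rep = verify_ry_decomposition(0.0)
        assert rep["p0_printed_sequence"] == pytest.approx(0.0, abs=1e-12)
        assert rep["diagnostic_flag"]
        for theta in (0.3, 1.2, -2.5):
            rep = verify_ry_decomposition(theta)
            assert rep["printed_is_complement"]
            assert rep["p0_printed_sequence"] == pytest.approx(
                np.sin(theta / 2) ** 2, abs=1e-12)


class TestZFeatureMap:
    def test_identical_inputs_unity(self, rng):
        a = rng.standard_normal(5)
        assert z_featuremap_kernel(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_single_feature_quarter_turn_closed_form(self):
        # |<phi(a)|phi(b)>|^2 = cos^2(a-b) for one rep of H, P(2x)
        assert z_featuremap_kernel([0.0], [np.pi / 2], reps=1) \
            == pytest.approx(0.0, abs=1e-12)
        assert z_featuremap_kernel([0.0], [np.pi / 4], reps=1) \
            == pytest.approx(0.5, abs=1e-12)

    def test_reps2_matches_full_statevector(self, rng):
        a = rng.uniform(-2, 2, 3)
        b = rng.uniform(-2, 2, 3)

        def state(x):
            circ = QuantumCircuit(3)
            for _ in range(2):
                for q in range(3):
                    circ.add(SingleQubitGate("H"), q)
                    circ.add(SingleQubitGate("P", 2 * x[q]), q)
            return statevector_simulate(circ)

        expect = float(np.abs(np.vdot(state(a), state(b))) ** 2)
        assert z_featuremap_kernel(a, b, reps=2) == pytest.approx(
            expect, abs=1e-12)


class TestZZFeatureMap:
    def test_identical_inputs_unity(self, rng):
        a = rng.standard_normal(3)
        assert zz_featuremap_kernel(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_reduces_to_z_map_when_entangling_phase_vanishes(self):
        # with x0 = pi the pairwise phase 2(pi-x0)(pi-x1) is zero, so the
        # entangler contributes nothing and the fidelity factorizes
        a = np.array([np.pi, 0.7])
        b = np.array([np.pi, -0.4])
        assert zz_featuremap_kernel(a, b, reps=1) == pytest.approx(
            z_featuremap_kernel(a, b, reps=1), abs=1e-12)

    def test_symmetric(self, rng):
        for _ in range(5):
            a = rng.uniform(-2, 2, 4)
            b = rng.uniform(-2, 2, 4)
            assert zz_featuremap_kernel(a, b) == pytest.approx(
                zz_featuremap_kernel(b, a), abs=1e-12)

    def test_too_many_features_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            zz_featuremap_kernel(np.zeros(21), np.zeros(21))

    def test_featuremap_gram_matches_pairwise(self, rng):
        X = rng.uniform(-1, 1, (4, 3))
        G = featuremap_gram(X, X, kind="zz")
        for i in range(4):
            for j in range(4):
                assert G[i, j] == pytest.approx(
                    zz_featuremap_kernel(X[i], X[j]), abs=1e-12)


def test_ry_matrix_definition():
    theta = 0.77
    m = ry(theta)
    expect = np.array([[np.cos(theta / 2), -np.sin(theta / 2)],
                       [np.sin(theta / 2), np.cos(theta / 2)]])
    np.testing.assert_allclose(m, expect, atol=1e-15)
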