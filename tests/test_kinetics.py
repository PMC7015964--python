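import numpy as np
import pytest
import scipy.linalg

from kinetic_ensemble import kinetics
from kinetic_ensemble.kinetics import (
    KineticScheme, hierarchical_matrix, kron_structure, kronecker_sum,
    rotation_rate_matrix, spectral_structure, two_state_matrix,
    uniform_jump_matrix, uniform_structure, hierarchical_structure,
    rotation_structure,
)


def eigvals(rm):
    return np.sort(np.linalg.eigvals(rm.Q).real)


class TestConstructions:
    def test_uniform_two_state(self):
        rm = uniform_jump_matrix(2, 1.0)
        np.testing.assert_allclose(rm.Q, [[-0.5, 0.5], [0.5, -0.5]])
        np.testing.assert_allclose(eigvals(rm), [-1.0, 0.0], atol=1e-12)

    def test_uniform_four_state(self):
        rm = uniform_jump_matrix(4, 1.0)
        assert rm.Q[0, 1] == pytest.approx(0.25)
        assert rm.Q[0, 0] == pytest.approx(-0.75)
        np.testing.assert_allclose(eigvals(rm), [-1, -1, -1, 0], atol=1e-12)

    def test_uniform_176_has_175_degenerate_eigenvalues(self):
        tau = 2e-9
        rm = uniform_jump_matrix(176, tau)
        w = eigvals(rm)
        n_deg = np.sum(np.abs(w + 1.0 / tau) < 1e-8 / tau)
        assert n_deg == 175
        assert np.abs(w).min() < 1e-8 / tau  # the single zero

    def test_hierarchical_three_distinct_eigenvalues(self):
        rm = hierarchical_matrix([139, 37], 1e-6, 1.4e-9)
        w = eigvals(rm)
        tol = 1e-6 * np.abs(w).max()
        uniq = [w[0]]
        for v in w[1:]:
            if abs(v - uniq[-1]) > tol:
                uniq.append(v)
        assert len(uniq) == 3
        assert min(abs(u + 1e6) for u in uniq) < 1e-2 * 1e6
        assert min(abs(u + 1 / 1.4e-9) for u in uniq) < 1e-6 / 1.4e-9

    def test_four_state_two_timescale_matrix(self):
        # 2+2 grouping: inter rate tau_s^-1/4, intra (tau_f^-1 - tau_s^-1/2)/2
        tau_s, tau_f = 5e-9, 50e-12
        rm = hierarchical_matrix([2, 2], tau_s, tau_f)
        assert rm.Q[0, 2] == pytest.approx(1 / (4 * tau_s))
        assert rm.Q[0, 1] == pytest.approx((1 / tau_f - 0.5 / tau_s) / 2)
        w = eigvals(rm)
        np.testing.assert_allclose(
            w, [-1 / tau_f, -1 / tau_f, -1 / tau_s, 0.0], rtol=1e-10, atol=1)

    def test_hierarchical_negative_intra_rate_rejected(self):
        with pytest.raises(ValueError, match="group 0"):
            hierarchical_matrix([3, 3], 1e-12, 1e-6)  # slow faster than fast

    def test_single_group_reduces_to_uniform(self):
        rm = hierarchical_matrix([5], 1.0, 2.0)
        np.testing.assert_allclose(rm.Q, uniform_jump_matrix(5, 2.0).Q)

    @pytest.mark.parametrize("order,tau", [(2, 100e-6), (3, 1e-12)])
    def test_rotation_matrices(self, order, tau):
        rm = rotation_rate_matrix(order, tau)
        assert rm.Q[0, 1] == pytest.approx(1 / (order * tau))
        w = eigvals(rm)
        np.testing.assert_allclose(w[:-1], -1 / tau, rtol=1e-10)
        assert abs(w[-1]) < 1e-8 / tau

    def test_two_state_asymmetric(self):
        rm = two_state_matrix(0.3, 1e-9)
        np.testing.assert_allclose(rm.populations @ rm.Q, 0.0, atol=1e-3)
        np.testing.assert_allclose(eigvals(rm), [-1e9, 0.0], atol=1e-3)


class TestKroneckerSum:
    def test_eigenvalues_are_pairwise_sums(self):
        a = uniform_jump_matrix(2, 1.0)          # {0, -1}
        b = rotation_rate_matrix(3, 0.5)         # {0, -2, -2}
        ks = kronecker_sum(a, b)
        np.testing.assert_allclose(
            eigvals(ks), [-3, -3, -2, -2, -1, 0], atol=1e-10)

    def test_identity_operand(self):
        a = uniform_jump_matrix(3, 2.0)
        one = kinetics.RateMatrix(np.zeros((1, 1)), np.ones(1))
        np.testing.assert_allclose(kronecker_sum(a, one).Q, a.Q)

    def test_stationary_distribution_is_outer_product(self):
        a = two_state_matrix(0.3, 1.0)
        b = rotation_rate_matrix(3, 1.0)
        ks = kronecker_sum(a, b)
        np.testing.assert_allclose(
            ks.populations, np.kron([0.3, 0.7], np.full(3, 1 / 3)))


class TestSpectralStructure:
    def test_uniform_projectors(self):
        rm = uniform_jump_matrix(4, 1.0)
        st = spectral_structure(rm)
        assert st.n_modes == 2
        A0, A1 = st.projectors()
        np.testing.assert_allclose(A0, np.full((4, 4), 0.25), atol=1e-12)
        np.testing.assert_allclose(A1, np.eye(4) - 0.25, atol=1e-12)

    def test_projector_algebra(self):
        # completeness and idempotence/orthogonality of spectral projectors
        for rm in (uniform_jump_matrix(5, 1.0),
                   hierarchical_matrix([5, 3], 10.0, 1.0),
                   kronecker_sum(uniform_jump_matrix(3, 1.0),
                                 rotation_rate_matrix(3, 0.1))):
            st = spectral_structure(rm)
            projs = st.projectors()
            np.testing.assert_allclose(sum(projs), np.eye(rm.n_states), atol=1e-9)
            for i, A in enumerate(projs):
                for j, B in enumerate(projs):
                    expected = A if i == j else np.zeros_like(A)
                    np.testing.assert_allclose(A @ B, expected, atol=1e-9)

    def test_one_state_matrix(self):
        rm = kinetics.RateMatrix(np.zeros((1, 1)), np.ones(1))
        st = spectral_structure(rm)
        assert st.n_modes == 1
        np.testing.assert_allclose(st.projectors()[0], 1.0)

    def test_reducible_matrix_rejected(self):
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = 1.0
        Q[2, 3] = Q[3, 2] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rm = kinetics.RateMatrix(Q, np.full(4, 0.25))
        with pytest.raises(ValueError, match="educible"):
            spectral_structure(rm)

    def test_propagator_is_stochastic(self):
        rm = hierarchical_matrix([4, 3], 5.0, 1.0)
        for tau in (0.0, 0.3, 2.0, 20.0):
            P = rm.propagator(tau)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)


class TestFastRecipes:
    """The symbolic partition recipes must reproduce the brute-force
    projectors entrywise on scaled-down instances of every scheme."""

    def _assert_recipes_match(self, symbolic, rm, timescales):
        numeric = spectral_structure(rm)
        num = {round(m.eigenvalue, 6): m.materialize() for m in numeric.modes}
        assert symbolic.n_modes == numeric.n_modes
        for mode in symbolic.modes:
            lam = round(mode.rate(timescales), 6)
            np.testing.assert_allclose(mode.materialize(), num[lam], atol=1e-10)

    def test_uniform(self):
        ts = {"tau_ensemble": 2.0}
        self._assert_recipes_match(uniform_structure(6), uniform_jump_matrix(6, 2.0), ts)

    def test_hierarchical(self):
        ts = {"tau_pincer": 10.0, "tau_ensemble": 1.0}
        labels = np.array([0] * 5 + [1] * 3)
        self._assert_recipes_match(
            hierarchical_structure(labels), hierarchical_matrix([5, 3], 10.0, 1.0), ts)

    def test_rotation(self):
        ts = {"tau_methyl": 0.5}
        self._assert_recipes_match(
            rotation_structure(3, "tau_methyl"), rotation_rate_matrix(3, 0.5), ts)

    def test_kronecker_uniform_by_methyl(self):
        ts = {"tau_ensemble": 2.0, "tau_methyl": 0.01}
        sym = kron_structure(uniform_structure(4), rotation_structure(3, "tau_methyl"))
        rm = kronecker_sum(uniform_jump_matrix(4, 2.0), rotation_rate_matrix(3, 0.01))
        self._assert_recipes_match(sym, rm, ts)

    def test_kronecker_hierarchical_by_aromatic(self):
        ts = {"tau_pincer": 50.0, "tau_ensemble": 1.0, "tau_aromatic": 0.2}
        labels = np.array([0, 0, 0, 1, 1])
        sym = kron_structure(hierarchical_structure(labels),
                             rotation_structure(2, "tau_aromatic"))
        rm = kronecker_sum(hierarchical_matrix([3, 2], 50.0, 1.0),
                           rotation_rate_matrix(2, 0.2))
        self._assert_recipes_match(sym, rm, ts)


class TestKineticScheme:
    def test_requires_pincer_slower_than_ensemble(self):
        with pytest.raises(ValueError):
            KineticScheme(tau_ensemble=2e-9, tau_pincer=1e-9)

    def test_member_structure_selection(self):
        uniform = KineticScheme(tau_ensemble=2e-9)
        assert uniform.member_structure(5).n_modes == 2
        hier = KineticScheme(tau_ensemble=2e-9, tau_pincer=1e-6)
        labels = np.array([0, 0, 0, 1, 1])
        assert hier.member_structure(5, labels).n_modes == 3
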