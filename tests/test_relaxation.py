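import numpy as np
import pytest

from kinetic_ensemble import kinetics, relaxation
from kinetic_ensemble.kinetics import KineticScheme
from kinetic_ensemble.relaxation import (
    SpinSystem, build_spin_system, buildup_curves, pair_spectra,
    read_buildup_table, relaxation_matrix, simulate_buildup_table,
    solomon_rates, transfer_matrices, write_buildup_table,
)
from kinetic_ensemble.spectral import PairSpectral
from kinetic_ensemble.structures import generate_synthetic_ensemble

OMEGA0 = 2 * np.pi * 900e6


def rigid_pair_spectral(r, tau_c):
    return PairSpectral(np.array([r ** -6]), np.array([0.0]), tau_c)


def closed_form_rates(r, tau_c, omega0):
    """Independent Solomon oracle from the single Lorentzian J."""
    def J(w):
        return 2 * tau_c / (1 + (w * tau_c) ** 2) * (r * 1e-10) ** -6
    K = relaxation.SOLOMON_K
    rho = K * (J(0) + 3 * J(omega0) + 6 * J(2 * omega0))
    sigma = K * (6 * J(2 * omega0) - J(0))
    return rho, sigma


class TestSolomonRates:
    def test_rigid_pair_matches_closed_form(self):
        rho, sigma = solomon_rates(rigid_pair_spectral(2.0, 4.3e-9), OMEGA0)
        rho_ref, sig_ref = closed_form_rates(2.0, 4.3e-9, OMEGA0)
        assert rho == pytest.approx(rho_ref, rel=1e-10)
        assert sigma == pytest.approx(sig_ref, rel=1e-10)

    def test_spin_diffusion_limit_negative_cross_relaxation(self):
        # omega tau_c >> 1: J(0) dominates, sigma < 0
        _, sigma = solomon_rates(rigid_pair_spectral(2.0, 10e-9), OMEGA0)
        assert sigma < 0

    def test_extreme_narrowing_limit(self):
        # omega tau_c << 1: sigma > 0 and sigma/rho -> 1/2
        rho, sigma = solomon_rates(rigid_pair_spectral(2.0, 1e-12), OMEGA0)
        assert sigma > 0
        assert sigma / rho == pytest.approx(0.5, abs=1e-4)


class TestBuildupCurves:
    def make_two_spin(self, r=2.5, tau_c=4.3e-9):
        system = SpinSystem(["a", "b"], {"a": ["a"], "b": ["b"]}, OMEGA0)
        spectra = {("a", "b"): rigid_pair_spectral(r, tau_c)}
        return relaxation_matrix(spectra, system), system

    def test_zero_mixing_time_is_identity(self):
        R, system = self.make_two_spin()
        curves = buildup_curves(R, system, np.array([0.0]))
        diag = curves[(curves.group1 == curves.group2)]
        cross = curves[(curves.group1 != curves.group2)]
        np.testing.assert_allclose(diag.intensity, 1.0, atol=1e-12)
        np.testing.assert_allclose(cross.intensity, 0.0, atol=1e-12)

    def test_two_spin_closed_form(self):
        R, system = self.make_two_spin()
        rho, sigma = R[0, 0], R[0, 1]
        taus = np.array([0.05, 0.2, 0.5])
        T = transfer_matrices(R, taus)
        # exp of the 2x2 [[rho, sigma],[sigma, rho]]: off-diagonal
        # -exp(-rho t) sinh(sigma t); positive for sigma < 0
        expected = 0.5 * np.exp(-(rho + sigma) * taus) \
            - 0.5 * np.exp(-(rho - sigma) * taus)
        np.testing.assert_allclose(T[:, 0, 1], expected, rtol=1e-10)

    def test_transfer_symmetric_for_symmetric_r(self):
        ens = generate_synthetic_ensemble(4, 6, 0.3, seed=8)
        scheme = KineticScheme(tau_ensemble=2e-9)
        system = build_spin_system(ens)
        spectra = pair_spectra(ens, scheme, 4.3e-9, system)
        R = relaxation_matrix(spectra, system)
        np.testing.assert_allclose(R, R.T, atol=1e-20)
        T = transfer_matrices(R, np.array([0.1]))[0]
        np.testing.assert_allclose(T, T.T, rtol=1e-10)

    def test_total_magnetization_decays(self):
        R, system = self.make_two_spin()
        taus = np.linspace(0, 1.0, 21)
        T = transfer_matrices(R, taus)
        row_sums = T.sum(axis=2)  # deviation magnetization has no sink except rho
        assert np.all(np.diff(row_sums, axis=0) <= 1e-12)

    def test_default_mixing_time_grid(self):
        # experimental design: 5-500 ms at 15 ms spacing = 34 points
        assert len(relaxation.DEFAULT_MIXING_TIMES) == 34
        assert relaxation.DEFAULT_MIXING_TIMES[0] == pytest.approx(5e-3)
        assert relaxation.DEFAULT_MIXING_TIMES[-1] == pytest.approx(500e-3)


class TestMethylExpansion:
    def test_kronecker_path_equals_relabeled_enumeration(self, dipeptide_ensemble):
        """A (methyl H, remote H) pair computed on the Kronecker-expanded
        state space must match brute-force enumeration over the explicitly
        relabeled (tripled) ensemble."""
        ens = dipeptide_ensemble
        scheme = KineticScheme(tau_ensemble=2e-9)
        methyl = next(g for g in ens.rotation_groups if g.kind == "methyl")
        a1 = methyl.member_atom_ids[0]
        a2 = "A.1ALA.HA"
        vecs, structure = relaxation.expanded_pair_states(ens, scheme, a1, a2)
        from kinetic_ensemble.dipolar import averaged_prefactors, dipole_vector
        a_fast = averaged_prefactors(dipole_vector(vecs), structure)
        rates_fast = structure.decay_rates(scheme.timescales())

        # oracle: explicit Kronecker-sum generator over the tripled ensemble
        rm = kinetics.kronecker_sum(
            kinetics.uniform_jump_matrix(ens.n_members, 2e-9),
            kinetics.rotation_rate_matrix(3, scheme.tau_methyl))
        idx = {a: i for i, a in enumerate(ens.atom_ids)}
        brute_vecs = []
        for m in range(ens.n_members):
            hname = a1
            for r in range(3):
                brute_vecs.append(ens.coords[m, idx[hname], :]
                                  - ens.coords[m, idx[a2], :])
                hname = methyl.permutation[hname]
        num = kinetics.spectral_structure(rm)
        a_brute = averaged_prefactors(dipole_vector(np.array(brute_vecs)), num)
        rates_brute = num.decay_rates({})

        fast = dict(zip(np.round(rates_fast, 3), a_fast))
        brute = dict(zip(np.round(rates_brute, 3), a_brute))
        assert set(fast) == set(brute)
        for lam in fast:
            assert fast[lam] == pytest.approx(brute[lam], rel=1e-10, abs=1e-14)

    def test_intra_methyl_pair_uses_single_rotation(self, dipeptide_ensemble):
        ens = dipeptide_ensemble
        scheme = KineticScheme(tau_ensemble=2e-9)
        methyl = next(g for g in ens.rotation_groups if g.kind == "methyl")
        a1, a2 = methyl.member_atom_ids[:2]
        vecs, structure = relaxation.expanded_pair_states(ens, scheme, a1, a2)
        assert structure.n_states == ens.n_members * 3
        # intra-methyl distances are rotation-invariant up to relabeling
        assert vecs.shape == (ens.n_members * 3, 3)

    def test_methyl_aromatic_pair_product_expansion(self, dipeptide_ensemble):
        ens = dipeptide_ensemble
        scheme = KineticScheme(tau_ensemble=2e-9)
        methyl = next(g for g in ens.rotation_groups if g.kind == "methyl")
        aromatic = next(g for g in ens.rotation_groups if g.kind == "aromatic")
        vecs, structure = relaxation.expanded_pair_states(
            ens, scheme, methyl.member_atom_ids[0], aromatic.member_atom_ids[0])
        assert structure.n_states == ens.n_members * 3 * 2
        assert vecs.shape[0] == ens.n_members * 6


class TestSpinSystem:
    def test_pseudoatom_groups_partition_spins(self):
        with pytest.raises(ValueError):
            SpinSystem(["a", "b"], {"g": ["a", "b"], "h": ["b"]}, OMEGA0)
        with pytest.raises(ValueError):
            SpinSystem(["a", "b"], {"g": ["a"]}, OMEGA0)

    def test_methyl_pseudoatom_label(self, dipeptide_ensemble):
        system = build_spin_system(dipeptide_ensemble)
        assert "A.1ALA.QB" in system.groups
        assert len(system.groups["A.1ALA.QB"]) == 3
        assert "A.2PHE.QD" in system.groups and "A.2PHE.QE" in system.groups
        assert len(system.groups["A.2PHE.QD"]) == 2
        assert system.groups["A.1ALA.HA"] == ["A.1ALA.HA"]


class TestSimulatedTable:
    def test_noiseless_equals_buildup_curves(self):
        ens = generate_synthetic_ensemble(3, 5, 0.2, seed=4)
        scheme = KineticScheme(tau_ensemble=2e-9)
        mts = np.array([0.05, 0.1, 0.2])
        table = simulate_buildup_table(ens, scheme, 4.3e-9, mts, noise_sd=0.0)
        system = build_spin_system(ens)
        spectra = pair_spectra(ens, scheme, 4.3e-9, system)
        curves = buildup_curves(relaxation_matrix(spectra, system), system, mts)
        merged = table.merge(curves, on=["group1", "group2", "mixing_time_ms"],
                             suffixes=("_t", "_c"))
        assert len(merged) == len(table)
        np.testing.assert_allclose(merged.intensity_t, merged.intensity_c)

    def test_noise_deterministic_per_seed(self):
        ens = generate_synthetic_ensemble(3, 5, 0.2, seed=4)
        scheme = KineticScheme(tau_ensemble=2e-9)
        mts = np.array([0.1])
        t1 = simulate_buildup_table(ens, scheme, 4.3e-9, mts, noise_sd=0.05, seed=7)
        t2 = simulate_buildup_table(ens, scheme, 4.3e-9, mts, noise_sd=0.05, seed=7)
        np.testing.assert_array_equal(t1.intensity, t2.intensity)

    def test_tsv_round_trip(self, tmp_path):
        ens = generate_synthetic_ensemble(2, 4, 0.2, seed=4)
        scheme = KineticScheme(tau_ensemble=2e-9)
        table = simulate_buildup_table(ens, scheme, 4.3e-9, np.array([0.1]))
        path = tmp_path / "table.tsv"
        write_buildup_table(table, path)
        back = read_buildup_table(path)
        np.testing.assert_allclose(back.intensity, table.intensity)
        # reader tolerates a missing replicate column
        trimmed = table.drop(columns=["replicate"])
        write_buildup_table(trimmed, path)
        back = read_buildup_table(path)
        assert (back.replicate == 0).all()
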