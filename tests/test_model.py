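import numpy as np
import pytest
from scipy.optimize import minimize

from lvcspec import (DiabaticState, FragmentData, InterStateCoupling,
                     LVCError, LVCHamiltonian, ModeBasis, adiabatic_analysis,
                     assemble_dimer_hamiltonian, classify_coupling,
                     diabatic_minimum, evaluate_diabatic_potential,
                     toggle_couplings)
from lvcspec.model import DIMER_STATE_LABELS


def one_state(energy=2.0, w=(1.0,), lam=(1.0,), dipole=(1, 0, 0)):
    return LVCHamiltonian(
        ModeBasis(np.asarray(w, float)),
        (DiabaticState("s", "LE", energy, np.asarray(lam, float),
                       np.asarray(dipole, float)),))


def make_fragment(N=2, g_scale=0.1, seed=0):
    rng = np.random.default_rng(seed)
    g = lambda: rng.normal(scale=g_scale, size=N)
    return FragmentData(
        modes=ModeBasis(rng.uniform(0.05, 0.3, N)),
        e_le=2.0, e_le2=2.1,
        grad_le=g(), grad_le2=g(), jt_linear=g(),
        grad_cation=g(), grad_anion=g(), grad_anion2=g(),
        dipole_le=np.array([1.0, 0, 0]), dipole_le2=np.array([0, 1.0, 0]),
        ct_energy=2.4, ct_energy2=2.5)


class TestModeBasis:
    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(LVCError):
            ModeBasis(np.array([0.1, -0.2]))
        with pytest.raises(LVCError):
            ModeBasis(np.array([]))

    def test_count(self):
        assert ModeBasis(np.array([0.1, 0.2, 0.3])).count == 3


class TestDiabaticState:
    def test_ct_requires_zero_dipole(self):
        with pytest.raises(LVCError):
            DiabaticState("ct", "CT", 2.4, np.zeros(1),
                          np.array([1.0, 0, 0]))

    def test_unknown_character_rejected(self):
        with pytest.raises(LVCError):
            DiabaticState("x", "XX", 2.0, np.zeros(1), np.zeros(3))


class TestInterStateCoupling:
    def test_pair_sorted(self):
        c = InterStateCoupling((3, 1), 0.05)
        assert c.pair == (1, 3)

    def test_self_pair_rejected(self):
        with pytest.raises(LVCError):
            InterStateCoupling((2, 2), 0.05)


class TestEvaluateDiabaticPotential:
    def test_franck_condon_point(self):
        H = LVCHamiltonian(
            ModeBasis(np.array([0.1])),
            (DiabaticState("a", "LE", 2.0, np.array([0.3]),
                           np.array([1.0, 0, 0])),
             DiabaticState("b", "CT", 2.5, np.array([0.1]), np.zeros(3))),
            (InterStateCoupling((0, 1), 0.07),))
        V = evaluate_diabatic_potential(H, np.zeros(1))
        assert np.allclose(V, [[2.0, 0.07], [0.07, 2.5]])

    def test_single_state_arithmetic(self):
        V = evaluate_diabatic_potential(one_state(), np.array([1.0]))
        assert V[0, 0] == pytest.approx(3.5, abs=1e-14)

    def test_term_by_term_oracle(self, random_model, rng):
        H = random_model(7, n_states=3, n_modes=4)
        q = rng.normal(size=4)
        V = evaluate_diabatic_potential(H, q)
        assert np.allclose(V, V.T, atol=0)
        harm = 0.5 * float(H.modes.frequencies @ q**2)
        for i in range(3):
            expect = H.states[i].energy0 + harm + H.states[i].gradient @ q
            assert V[i, i] == pytest.approx(expect, rel=1e-13)
        for c in H.couplings:
            i, j = c.pair
            assert V[i, j] == pytest.approx(c.constant, rel=1e-13)

    def test_dimension_mismatch(self):
        with pytest.raises(LVCError):
            evaluate_diabatic_potential(one_state(), np.zeros(2))


class TestAssembleDimer:
    def test_shape_and_order(self):
        fragA, fragB = make_fragment(3, seed=1), make_fragment(3, seed=2)
        H = assemble_dimer_hamiltonian(fragA, fragB, np.zeros((8, 8)))
        assert H.n_modes == 6
        assert H.n_states == 8
        assert tuple(s.label for s in H.states) == DIMER_STATE_LABELS

    def test_le_gradients_block_padded(self):
        fragA, fragB = make_fragment(3, seed=1), make_fragment(3, seed=2)
        H = assemble_dimer_hamiltonian(fragA, fragB, np.zeros((8, 8)))
        assert np.array_equal(H.states[0].gradient,
                              np.concatenate([fragA.grad_le, np.zeros(3)]))
        # gradient of |L2> is {0, g}
        assert np.array_equal(H.states[2].gradient,
                              np.concatenate([np.zeros(3), fragB.grad_le]))

    def test_ct_gradients_from_ionic_species(self):
        fragA, fragB = make_fragment(2, seed=3), make_fragment(2, seed=4)
        H = assemble_dimer_hamiltonian(fragA, fragB, np.zeros((8, 8)))
        # CT(1->2): cation on monomer 1, anion on monomer 2
        assert np.array_equal(
            H.states[4].gradient,
            np.concatenate([fragA.grad_cation, fragB.grad_anion]))
        assert np.array_equal(
            H.states[5].gradient,
            np.concatenate([fragA.grad_cation, fragB.grad_anion2]))
        # CT(2->1): anion on monomer 1, cation on monomer 2
        assert np.array_equal(
            H.states[6].gradient,
            np.concatenate([fragA.grad_anion, fragB.grad_cation]))

    def test_ct_states_dark(self):
        H = assemble_dimer_hamiltonian(make_fragment(), make_fragment(),
                                       np.zeros((8, 8)))
        for s in H.states[4:]:
            assert s.character == "CT"
            assert np.all(s.dipole == 0)

    def test_jt_pairs_linear_with_zero_constant(self):
        fragA, fragB = make_fragment(2, seed=5), make_fragment(2, seed=6)
        H = assemble_dimer_hamiltonian(fragA, fragB, np.zeros((8, 8)))
        jt1 = H.coupling_for(0, 1)
        jt2 = H.coupling_for(2, 3)
        assert jt1.constant == 0.0 and jt2.constant == 0.0
        assert np.array_equal(jt1.linear,
                              np.concatenate([fragA.jt_linear, np.zeros(2)]))
        assert np.array_equal(jt2.linear,
                              np.concatenate([np.zeros(2), fragB.jt_linear]))
        # all other pairs carry no linear coupling
        for c in H.couplings:
            if c.pair not in ((0, 1), (2, 3)):
                assert c.linear is None

    def test_zero_ionic_gradients_give_zero_ct_reorganization(self):
        frag = make_fragment(2, seed=7)
        frag = FragmentData(
            modes=frag.modes, e_le=frag.e_le, e_le2=frag.e_le2,
            grad_le=frag.grad_le, grad_le2=frag.grad_le2,
            jt_linear=frag.jt_linear,
            grad_cation=np.zeros(2), grad_anion=np.zeros(2),
            grad_anion2=np.zeros(2),
            dipole_le=frag.dipole_le, dipole_le2=frag.dipole_le2,
            ct_energy=frag.ct_energy, ct_energy2=frag.ct_energy2)
        H = assemble_dimer_hamiltonian(frag, frag, np.zeros((8, 8)))
        for i in range(4, 8):
            _, _, e_reorg = diabatic_minimum(H, i)
            assert e_reorg == 0.0

    def test_nonsymmetric_couplings_rejected(self):
        C = np.zeros((8, 8))
        C[0, 2] = 0.05
        with pytest.raises(LVCError):
            assemble_dimer_hamiltonian(make_fragment(), make_fragment(), C)

    def test_mismatched_mode_counts_rejected(self):
        with pytest.raises(LVCError):
            assemble_dimer_hamiltonian(make_fragment(2), make_fragment(3),
                                       np.zeros((8, 8)))


class TestAdiabaticAnalysis:
    def test_h_aggregate_two_level(self):
        # two degenerate LE states, J = +0.05, parallel unit dipoles
        H = LVCHamiltonian(
            ModeBasis(np.array([0.15])),
            (DiabaticState("a", "LE", 2.0, np.zeros(1),
                           np.array([1.0, 0, 0])),
             DiabaticState("b", "LE", 2.0, np.zeros(1),
                           np.array([1.0, 0, 0]))),
            (InterStateCoupling((0, 1), 0.05),))
        ad = adiabatic_analysis(H)
        assert np.allclose(ad.energies, [1.95, 2.05], atol=1e-14)
        f = ad.oscillator_strengths
        assert f[0] == pytest.approx(0.0, abs=1e-14)
        assert f[1] > 0

    def test_uncoupled_ct_state_has_zero_strength(self):
        H = LVCHamiltonian(
            ModeBasis(np.array([0.15])),
            (DiabaticState("ct", "CT", 2.4, np.zeros(1), np.zeros(3)),))
        ad = adiabatic_analysis(H)
        assert ad.oscillator_strengths[0] == 0.0

    def test_matches_dense_diagonalization_oracle(self, random_model, rng):
        H = random_model(11, n_states=8, n_modes=3, ct_fraction=0.3)
        q = rng.normal(size=3)
        ad = adiabatic_analysis(H, q)
        evals = np.linalg.eigvalsh(evaluate_diabatic_potential(H, q))
        assert np.allclose(ad.energies, evals, atol=1e-10)
        # eigenvectors orthonormal
        G = ad.eigenvectors.T @ ad.eigenvectors
        assert np.allclose(G, np.eye(8), atol=1e-12)

    def test_dipole_strength_sum_rotation_invariant(self, random_model):
        H = random_model(13, n_states=5, n_modes=2)
        ad = adiabatic_analysis(H, oscillator_convention=False)
        assert ad.oscillator_strengths.sum() == pytest.approx(
            float(np.sum(H.dipoles**2)), rel=1e-12)

    def test_composition_percentages(self, random_model):
        H = random_model(17, n_states=4, n_modes=2, ct_fraction=0.5)
        ad = adiabatic_analysis(H)
        assert np.allclose(ad.composition.sum(axis=1), 100.0, atol=1e-10)
        assert np.all(ad.composition >= -1e-12)


class TestDiabaticMinimum:
    def test_closed_form(self):
        H = one_state(2.0, w=(0.1,), lam=(0.1,))
        q_min, e_min, e_reorg = diabatic_minimum(H, 0)
        assert q_min[0] == pytest.approx(-1.0, abs=1e-14)
        assert e_reorg == pytest.approx(0.05, abs=1e-14)
        assert e_min == pytest.approx(1.95, abs=1e-14)

    def test_undisplaced(self):
        H = one_state(2.0, w=(0.1,), lam=(0.0,))
        q_min, e_min, _ = diabatic_minimum(H, 0)
        assert np.all(q_min == 0)
        assert e_min == 2.0

    def test_matches_numerical_minimizer(self, random_model):
        H = random_model(19, n_states=2, n_modes=4)
        q_min, e_min, _ = diabatic_minimum(H, 1)

        def vii(q):
            return evaluate_diabatic_potential(H, q)[1, 1]

        res = minimize(vii, np.zeros(4), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.allclose(q_min, res.x, atol=1e-6)
        assert e_min == pytest.approx(res.fun, abs=1e-9)


class TestToggleCouplings:
    def test_empty_selection_removes_all(self, dimer):
        H0 = toggle_couplings(dimer, [])
        for c in H0.couplings:
            assert c.constant == 0.0 and c.linear is None

    def test_all_classes_is_identity(self, dimer):
        H1 = toggle_couplings(dimer, ["LE-LE", "LE-CT", "CT-CT", "JT"])
        for c0, c1 in zip(dimer.couplings, H1.couplings):
            assert c0.constant == c1.constant
            if c0.linear is None:
                assert c1.linear is None
            else:
                assert np.array_equal(c0.linear, c1.linear)

    def test_unknown_class_rejected(self, dimer):
        with pytest.raises(LVCError):
            toggle_couplings(dimer, ["LE-LE", "bogus"])

    def test_classification(self):
        H = make_jt_dimerless()
        jt = H.coupling_for(0, 1)
        assert classify_coupling(H, jt) == "JT"


def make_jt_dimerless():
    from lvcspec import make_jt_monomer
    return make_jt_monomer()
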