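"""Amber-form energy terms, gradients, minimization, relative energies."""

import math

import numpy as np
import pytest

from uaaff.core import AtomRecord, ChargeSet, Conformer, ForceFieldParameters
from uaaff.energy import (
    COULOMB_CONSTANT,
    ConformerPair,
    TorsionRestraint,
    energy,
    energy_and_gradient,
    minimize,
    relative_energy,
)
from uaaff.fixtures import PHI_ATOMS, PSI_ATOMS
from uaaff.core import measure_dihedral

from conftest import random_rotation


def _conf(coords, elements=None):
    elements = elements or ["C"] * len(coords)
    atoms = [
        AtomRecord(i, f"X{i}", elements[i], "RES", 1, tuple(c))
        for i, c in enumerate(coords)
    ]
    return Conformer(atoms=atoms)


def _zero_lj(n):
    return [(0.0, 0.0)] * n


def _all_excluded(n):
    return {(i, j) for i in range(n) for j in range(i + 1, n)}


class TestClosedForms:
    def test_bond_term(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])
        params = ForceFieldParameters(
            bonds=[(0, 1, 100.0, 1.5)], lj=_zero_lj(2), exclusions={(0, 1)}
        )
        b = energy(_conf(coords), params, ChargeSet(np.zeros(2), 0))
        assert b.e_bond == pytest.approx(1.0, abs=1e-12)
        assert b.e_total == pytest.approx(1.0, abs=1e-12)

    def test_dihedral_term_at_syn(self):
        coords = np.array(
            [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0]]
        )
        params = ForceFieldParameters(
            dihedrals=[(0, 1, 2, 3, 2.0, 1, 0.0)],
            lj=_zero_lj(4),
            exclusions=_all_excluded(4),
        )
        b = energy(_conf(coords), params, ChargeSet(np.zeros(4), 0))
        assert b.e_dihedral == pytest.approx(2.0, abs=1e-12)

    def test_coulomb_pair_with_amber_constant(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        params = ForceFieldParameters(lj=_zero_lj(2))
        q = ChargeSet(np.array([0.5, 0.5]), 1)
        b = energy(_conf(coords), params, q)
        assert b.e_es == pytest.approx(COULOMB_CONSTANT * 0.25 / 3.0, abs=1e-9)
        assert b.e_es == pytest.approx(27.672, abs=1e-3)

    def test_lj_minimum_depth(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.6, 0.0, 0.0]])
        params = ForceFieldParameters(lj=[(1.8, 0.2), (1.8, 0.2)])
        b = energy(_conf(coords), params, ChargeSet(np.zeros(2), 0))
        assert b.e_vdw == pytest.approx(-0.2, abs=1e-12)

    def test_one_four_scaling(self):
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        q = ChargeSet(np.array([0.3, -0.3]), 0)
        full = ForceFieldParameters(lj=[(1.8, 0.1)] * 2)
        scaled = ForceFieldParameters(
            lj=[(1.8, 0.1)] * 2, pairs14={(0, 1)}
        )
        bf = energy(_conf(coords), full, q)
        bs = energy(_conf(coords), scaled, q)
        assert bs.e_es == pytest.approx(bf.e_es / 1.2, abs=1e-12)
        assert bs.e_vdw == pytest.approx(bf.e_vdw / 2.0, abs=1e-12)

    def test_overlapping_atoms_raise(self):
        coords = np.zeros((2, 3))
        params = ForceFieldParameters(lj=_zero_lj(2))
        with pytest.raises(ValueError):
            energy(_conf(coords), params, ChargeSet(np.array([0.1, -0.1]), 0))


class TestInvariants:
    def test_total_is_sum_of_terms(self, toy):
        b = energy(toy.pair.alpha, toy.params, toy.q_alpha)
        s = b.e_bond + b.e_angle + b.e_dihedral + b.e_es + b.e_vdw
        assert b.e_total == pytest.approx(s, abs=1e-9)

    def test_rigid_transform_invariance(self, toy):
        rng = np.random.default_rng(4)
        base = energy(toy.pair.alpha, toy.params, toy.q_alpha).e_total
        coords = toy.pair.alpha.coordinates()
        for _ in range(3):
            moved = coords @ random_rotation(rng).T + rng.normal(scale=5.0, size=3)
            e = energy(
                toy.pair.alpha.with_coordinates(moved), toy.params, toy.q_alpha
            ).e_total
            assert e == pytest.approx(base, abs=1e-9)

    def test_doubling_charges_quadruples_electrostatics(self, toy):
        b1 = energy(toy.pair.alpha, toy.params, toy.q_alpha)
        doubled = ChargeSet(toy.q_alpha.charges * 2.0, 0, toy.q_alpha.group_of_atom)
        b2 = energy(toy.pair.alpha, toy.params, doubled)
        assert b2.e_es == pytest.approx(4.0 * b1.e_es, rel=1e-12)

    def test_zero_epsilon_zeroes_vdw(self, toy):
        params = ForceFieldParameters(
            bonds=toy.params.bonds,
            angles=toy.params.angles,
            dihedrals=toy.params.dihedrals,
            lj=[(r, 0.0) for r, _ in toy.params.lj],
            exclusions=toy.params.exclusions,
            pairs14=toy.params.pairs14,
        )
        assert energy(toy.pair.alpha, params, toy.q_alpha).e_vdw == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_analytic_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        coords = rng.normal(scale=4.0, size=(n, 3))
        params = ForceFieldParameters(
            bonds=[(0, 1, 300.0, 1.5), (1, 2, 250.0, 1.4)],
            angles=[(0, 1, 2, 50.0, 110.0), (1, 2, 3, 40.0, 120.0)],
            dihedrals=[
                (0, 1, 2, 3, 2.0, 1, 0.0),
                (1, 2, 3, 4, 1.5, 2, 180.0),
                (2, 3, 4, 5, 0.8, 3, 60.0),
            ],
            lj=[(1.8, 0.1)] * n,
            exclusions={(0, 1), (1, 2), (0, 2)},
            pairs14={(0, 3)},
        )
        q = rng.normal(scale=0.3, size=n)
        q -= q.mean()
        cs = ChargeSet(q, 0)
        _, g = energy_and_gradient(coords, params, cs)
        h = 1e-5
        gnum = np.zeros_like(coords)
        for i in range(n):
            for d in range(3):
                cp, cm = coords.copy(), coords.copy()
                cp[i, d] += h
                cm[i, d] -= h
                ep, _ = energy_and_gradient(cp, params, cs, False)
                em, _ = energy_and_gradient(cm, params, cs, False)
                gnum[i, d] = (ep.e_total - em.e_total) / (2 * h)
        rel = np.abs(g - gnum).max() / max(1.0, np.abs(gnum).max())
        assert rel < 1e-6


class TestMinimize:
    def test_diatomic_converges_to_equilibrium(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.8, 0.0, 0.0]])
        params = ForceFieldParameters(
            bonds=[(0, 1, 200.0, 1.5)], lj=_zero_lj(2), exclusions={(0, 1)}
        )
        final, b, _ = minimize(
            _conf(coords), params, ChargeSet(np.zeros(2), 0)
        )
        r = np.linalg.norm(np.diff(final.coordinates(), axis=0))
        assert r == pytest.approx(1.5, abs=1e-5)
        assert b.e_bond == pytest.approx(0.0, abs=1e-8)

    def test_exact_minimum_is_fixed_point(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        params = ForceFieldParameters(
            bonds=[(0, 1, 200.0, 1.5)], lj=_zero_lj(2), exclusions={(0, 1)}
        )
        final, _, _ = minimize(_conf(coords), params, ChargeSet(np.zeros(2), 0))
        assert np.allclose(final.coordinates(), coords, atol=1e-9)

    def test_torsion_restraint_dominates(self, toy):
        # the beta geometry relaxed under a strong phi restraint at -60
        # must end close to the restraint target, not at the beta value
        restraints = [TorsionRestraint(PHI_ATOMS, -60.0, 100.0)]
        final, _, _ = minimize(
            toy.pair.beta, toy.params, toy.q_alpha, restraints=restraints
        )
        phi = measure_dihedral(final, *PHI_ATOMS)
        assert abs(phi - (-60.0)) < 1.0


class TestRelativeEnergy:
    def test_identical_geometries_give_zero(self, toy):
        pair = ConformerPair(1, toy.pair.alpha, toy.pair.alpha)
        re = relative_energy(pair, toy.params, toy.q_alpha, mode="single_point")
        assert re == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_moved_copy_gives_zero(self, toy):
        rng = np.random.default_rng(8)
        moved = toy.pair.alpha.with_coordinates(
            toy.pair.alpha.coordinates() @ random_rotation(rng).T + [1.0, -2.0, 0.5]
        )
        pair = ConformerPair(1, toy.pair.alpha, moved)
        re = relative_energy(pair, toy.params, toy.q_alpha, mode="single_point")
        assert re == pytest.approx(0.0, abs=1e-9)

    def test_single_point_matches_term_wise_sum(self, toy):
        ea = energy(toy.pair.alpha, toy.params, toy.q_alpha)
        eb = energy(toy.pair.beta, toy.params, toy.q_alpha)
        expected = sum(
            getattr(ea, t) - getattr(eb, t)
            for t in ("e_bond", "e_angle", "e_dihedral", "e_es", "e_vdw")
        )
        re = relative_energy(toy.pair, toy.params, toy.q_alpha, mode="single_point")
        assert re == pytest.approx(expected, abs=1e-9)

    def test_minimized_mode_keeps_backbone_targets(self, toy):
        rest_alpha = [
            TorsionRestraint(PHI_ATOMS, -60.0), TorsionRestraint(PSI_ATOMS, -40.0)
        ]
        final, _, _ = minimize(
            toy.pair.alpha, toy.params, toy.q_alpha, restraints=rest_alpha
        )
        assert abs(measure_dihedral(final, *PHI_ATOMS) - (-60.0)) < 5.0
        re = relative_energy(
            toy.pair, toy.params, toy.q_alpha,
            mode="minimized", phi_atoms=PHI_ATOMS, psi_atoms=PSI_ATOMS,
        )
        assert math.isfinite(re)
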