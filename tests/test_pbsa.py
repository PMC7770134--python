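"""Poisson-Boltzmann solvation, SASA, binding energy and decomposition."""

import math

import numpy as np
import pytest

from uaaff.core import ChargeSet, ForceFieldParameters
from uaaff.energy import COULOMB_CONSTANT
from uaaff.fixtures import make_binding_complex
from uaaff.pbsa import (
    PbsaOptions,
    binding_energy,
    cross_interaction,
    nonpolar_solvation,
    per_residue_decomposition,
    population_sd,
    sasa,
    solve_pb,
)

BORN_EXACT = -0.5 * COULOMB_CONSTANT * (1.0 - 1.0 / 80.0) / 2.0


class TestSolvePb:
    def test_zero_charges_give_zero(self):
        opt = PbsaOptions(grid_spacing=0.8, grid_padding=6.0, ionic_strength=0.0)
        e = solve_pb(np.zeros((1, 3)), np.zeros(1), np.array([2.0]), opt)
        assert e == 0.0

    def test_zero_dielectric_contrast_gives_zero(self):
        opt = PbsaOptions(
            grid_spacing=0.8, grid_padding=6.0, ionic_strength=0.0,
            eps_solvent=1.0 + 1e-13,
        )
        e = solve_pb(np.zeros((1, 3)), np.ones(1), np.array([2.0]), opt)
        assert e == pytest.approx(0.0, abs=1e-6)

    def test_born_ion_coarse_grid(self):
        opt = PbsaOptions(grid_spacing=0.8, grid_padding=10.0, ionic_strength=0.0)
        e = solve_pb(np.zeros((1, 3)), np.ones(1), np.array([2.0]), opt)
        assert abs(e - BORN_EXACT) / abs(BORN_EXACT) < 0.05

    def test_rigid_shift_robustness(self):
        opt = PbsaOptions(grid_spacing=0.8, grid_padding=8.0, ionic_strength=0.0)
        e0 = solve_pb(np.zeros((1, 3)), np.ones(1), np.array([2.0]), opt)
        e1 = solve_pb(
            np.array([[0.31, -0.17, 0.23]]), np.ones(1), np.array([2.0]), opt
        )
        assert abs(e1 - e0) / abs(e0) < 0.02

    def test_salt_stabilizes_ion(self):
        base = PbsaOptions(grid_spacing=0.8, grid_padding=8.0, ionic_strength=0.0)
        salty = PbsaOptions(grid_spacing=0.8, grid_padding=8.0, ionic_strength=0.1)
        e0 = solve_pb(np.zeros((1, 3)), np.ones(1), np.array([2.0]), base)
        e1 = solve_pb(np.zeros((1, 3)), np.ones(1), np.array([2.0]), salty)
        assert e1 < e0  # screening makes solvation more favorable

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            solve_pb(np.zeros((1, 3)), np.ones(1), np.array([0.0]), PbsaOptions())


class TestSasa:
    def test_isolated_sphere_analytic_area(self):
        per_atom, total = sasa(np.zeros((1, 3)), np.array([1.9]), 1.4, 960)
        exact = 4.0 * math.pi * 3.3**2
        assert abs(total - exact) / exact < 0.01
        assert total == pytest.approx(exact, rel=0.01)
        assert exact == pytest.approx(136.85, abs=0.01)

    def test_far_separated_additivity(self):
        coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        radii = np.array([1.9, 1.5])
        _, total = sasa(coords, radii, 1.4, 480)
        _, a = sasa(coords[:1], radii[:1], 1.4, 480)
        _, b = sasa(coords[1:], radii[1:], 1.4, 480)
        assert total == pytest.approx(a + b, abs=1e-9)

    def test_buried_atom_has_zero_area(self):
        coords = np.zeros((2, 3))
        coords[1, 0] = 0.1
        per_atom, _ = sasa(coords, np.array([1.0, 6.0]), 1.4, 480)
        assert per_atom[0] == 0.0

    def test_point_count_convergence(self, complex_small):
        coords = complex_small.snapshots[0].coordinates()
        _, t1 = sasa(coords, complex_small.radii, 1.4, 960)
        _, t2 = sasa(coords, complex_small.radii, 1.4, 1920)
        assert abs(t2 - t1) / t1 < 0.005


class TestNonpolar:
    def test_zero_area_returns_intercept(self):
        assert nonpolar_solvation(0.0) == pytest.approx(0.92)

    def test_linear_form_with_standard_constants(self):
        assert nonpolar_solvation(100.0) == pytest.approx(1.462)

    def test_gamma_scales_area_part(self):
        opt2 = PbsaOptions(gamma=2 * 0.00542)
        base = nonpolar_solvation(250.0) - 0.92
        assert nonpolar_solvation(250.0, opt2) - 0.92 == pytest.approx(2 * base)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_solvation(-1.0)


class TestPopulationSd:
    def test_hand_example(self):
        assert population_sd([1.0, 2.0, 3.0]) == pytest.approx(
            math.sqrt(2.0 / 3.0), abs=1e-12
        )
        assert population_sd([1.0, 2.0, 3.0]) == pytest.approx(0.8165, abs=1e-4)

    def test_single_observation_is_zero(self):
        assert population_sd([4.2]) == 0.0


class TestBindingEnergy:
    def test_two_point_charges_cross_coulomb(self):
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        params = ForceFieldParameters(lj=[(1.8, 0.0), (1.8, 0.0)])
        q = np.array([1.0, -1.0])
        e_ele, e_vdw = cross_interaction(
            coords, q, params, np.array([0]), np.array([1])
        )
        assert e_ele == pytest.approx(-COULOMB_CONSTANT / 4.0, abs=1e-9)
        assert e_ele == pytest.approx(-83.016, abs=1e-3)
        assert e_vdw == 0.0

    def test_noninteracting_ligand_gives_zero_mm_and_pb(self, fast_pb_options):
        bc = make_binding_complex(seed=6, n_res=3, n_snapshots=2,
                                  charged_ligand=False)
        res = binding_energy(
            bc.snapshots, bc.ligand_atoms, fast_pb_options,
            bc.params, bc.charges, bc.radii,
        )
        assert res.de_mm == pytest.approx(0.0, abs=1e-9)
        # ligand carries no charge: polar term differences vanish up to
        # grid discretization of the receptor reaction field
        assert abs(res.dg_pb_solv) < 0.3

    def test_component_identities(self, complex_small, fast_pb_options):
        bc = complex_small
        res = binding_energy(
            bc.snapshots, bc.ligand_atoms, fast_pb_options,
            bc.params, bc.charges, bc.radii,
        )
        assert res.de_mm == pytest.approx(res.de_vdw + res.de_ele, abs=1e-12)
        assert res.dg_solv == pytest.approx(
            res.dg_pb_solv + res.dg_np_solv, abs=1e-12
        )
        assert res.dg_bind == pytest.approx(res.de_mm + res.dg_solv, abs=1e-12)
        for key, vals in res.per_snapshot.items():
            assert len(vals) == len(bc.snapshots)
        assert res.de_vdw == pytest.approx(
            np.mean(res.per_snapshot["de_vdw"]), abs=1e-12
        )

    def test_single_snapshot_sd_is_zero(self, fast_pb_options):
        bc = make_binding_complex(seed=9, n_res=2, n_snapshots=1)
        res = binding_energy(
            bc.snapshots, bc.ligand_atoms, fast_pb_options,
            bc.params, bc.charges, bc.radii,
        )
        assert all(sd == 0.0 for sd in res.sd.values())

    def test_far_separated_ligand_decouples(self, fast_pb_options):
        bc = make_binding_complex(seed=12, n_res=2, n_snapshots=1, jitter=0.0)
        snap = bc.snapshots[0]
        coords = snap.coordinates()
        coords[bc.ligand_atoms] += np.array([1000.0, 0.0, 0.0])
        moved = snap.with_coordinates(coords)
        e_ele, e_vdw = cross_interaction(
            coords, bc.charges.charges, bc.params,
            np.array([i for i in range(snap.n_atoms) if i not in bc.ligand_atoms]),
            np.array(bc.ligand_atoms),
        )
        assert abs(e_ele) < 0.05 and abs(e_vdw) < 1e-6
        _, s_cplx = sasa(coords, bc.radii, 1.4, 480)
        rec = [i for i in range(snap.n_atoms) if i not in bc.ligand_atoms]
        _, s_rec = sasa(coords[rec], bc.radii[rec], 1.4, 480)
        _, s_lig = sasa(coords[bc.ligand_atoms], bc.radii[bc.ligand_atoms], 1.4, 480)
        assert s_cplx == pytest.approx(s_rec + s_lig, abs=1e-9)

    def test_overlapping_selection_rejected(self, complex_small, fast_pb_options):
        bc = complex_small
        with pytest.raises(ValueError):
            binding_energy(
                bc.snapshots, list(range(bc.snapshots[0].n_atoms)),
                fast_pb_options, bc.params, bc.charges, bc.radii,
            )


class TestPerResidueDecomposition:
    def test_mm_and_np_sums_conserved(self, complex_small, fast_pb_options):
        bc = complex_small
        snap = bc.snapshots[0]
        dec = per_residue_decomposition(
            snap, bc.ligand_atoms, fast_pb_options, bc.params, bc.charges, bc.radii
        )
        rec = np.array(
            [i for i in range(snap.n_atoms) if i not in bc.ligand_atoms]
        )
        e_ele, e_vdw = cross_interaction(
            snap.coordinates(), bc.charges.charges, bc.params,
            rec, np.array(bc.ligand_atoms),
        )
        assert dec.de_mm_res.sum() == pytest.approx(e_ele + e_vdw, abs=1e-6)
        res1 = binding_energy(
            [snap], bc.ligand_atoms, fast_pb_options, bc.params, bc.charges, bc.radii
        )
        assert dec.dg_np_res.sum() == pytest.approx(res1.dg_np_solv, abs=1e-6)
        assert dec.dg_pb_res.sum() == pytest.approx(res1.dg_pb_solv, abs=1e-6)

    def test_one_residue_receptor_collects_everything(self, fast_pb_options):
        bc = make_binding_complex(seed=4, n_res=2, n_snapshots=1)
        snap = bc.snapshots[0]
        # merge the two receptor residues into one by re-tagging
        from dataclasses import replace
        atoms = [
            replace(a, residue_index=1 if a.residue_index <= 2 else 2)
            for a in snap.atoms
        ]
        from uaaff.core import Conformer
        merged = Conformer(atoms=atoms)
        dec = per_residue_decomposition(
            merged, bc.ligand_atoms, fast_pb_options, bc.params, bc.charges, bc.radii
        )
        assert len(dec.residue_ids) == 2
        rec = np.array(
            [i for i in range(snap.n_atoms) if i not in bc.ligand_atoms]
        )
        e_ele, e_vdw = cross_interaction(
            merged.coordinates(), bc.charges.charges, bc.params,
            rec, np.array(bc.ligand_atoms),
        )
        # half the cross energy sits on the receptor residue, half on the ligand
        assert dec.de_mm_res[0] == pytest.approx((e_ele + e_vdw) / 2, abs=1e-9)

    def test_symmetric_dimer_shares_equally(self, fast_pb_options):
        from uaaff.core import AtomRecord, Conformer

        coords = np.array([[-2.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        atoms = [
            AtomRecord(0, "C1", "C", "A", 1, tuple(coords[0])),
            AtomRecord(1, "C2", "C", "B", 2, tuple(coords[1])),
        ]
        snap = Conformer(atoms=atoms)
        params = ForceFieldParameters(lj=[(1.8, 0.1)] * 2)
        charges = ChargeSet(np.array([0.5, 0.5]), 1)
        dec = per_residue_decomposition(
            snap, [1], fast_pb_options, params, charges, np.array([1.7, 1.7])
        )
        assert dec.de_mm_res[0] == pytest.approx(dec.de_mm_res[1], abs=1e-9)
        # surface quadrature points are not mirror-symmetric, so the
        # nonpolar halves agree only to the quadrature resolution
        assert dec.dg_np_res[0] == pytest.approx(dec.dg_np_res[1], abs=0.01)
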