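"""Complementarity-function algebra and the three analysis modes."""

import numpy as np
import pytest

from surfkit.atomtypes import assign_types, element_fallback_def
from surfkit.cf import (pair_cf, particular_residues, protein_ligand,
                        protein_protein, residue_totals,
                        resolve_residue_label)
from surfkit.energy import EnergyMatrix
from surfkit.fixtures import make_toy_complex, make_two_atom_fixture
from surfkit.geometry import contact_areas
from surfkit.structure import Structure


@pytest.fixture(scope="module")
def dimer_report(toy_dimer, toy_table, matrix):
    return protein_protein(toy_dimer, toy_table, ["A"], ["B"], matrix)


@pytest.fixture(scope="module")
def dimer_ctx(toy_dimer, toy_table):
    typed = assign_types(toy_dimer, toy_table)
    return typed, contact_areas(typed)


class TestPairCF:
    def test_zero_matrix_gives_zero(self, two_carbons_typed):
        cmap = contact_areas(two_carbons_typed)
        names = tuple(f"T{i}" for i in range(4))
        zero = EnergyMatrix(values=np.zeros((4, 4)), type_names=names)
        assert pair_cf([0], [1], two_carbons_typed, cmap, zero) == 0.0

    def test_two_atom_product(self, two_carbons_typed):
        # eps = -0.5 on the single contacting pair, S12 ≈ 21.43
        cmap = contact_areas(two_carbons_typed)
        tid = two_carbons_typed[0].type_id
        vals = np.zeros((40, 40))
        vals[tid - 1, tid - 1] = -0.5
        from surfkit.atomtypes import SYBYL_TYPES
        m = EnergyMatrix(values=vals, type_names=SYBYL_TYPES)
        cf = pair_cf([0], [1], two_carbons_typed, cmap, m)
        assert cf == pytest.approx(-10.71, rel=0.01)

    def test_no_contacts_zero(self, matrix):
        s = make_two_atom_fixture(("C", "C"), 100.0)
        typed = assign_types(s, element_fallback_def(s))
        cmap = contact_areas(typed)
        assert pair_cf([0], [1], typed, cmap, matrix) == 0.0

    def test_overlapping_sets_error(self, two_carbons_typed, matrix):
        cmap = contact_areas(two_carbons_typed)
        with pytest.raises(ValueError, match="overlap"):
            pair_cf([0, 1], [1], two_carbons_typed, cmap, matrix)


class TestAlgebra:
    def test_grand_total_equals_whole_set_cf(self, toy_dimer, dimer_report,
                                             dimer_ctx, matrix):
        typed, cmap = dimer_ctx
        ia = [i for i, a in enumerate(toy_dimer.atoms) if a.chain_id == "A"]
        ib = [i for i, a in enumerate(toy_dimer.atoms) if a.chain_id == "B"]
        whole = pair_cf(ia, ib, typed, cmap, matrix)
        assert dimer_report.grand_total == pytest.approx(whole, abs=1e-9)

    def test_bilinearity_over_partitions(self, toy_dimer, dimer_ctx, matrix):
        typed, cmap = dimer_ctx
        ia = [i for i, a in enumerate(toy_dimer.atoms) if a.chain_id == "A"]
        ib = [i for i, a in enumerate(toy_dimer.atoms) if a.chain_id == "B"]
        whole = pair_cf(ia, ib, typed, cmap, matrix)
        parts = sum(pair_cf([i], ib, typed, cmap, matrix) for i in ia)
        assert parts == pytest.approx(whole, abs=1e-9)

    def test_matrix_scaling_scales_cells(self, toy_dimer, toy_table, matrix,
                                         dimer_report):
        scaled = protein_protein(toy_dimer, toy_table, ["A"], ["B"],
                                 matrix.scaled(3.0))
        assert np.allclose(scaled.cf, 3.0 * dimer_report.cf, atol=1e-9)

    def test_zero_matrix_zero_report(self, toy_dimer, toy_table, matrix):
        zero = matrix.scaled(0.0)
        rep = protein_protein(toy_dimer, toy_table, ["A"], ["B"], zero)
        assert np.all(rep.cf == 0.0)


class TestProteinProtein:
    def test_contacting_residues_have_nonzero_cells(self, dimer_report):
        assert (dimer_report.cf != 0).sum() >= 1
        assert [u.label for u in dimer_report.rows] == [
            f"GLY{i}A" for i in range(1, 6)]

    def test_separated_chains_all_zero(self, toy_table, matrix):
        from dataclasses import replace
        s = make_toy_complex(seed=1, with_ligand=False)
        moved = [replace(a, x=a.x + 100.0) if a.chain_id == "B" else a
                 for a in s.atoms]
        rep = protein_protein(Structure(atoms=moved), toy_table, ["A"], ["B"],
                              matrix)
        assert np.all(rep.cf == 0.0)

    def test_intra_group_pairs_never_contribute(self, toy_dimer, dimer_ctx,
                                                dimer_report, matrix):
        # moving group-B rows into group A must not change any A-B cell sum
        typed, cmap = dimer_ctx
        ia = [i for i, a in enumerate(toy_dimer.atoms) if a.chain_id == "A"]
        ib = [i for i, a in enumerate(toy_dimer.atoms) if a.chain_id == "B"]
        assert dimer_report.grand_total == pytest.approx(
            pair_cf(ia, ib, typed, cmap, matrix), abs=1e-9)


class TestProteinLigand:
    def test_column_per_ligand_atom(self, toy_complex, toy_table, matrix):
        rep = protein_ligand(toy_complex, toy_table, "LIG", matrix)
        assert [u.label for u in rep.cols] == [
            "C1.LIG201L", "C2.LIG201L", "O1.LIG201L"]
        assert (rep.cf != 0).sum() >= 1

    def test_two_ligand_copies_distinct_columns(self, toy_table, matrix):
        from dataclasses import replace
        s = make_toy_complex(seed=1)
        extra = [replace(a, serial=a.serial + 100, res_seq=202, x=a.x + 3.5,
                         y=a.y - 1.0)
                 for a in s.atoms if a.res_name == "LIG"]
        s2 = Structure(atoms=list(s.atoms) + extra)
        rep = protein_ligand(s2, toy_table, "LIG", matrix)
        labels = [u.label for u in rep.cols]
        assert len(labels) == 6 and len(set(labels)) == 6

    def test_missing_code_error(self, toy_complex, toy_table, matrix):
        with pytest.raises(ValueError, match="XYZ"):
            protein_ligand(toy_complex, toy_table, "XYZ", matrix)

    def test_mode_consistency_with_chain_group_run(self, toy_complex,
                                                   toy_table, matrix):
        pl = protein_ligand(toy_complex, toy_table, "LIG", matrix)
        pp = protein_protein(toy_complex, toy_table, ["A", "B"], ["L"], matrix)
        pl_sums = dict(zip((u.label for u in pl.rows), pl.row_totals))
        pp_sums = dict(zip((u.label for u in pp.rows), pp.row_totals))
        assert set(pl_sums) == set(pp_sums)
        for k in pp_sums:
            assert pl_sums[k] == pytest.approx(pp_sums[k], abs=1e-9)


class TestParticularResidues:
    def test_only_contacting_partners_as_columns(self, toy_complex, toy_table,
                                                 matrix):
        rep = particular_residues(toy_complex, toy_table, ["GLY3A"], matrix)
        assert [u.label for u in rep.rows] == ["GLY3A"]
        assert len(rep.cols) >= 1
        # every column has an actual contact with the selection
        assert np.all(rep.cf != 0.0) or rep.cf.size == 0

    def test_includes_intra_chain_partners(self, toy_complex, toy_table,
                                           matrix):
        rep = particular_residues(toy_complex, toy_table, ["GLY3A"], matrix)
        labels = {u.label for u in rep.cols}
        assert any(lbl.endswith("A") for lbl in labels)  # same chain
        assert any(not lbl.endswith("A") for lbl in labels)  # other units

    def test_isolated_residue_empty_columns(self, toy_table, matrix):
        from dataclasses import replace
        s = make_toy_complex(seed=1, with_ligand=False)
        moved = [replace(a, x=a.x + 500.0) if a.res_seq == 5 and a.chain_id == "B"
                 else a for a in s.atoms]
        rep = particular_residues(Structure(atoms=moved), toy_table,
                                  ["GLY5B"], matrix)
        assert rep.cols == [] and rep.cf.shape == (1, 0)

    def test_selected_pair_symmetric_cells(self, toy_complex, toy_table,
                                           matrix):
        one = particular_residues(toy_complex, toy_table, ["GLY3A"], matrix)
        partners = [u.label for u in one.cols]
        partner = partners[0]
        rep = particular_residues(toy_complex, toy_table, ["GLY3A", partner],
                                  matrix)
        frame = rep.to_frame()
        assert frame.loc["GLY3A", partner] == pytest.approx(
            frame.loc[partner, "GLY3A"], abs=1e-12)

    def test_skip_adjacent_flag(self, toy_complex, toy_table, matrix):
        rep = particular_residues(toy_complex, toy_table, ["GLY3A"], matrix,
                                  skip_adjacent=True)
        labels = {u.label for u in rep.cols}
        assert "GLY2A" not in labels and "GLY4A" not in labels

    def test_ambiguous_label_lists_matches(self, toy_complex, toy_table,
                                           matrix):
        with pytest.raises(ValueError, match="GLY3A.*GLY3B|GLY3B.*GLY3A"):
            particular_residues(toy_complex, toy_table, ["GLY3"], matrix)

    def test_missing_label_error(self, toy_complex):
        with pytest.raises(ValueError, match="not found"):
            resolve_residue_label(toy_complex, "TRP99")


class TestResidueTotals:
    def test_single_cell_report(self, toy_complex, toy_table, matrix):
        rep = protein_ligand(toy_complex, toy_table, "LIG", matrix)
        nets = residue_totals(rep)
        for u, t in zip(rep.rows, rep.row_totals):
            assert nets[u.label] == pytest.approx(t)

    def test_row_and_column_nets_share_grand_total(self, dimer_report):
        assert dimer_report.row_totals.sum() == pytest.approx(
            dimer_report.col_totals.sum(), abs=1e-9)
        assert dimer_report.row_totals.sum() == pytest.approx(
            dimer_report.grand_total, abs=1e-9)

    def test_zero_report_zero_nets(self, toy_dimer, toy_table, matrix):
        rep = protein_protein(toy_dimer, toy_table, ["A"], ["B"],
                              matrix.scaled(0.0))
        assert all(v == 0.0 for v in residue_totals(rep).values())
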