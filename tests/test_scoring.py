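import numpy as np
import pytest

from symstack.errors import ParameterError, SingularGeometryError, SymstackError
from symstack.geometry import AffineOperator
from symstack.scoring import (
    StackEnergyReport,
    VdwParameterTable,
    assign_vdw_types,
    load_default_table,
    pair_vdw_energy,
    rank_poses,
    stack_score,
)
from symstack.stacking import ClashConfig, LigandAtom, LigandPose

from conftest import make_screw, random_operator


def single_atom(mol_id, element, xyz, vdw_type=None):
    return LigandPose(mol_id, [LigandAtom(element, f"{element}1", np.array(xyz),
                                          vdw_type=vdw_type)])


def lj(eps, rmin, r):
    x6 = (rmin / r) ** 6
    return eps * (x6 * x6 - 2 * x6)


class TestParameterTable:
    def test_parse_text(self):
        table = VdwParameterTable.from_text(
            "# comment\nX 1.0 1.7\nY 0.5 2.0  # inline\ndefault C X\n"
        )
        assert table.lookup("X") == (1.0, 1.7)
        assert table.default_type("C") == "X"

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ParameterError):
            VdwParameterTable(params={"X": (-0.1, 1.7)})

    def test_nonpositive_rmin_rejected(self):
        with pytest.raises(ParameterError):
            VdwParameterTable(params={"X": (0.1, 0.0)})

    def test_default_must_exist(self):
        with pytest.raises(ParameterError):
            VdwParameterTable(params={"X": (0.1, 1.7)}, element_defaults={"C": "Z"})

    def test_combination_rules(self, round_table):
        eps, rmin = round_table.pair_params("X", "Y")
        assert eps == pytest.approx(np.sqrt(1.0 * 0.25))
        assert rmin == pytest.approx(1.7 + 2.0)

    def test_shipped_table_loads(self):
        table = load_default_table()
        assert "C.ar" in table.params
        assert table.default_type("C") in table.params

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            VdwParameterTable.from_text("# nothing here\n")


class TestAssignTypes:
    def test_defaults_applied(self, hexagon, round_table):
        typed = assign_vdw_types(hexagon, round_table)
        assert all(a.vdw_type == "X" for a in typed.atoms)

    def test_explicit_types_preserved(self, round_table):
        pose = single_atom("m", "C", [0, 0, 0], vdw_type="Y")
        typed = assign_vdw_types(pose, round_table)
        assert typed.atoms[0].vdw_type == "Y"

    def test_unknown_element_reported(self, round_table):
        pose = LigandPose("m", [LigandAtom("Xe", "XE1", np.zeros(3)),
                                LigandAtom("C", "C1", np.array([1.5, 0, 0]))])
        with pytest.raises(ParameterError) as err:
            assign_vdw_types(pose, round_table)
        assert "Xe" in str(err.value)


class TestPairVdwEnergy:
    def test_lj_minimum_is_minus_epsilon(self, round_table):
        # rmin_ij = 2 * 1.7 = 3.4; energy there is exactly -eps
        a = single_atom("a", "C", [0.0, 0.0, 0.0])
        b = single_atom("b", "C", [3.4, 0.0, 0.0])
        e = pair_vdw_energy(
            assign_vdw_types(a, round_table), assign_vdw_types(b, round_table),
            round_table,
        )
        assert e == pytest.approx(-1.0, abs=1e-12)

    def test_asymptotic_zero(self, round_table):
        a = assign_vdw_types(single_atom("a", "C", [0, 0, 0]), round_table)
        b = assign_vdw_types(single_atom("b", "C", [100.0, 0, 0]), round_table)
        assert abs(pair_vdw_energy(a, b, round_table)) < 1e-6

    def test_double_loop_oracle(self, hexagon, round_table):
        from symstack.stacking import symmetry_clash_check

        rng = np.random.default_rng(31)
        typed = assign_vdw_types(hexagon, round_table)
        n_done = 0
        while n_done < 50:
            op = random_operator(rng)
            # scored pairs are clash-filtered first by contract
            if not symmetry_clash_check(hexagon, op, ClashConfig(cutoff=2.0))[0]:
                continue
            n_done += 1
            other = typed.transformed(op)
            got = pair_vdw_energy(typed, other, round_table)
            # oracle: explicit double loop over atom pairs
            expected = 0.0
            for ai in typed.atoms:
                for bj in other.atoms:
                    r = np.linalg.norm(ai.coord - bj.coord)
                    eps, rmin = round_table.pair_params(ai.vdw_type, bj.vdw_type)
                    expected += lj(eps, rmin, r)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetry_in_arguments(self, hexagon, round_table):
        typed = assign_vdw_types(hexagon, round_table)
        op = make_screw([0, 0, 1], -1.0, 4.0)
        other = typed.transformed(op)
        assert pair_vdw_energy(typed, other, round_table) == pytest.approx(
            pair_vdw_energy(other, typed, round_table), abs=1e-12
        )

    def test_zero_distance_rejected(self, round_table):
        a = assign_vdw_types(single_atom("a", "C", [0, 0, 0]), round_table)
        with pytest.raises(SingularGeometryError):
            pair_vdw_energy(a, a, round_table)

    def test_untyped_pose_rejected(self, hexagon, round_table):
        with pytest.raises(ParameterError):
            pair_vdw_energy(hexagon, hexagon, round_table)

    def test_translation_invariance_along_stack(self, hexagon, round_table):
        op = make_screw([0, 0, 1], -1.0, 4.0)
        typed = assign_vdw_types(hexagon, round_table)
        e01 = pair_vdw_energy(typed, typed.transformed(op), round_table)
        e12 = pair_vdw_energy(
            typed.transformed(op), typed.transformed(op.power(2)), round_table
        )
        assert e01 == pytest.approx(e12, abs=1e-9)

    def test_global_rigid_motion_invariance(self, hexagon, round_table):
        rng = np.random.default_rng(37)
        op = make_screw([0, 0, 1], -1.0, 4.0)
        typed = assign_vdw_types(hexagon, round_table)
        e0 = pair_vdw_energy(typed, typed.transformed(op), round_table)
        for _ in range(5):
            g = random_operator(rng)
            e = pair_vdw_energy(
                typed.transformed(g), typed.transformed(op).transformed(g), round_table
            )
            assert e == pytest.approx(e0, abs=1e-9)


class TestStackScore:
    def test_clashing_pose_not_scored(self, hexagon, round_table):
        rep = stack_score(hexagon, AffineOperator.identity(), round_table)
        assert not rep.passes_clash
        assert rep.ligand_ligand_vdw is None
        assert rep.total_score is None

    def test_report_invariant_enforced(self):
        with pytest.raises(SymstackError):
            StackEnergyReport("p", False, 0.5, ligand_ligand_vdw=-1.0)

    def test_optimal_separation_is_negative(self, hexagon, round_table):
        # oracle: 1D separation scan locates the LJ-optimal rise
        seps = np.linspace(2.5, 8.0, 200)
        energies = []
        typed = assign_vdw_types(hexagon, round_table)
        for s in seps:
            op = AffineOperator(np.eye(3), np.array([0.0, 0.0, s]))
            energies.append(pair_vdw_energy(typed, typed.transformed(op), round_table))
        best = seps[int(np.argmin(energies))]
        op = AffineOperator(np.eye(3), np.array([0.0, 0.0, best]))
        rep = stack_score(hexagon, op, round_table)
        assert rep.passes_clash
        assert rep.ligand_ligand_vdw < 0

    def test_protein_terms_additive(self, hexagon, round_table, translation_op):
        rep0 = stack_score(hexagon, translation_op, round_table,
                           protein_terms={"all": 0.0})
        assert rep0.total_score == pytest.approx(rep0.ligand_ligand_vdw, abs=1e-12)
        rep = stack_score(hexagon, translation_op, round_table,
                          protein_terms={"vdw": -3.0, "es": -1.5})
        assert rep.total_score == pytest.approx(rep.ligand_ligand_vdw - 4.5, abs=1e-12)

    def test_boundary_consistency(self, hexagon, round_table):
        # slide the pose's image closer until the verdict must flip
        cfg = ClashConfig(cutoff=2.0)
        for sep in (4.0, 3.0, 2.1, 1.9, 1.0):
            op = AffineOperator(np.eye(3), np.array([0.0, 0.0, sep]))
            rep = stack_score(hexagon, op, round_table, cfg)
            assert rep.passes_clash == (sep >= 2.0)

    def test_multi_image_sum(self, hexagon, round_table, translation_op):
        rep1 = stack_score(hexagon, translation_op, round_table, n_images=1)
        rep2 = stack_score(hexagon, translation_op, round_table, n_images=2)
        typed = assign_vdw_types(hexagon, round_table)
        second = pair_vdw_energy(
            typed, typed.transformed(translation_op.power(2)), round_table
        )
        assert rep2.ligand_ligand_vdw == pytest.approx(
            rep1.ligand_ligand_vdw + second, abs=1e-9
        )


class TestRankPoses:
    def test_orders_ascending(self):
        reports = [
            StackEnergyReport("a", True, 3.0, -5.0, total_score=-5.0),
            StackEnergyReport("b", True, 3.0, -7.0, total_score=-7.0),
            StackEnergyReport("c", True, 3.0, -6.0, total_score=-6.0),
        ]
        assert [r.pose_id for r in rank_poses(reports)] == ["b", "c", "a"]

    def test_clashing_excluded(self):
        reports = [
            StackEnergyReport("bad", False, 0.5),
            StackEnergyReport("good", True, 3.0, -2.0, total_score=-2.0),
        ]
        assert [r.pose_id for r in rank_poses(reports)] == ["good"]

    def test_mixed_term_sets_rejected(self):
        reports = [
            StackEnergyReport("a", True, 3.0, -5.0, total_score=-5.0),
            StackEnergyReport("b", True, 3.0, -7.0),
        ]
        with pytest.raises(SymstackError):
            rank_poses(reports)

    def test_reference_sort_oracle(self):
        rng = np.random.default_rng(41)
        reports = [
            StackEnergyReport(f"p{i:03d}", True, 3.0, float(s), total_score=float(s))
            for i, s in enumerate(rng.normal(size=100))
        ]
        got = [r.pose_id for r in rank_poses(reports)]
        want = [r.pose_id for r in sorted(reports, key=lambda r: (r.total_score, r.pose_id))]
        assert got == want

    def test_stable_tie_break_by_id(self):
        reports = [
            StackEnergyReport("z", True, 3.0, -5.0, total_score=-5.0),
            StackEnergyReport("a", True, 3.0, -5.0, total_score=-5.0),
        ]
        assert [r.pose_id for r in rank_poses(reports)] == ["a", "z"]
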