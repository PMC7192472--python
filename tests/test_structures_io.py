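"""Structure containers, PDB round-trips, parameters and selections."""

import numpy as np
import pytest

from stapletherm import (
    LINKER_GROUP,
    ParameterTable,
    Trajectory,
    assign_parameters,
    define_complex,
    generate_complex,
    generate_trajectory,
    group_decomposition,
    label_linker,
    linker_atom_ids,
    parameter_table_for,
    read_pdb,
    write_pdb,
)
from stapletherm.binding import effective_binding_energy
from stapletherm.structures import ParameterError, SelectionError, StructureError

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)


def test_read_single_atom_pdb(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(MINIMAL_PDB)
    traj = read_pdb(path)
    assert traj.n_frames == 1 and traj.n_atoms == 1
    atom = traj.topology.atoms[0]
    assert atom.atom_name == "CA" and atom.residue_name == "ALA"
    np.testing.assert_allclose(traj.frames[0, 0], [1.0, 2.0, 3.0])


def test_missing_file_raises():
    with pytest.raises(StructureError, match="no such"):
        read_pdb("does/not/exist.pdb")


def test_inconsistent_model_atom_counts(tmp_path):
    lines = ["MODEL        1"]
    for i in range(5):
        lines.append(
            f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    {1.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}"
            "  1.00  0.00           C"
        )
    lines += ["ENDMDL", "MODEL        2"]
    for i in range(4):
        lines.append(
            f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    {1.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}"
            "  1.00  0.00           C"
        )
    lines += ["ENDMDL", "END"]
    path = tmp_path / "ragged.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(StructureError, match="inconsistent atom count"):
        read_pdb(path)


def test_coordinate_serialization_rounds_to_three_decimals(tmp_path, synthetic_complex):
    system, _ = synthetic_complex
    traj = system.trajectory
    shifted = Trajectory(traj.topology, traj.frames + 12.3456 - traj.frames[0, 0, 0])
    path = tmp_path / "round.pdb"
    write_pdb(shifted, path)
    assert "  12.346" in path.read_text()


@pytest.mark.parametrize("n_frames", [1, 3])
def test_pdb_round_trip_preserves_everything(tmp_path, synthetic_complex, n_frames):
    """Round trip keeps atom count, order, names and coordinates to 1e-3 Å."""
    system, _ = synthetic_complex
    from dataclasses import replace
    spec = replace(__import__("stapletherm").SyntheticSpec(), n_frames=n_frames)
    traj = generate_trajectory(system, spec, replica_seed=7)
    path = tmp_path / "traj.pdb"
    write_pdb(traj, path)
    back = read_pdb(path)
    assert back.n_frames == n_frames
    assert [a.atom_name for a in back.topology.atoms] == \
        [a.atom_name for a in traj.topology.atoms]
    assert [a.residue_name for a in back.topology.atoms] == \
        [a.residue_name for a in traj.topology.atoms]
    assert np.abs(back.frames - traj.frames).max() <= 1e-3
    # single-frame files carry no MODEL records, multi-frame files do
    has_model = "MODEL" in path.read_text()
    assert has_model == (n_frames > 1)
    # second round trip is the identity on the parsed representation
    path2 = tmp_path / "traj2.pdb"
    write_pdb(back, path2)
    again = read_pdb(path2)
    np.testing.assert_array_equal(again.frames, back.frames)


class TestAssignParameters:
    def test_copies_fields_verbatim_and_checks_formal_charges(self, synthetic_complex):
        system, _ = synthetic_complex
        table = parameter_table_for(system)
        assigned = assign_parameters(system.trajectory, table)
        for a_in, a_out in zip(system.topology.atoms, assigned.topology.atoms):
            key = (a_in.residue_name, a_in.atom_name)
            q, s, e, r = table.entries[key]
            assert (a_out.partial_charge, a_out.lj_sigma,
                    a_out.lj_epsilon, a_out.intrinsic_radius) == (q, s, e, r)

    def test_unknown_atom_strict_mode_names_it(self, synthetic_complex):
        system, _ = synthetic_complex
        table = parameter_table_for(system)
        del table.entries[("PRB", "P1")]
        with pytest.raises(ParameterError, match=r"\(PRB, P1\)"):
            assign_parameters(system.trajectory, table)

    def test_formal_charge_mismatch_detected(self, synthetic_complex):
        system, _ = synthetic_complex
        table = parameter_table_for(system)
        q, s, e, r = table.entries[("PRB", "P1")]
        table.entries[("PRB", "P1")] = (q + 0.5, s, e, r)
        with pytest.raises(ParameterError, match="formal charge"):
            assign_parameters(system.trajectory, table)

    def test_idempotent(self, synthetic_complex):
        system, _ = synthetic_complex
        table = parameter_table_for(system)
        once = assign_parameters(system.trajectory, table)
        twice = assign_parameters(once, table)
        assert all(
            a.partial_charge == b.partial_charge and a.group_label == b.group_label
            for a, b in zip(once.topology.atoms, twice.topology.atoms)
        )

    def test_csv_round_trip(self, tmp_path, synthetic_complex):
        system, _ = synthetic_complex
        table = parameter_table_for(system)
        path = tmp_path / "params.csv"
        table.to_csv(path)
        back = ParameterTable.from_csv(path)
        assert set(back.entries) == set(table.entries)
        for key in table.entries:
            np.testing.assert_allclose(back.entries[key], table.entries[key],
                                       atol=1e-6)
        assert back.formal_charges.keys() == table.formal_charges.keys()


class TestDefineComplex:
    def test_sizes_match_generator_records(self, synthetic_complex):
        system, _ = synthetic_complex
        rebuilt = define_complex(system.trajectory, "chain P", "chain R")
        assert rebuilt.peptide_atom_ids == system.peptide_atom_ids
        assert rebuilt.receptor_atom_ids == system.receptor_atom_ids

    def test_partition_exact_and_exhaustive(self, synthetic_complex):
        system, _ = synthetic_complex
        all_ids = set(system.topology.atom_ids.tolist())
        pep, rec = system.peptide_atom_ids, system.receptor_atom_ids
        assert pep | rec <= all_ids
        assert not pep & rec
        neither = all_ids - pep - rec
        assert (pep | rec | neither) == all_ids

    def test_overlap_raises(self, synthetic_complex):
        system, _ = synthetic_complex
        with pytest.raises(SelectionError, match="overlap"):
            define_complex(system.trajectory, "chain P", "chain P")

    def test_empty_selection_raises(self, synthetic_complex):
        system, _ = synthetic_complex
        with pytest.raises(SelectionError, match="empty selection"):
            define_complex(system.trajectory, "chain Z", "chain R")


class TestLabelLinker:
    def test_labels_exactly_the_given_atoms(self, synthetic_complex):
        system, _ = synthetic_complex
        ids = linker_atom_ids(system)
        assert len(ids) == 8
        relabeled = label_linker(system.trajectory, ids)
        got = [a.atom_id for a in relabeled.topology.atoms
               if a.group_label == LINKER_GROUP]
        assert got == ids

    def test_empty_set_is_identity(self, synthetic_complex):
        system, _ = synthetic_complex
        out = label_linker(system.trajectory, set())
        assert [a.group_label for a in out.topology.atoms] == \
            [a.group_label for a in system.trajectory.topology.atoms]

    def test_unknown_atom_id_raises(self, synthetic_complex):
        system, _ = synthetic_complex
        with pytest.raises(StructureError, match="unknown atom ids"):
            label_linker(system.trajectory, {10 ** 6})

    def test_linker_group_in_decomposition_has_eight_members(self, synthetic_complex):
        system, _ = synthetic_complex
        decomp = effective_binding_energy(system, system.trajectory.frames[0])
        members = [a for a in system.topology.atoms
                   if a.group_label == LINKER_GROUP]
        assert len(members) == 8
        grouped = group_decomposition(decomp, system.topology)
        assert LINKER_GROUP in grouped.per_group
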