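"""System loading, trajectory round-trips and system-preparation math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligotraj import sequences
from oligotraj.errors import (
    ConfigurationError,
    DataError,
    TopologyError,
    ValidationError,
)
from oligotraj.model import (
    ChainRole,
    Frame,
    Trajectory,
    formal_charge,
    formal_charge_parts,
    iter_frames,
    load_system,
    molar_concentration,
    read_trajectory,
    write_pdb,
    write_trajectory,
)
from oligotraj.synthetic import build_bead_model

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  HA  ALA A   1       1.700   1.000   0.000  1.00  0.00           H
ATOM      4  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  SER A   3       8.000   0.000   0.000  1.00  0.00           C
TER       6      SER A   3
ATOM      7  CA  LEU B  10      20.000   0.000   0.000  1.00  0.00           C
ATOM      8  H   LEU B  10      20.500   1.000   0.000  1.00  0.00           H
ATOM      9  CA  VAL B  11      24.000   0.000   0.000  1.00  0.00           C
TER      10      VAL B  11
END
"""

ROLES = {"A": "peptide", "B": "inhibitor"}


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


class TestLoadSystem:
    def test_minimal_two_chain_structure(self, mini_pdb):
        model = load_system(mini_pdb, ROLES)
        assert len(model.chains) == 2
        assert model.n_residues == 5
        assert model.chains[0].role is ChainRole.PEPTIDE
        assert model.chains[1].role is ChainRole.INHIBITOR
        assert model.inhibitor_chain_ids == ["B"]

    def test_hydrogens_excluded(self, mini_pdb):
        model = load_system(mini_pdb, ROLES)
        assert all(el != "H" for el in model.atom_elements)
        assert model.n_atoms == 6  # 2 of the 8 ATOM records are hydrogens

    def test_deterministic_parse(self, mini_pdb):
        m1 = load_system(mini_pdb, ROLES)
        m2 = load_system(mini_pdb, ROLES)
        assert m1.chains == m2.chains
        assert m1.atom_names == m2.atom_names

    def test_missing_role_is_configuration_error(self, mini_pdb):
        with pytest.raises(ConfigurationError):
            load_system(mini_pdb, {"A": "peptide"})

    def test_pdb_roundtrip_via_writer(self, tmp_path):
        model = build_bead_model(2, "lysozyme")
        coords = np.random.default_rng(0).uniform(0, 50, (model.n_atoms, 3))
        write_pdb(model, coords, tmp_path / "sys.pdb", box=np.full(3, 60.0))
        again = load_system(tmp_path / "sys.pdb",
                            {"0": "peptide", "1": "peptide", "L": "inhibitor"})
        assert again.n_atoms == model.n_atoms
        assert again.residue_names == model.residue_names


class TestTrajectoryIO:
    def _mk_traj(self, n_frames=3, dt=0.1):
        model = build_bead_model(1, None)
        rng = np.random.default_rng(1)
        frames = [
            Frame(i * dt, rng.uniform(0, 40, (model.n_atoms, 3)), np.full(3, 50.0))
            for i in range(n_frames)
        ]
        return Trajectory(model, frames)

    def test_three_frame_roundtrip_times(self, tmp_path):
        traj = self._mk_traj()
        path = tmp_path / "t.txt"
        write_trajectory(traj, path)
        frames = list(iter_frames(path, traj.model))
        assert len(frames) == 3
        assert [f.time for f in frames] == pytest.approx([0.0, 0.1, 0.2])

    def test_roundtrip_coordinates_within_write_precision(self, tmp_path):
        traj = self._mk_traj()
        path = tmp_path / "t.txt"
        write_trajectory(traj, path)
        back = read_trajectory(path, traj.model)
        for a, b in zip(traj.frames, back.frames):
            assert np.abs(a.coords - b.coords).max() <= 1e-4
            assert np.allclose(a.box, b.box)

    def test_atom_count_mismatch_is_topology_error(self, tmp_path):
        traj = self._mk_traj()
        path = tmp_path / "t.txt"
        write_trajectory(traj, path)
        from conftest import point_system
        # topology one atom short of the file
        wrong = point_system({"0": ("peptide", traj.model.n_atoms - 1)})
        with pytest.raises(TopologyError):
            list(iter_frames(path, wrong))

    def test_non_monotonic_times_are_data_error(self, tmp_path):
        traj = self._mk_traj()
        path = tmp_path / "t.txt"
        write_trajectory(traj, path)
        text = path.read_text().replace("frame 0.200000", "frame 0.050000")
        path.write_text(text)
        with pytest.raises(DataError):
            list(iter_frames(path, traj.model))

    def test_binary_dcd_roundtrip(self, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        from oligotraj.model import _mdtraj_topology

        traj = self._mk_traj()
        top = _mdtraj_topology(traj.model)
        xyz = np.stack([f.coords for f in traj.frames]) / 10.0   # Å -> nm
        mt = mdtraj.Trajectory(xyz, top,
                               time=np.array([f.time * 1000 for f in traj.frames]),
                               unitcell_lengths=np.tile([5.0, 5.0, 5.0], (3, 1)),
                               unitcell_angles=np.tile([90.0] * 3, (3, 1)))
        mt.save_dcd(str(tmp_path / "t.dcd"))
        frames = list(iter_frames(tmp_path / "t.dcd", traj.model))
        assert len(frames) == 3
        assert np.allclose(frames[1].coords, traj.frames[1].coords, atol=1e-3)


class TestFormalCharge:
    @pytest.mark.parametrize("seq,expected", [
        (sequences.ABETA_17_42, -1),   # Aβ17-42 with charged termini
        ("GGGG", 0),
        ("KRDE", 0),
    ])
    def test_known_charges(self, seq, expected):
        assert formal_charge(seq, charged_termini=True) == expected

    def test_termini_reported_separately(self):
        side, n_term, c_term = formal_charge_parts("GGGG", charged_termini=True)
        assert (side, n_term, c_term) == (0, 1, -1)
        assert formal_charge_parts("GGGG", charged_termini=False) == (0, 0, 0)

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValidationError):
            formal_charge("AXB")
        with pytest.raises(ValidationError):
            formal_charge("")

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
    )
    def test_additive_over_concatenation_without_termini(self, a, b):
        assert formal_charge(a + b, charged_termini=False) == \
            formal_charge(a, charged_termini=False) + \
            formal_charge(b, charged_termini=False)


class TestMolarConcentration:
    def test_simulated_box_concentration(self):
        # ten peptides in the 124 Å cubic box
        assert molar_concentration(10, 124.0) == pytest.approx(8.7, abs=0.05)

    def test_zero_molecules(self):
        assert molar_concentration(0, 50.0) == 0.0

    def test_closed_form_single_molecule(self):
        # 1 / (N_A * 1e6 Å^3 in litres) = 1.661 mM
        assert molar_concentration(1, 100.0) == pytest.approx(1.661, abs=1e-3)

    def test_linear_in_n_and_inverse_in_volume(self):
        c1 = molar_concentration(3, [100, 100, 100])
        assert molar_concentration(6, [100, 100, 100]) == pytest.approx(2 * c1)
        assert molar_concentration(3, [200, 100, 100]) == pytest.approx(c1 / 2)

    def test_invalid_edges(self):
        with pytest.raises(ValidationError):
            molar_concentration(1, -5.0)
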