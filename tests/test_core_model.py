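"""Core types, PDB/DCD I/O, parameter assignment, selections, trimming."""

import struct

import numpy as np
import pandas as pd
import pytest

import helixscope as hx
from helixscope.errors import (
    FormatError,
    HelixscopeError,
    InconsistencyError,
    ParameterAssignmentError,
    SelectionSyntaxError,
    TruncatedFileError,
)

PDB_3ATOM = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00      PROT
ATOM      2  CA  ALA A   1       2.500   3.500   4.500  1.00  0.00      PROT
ATOM      3  C   ALA A   1       4.000   5.250   6.125  1.00  0.00      PROT
END
"""


def two_model_pdb(drop_last_atom_in_model2: bool = False) -> str:
    atoms = PDB_3ATOM.splitlines()[:3]
    m2 = atoms[: 2 if drop_last_atom_in_model2 else 3]
    lines = ["MODEL     1", *atoms, "ENDMDL", "MODEL     2", *m2, "ENDMDL",
             "END"]
    return "\n".join(lines) + "\n"


class TestPDB:
    def test_single_model_identity_read(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(PDB_3ATOM)
        traj = hx.read_pdb(path)
        assert traj.n_frames == 1 and traj.n_atoms == 3
        np.testing.assert_allclose(
            traj.frames[0].coordinates,
            [[1, 2, 3], [2.5, 3.5, 4.5], [4, 5.25, 6.125]])
        assert [a.atom_name for a in traj.topology] == ["N", "CA", "C"]
        assert traj.topology[0].residue_id == 1
        assert traj.topology[0].segment_id == "PROT"

    def test_two_models_two_frames(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(two_model_pdb())
        traj = hx.read_pdb(path)
        assert traj.n_frames == 2 and traj.n_atoms == 3

    def test_inconsistent_model_atom_count(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(two_model_pdb(drop_last_atom_in_model2=True))
        with pytest.raises(InconsistencyError, match="MODEL 2"):
            hx.read_pdb(path)

    def test_unparseable_atom_line_names_line_number(self, tmp_path):
        bad = PDB_3ATOM.replace("   4.000", "   x.000")
        path = tmp_path / "garbled.pdb"
        path.write_text(bad)
        with pytest.raises(FormatError, match="line 3"):
            hx.read_pdb(path)

    def test_round_trip_multi_model(self, tmp_path, small_traj):
        sub = hx.Trajectory(small_traj.topology, small_traj.frames[:3])
        path = tmp_path / "rt.pdb"
        hx.write_pdb(sub, path)
        back = hx.read_pdb(path)
        assert back.n_frames == 3
        # PDB stores 3 decimals
        np.testing.assert_allclose(back.coordinates(), sub.coordinates(),
                                   atol=5.1e-4)
        assert [a.key for a in back.topology] == [a.key for a in sub.topology]

    def test_third_party_reader_agrees(self, tmp_path, small_traj):
        mdtraj = pytest.importorskip("mdtraj")
        one = hx.Trajectory(small_traj.topology, [small_traj.frames[0]])
        path = tmp_path / "oracle.pdb"
        hx.write_pdb(one, path)
        ref = mdtraj.load_pdb(str(path))
        np.testing.assert_allclose(ref.xyz[0] * 10.0,
                                   one.frames[0].coordinates, atol=5.1e-4)


def _byteswap_dcd(src, dst):
    """Rewrite a (native little-endian) DCD with swapped byte order."""
    data = open(src, "rb").read()
    out = bytearray()
    i = 0
    rec_no = 0
    while i < len(data):
        (n,) = struct.unpack("<i", data[i:i + 4])
        payload = data[i + 4:i + 4 + n]
        if rec_no == 0:
            swapped = payload[:4] + np.frombuffer(
                payload[4:], "<i4").byteswap().tobytes()
        elif rec_no == 1:  # title: leading count int, then raw chars
            swapped = np.frombuffer(
                payload[:4], "<i4").byteswap().tobytes() + payload[4:]
        elif rec_no == 2:
            swapped = np.frombuffer(payload, "<i4").byteswap().tobytes()
        elif n == 48:  # unit-cell block (6 doubles; atom count ≠ 12 here)
            swapped = np.frombuffer(payload, "<f8").byteswap().tobytes()
        else:  # coordinate block (float32)
            swapped = np.frombuffer(payload, "<f4").byteswap().tobytes()
        marker = struct.pack(">i", n)
        out += marker + swapped + marker
        rec_no += 1
        i += 8 + n
    open(dst, "wb").write(bytes(out))


class TestDCD:
    @pytest.fixture()
    def five_frame(self, small_traj):
        return hx.Trajectory(small_traj.topology, small_traj.frames[:5],
                             frame_interval=small_traj.frame_interval)

    def test_round_trip_float32(self, tmp_path, five_frame):
        path = tmp_path / "t.dcd"
        hx.write_dcd(five_frame, path)
        back = hx.read_dcd(path, five_frame.topology)
        assert back.n_frames == 5
        np.testing.assert_array_equal(
            back.coordinates(),
            five_frame.coordinates().astype(np.float32).astype(float))
        assert back.frame_interval == pytest.approx(
            five_frame.frame_interval, rel=1e-6)
        np.testing.assert_allclose(back.frames[0].box, five_frame.frames[0].box)

    def test_byte_swapped_copy_identical(self, tmp_path, five_frame):
        native = tmp_path / "n.dcd"
        swapped = tmp_path / "s.dcd"
        hx.write_dcd(five_frame, native)
        _byteswap_dcd(native, swapped)
        a = hx.read_dcd(native, five_frame.topology)
        b = hx.read_dcd(swapped, five_frame.topology)
        np.testing.assert_array_equal(a.coordinates(), b.coordinates())
        assert a.frame_interval == pytest.approx(b.frame_interval, rel=1e-6)

    def test_truncated_file_reports_complete_frames(self, tmp_path, five_frame):
        path = tmp_path / "t.dcd"
        hx.write_dcd(five_frame, path)
        data = open(path, "rb").read()
        cut = tmp_path / "cut.dcd"
        cut.write_bytes(data[:len(data) - five_frame.n_atoms * 4 - 20])
        with pytest.raises(TruncatedFileError) as err:
            hx.read_dcd(cut, five_frame.topology)
        assert err.value.complete_frames == 4
        assert "4 complete frame" in str(err.value)

    def test_atom_count_mismatch(self, tmp_path, five_frame):
        path = tmp_path / "t.dcd"
        hx.write_dcd(five_frame, path)
        small_top = hx.Topology(list(five_frame.topology)[:10])
        with pytest.raises(InconsistencyError, match="topology has 10"):
            hx.read_dcd(path, small_top)

    def test_empty_trajectory_rejected(self, small_traj):
        with pytest.raises(HelixscopeError, match="at least one frame"):
            hx.Trajectory(small_traj.topology, [])

    def test_third_party_reader_agrees(self, tmp_path, five_frame):
        mda = pytest.importorskip("MDAnalysis")
        dcd = tmp_path / "t.dcd"
        pdb = tmp_path / "t.pdb"
        hx.write_dcd(five_frame, dcd)
        hx.write_pdb(hx.Trajectory(five_frame.topology,
                                   [five_frame.frames[0]]), pdb)
        u = mda.Universe(str(pdb), str(dcd))
        assert len(u.trajectory) == 5
        for f, ts in enumerate(u.trajectory):
            np.testing.assert_allclose(
                ts.positions,
                five_frame.frames[f].coordinates.astype(np.float32))
        assert u.trajectory.dt == pytest.approx(five_frame.frame_interval,
                                                rel=1e-6)


class TestParameters:
    @pytest.fixture()
    def three_ca(self):
        return hx.Topology([
            hx.AtomRecord("CA", "ALA", i, "PROT") for i in (1, 2, 3)])

    def test_wildcard_row_assigns_all(self, three_ca):
        table = pd.DataFrame([{"segid": "*", "resname": "*", "name": "CA",
                               "mass": 12.011, "charge": 0.07,
                               "epsilon": 0.07, "rmin_half": 1.9924}])
        top = hx.assign_parameters(three_ca, table)
        assert all(a.mass == 12.011 and a.lj_rmin_half == 1.9924 for a in top)

    def test_specific_row_overrides_wildcard(self, three_ca):
        table = pd.DataFrame([
            {"segid": "*", "resname": "*", "name": "CA", "mass": 12.011,
             "charge": 0.07, "epsilon": 0.07, "rmin_half": 1.9924},
            {"segid": "PROT", "resname": "ALA", "name": "CA", "mass": 13.0,
             "charge": -0.2, "epsilon": 0.1, "rmin_half": 2.0},
        ])
        top = hx.assign_parameters(three_ca, table)
        assert all(a.mass == 13.0 and a.charge == -0.2 for a in top)

    def test_unmatched_atom_lists_triples(self, three_ca):
        table = pd.DataFrame([{"segid": "*", "resname": "*", "name": "CB",
                               "mass": 1, "charge": 0, "epsilon": 0,
                               "rmin_half": 1}])
        with pytest.raises(ParameterAssignmentError) as err:
            hx.assign_parameters(three_ca, table)
        assert len(err.value.unmatched) == 3
        assert ("PROT", 1, "CA") in err.value.unmatched


class TestSelect:
    def test_tmd_ca_count(self, small_system):
        top, _ = small_system
        sel = hx.select(top, "resid 57 to 82 and name CA")
        assert len(sel) == 26

    def test_single_residue(self, small_system):
        top, _ = small_system
        assert len(hx.select(top, "resid 69 and name CA")) == 1

    def test_unknown_name_yields_empty(self, small_system):
        top, _ = small_system
        assert len(hx.select(top, "name XX")) == 0

    def test_syntax_error_carries_position(self, small_system):
        top, _ = small_system
        with pytest.raises(SelectionSyntaxError) as err:
            hx.select(top, "resid 57 to")
        assert err.value.position == len("resid 57 to")

    @pytest.mark.parametrize("a,b", [
        ("resid 57 to 82", "name CA"),
        ("segid PROT", "resid 60 to 100"),
        ("name P", "segid MEMB"),
        ("not name CA", "resid 1 to 50 or resid 90 to 103"),
    ])
    def test_and_is_set_intersection(self, small_system, a, b):
        top, _ = small_system
        lhs = set(hx.select(top, f"({a}) and ({b})").indices)
        rhs = set(hx.select(top, a).indices) & set(hx.select(top, b).indices)
        assert lhs == rhs
        ors = set(hx.select(top, f"({a}) or ({b})").indices)
        assert ors == set(hx.select(top, a).indices) | set(
            hx.select(top, b).indices)

    def test_not_is_complement(self, small_system):
        top, _ = small_system
        inside = set(hx.select(top, "segid PROT").indices)
        outside = set(hx.select(top, "not segid PROT").indices)
        assert inside | outside == set(range(len(top)))
        assert inside & outside == set()

    def test_indices_strictly_increasing(self, small_system):
        top, _ = small_system
        idx = hx.select(top, "resid 90 to 95 or resid 10 to 30").array
        assert np.all(np.diff(idx) > 0)


class TestTrim:
    @pytest.fixture()
    def traj200(self, small_system):
        top, frame = small_system
        frames = [hx.Frame(frame.coordinates.copy()) for _ in range(200)]
        return hx.Trajectory(top, frames, frame_interval=1000.0)

    def test_default_cut_drops_first_15ns(self, traj200):
        out = hx.trim_equilibration(traj200, 15000.0)
        assert out.n_frames == 185
        assert out.origin_time == 15000.0

    def test_zero_cut_is_identity(self, traj200):
        out = hx.trim_equilibration(traj200, 0.0)
        assert out is traj200

    def test_cut_beyond_last_frame_errors(self, traj200):
        with pytest.raises(HelixscopeError, match="removes all"):
            hx.trim_equilibration(traj200, 1e9)

    @pytest.mark.parametrize("a,b", [(3000, 8000), (8000, 3000),
                                     (15000, 15000)])
    def test_composition_takes_max(self, traj200, a, b):
        twice = hx.trim_equilibration(hx.trim_equilibration(traj200, a), b)
        once = hx.trim_equilibration(traj200, max(a, b))
        assert twice.n_frames == once.n_frames
        assert twice.origin_time == once.origin_time
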