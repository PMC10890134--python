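"""PDB v3.3 reading and writing (ATOM/HETATM/MODEL/ENDMDL records).

Only the coordinate section is interpreted; everything else is skipped.
Atom order within a model is preserved exactly. A file without MODEL
records yields a single-frame trajectory. Charges and LJ parameters are
left at zero for :func:`helixscope.parameters.assign_parameters` to fill.
"""

from __future__ import annotations

import logging
from typing import List, Optional

import numpy as np

from .errors import FormatError, HelixscopeError, InconsistencyError
from .model import AtomRecord, Frame, Topology, Trajectory

log = logging.getLogger(__name__)

__all__ = ["read_pdb", "write_pdb"]


def _parse_atom_line(line: str, lineno: int):
    # PDB v3.3 fixed columns (0-based slices)
    try:
        name = line[12:16].strip()
        resname = line[17:21].strip()
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM/HETATM record at line {lineno}: {exc}")
    segid = line[72:76].strip() if len(line) >= 73 else ""
    if not segid:
        segid = line[21].strip()  # fall back to chain id
    if not name:
        raise FormatError(f"missing atom name at line {lineno}")
    return name, resname, resid, segid, (x, y, z)


def read_pdb(path, frame_interval: float = 1.0, origin_time: float = 0.0) -> Trajectory:
    """Read a single- or multi-model PDB file into a :class:`Trajectory`.

    Each MODEL becomes one frame; all models must list the same atoms in
    the same order. ``frame_interval`` (ps) cannot be recovered from a PDB
    and must be supplied by the caller when it matters.
    """
    models: List[list] = []
    current: Optional[list] = None
    seen_model_record = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "MODEL":
                seen_model_record = True
                if current:
                    models.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                current.append(_parse_atom_line(raw.rstrip("\n"), lineno))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    ref = models[0]
    n = len(ref)
    for m, model in enumerate(models[1:], start=2):
        if len(model) != n:
            raise InconsistencyError(
                f"{path}: MODEL {m} has {len(model)} atoms, MODEL 1 has {n}"
            )
        for a, (rec, refrec) in enumerate(zip(model, ref)):
            if rec[:4] != refrec[:4]:
                raise InconsistencyError(
                    f"{path}: MODEL {m} atom {a + 1} is {rec[:4]}, "
                    f"MODEL 1 has {refrec[:4]}"
                )

    atoms = [
        AtomRecord(atom_name=name, residue_name=resname, residue_id=resid,
                   segment_id=segid)
        for name, resname, resid, segid, _ in ref
    ]
    topology = Topology(atoms)
    frames = [
        Frame(np.array([xyz for *_, xyz in model], dtype=float))
        for model in models
    ]
    log.info("read_pdb %s: %d atoms, %d frame(s)%s", path, n, len(frames),
             "" if seen_model_record else " (no MODEL records)")
    return Trajectory(topology, frames, frame_interval=frame_interval,
                      origin_time=origin_time)


def write_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a (multi-)model PDB v3.3 file."""
    if traj.n_frames < 1:
        raise HelixscopeError("cannot write an empty trajectory")
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        for f, frame in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL     {f:4d}\n")
            for i, (atom, xyz) in enumerate(
                zip(traj.topology, frame.coordinates), start=1
            ):
                name = atom.atom_name
                # PDB convention: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
                fh.write(
                    "ATOM  {serial:5d} {name:4s} {resname:<4s}{chain:1s}"
                    "{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "      {segid:<4s}\n".format(
                        serial=i % 100000,
                        name=name_field,
                        resname=atom.residue_name[:4],
                        chain=(atom.segment_id[:1] or "A"),
                        resid=atom.residue_id % 10000,
                        x=xyz[0], y=xyz[1], z=xyz[2],
                        occ=1.0, b=0.0,
                        segid=atom.segment_id[:4],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    log.info("write_pdb %s: %d atoms, %d frame(s)", path, traj.n_atoms,
             traj.n_frames)
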