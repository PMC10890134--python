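"""CHARMM/NAMD binary DCD trajectory reading and writing.

The dialect is CHARMM-style: a 'CORD' header with a 20-integer control
block, title block, atom-count block, then per frame an optional 48-byte
unit-cell record followed by three float32 records (X, Y, Z). Both byte
orders are accepted on read (detected from the leading Fortran record
marker); files are written native-endian. Coordinates are Å; the header
timestep is stored in AKMA units as CHARMM does.
"""

from __future__ import annotations

import logging
import struct
from typing import Optional

import numpy as np

from .errors import FormatError, InconsistencyError, TruncatedFileError
from .model import Frame, Topology, Trajectory

log = logging.getLogger(__name__)

__all__ = ["read_dcd", "write_dcd"]

AKMA_TIME_PS = 0.04888821  # 1 AKMA time unit in ps (CHARMM convention)
_HDR_SIZE = 84


def _read_record(fh, endian: str, context: str, frames_done: int) -> bytes:
    head = fh.read(4)
    if len(head) == 0:
        raise EOFError
    if len(head) < 4:
        raise TruncatedFileError(
            f"truncated record marker while reading {context}; "
            f"{frames_done} complete frame(s) read", frames_done)
    (nbytes,) = struct.unpack(endian + "i", head)
    payload = fh.read(nbytes)
    tail = fh.read(4)
    if len(payload) < nbytes or len(tail) < 4:
        raise TruncatedFileError(
            f"truncated {context} record; {frames_done} complete frame(s) read",
            frames_done)
    (check,) = struct.unpack(endian + "i", tail)
    if check != nbytes:
        raise FormatError(
            f"corrupt {context} record: leading marker {nbytes}, trailing {check}")
    return payload


def _write_record(fh, payload: bytes) -> None:
    marker = struct.pack("=i", len(payload))
    fh.write(marker)
    fh.write(payload)
    fh.write(marker)


def read_dcd(
    path,
    topology: Topology,
    frame_interval: Optional[float] = None,
    origin_time: Optional[float] = None,
) -> Trajectory:
    """Read a DCD file against a known topology.

    The frame spacing is taken from the header (timestep × save frequency,
    AKMA → ps) when the header carries one; pass ``frame_interval`` (ps) to
    override or to supply it when the header field is zero.
    """
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise FormatError(f"{path}: not a DCD file (too short)")
        for endian in ("<", ">"):
            if struct.unpack(endian + "i", head)[0] == _HDR_SIZE:
                break
        else:
            raise FormatError(f"{path}: bad DCD header magic {head!r}")
        fh.seek(0)

        header = _read_record(fh, endian, "header", 0)
        if len(header) != _HDR_SIZE or header[:4] != b"CORD":
            raise FormatError(f"{path}: DCD header is not a CORD block")
        icntrl = np.frombuffer(header[4:], dtype=np.dtype(endian + "i4"))
        nset, istart, nsavc = int(icntrl[0]), int(icntrl[1]), int(icntrl[2])
        has_cell = int(icntrl[10]) != 0
        delta = float(np.frombuffer(header[4 + 9 * 4:4 + 10 * 4],
                                    dtype=np.dtype(endian + "f4"))[0])

        _read_record(fh, endian, "title", 0)
        natom_rec = _read_record(fh, endian, "atom count", 0)
        (natoms,) = struct.unpack(endian + "i", natom_rec[:4])
        if natoms != len(topology):
            raise InconsistencyError(
                f"{path}: DCD has {natoms} atoms, topology has {len(topology)}")

        f4 = np.dtype(endian + "f4")
        f8 = np.dtype(endian + "f8")
        frames = []
        while True:
            nread = len(frames)
            first = True
            try:
                if has_cell:
                    cell = np.frombuffer(
                        _read_record(fh, endian, "unit cell", nread), f8)
                    first = False
                    box = np.array([cell[0], cell[2], cell[5]], dtype=float)
                else:
                    box = None
                xyz = np.empty((natoms, 3))
                for k, axis in enumerate("xyz"):
                    rec = _read_record(fh, endian, f"{axis} coordinates", nread)
                    first = False
                    vals = np.frombuffer(rec, f4)
                    if vals.size != natoms:
                        raise FormatError(
                            f"{path}: {axis} record has {vals.size} values, "
                            f"expected {natoms}")
                    xyz[:, k] = vals
            except EOFError:
                if first:
                    break  # clean end between frames
                raise TruncatedFileError(
                    f"{path}: file ends mid-frame; {nread} complete frame(s) "
                    f"read", nread)
            frames.append(Frame(xyz, box=box))
        if not frames:
            raise FormatError(f"{path}: DCD contains no frames")
        if nset and nset != len(frames):
            log.warning("%s: header NSET=%d but %d frames present; using actual",
                        path, nset, len(frames))

    if frame_interval is None:
        if delta > 0 and nsavc > 0:
            frame_interval = delta * AKMA_TIME_PS * nsavc
        else:
            frame_interval = 1.0
    if origin_time is None:
        origin_time = istart * delta * AKMA_TIME_PS if delta > 0 else 0.0
    log.info("read_dcd %s: %d atoms, %d frames, dt=%.4g ps", path, natoms,
             len(frames), frame_interval)
    return Trajectory(topology, frames, frame_interval=frame_interval,
                      origin_time=origin_time)


def write_dcd(traj: Trajectory, path) -> None:
    """Write a trajectory as a native-endian CHARMM-style DCD file."""
    if traj.n_frames < 1:
        raise FormatError("cannot write an empty trajectory")
    has_cell = all(f.box is not None for f in traj.frames)
    delta_akma = traj.frame_interval / AKMA_TIME_PS
    istart = int(round(traj.origin_time / traj.frame_interval))

    icntrl = np.zeros(20, dtype=np.int32)
    icntrl[0] = traj.n_frames          # NSET
    icntrl[1] = istart                 # ISTART (in save-frequency units)
    icntrl[2] = 1                      # NSAVC
    icntrl[3] = traj.n_frames          # NSTEP
    icntrl[9] = np.float32(delta_akma).view(np.int32)  # DELTA as float32 bits
    icntrl[10] = 1 if has_cell else 0
    icntrl[19] = 24                    # CHARMM version stamp

    with open(path, "wb") as fh:
        _write_record(fh, b"CORD" + icntrl.tobytes())
        title = b"* written by helixscope".ljust(80)
        _write_record(fh, struct.pack("=i", 1) + title)
        _write_record(fh, struct.pack("=i", traj.n_atoms))
        for frame in traj.frames:
            if has_cell:
                lx, ly, lz = frame.box
                # CHARMM layout: a, cos(gamma), b, cos(beta), cos(alpha), c
                cell = np.array([lx, 0.0, ly, 0.0, 0.0, lz])
                _write_record(fh, cell.astype("=f8").tobytes())
            xyz = frame.coordinates.astype("=f4")
            for k in range(3):
                _write_record(fh, xyz[:, k].tobytes())
    log.info("write_dcd %s: %d atoms, %d frames", path, traj.n_atoms,
             traj.n_frames)
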