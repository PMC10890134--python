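"""Core domain types: atoms, topologies, frames, trajectories, selections.

Conventions (CHARMM/NAMD style) used throughout the package:

* coordinates in Angstrom (Å), times stored in picoseconds and reported in
  nanoseconds, energies in kcal/mol, angles in degrees;
* residue ids follow the author/PDB ``resid`` field, 1-based, never
  renumbered;
* the order of atoms in a :class:`Topology` defines the atom index used by
  every :class:`Frame` and :class:`Selection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import HelixscopeError, InconsistencyError

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "ScalarSeries",
    "trim_equilibration",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom's frame-invariant metadata.

    ``charge`` (elementary charges), ``lj_epsilon`` (kcal/mol, well depth,
    stored non-negative) and ``lj_rmin_half`` (Å, half the LJ minimum
    distance) stay zero until :func:`helixscope.parameters.assign_parameters`
    fills them from a parameter table.
    """

    atom_name: str
    residue_name: str
    residue_id: int
    segment_id: str
    mass: float = 0.0
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0

    @property
    def key(self) -> tuple:
        return (self.segment_id, self.residue_id, self.atom_name)


class Topology:
    """Ordered, immutable list of :class:`AtomRecord`.

    The (segment_id, residue_id, atom_name) triple must be unique; atom
    order is significant and defines atom indices.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = tuple(atoms)
        if not atoms:
            raise HelixscopeError("Topology must contain at least one atom")
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise InconsistencyError(
                f"duplicate atom {dup!r}: (segid, resid, name) must be unique"
            )
        self.atoms = atoms
        # cached per-atom arrays for vectorized consumers
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.charges = np.array([a.charge for a in atoms], dtype=float)
        self.lj_epsilons = np.array([a.lj_epsilon for a in atoms], dtype=float)
        self.lj_rmin_halves = np.array([a.lj_rmin_half for a in atoms], dtype=float)
        self.residue_ids = np.array([a.residue_id for a in atoms], dtype=int)
        self.atom_names = np.array([a.atom_name for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.segment_ids = np.array([a.segment_id for a in atoms], dtype=object)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i: int) -> AtomRecord:
        return self.atoms[i]

    def with_atoms(self, atoms: Sequence[AtomRecord]) -> "Topology":
        return Topology(atoms)


@dataclass
class Frame:
    """One coordinate set (N×3, Å) with an optional orthorhombic box."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None  # (lx, ly, lz) edge lengths, Å

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise HelixscopeError(
                f"Frame coordinates must be N×3, got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise HelixscopeError("Frame contains non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Time-ordered frames over a fixed :class:`Topology`.

    ``frame_interval`` is the spacing (ps) between stored frames and
    ``origin_time`` the absolute time (ps) of the first stored frame; frame
    ``i`` is at ``origin_time + i * frame_interval``.
    """

    def __init__(
        self,
        topology: Topology,
        frames: Sequence[Frame],
        frame_interval: float = 1.0,
        origin_time: float = 0.0,
    ):
        frames = list(frames)
        if not frames:
            raise HelixscopeError("Trajectory must contain at least one frame")
        if frame_interval <= 0:
            raise HelixscopeError("frame_interval must be positive")
        n = len(topology)
        for i, fr in enumerate(frames):
            if fr.n_atoms != n:
                raise InconsistencyError(
                    f"frame {i} has {fr.n_atoms} atoms, topology has {n}"
                )
        self.topology = topology
        self.frames = frames
        self.frame_interval = float(frame_interval)
        self.origin_time = float(origin_time)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def times(self) -> np.ndarray:
        """Absolute frame times in ps."""
        return self.origin_time + self.frame_interval * np.arange(self.n_frames)

    def coordinates(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """Stacked (F, N, 3) coordinate array, optionally sliced to atoms."""
        coords = np.stack([f.coordinates for f in self.frames])
        if indices is not None:
            coords = coords[:, np.asarray(indices, dtype=int), :]
        return coords

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


@dataclass(frozen=True)
class Selection:
    """Ordered atom-index subset, with the expression that produced it."""

    indices: tuple
    expression: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise HelixscopeError("Selection indices must be strictly increasing")
        if idx and idx[0] < 0:
            raise HelixscopeError("Selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)

    def validate(self, topology: Topology) -> None:
        if self.indices and self.indices[-1] >= len(topology):
            raise HelixscopeError(
                f"Selection index {self.indices[-1]} out of bounds "
                f"for topology of {len(topology)} atoms"
            )


@dataclass
class ScalarSeries:
    """A unit-tagged per-frame scalar time series."""

    time_ps: np.ndarray
    values: np.ndarray
    unit: str = ""
    name: str = ""

    def __post_init__(self):
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_ps.shape[0] != self.values.shape[0]:
            raise HelixscopeError("time and value lengths differ")

    @property
    def time_ns(self) -> np.ndarray:
        return self.time_ps / 1000.0

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self):
        import pandas as pd

        col = self.name or "value"
        if self.unit:
            col = f"{col}_{self.unit}"
        return pd.DataFrame({"time_ns": self.time_ns, col: self.values})


def trim_equilibration(traj: Trajectory, t_cut: float = 15000.0) -> Trajectory:
    """Drop the equilibration transient: frames with absolute time < ``t_cut`` ps.

    The default 15 ns reflects the usual relaxation time of a solvated
    protein–bilayer system after release of construction restraints.
    Raises if nothing would remain.
    """
    if t_cut < 0:
        raise HelixscopeError("t_cut must be non-negative")
    times = traj.times
    keep = np.nonzero(times >= t_cut)[0]
    if keep.size == 0:
        raise HelixscopeError(
            f"t_cut={t_cut} ps removes all {traj.n_frames} frames "
            f"(last frame at {times[-1]} ps)"
        )
    first = int(keep[0])
    if first == 0:
        return traj
    return Trajectory(
        traj.topology,
        traj.frames[first:],
        frame_interval=traj.frame_interval,
        origin_time=float(times[first]),
    )
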