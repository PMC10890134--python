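"""Helix-axis tilt and the three-point bending angle.

Tilt is the angle between the helix principal axis and the membrane
normal (+Z), folded into [0°, 90°] since a helix has no head/tail with
respect to the normal. The default axis estimator is the dominant
right-singular direction of the centered Cα trace; terminal-vector and
gyration-tensor estimators are available for sensitivity checks.

The bending angle θ at an anchor residue is the angle between the vector
from the anchor Cα to the Cα three residues upstream and the vector to
the Cα three residues downstream; θ = 180° means exactly collinear
(straight helix). Defaults (71, 74, 77) probe the bend near the C-end of
a transmembrane helix whose anchor is residue 74.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, HelixscopeError
from .model import ScalarSeries, Trajectory
from .selections import select

log = logging.getLogger(__name__)

__all__ = ["BendSpec", "helix_axis", "tilt_angle", "bending_angle",
           "tilt_series"]


@dataclass(frozen=True)
class BendSpec:
    """The three Cα sites of the bending angle: up, anchor, down."""

    up_residue: int = 71
    anchor_residue: int = 74
    down_residue: int = 77

    def __post_init__(self):
        ids = {self.up_residue, self.anchor_residue, self.down_residue}
        if len(ids) != 3:
            raise HelixscopeError("bend residues must be three distinct ids")


def helix_axis(ca_coords: np.ndarray, method: str = "svd") -> np.ndarray:
    """Unit axis of an ordered Cα trace, oriented N-terminus → C-terminus.

    ``method``: ``svd`` (principal axis of the centered point set,
    default), ``terminal`` (normalized last-minus-first vector), or
    ``gyration`` (dominant eigenvector of the gyration tensor — identical
    to svd up to round-off; kept as an independent formulation).
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
        raise HelixscopeError("helix_axis needs an N×3 array with N ≥ 4")
    centered = coords - coords.mean(axis=0)
    terminal = coords[-1] - coords[0]
    if method == "terminal":
        norm = np.linalg.norm(terminal)
        if norm == 0:
            raise DegenerateGeometryError("coincident terminal Cαs")
        return terminal / norm
    if method == "svd":
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[0] == 0 or s[1] / s[0] > 1.0 - 1e-9:
            raise DegenerateGeometryError("point set has no dominant axis")
        axis = vt[0]
    elif method == "gyration":
        gyr = centered.T @ centered / coords.shape[0]
        evals, evecs = np.linalg.eigh(gyr)
        if evals[-1] <= 0 or evals[-2] / evals[-1] > 1.0 - 1e-9:
            raise DegenerateGeometryError("point set has no dominant axis")
        axis = evecs[:, -1]
    else:
        raise HelixscopeError(f"unknown axis method {method!r}")
    if axis @ terminal < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def tilt_angle(axis: np.ndarray, normal: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, folded to [0, 90]) between an axis and the normal."""
    axis = np.asarray(axis, dtype=float)
    normal = np.asarray(normal, dtype=float)
    na, nn = np.linalg.norm(axis), np.linalg.norm(normal)
    if na == 0 or nn == 0:
        raise HelixscopeError("zero-length vector has no tilt")
    cos = abs(float(axis @ normal) / (na * nn))
    return float(np.degrees(np.arccos(min(cos, 1.0))))


def tilt_series(
    traj: Trajectory,
    ca_expression: str = "resid 57 to 82 and name CA",
    method: str = "svd",
) -> ScalarSeries:
    """Per-frame tilt of the selected Cα trace's axis vs the +Z normal."""
    sel = select(traj.topology, ca_expression)
    if len(sel) < 4:
        raise HelixscopeError(
            f"tilt needs ≥ 4 Cαs, selection {ca_expression!r} has {len(sel)}")
    idx = sel.array
    values = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        values[f] = tilt_angle(helix_axis(frame.coordinates[idx],
                                          method=method))
    return ScalarSeries(traj.times, values, unit="deg", name="tilt")


def _ca_index(traj: Trajectory, resid: int) -> int:
    sel = select(traj.topology, f"resid {resid} and name CA")
    if len(sel) != 1:
        raise HelixscopeError(
            f"expected exactly one CA for resid {resid}, found {len(sel)}")
    return sel.indices[0]


def bending_angle(traj: Trajectory, bend: BendSpec = BendSpec()) -> ScalarSeries:
    """Per-frame bending angle θ (degrees) at the anchor Cα.

    θ = arccos(R21·R23 / (|R21||R23|)) with R21 from the anchor to the up
    residue's Cα and R23 from the anchor to the down residue's Cα. Frames
    where either vector has zero length get NaN (logged) and are excluded
    from summaries.
    """
    i_up = _ca_index(traj, bend.up_residue)
    i_anchor = _ca_index(traj, bend.anchor_residue)
    i_down = _ca_index(traj, bend.down_residue)
    values = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        c = frame.coordinates
        r21 = c[i_up] - c[i_anchor]
        r23 = c[i_down] - c[i_anchor]
        n21, n23 = np.linalg.norm(r21), np.linalg.norm(r23)
        if n21 == 0 or n23 == 0:
            log.warning("frame %d: coincident bend points, θ undefined", f)
            values[f] = np.nan
            continue
        cos = np.clip(r21 @ r23 / (n21 * n23), -1.0, 1.0)
        values[f] = np.degrees(np.arccos(cos))
    return ScalarSeries(traj.times, values, unit="deg", name="theta")
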