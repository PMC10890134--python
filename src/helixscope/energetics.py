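"""Pairwise nonbonded energetics with CHARMM-style energy switching.

Lennard-Jones: V(r) = ε_ij [(R_ij/r)¹² − 2 (R_ij/r)⁶] with Lorentz–
Berthelot/CHARMM combining (ε_ij = √(ε_i ε_j), R_ij = Rmin/2_i +
Rmin/2_j), so V(R_ij) = −ε_ij exactly. Coulomb: k_C q_i q_j / (ε_r r)
with k_C = 332.0636 kcal·Å/(mol·e²). Both terms are tapered to zero by
the CHARMM energy-switching function between ``switch_on`` and
``cutoff`` (defaults 10 and 12 Å).

Electrostatics here is a real-space switched cutoff, not Ewald/PME: a
reciprocal-space sum has no meaningful decomposition into region–region
pair energies, which is precisely what these series report. Absolute
electrostatic energies therefore differ from PME-based totals.

Pair enumeration uses a k-d tree (periodic when a box is present and
minimum-imaging is requested); ``method="naive"`` runs the O(N²) double
loop, which the accelerated path must match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import HelixscopeError
from .model import Selection, Trajectory

__all__ = ["NonbondedOptions", "switching_factor", "pair_energy",
           "interaction_energy", "internal_energy"]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)


@dataclass(frozen=True)
class NonbondedOptions:
    cutoff: float = 12.0          # Å
    switch_on: float = 10.0       # Å
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric: float = 1.0
    use_minimum_image: bool = True

    def __post_init__(self):
        if not 0 < self.switch_on < self.cutoff:
            raise HelixscopeError("require 0 < switch_on < cutoff")
        if self.dielectric <= 0:
            raise HelixscopeError("dielectric must be positive")


def switching_factor(r, opts: NonbondedOptions = NonbondedOptions()):
    """CHARMM energy-switching factor sw(r) ∈ [0, 1].

    sw = 1 for r ≤ switch_on, 0 for r ≥ cutoff, and
    (c²−r²)²(c²+2r²−3s²)/(c²−s²)³ in between — C¹-continuous at both ends.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise HelixscopeError("distance must be non-negative")
    c2, s2, r2 = opts.cutoff ** 2, opts.switch_on ** 2, r ** 2
    mid = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * s2) / (c2 - s2) ** 3
    out = np.where(r2 <= s2, 1.0, np.where(r2 >= c2, 0.0, mid))
    return float(out) if out.ndim == 0 else out


def _pair_terms(eps_i, eps_j, rmin_i, rmin_j, q_i, q_j, r,
                opts: NonbondedOptions):
    """Switched (elec, vdw) for vectorized parameter/distance arrays."""
    sw = switching_factor(r, opts)
    eps = np.sqrt(eps_i * eps_j)
    rmin = rmin_i + rmin_j
    ratio6 = np.where(r > 0, (rmin / np.where(r > 0, r, 1.0)) ** 6, 0.0)
    vdw = sw * eps * (ratio6 ** 2 - 2.0 * ratio6)
    elec = sw * opts.coulomb_constant * q_i * q_j / (opts.dielectric * r)
    return elec, vdw


def pair_energy(atom_i, atom_j, r: float,
                opts: NonbondedOptions = NonbondedOptions()):
    """Switched (elec, vdw) energy in kcal/mol of one atom pair at r Å."""
    if r <= 0:
        raise HelixscopeError("pair distance must be positive")
    elec, vdw = _pair_terms(
        atom_i.lj_epsilon, atom_j.lj_epsilon,
        atom_i.lj_rmin_half, atom_j.lj_rmin_half,
        atom_i.charge, atom_j.charge, np.float64(r), opts)
    return float(elec), float(vdw)


def _min_image_disp(disp: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def _frame_pairs_kdtree(coords_a, coords_b, box, opts):
    """Index pairs (into a, b) within cutoff, k-d tree accelerated."""
    if box is not None:
        wrapped_a = np.mod(coords_a, box)
        wrapped_b = np.mod(coords_b, box)
        tree_a = cKDTree(wrapped_a, boxsize=box)
        tree_b = cKDTree(wrapped_b, boxsize=box)
    else:
        tree_a = cKDTree(coords_a)
        tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, r=opts.cutoff)
    ia = np.concatenate([[i] * len(js) for i, js in enumerate(pairs)]) \
        if any(pairs) else np.empty(0, dtype=int)
    ib = np.concatenate([js for js in pairs if js]).astype(int) \
        if any(pairs) else np.empty(0, dtype=int)
    return ia.astype(int), ib


def _frame_energy(coords_a, coords_b, params_a, params_b, box, opts,
                  exclude=None, method="kdtree"):
    eps_a, rmin_a, q_a = params_a
    eps_b, rmin_b, q_b = params_b
    if method == "naive":
        na, nb = coords_a.shape[0], coords_b.shape[0]
        elec = vdw = 0.0
        for i in range(na):
            disp = _min_image_disp(coords_b - coords_a[i],
                                   box if opts.use_minimum_image else None)
            r = np.sqrt((disp ** 2).sum(axis=1))
            for j in range(nb):
                if exclude is not None and exclude(i, j):
                    continue
                if r[j] <= 0 or r[j] > opts.cutoff:
                    continue
                e, v = _pair_terms(eps_a[i], eps_b[j], rmin_a[i], rmin_b[j],
                                   q_a[i], q_b[j], r[j], opts)
                elec += float(e)
                vdw += float(v)
        return elec, vdw
    ia, ib = _frame_pairs_kdtree(
        coords_a, coords_b, box if opts.use_minimum_image else None, opts)
    if exclude is not None and ia.size:
        keep = np.fromiter((not exclude(i, j) for i, j in zip(ia, ib)),
                           dtype=bool, count=ia.size)
        ia, ib = ia[keep], ib[keep]
    if ia.size == 0:
        return 0.0, 0.0
    disp = _min_image_disp(coords_b[ib] - coords_a[ia],
                           box if opts.use_minimum_image else None)
    r = np.sqrt((disp ** 2).sum(axis=1))
    ok = (r > 0) & (r <= opts.cutoff)
    ia, ib, r = ia[ok], ib[ok], r[ok]
    # sort pairs so that summation order matches the naive double loop
    order = np.lexsort((ib, ia))
    ia, ib, r = ia[order], ib[order], r[order]
    elec, vdw = _pair_terms(eps_a[ia], eps_b[ib], rmin_a[ia], rmin_b[ib],
                            q_a[ia], q_b[ib], r, opts)
    return float(elec.sum()), float(vdw.sum())


def _params(traj: Trajectory, idx: np.ndarray):
    top = traj.topology
    return top.lj_epsilons[idx], top.lj_rmin_halves[idx], top.charges[idx]


def interaction_energy(
    traj: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    opts: NonbondedOptions = NonbondedOptions(),
    method: str = "kdtree",
) -> pd.DataFrame:
    """Per-frame switched nonbonded energy between two disjoint selections.

    Returns a DataFrame with columns ``time_ns, elec, vdw, total``
    (kcal/mol). Minimum-image distances are used when the frame has a box
    and ``opts.use_minimum_image`` is set; otherwise plain distances with
    a logged warning when a box is absent but imaging was requested.
    """
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise HelixscopeError("selections must be non-empty")
    if set(sel_a.indices) & set(sel_b.indices):
        raise HelixscopeError("selections overlap; pair energy is ill-defined")
    ia, ib = sel_a.array, sel_b.array
    pa, pb = _params(traj, ia), _params(traj, ib)
    elec = np.empty(traj.n_frames)
    vdw = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        e, v = _frame_energy(frame.coordinates[ia], frame.coordinates[ib],
                             pa, pb, frame.box, opts, method=method)
        elec[f], vdw[f] = e, v
    return pd.DataFrame({
        "time_ns": traj.times / 1000.0,
        "elec": elec,
        "vdw": vdw,
        "total": elec + vdw,
    })


def internal_energy(
    traj: Trajectory,
    sel: Selection,
    opts: NonbondedOptions = NonbondedOptions(),
    min_residue_separation: int = 3,
    method: str = "kdtree",
) -> pd.DataFrame:
    """Per-frame switched nonbonded energy within one selection.

    Pairs of atoms in the same segment closer than
    ``min_residue_separation`` residues are excluded — the Cα-trace
    analogue of the usual 1-2/1-3 bonded exclusions.
    """
    if len(sel) < 2:
        raise HelixscopeError("internal energy needs at least two atoms")
    idx = sel.array
    top = traj.topology
    resids = top.residue_ids[idx]
    segids = top.segment_ids[idx]
    params = _params(traj, idx)

    def exclude(i, j):
        if i >= j:  # count each unordered pair once; drop self
            return True
        return (segids[i] == segids[j]
                and abs(int(resids[i]) - int(resids[j])) < min_residue_separation)

    elec = np.empty(traj.n_frames)
    vdw = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        coords = frame.coordinates[idx]
        e, v = _frame_energy(coords, coords, params, params, frame.box, opts,
                             exclude=exclude, method=method)
        elec[f], vdw[f] = e, v
    return pd.DataFrame({
        "time_ns": traj.times / 1000.0,
        "elec": elec,
        "vdw": vdw,
        "total": elec + vdw,
    })
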