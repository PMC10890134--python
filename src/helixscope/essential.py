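"""Essential dynamics: PCA of an aligned Cα ensemble, dynamic
cross-correlation maps, per-mode b-factors, and NMD export.

The ensemble is built by superposing every frame's selection onto a
reference frame (removing rigid-body motion), flattening the selected
coordinates to rows of length 3M. PCA diagonalizes the sample covariance
(divisor F−1) of displacements from the ensemble mean. The DCCM is
computed from the covariance filtered through the top k modes (k = 2 by
default): C_ij = Σ_m λ_m v_mi·v_mj normalized by the filtered per-atom
mean-square fluctuations, so +1 means perfectly same-direction motion
and −1 perfectly opposed motion within that essential subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import HelixscopeError
from .model import Selection, Trajectory
from .superposition import kabsch_fit

log = logging.getLogger(__name__)

__all__ = ["ModeSet", "CrossCorrelationMatrix", "build_ensemble", "pca",
           "dccm", "mode_bfactors", "write_nmd", "read_nmd"]


@dataclass
class ModeSet:
    """Eigenpairs of a Cα displacement covariance.

    ``eigenvalues`` (Å², non-increasing), ``eigenvectors`` (rows,
    orthonormal, length 3M), ``variance_fraction`` summing to 1,
    ``reference_coords`` (M×3) the ensemble mean, and the selection the
    ensemble was built from (may carry resids/names for export).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fraction: np.ndarray
    reference_coords: np.ndarray
    resids: np.ndarray
    atom_names: np.ndarray

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < -1e-10) or np.any(np.diff(ev) > 1e-10):
            raise HelixscopeError("eigenvalues must be non-negative, descending")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(len(ev)), atol=1e-8):
            raise HelixscopeError("eigenvectors must be orthonormal")
        if abs(self.variance_fraction.sum() - 1.0) > 1e-10:
            raise HelixscopeError("variance fractions must sum to 1")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_atoms(self) -> int:
        return self.reference_coords.shape[0]

    def atom_blocks(self, m: int) -> np.ndarray:
        """Mode m reshaped to per-atom 3-vectors (M×3)."""
        return self.eigenvectors[m].reshape(-1, 3)


@dataclass
class CrossCorrelationMatrix:
    """Residue-pair cross-correlations in [−1, 1], unit diagonal."""

    values: np.ndarray
    mode_count: int
    resids: np.ndarray

    def __post_init__(self):
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise HelixscopeError("DCCM must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise HelixscopeError("DCCM entries must lie in [−1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.resids,
                            columns=self.resids)


def build_ensemble(
    traj: Trajectory,
    sel: Selection,
    ref_frame: int = 0,
) -> np.ndarray:
    """Aligned, flattened coordinate matrix (frames × 3M) for ``sel``."""
    if len(sel) == 0:
        raise HelixscopeError("selection is empty")
    idx = sel.array
    ref = traj.frames[ref_frame].coordinates[idx]
    rows = np.empty((traj.n_frames, idx.size * 3))
    for f, frame in enumerate(traj.frames):
        fit = kabsch_fit(frame.coordinates[idx], ref)
        rows[f] = fit.transform(frame.coordinates[idx]).ravel()
    return rows


def pca(ensemble: np.ndarray, traj: Trajectory = None, sel: Selection = None
        ) -> ModeSet:
    """Eigendecomposition of the ensemble displacement covariance.

    Equivalent to an SVD of the centered ensemble with λ_m = s_m²/(F−1).
    ``traj``/``sel`` (optional) only supply residue ids and atom names for
    export; anonymous ensembles get sequential ids.
    """
    ensemble = np.asarray(ensemble, dtype=float)
    if ensemble.ndim != 2 or ensemble.shape[0] < 2:
        raise HelixscopeError("PCA needs a 2D ensemble with ≥ 2 frames")
    nframes, ncoord = ensemble.shape
    mean = ensemble.mean(axis=0)
    centered = ensemble - mean
    if not np.any(np.abs(centered) > 1e-12):
        raise HelixscopeError("ensemble has no variance (rank 0)")
    # SVD route: numerically stabler than forming the 3M×3M covariance
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / (nframes - 1)
    keep = min(len(eigenvalues), ncoord)
    eigenvalues = eigenvalues[:keep]
    eigenvectors = vt[:keep]
    total = eigenvalues.sum()
    fractions = eigenvalues / total
    # renormalize exactly (guards the sums-to-1 invariant against roundoff)
    fractions = fractions / fractions.sum()
    m = ncoord // 3
    if traj is not None and sel is not None:
        resids = traj.topology.residue_ids[sel.array]
        names = traj.topology.atom_names[sel.array]
    else:
        resids = np.arange(1, m + 1)
        names = np.array(["CA"] * m, dtype=object)
    return ModeSet(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        variance_fraction=fractions,
        reference_coords=mean.reshape(m, 3),
        resids=resids,
        atom_names=names,
    )


def dccm(modes: ModeSet, k: int = 2) -> CrossCorrelationMatrix:
    """Dynamic cross-correlation matrix from the top ``k`` modes.

    Normalization uses the k-mode-filtered covariance itself, so the
    matrix describes correlations *within* the retained essential
    subspace. Atoms with no displacement in that subspace get zero
    off-diagonal entries (with a warning) and a unit diagonal.
    """
    if not 1 <= k <= modes.n_modes:
        raise HelixscopeError(f"k={k} out of range (1..{modes.n_modes})")
    m = modes.n_atoms
    cov = np.zeros((m, m))
    for mode in range(k):
        lam = modes.eigenvalues[mode]
        blocks = modes.atom_blocks(mode)
        cov += lam * (blocks @ blocks.T)
    diag = np.diag(cov).copy()
    dead = diag <= 1e-14
    if np.any(dead):
        log.warning("%d atom(s) have no displacement in the top-%d subspace; "
                    "their correlations are set to 0", int(dead.sum()), k)
        diag[dead] = 1.0
    norm = np.sqrt(np.outer(diag, diag))
    values = cov / norm
    values[dead, :] = 0.0
    values[:, dead] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(0.5 * (values + values.T), -1.0, 1.0)
    return CrossCorrelationMatrix(values=values, mode_count=k,
                                  resids=modes.resids)


def mode_bfactors(modes: ModeSet, m: int = 0,
                  crystallographic: bool = False) -> pd.Series:
    """Per-residue mean-square fluctuation (Å²) contributed by mode ``m``.

    b_i = λ_m |v_m,i|²; with ``crystallographic`` the 8π²/3 Debye–Waller
    scaling is applied. Sums over residues to λ_m (unit-norm modes).
    """
    if not 0 <= m < modes.n_modes:
        raise HelixscopeError(f"mode index {m} out of range")
    blocks = modes.atom_blocks(m)
    b = modes.eigenvalues[m] * (blocks ** 2).sum(axis=1)
    if crystallographic:
        b = b * (8.0 * np.pi ** 2 / 3.0)
    out = pd.Series(b, index=modes.resids, name="bfactor_A2")
    out.index.name = "resid"
    return out


def write_nmd(modes: ModeSet, path, name: str = "helixscope",
              n_modes: Optional[int] = None) -> None:
    """Write modes in NMD plain-text format for normal-mode visualizers.

    Each ``mode`` line carries the mode number, sqrt(λ) as the scale, and
    the unit eigenvector components. ``n_modes`` limits how many modes
    are exported (default: all).
    """
    if modes.n_modes == 0:
        raise HelixscopeError("cannot write an empty ModeSet")
    n_out = modes.n_modes if n_modes is None else min(n_modes, modes.n_modes)
    with open(path, "w") as fh:
        fh.write(f"name {name}\n")
        fh.write("atomnames " + " ".join(modes.atom_names) + "\n")
        fh.write("resids " + " ".join(str(r) for r in modes.resids) + "\n")
        fh.write("coordinates "
                 + " ".join(f"{x:.6f}" for x in modes.reference_coords.ravel())
                 + "\n")
        for m in range(n_out):
            scale = np.sqrt(max(modes.eigenvalues[m], 0.0))
            comps = " ".join(f"{x:.9f}" for x in modes.eigenvectors[m])
            fh.write(f"mode {m + 1} {scale:.9f} {comps}\n")
    log.info("write_nmd %s: %d modes, %d atoms", path, modes.n_modes,
             modes.n_atoms)


def read_nmd(path) -> ModeSet:
    """Read back an NMD file written by :func:`write_nmd`."""
    names = resids = coords = None
    eigenvalues, eigenvectors = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0]
            if key == "atomnames":
                names = np.array(parts[1:], dtype=object)
            elif key == "resids":
                resids = np.array(parts[1:], dtype=int)
            elif key == "coordinates":
                coords = np.array(parts[1:], dtype=float).reshape(-1, 3)
            elif key == "mode":
                scale = float(parts[2])
                vec = np.array(parts[3:], dtype=float)
                eigenvalues.append(scale ** 2)
                eigenvectors.append(vec)
    if coords is None or not eigenvalues:
        raise HelixscopeError(f"{path}: not a complete NMD file")
    eigenvalues = np.array(eigenvalues)
    eigenvectors = np.array(eigenvectors)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.ones_like(eigenvalues)
    fractions = fractions / fractions.sum()
    return ModeSet(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        variance_fraction=fractions,
        reference_coords=coords,
        resids=resids if resids is not None
        else np.arange(1, coords.shape[0] + 1),
        atom_names=names if names is not None
        else np.array(["CA"] * coords.shape[0], dtype=object),
    )
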