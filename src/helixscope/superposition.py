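"""Optimal rigid-body superposition (Kabsch) and RMSD/RMSF statistics.

The fit minimizes the (optionally weighted) RMSD between two point sets
over proper rotations and translations. RMSD series and per-residue RMSF
follow the usual MD convention: every frame is first superposed onto a
reference frame using a fit selection, then the deviation/fluctuation is
measured on a (possibly different) measurement selection. By default the
two selections coincide, so each region is aligned on itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, EmptySelectionError, HelixscopeError
from .model import ScalarSeries, Selection, Trajectory

__all__ = ["FitResult", "kabsch_fit", "apply_fit", "rmsd_series", "rmsf"]


@dataclass
class FitResult:
    """A proper rigid transform ``x -> rotation @ x + translation`` and the
    weighted RMSD it achieves."""

    rotation: np.ndarray      # 3×3, det = +1
    translation: np.ndarray   # Å
    rmsd: float               # Å

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_points(x, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise HelixscopeError(f"{label} must be an N×3 array, got {x.shape}")
    return x


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> FitResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both point sets are centered at their (weighted) centroid; the optimal
    proper rotation comes from the SVD of the weighted covariance with the
    reflection corrected, so ``det(rotation) = +1`` always. Weights default
    to uniform; pass per-atom masses for a mass-weighted fit.
    """
    mobile = _as_points(mobile, "mobile")
    reference = _as_points(reference, "reference")
    if mobile.shape != reference.shape:
        raise HelixscopeError(
            f"point counts differ: {mobile.shape[0]} vs {reference.shape[0]}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need ≥ 3 points to fit, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise HelixscopeError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(0) / wsum
    ref_c = (w[:, None] * reference).sum(0) / wsum
    mob0 = mobile - mob_c
    ref0 = reference - ref_c
    # collinear sets leave the rotation about the common axis undetermined
    sv = np.linalg.svd(mob0, compute_uv=False)
    if sv[1] < 1e-9 * max(1.0, sv[0]):
        raise DegenerateGeometryError("mobile point set is (near-)collinear")
    rot, _ = Rotation.align_vectors(ref0, mob0, weights=w)
    rotation = rot.as_matrix()
    fitted = mob0 @ rotation.T
    msd = float((w * ((fitted - ref0) ** 2).sum(axis=1)).sum() / wsum)
    return FitResult(
        rotation=rotation,
        translation=ref_c - rotation @ mob_c,
        rmsd=float(np.sqrt(max(msd, 0.0))),
    )


def apply_fit(fit: FitResult, coords: np.ndarray) -> np.ndarray:
    return fit.transform(np.asarray(coords, dtype=float))


def _check_selection(sel: Selection, label: str) -> np.ndarray:
    if len(sel) == 0:
        raise EmptySelectionError(f"{label} is empty")
    return sel.array


def rmsd_series(
    traj: Trajectory,
    fit_sel: Selection,
    measure_sel: Optional[Selection] = None,
    ref_frame: int = 0,
    weights: Optional[np.ndarray] = None,
) -> ScalarSeries:
    """Per-frame RMSD of ``measure_sel`` after superposing ``fit_sel``.

    ``measure_sel`` defaults to ``fit_sel`` (each region aligned on
    itself). The value at ``ref_frame`` is identically zero.
    """
    if measure_sel is None:
        measure_sel = fit_sel
    fit_idx = _check_selection(fit_sel, "fit selection")
    mea_idx = _check_selection(measure_sel, "measurement selection")
    if not 0 <= ref_frame < traj.n_frames:
        raise HelixscopeError(f"ref_frame {ref_frame} out of range")
    ref_fit = traj.frames[ref_frame].coordinates[fit_idx]
    ref_mea = traj.frames[ref_frame].coordinates[mea_idx]
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        fit = kabsch_fit(frame.coordinates[fit_idx], ref_fit, weights=weights)
        moved = fit.transform(frame.coordinates[mea_idx])
        out[f] = np.sqrt(((moved - ref_mea) ** 2).sum(axis=1).mean())
    return ScalarSeries(traj.times, out, unit="A", name="rmsd")


def rmsf(
    traj: Trajectory,
    sel: Selection,
    fit_sel: Optional[Selection] = None,
    ref_frame: int = 0,
    align: bool = True,
) -> pd.Series:
    """Per-residue RMSF of ``sel`` about the ensemble mean after alignment.

    All frames are superposed on ``fit_sel`` (default: ``sel``) to
    ``ref_frame``; then RMSF_i = sqrt(mean_f |r_i(f) − ⟨r_i⟩|²). Indexed by
    residue id — intended for one-Cα-per-residue selections; with several
    atoms per residue the per-residue value is the RMS over its atoms.
    Set ``align=False`` to measure raw (lab-frame) fluctuations.
    """
    idx = _check_selection(sel, "selection")
    if traj.n_frames < 2:
        raise HelixscopeError("RMSF is undefined for a single-frame trajectory")
    if fit_sel is None:
        fit_sel = sel
    coords = np.empty((traj.n_frames, idx.size, 3))
    if align:
        fit_idx = _check_selection(fit_sel, "fit selection")
        ref_fit = traj.frames[ref_frame].coordinates[fit_idx]
        for f, frame in enumerate(traj.frames):
            fit = kabsch_fit(frame.coordinates[fit_idx], ref_fit)
            coords[f] = fit.transform(frame.coordinates[idx])
    else:
        for f, frame in enumerate(traj.frames):
            coords[f] = frame.coordinates[idx]
    mean = coords.mean(axis=0)
    msf = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom, Å²
    resids = traj.topology.residue_ids[idx]
    per_res = pd.Series(msf).groupby(resids).mean()
    out = np.sqrt(per_res)
    out.index.name = "resid"
    out.name = "rmsf_A"
    return out
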