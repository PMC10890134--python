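"""Bilayer geometry along the membrane normal (+Z by convention).

The bilayer width is measured the standard way for flat bilayers: as the
distance between the two peaks of the phosphate mass-density profile
along Z, one peak per leaflet. Peak positions are refined by parabolic
interpolation through the three bins around each argmax so the estimate
is not quantized to the bin grid. Z-distances are signed distances
between mass-weighted centers of mass, with the membrane selection
defining Z = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import EmptySelectionError, HelixscopeError
from .model import ScalarSeries, Selection, Trajectory

log = logging.getLogger(__name__)

__all__ = ["DensityProfile", "density_profile", "bilayer_width", "z_distance"]


@dataclass
class DensityProfile:
    """1D mass density along Z: amu per Å per frame, uniform bins."""

    bin_centers: np.ndarray
    density: np.ndarray
    bin_width: float

    def __post_init__(self):
        if np.any(self.density < 0):
            raise HelixscopeError("density must be non-negative")

    @property
    def total_mass(self) -> float:
        """Integral of the profile (amu, per frame)."""
        return float(self.density.sum() * self.bin_width)


def _sel_indices(sel: Selection, label: str) -> np.ndarray:
    if len(sel) == 0:
        raise EmptySelectionError(f"{label} is empty")
    return sel.array


def _mass_com_z(z: np.ndarray, masses: np.ndarray) -> float:
    if masses.sum() <= 0:  # parameters not yet assigned: fall back to geometric
        return float(z.mean())
    return float((z * masses).sum() / masses.sum())


def density_profile(
    traj: Trajectory,
    sel: Selection,
    bin_width: float = 1.0,
    frame_range: Optional[Tuple[int, int]] = None,
) -> DensityProfile:
    """Mass-weighted Z histogram of ``sel``, averaged over frames.

    Z is measured relative to the selection's own mass-weighted center of
    mass in each frame, so the profile is centered on the membrane midplane
    when ``sel`` covers both leaflets.
    """
    idx = _sel_indices(sel, "selection")
    if bin_width <= 0:
        raise HelixscopeError("bin_width must be positive")
    lo, hi = frame_range if frame_range is not None else (0, traj.n_frames)
    frames = traj.frames[lo:hi]
    if not frames:
        raise HelixscopeError("frame_range selects no frames")
    masses = traj.topology.masses[idx]
    zs = []
    for frame in frames:
        z = frame.coordinates[idx, 2]
        zs.append(z - _mass_com_z(z, masses))
    zall = np.concatenate(zs)
    zmin, zmax = zall.min(), zall.max()
    # bin centers sit on multiples of bin_width, symmetric about the
    # membrane COM (z = 0): leaflet peaks at ±w/2 then fall on centers,
    # and the grid is invariant under z → −z
    kmin = int(np.floor(zmin / bin_width + 0.5))
    kmax = int(np.floor(zmax / bin_width + 0.5))
    edges = (np.arange(kmin, kmax + 2) - 0.5) * bin_width
    if edges[0] > zmin:
        edges = np.concatenate([[edges[0] - bin_width], edges])
    if edges[-1] < zmax:
        edges = np.concatenate([edges, [edges[-1] + bin_width]])
    wts = np.tile(masses, len(frames))
    hist, _ = np.histogram(zall, bins=edges, weights=wts)
    density = hist / (bin_width * len(frames))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(bin_centers=centers, density=density,
                          bin_width=bin_width)


def _refined_peak(profile: DensityProfile, mask: np.ndarray, side: str,
                  tie_counter: Optional[list] = None) -> float:
    dens = np.where(mask, profile.density, -np.inf)
    if not np.any(np.isfinite(dens) & (dens > 0)):
        raise HelixscopeError(f"no density in the {side} half-space")
    peak_val = dens.max()
    ties = np.nonzero(dens == peak_val)[0]
    if ties.size > 1:
        if tie_counter is None:
            log.warning("multiple equal density maxima on %s side; "
                        "taking the outermost", side)
        else:
            tie_counter.append(side)
    i = int(max(ties, key=lambda k: abs(profile.bin_centers[k])))
    # parabolic refinement through (i-1, i, i+1) where available
    if 0 < i < len(dens) - 1 and np.isfinite(profile.density[i - 1]) \
            and np.isfinite(profile.density[i + 1]):
        y0, y1, y2 = profile.density[i - 1: i + 2]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return float(profile.bin_centers[i] + shift * profile.bin_width)


def width_from_profile(profile: DensityProfile,
                       tie_counter: Optional[list] = None) -> float:
    """Peak-to-peak distance of a two-leaflet profile (Å)."""
    z = profile.bin_centers
    return (_refined_peak(profile, z > 0, "upper", tie_counter)
            - _refined_peak(profile, z < 0, "lower", tie_counter))


def bilayer_width(
    traj: Trajectory,
    phosphate_sel: Selection,
    bin_width: float = 1.0,
    per_frame: bool = True,
    window: int = 1,
) -> ScalarSeries:
    """Bilayer width time series from phosphate density-profile peaks.

    With ``per_frame`` (default), each frame (or each ``window``-frame
    block) contributes one width from its own profile; otherwise a single
    whole-trajectory profile yields one value replicated over frames.
    """
    _sel_indices(phosphate_sel, "phosphate selection")
    if not per_frame:
        w = width_from_profile(density_profile(traj, phosphate_sel, bin_width))
        values = np.full(traj.n_frames, w)
        return ScalarSeries(traj.times, values, unit="A", name="width")
    if window < 1:
        raise HelixscopeError("window must be ≥ 1")
    values = np.empty(traj.n_frames)
    ties: list = []
    for start in range(0, traj.n_frames, window):
        stop = min(start + window, traj.n_frames)
        prof = density_profile(traj, phosphate_sel, bin_width, (start, stop))
        values[start:stop] = width_from_profile(prof, tie_counter=ties)
    if ties:
        log.warning("equal density maxima in %d window(s); outermost bin "
                    "taken each time", len(ties))
    return ScalarSeries(traj.times, values, unit="A", name="width")


def z_distance(
    traj: Trajectory,
    sel: Selection,
    membrane_sel: Selection,
) -> ScalarSeries:
    """Signed Z of ``sel``'s mass-weighted COM relative to the membrane COM."""
    idx = _sel_indices(sel, "selection")
    mem = _sel_indices(membrane_sel, "membrane selection")
    m_sel = traj.topology.masses[idx]
    m_mem = traj.topology.masses[mem]
    values = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        values[f] = (_mass_com_z(frame.coordinates[idx, 2], m_sel)
                     - _mass_com_z(frame.coordinates[mem, 2], m_mem))
    return ScalarSeries(traj.times, values, unit="A", name="zdist")
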