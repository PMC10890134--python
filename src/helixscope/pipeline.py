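"""Config-driven orchestration of the full analysis battery.

Given a topology (PDB), a trajectory (DCD or multi-model PDB) and a
parameter table, ``run_analysis`` trims the equilibration transient and
runs, per configured region: RMSD and RMSF (each region aligned on
itself), bilayer width, Z-distances, TMD tilt, bending angle, essential
dynamics (spectrum, DCCM, b-factors, NMD export), protein–lipid
interaction and protein internal energies, plus histograms and the
tilt-vs-Z 2D density. Every table is CSV; a JSON manifest records the
config hash, versions, seed and per-stage status. Stage failures are
recorded and independent stages continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dcdio import read_dcd
from .energetics import NonbondedOptions, interaction_energy, internal_energy
from .errors import ConfigError, HelixscopeError
from .essential import build_ensemble, dccm, mode_bfactors, pca, write_nmd
from .helix import BendSpec, bending_angle, tilt_series
from .membrane import bilayer_width, z_distance
from .model import ScalarSeries, Trajectory, trim_equilibration
from .parameters import assign_parameters
from .pdbio import read_pdb
from .selections import select
from .superposition import rmsd_series, rmsf

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_analysis", "histogram", "density2d",
           "ProbabilityGrid"]

STAGES = ("rmsd", "rmsf", "width", "zdist", "tilt", "bend", "pca", "energy",
          "histograms", "density2d")

DEFAULT_REGIONS = {
    "tmd": "resid 57 to 82 and name CA",
    "n_helix": "resid 10 to 30 and name CA",
    "c_helix": "resid 90 to 95 and name CA",
    "n_terminus": "resid 1 to 56 and name CA",
    "c_terminus": "resid 83 to 103 and name CA",
}


@dataclass
class AnalysisConfig:
    topology: str = "system.pdb"
    trajectory: Optional[str] = "traj.dcd"
    parameters: Optional[str] = "params.csv"
    outdir: str = "analysis"
    regions: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    probe_residues: Tuple[int, ...] = (57, 69, 82)
    membrane_expression: str = "segid MEMB and name P"
    trim_ns: float = 15.0
    frame_interval_ps: Optional[float] = None
    stages: Tuple[str, ...] = STAGES
    bend_up: int = 71
    bend_anchor: int = 74
    bend_down: int = 77
    profile_bin_A: float = 1.0
    width_hist_bin: float = 0.047
    energy_hist_bin: float = 9.4
    internal_hist_bin: float = 8.2
    density2d_bins: int = 50
    density2d_smooth: float = 0.0
    pca_modes_exported: int = 10
    seed: int = 0

    def __post_init__(self):
        for stage in self.stages:
            if stage not in STAGES:
                raise ConfigError(f"unknown stage {stage!r}; "
                                  f"known: {', '.join(STAGES)}")
        self.stages = tuple(self.stages)
        self.probe_residues = tuple(int(r) for r in self.probe_residues)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self) -> str:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        return yaml.safe_dump(data, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def histogram(values, bin_width: float) -> Tuple[np.ndarray, np.ndarray]:
    """Probability histogram with edges anchored at the series minimum.

    Returns (bin_centers, probability); probabilities sum to 1.
    """
    if isinstance(values, ScalarSeries):
        values = values.values
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise HelixscopeError("cannot histogram an empty series")
    if bin_width <= 0:
        raise HelixscopeError("bin_width must be positive")
    lo, hi = values.min(), values.max()
    nbins = max(1, int(np.floor((hi - lo) / bin_width)) + 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, prob


@dataclass
class ProbabilityGrid:
    """2D probability density on a uniform grid; integral = 1."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    density: np.ndarray   # shape (nx, ny)
    dx: float
    dy: float

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.dx * self.dy)

    def marginal_x(self) -> np.ndarray:
        """Probability mass per x-bin (sums to 1)."""
        return self.density.sum(axis=1) * self.dx * self.dy


def density2d(x, y, bins: int = 50, smooth: float = 0.0) -> ProbabilityGrid:
    """Normalized 2D histogram of two equal-length series.

    ``smooth`` > 0 applies a Gaussian filter of that bandwidth (in bins)
    and renormalizes. The grid integrates to 1.
    """
    if isinstance(x, ScalarSeries):
        x = x.values
    if isinstance(y, ScalarSeries):
        y = y.values
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise HelixscopeError("x and y series lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise HelixscopeError("no finite points to grid")
    pad = 1e-9
    hist, xe, ye = np.histogram2d(
        x, y, bins=bins,
        range=[[x.min() - pad, x.max() + pad], [y.min() - pad, y.max() + pad]])
    dx = xe[1] - xe[0]
    dy = ye[1] - ye[0]
    if smooth > 0:
        from scipy.ndimage import gaussian_filter

        hist = gaussian_filter(hist, sigma=smooth, mode="constant")
    total = hist.sum() * dx * dy
    density = hist / total
    return ProbabilityGrid(
        x_centers=0.5 * (xe[:-1] + xe[1:]),
        y_centers=0.5 * (ye[:-1] + ye[1:]),
        density=density, dx=float(dx), dy=float(dy))


def _load_trajectory(config: AnalysisConfig) -> Trajectory:
    top_traj = read_pdb(config.topology)
    topology = top_traj.topology
    if config.parameters:
        topology = assign_parameters(topology, config.parameters)
    if config.trajectory is None:
        traj = Trajectory(topology, top_traj.frames,
                          frame_interval=config.frame_interval_ps or 1.0)
    elif str(config.trajectory).endswith(".pdb"):
        pdb = read_pdb(config.trajectory,
                       frame_interval=config.frame_interval_ps or 1.0)
        traj = Trajectory(topology, pdb.frames,
                          frame_interval=pdb.frame_interval)
    else:
        traj = read_dcd(config.trajectory, topology,
                        frame_interval=config.frame_interval_ps)
    return traj


def _write_series_csv(series: ScalarSeries, path: Path, column: str) -> None:
    df = pd.DataFrame({"time_ns": series.time_ns, column: series.values})
    df.to_csv(path, index=False, float_format="%.6f")


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute every configured stage; return the manifest dict.

    The manifest lists each stage as ``ok`` or ``failed: <reason>`` and is
    also written to ``<outdir>/manifest.json``. Output files are pure
    functions of the inputs and config, so re-running an identical config
    on identical inputs reproduces the bundle byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    traj = _load_trajectory(config)
    traj = trim_equilibration(traj, t_cut=config.trim_ns * 1000.0)
    top = traj.topology

    regions = {}
    for name, expr in config.regions.items():
        sel = select(top, expr)
        log.info("region %-12s %-35r %d atoms", name, expr, len(sel))
        regions[name] = sel
    membrane_sel = select(top, config.membrane_expression)
    tmd_expr = config.regions.get("tmd", DEFAULT_REGIONS["tmd"])

    status: Dict[str, str] = {}
    series_store: Dict[str, ScalarSeries] = {}

    def run_stage(stage: str, fn) -> None:
        if stage not in config.stages:
            status[stage] = "skipped"
            return
        t = time.time()
        try:
            fn()
            status[stage] = "ok"
            log.info("stage %-10s ok (%.2f s)", stage, time.time() - t)
        except Exception as exc:  # keep independent stages running
            status[stage] = f"failed: {exc}"
            log.error("stage %-10s failed: %s", stage, exc)

    def stage_rmsd():
        for name, sel in regions.items():
            series = rmsd_series(traj, sel)
            _write_series_csv(series, outdir / f"rmsd_{name}.csv", "rmsd_A")

    def stage_rmsf():
        for name, sel in regions.items():
            prof = rmsf(traj, sel)
            prof.to_csv(outdir / f"rmsf_{name}.csv", float_format="%.6f")

    def stage_width():
        series = bilayer_width(traj, membrane_sel,
                               bin_width=config.profile_bin_A)
        series_store["width"] = series
        _write_series_csv(series, outdir / "width.csv", "width_A")

    def stage_zdist():
        for resid in config.probe_residues:
            sel = select(top, f"resid {resid} and name CA")
            series = z_distance(traj, sel, membrane_sel)
            series_store[f"zdist_{resid}"] = series
            _write_series_csv(series, outdir / f"zdist_res{resid}.csv",
                              "zdist_A")
        tmd_series = z_distance(traj, regions["tmd"], membrane_sel) \
            if "tmd" in regions else None
        if tmd_series is not None:
            series_store["zdist_tmd"] = tmd_series
            _write_series_csv(tmd_series, outdir / "zdist_tmd.csv", "zdist_A")

    def stage_tilt():
        series = tilt_series(traj, tmd_expr)
        series_store["tilt"] = series
        _write_series_csv(series, outdir / "tilt.csv", "tilt_deg")

    def stage_bend():
        series = bending_angle(traj, BendSpec(config.bend_up,
                                              config.bend_anchor,
                                              config.bend_down))
        series_store["bend"] = series
        df = pd.DataFrame({
            "time_ns": series.time_ns,
            "theta_deg": series.values,
            "deviation_deg": 180.0 - series.values,
        })
        df.to_csv(outdir / "bend.csv", index=False, float_format="%.6f")

    def stage_pca():
        sel = regions["tmd"]
        ensemble = build_ensemble(traj, sel)
        modes = pca(ensemble, traj, sel)
        spectrum = pd.DataFrame({
            "mode": np.arange(1, modes.n_modes + 1),
            "lambda_A2": modes.eigenvalues,
            "fraction": modes.variance_fraction,
        })
        spectrum.to_csv(outdir / "pca_spectrum.csv", index=False,
                        float_format="%.8f")
        matrix = dccm(modes, k=min(2, modes.n_modes))
        matrix.to_dataframe().to_csv(outdir / "dccm.csv",
                                     float_format="%.6f")
        for m in range(min(2, modes.n_modes)):
            mode_bfactors(modes, m).to_csv(outdir / f"bfactors_pc{m + 1}.csv",
                                           float_format="%.6f")
        write_nmd(modes, outdir / "modes.nmd",
                  n_modes=min(config.pca_modes_exported, modes.n_modes))

    def stage_energy():
        if len(membrane_sel) == 0:
            raise HelixscopeError("membrane selection is empty")
        opts = NonbondedOptions()
        protein_sel = select(top, "segid PROT")
        for name, sel in regions.items():
            df = interaction_energy(traj, sel, membrane_sel, opts)
            df.to_csv(outdir / f"energy_{name}_lipid.csv", index=False,
                      float_format="%.6f")
            series_store[f"energy_{name}"] = ScalarSeries(
                traj.times, df["total"].to_numpy(), unit="kcal/mol",
                name=f"energy_{name}")
        internal = internal_energy(traj, protein_sel, opts)
        internal.to_csv(outdir / "energy_internal.csv", index=False,
                        float_format="%.6f")
        series_store["energy_internal"] = ScalarSeries(
            traj.times, internal["total"].to_numpy(), unit="kcal/mol",
            name="energy_internal")

    def stage_histograms():
        specs = []
        if "width" in series_store:
            specs.append(("width", series_store["width"],
                          config.width_hist_bin))
        if "bend" in series_store:
            specs.append(("bend", series_store["bend"], 1.0))
        for key, series in series_store.items():
            if key.startswith("energy_") and key != "energy_internal":
                specs.append((key, series, config.energy_hist_bin))
        if "energy_internal" in series_store:
            specs.append(("energy_internal", series_store["energy_internal"],
                          config.internal_hist_bin))
        if not specs:
            raise HelixscopeError(
                "no upstream series available to histogram (enable width/"
                "bend/energy stages)")
        for name, series, bw in specs:
            values = series.values[np.isfinite(series.values)]
            # nonbonded energies on excluded-volume-free traces are heavy-
            # tailed (steric-clash spikes); with a fixed bin width a single
            # outlier would dictate millions of empty bins, so restrict to a
            # robust (IQR-based) range and drop the flagged outliers
            span = values.max() - values.min()
            if span / bw > 1e5:
                q25, q75 = np.percentile(values, [25, 75])
                iqr = max(q75 - q25, bw)
                lo, hi = q25 - 5 * iqr, q75 + 5 * iqr
                clipped = values[(values >= lo) & (values <= hi)]
                log.warning("hist_%s: raw range %.3g spans >1e5 bins of %.3g;"
                            " using robust range [%.4g, %.4g] "
                            "(%d of %d values kept)",
                            name, span, bw, lo, hi, clipped.size, values.size)
                values = clipped
            centers, prob = histogram(values, bw)
            pd.DataFrame({"bin_center": centers, "probability": prob}).to_csv(
                outdir / f"hist_{name}.csv", index=False, float_format="%.8f")

    def stage_density2d():
        if "tilt" not in series_store or "zdist_tmd" not in series_store:
            raise HelixscopeError("density2d needs the tilt and zdist stages")
        grid = density2d(series_store["tilt"], series_store["zdist_tmd"],
                         bins=config.density2d_bins,
                         smooth=config.density2d_smooth)
        df = pd.DataFrame(grid.density, index=grid.x_centers,
                          columns=grid.y_centers)
        df.to_csv(outdir / "tilt_vs_z_density.csv", float_format="%.8f")

    run_stage("rmsd", stage_rmsd)
    run_stage("rmsf", stage_rmsf)
    run_stage("width", stage_width)
    run_stage("zdist", stage_zdist)
    run_stage("tilt", stage_tilt)
    run_stage("bend", stage_bend)
    run_stage("pca", stage_pca)
    run_stage("energy", stage_energy)
    run_stage("histograms", stage_histograms)
    run_stage("density2d", stage_density2d)

    manifest = {
        "config_hash": config.config_hash,
        "helixscope_version": __version__,
        "seed": config.seed,
        "n_frames_analyzed": traj.n_frames,
        "n_atoms": traj.n_atoms,
        "stages": status,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
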