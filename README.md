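# helixscope

Trajectory analysis for single-pass membrane proteins in lipid bilayers.

`helixscope` re-implements, as a tested and reusable package, the standard
analysis battery applied to molecular-dynamics simulations of a
transmembrane (TM) helix embedded in a two-leaflet bilayer — the kind of
system exemplified by the KCNE3 transmembrane domain (residues 57–82) in a
POPC/POPG membrane:

* **Superposition statistics** — Kabsch least-squares rigid superposition,
  per-frame RMSD of a region against a reference structure, and per-residue
  RMSF about the aligned ensemble mean.
* **Bilayer geometry** — membrane width as the distance between the two
  peaks of the phosphate mass-density profile along the membrane normal
  (+Z), with parabolic peak refinement; signed Z-distances of protein
  regions from the bilayer center of mass (Z = 0).
* **Helix geometry** — TM helical tilt as the angle between the helix
  principal axis (dominant SVD direction of the Cα trace) and the membrane
  normal, folded to [0°, 90°]; and the three-point bending angle

  θ = arccos( R⃗₂₁ · R⃗₂₃ / (‖R⃗₂₁‖ ‖R⃗₂₃‖) ),

  where R⃗₂₁ and R⃗₂₃ point from an anchor Cα (default residue 74) to the
  Cαs three residues up- and downstream (defaults 71 and 77); θ = 180°
  means exactly collinear.
* **Essential dynamics** — PCA of the aligned TM Cα ensemble (sample
  covariance, divisor F−1), per-mode variance fractions, the dynamic
  cross-correlation matrix (DCCM) filtered through the top two principal
  components, per-residue mode b-factors λₘ|v₍ₘ,ᵢ₎|², and NMD export for
  normal-mode visualizers.
* **Nonbonded energetics** — Lennard-Jones (ε_ij = √(ε_i ε_j),
  R_ij = Rmin/2ᵢ + Rmin/2ⱼ) and real-space Coulomb pair energies tapered by
  the CHARMM energy-switching function between 10 and 12 Å, summed per
  frame between arbitrary disjoint regions (e.g. protein–lipid) or within
  one region (internal energy with 1-2/1-3-style exclusions).
* **A synthetic-trajectory generator** that builds Cα-trace systems with
  *known* tilt, bend, bilayer width and planted orthonormal fluctuation
  modes, so every analysis stage has an exact recovery test without
  running MD.

Inputs are standard formats: PDB (single- or multi-model), CHARMM/NAMD
binary DCD (both byte orders), and a plain CSV table of per-atom nonbonded
parameters. Outputs are CSV tables, an NMD mode file and a JSON run
manifest.

## Worked example

Generate the default synthetic study system — a 103-residue chain whose
residues 57–82 form a straight, untilted TM helix spanning a 38 Å bilayer
(512 phosphate pseudo-atoms, Gaussian vertical spread 1.5 Å), fluctuating
with planted stretch (8.7 Å²) and rotation (1.3 Å²) modes plus free
termini, 2000 frames at 100 ps — then run the full battery:

```sh
helixscope make-synthetic --out demo/bundle --seed 1
helixscope init-config --out demo/config.yaml   # edit paths, or:
helixscope analyze --config demo/config.yaml
```

With `topology/trajectory/parameters` pointed at the bundle, the run
prints one status line per stage (`rmsd ok`, `rmsf ok`, …) and writes 36
CSVs plus `modes.nmd` and `manifest.json`. Summarizing the output tables
of that exact run:

| quantity | value | ground truth |
|---|---|---|
| TM tilt (mean ± sd) | 0.78° ± 0.04° | 0° imposed (0.78° is the discrete-helix axis residual) |
| bilayer width | 37.97 ± 0.33 Å | 38 Å |
| bending angle θ | 153.58° ± 1.12° | straight helix (geometric offset of a 100°/residue helix; 180° would be three-point collinear) |
| Z of residue 69 | −0.04 Å | 0 (bilayer center) |
| mean RMSF, TM vs N-terminus | 0.51 Å vs 1.70 Å | TM quieter than termini |
| protein–lipid energy, TM region | −169 kcal/mol | attractive; terminal regions ≈ 0 |
| PC1 variance fraction (aligned ensemble) | 99.9 % | alignment absorbs the planted rigid-rotation mode, leaving stretch dominant |

Run PCA on the *raw* (unaligned) ensemble instead and the planted 87/13 %
stretch/rotation split is recovered within 0.02 (see
`tests/test_acceptance.py::test_pca_planted_mode_recovery`).

## Layout

```
src/helixscope/
  model.py        core types (Topology, Trajectory, Selection, …), trimming
  pdbio.py        PDB v3.3 reader/writer
  dcdio.py        CHARMM/NAMD DCD reader/writer (endianness auto-detected)
  parameters.py   nonbonded parameter table assignment
  selections.py   selection mini-language (name/resid/segid, and/or/not)
  synthetic.py    ground-truth system and trajectory generator
  superposition.py  Kabsch fit, RMSD series, RMSF
  membrane.py     density profiles, bilayer width, Z-distances
  helix.py        helix axis, tilt, bending angle
  essential.py    PCA, DCCM, b-factors, NMD I/O
  energetics.py   switched LJ/Coulomb pair energetics
  pipeline.py     config-driven orchestration, histograms, 2D densities
  cli.py          helixscope make-synthetic | analyze | init-config
```

See `docs/methods.md` for the models, conventions and design decisions.
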