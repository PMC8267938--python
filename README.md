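# clampmd

Analysis of clamp-like ("clamshell") domain motion in MD trajectories of
two-lobed proteins, built around the hinge dynamics of the SET- and
MYND-domain methyltransferase SMYD3: its C-terminal domain (CTD) swings
between **closed**, **intermediate** and **open** poses, and that motion
gates access of peptide substrates to the catalytic cleft. `clampmd` turns
raw coordinate frames into the quantities used to characterize such
motion, and ships a synthetic three-state generator so the entire pipeline
can be validated at desk scale against known ground truth.

## What it computes

Given a topology (PDB) and trajectories (multi-model PDB or XYZ):

* **Geometric descriptors** — mass-weighted RMSD
  (`sqrt(Σ m_i |X_i − Y_i|² / M)` after weighted Kabsch superposition),
  per-residue RMSF, radius of gyration, the hinge-monitoring centroid
  distances **D1** (MYND 42–48 ↔ CTD 298–302), **D2** (SET 209–227 ↔ CTD
  363–365) and **D3** (sidechain centroids of residues 183 and 239), and
  the residue-239 CA–CB–CG–CD2 torsion in [0°, 360°).
* **Ensemble statistics** — dynamic cross-correlation maps (DCCM) over CA
  displacements; geometric hydrogen-bond detection (3.5 Å / 135°
  defaults) with exact per-pair occupancies; deterministic 1-D k-means for
  representative-frame extraction.
* **Free-energy landscapes** — Boltzmann inversion `ΔG = −k_B T ln g` of
  1-D (D1) and 2-D (D1 × RMSD) histograms at 0.1 Å bins, minimum shifted
  to zero; classification into closed/intermediate/open states on D1
  (default cuts 9.5 and 12.0 Å) with occupancy tables and population
  free-energy gaps `−k_B T ln(p_b/p_a)`.
* **Synthetic dynamics** — overdamped Langevin sampling of D1 on a smooth
  triple-well potential (minima near 8.5/10.5/13.5 Å), rigid-hinge
  embedding onto a toy two-lobe structure (D1 reproduced to 1e-6 Å, D2
  anti-correlated by construction), scheduled hydrogen-bond toggling, and
  a toy well-tempered metadynamics engine (tempered Gaussian deposition,
  half-harmonic walls, `F = −(γ/(γ−1)) V̄`).

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Generate a synthetic three-state trajectory and analyze it:

```bash
clampmd generate --out demo/bundle --seed 7 --n-steps 30000
clampmd analyze --trajectory demo/bundle/trajectory.pdb \
                --out demo/report --system Apo-like --seed 7
```

which prints

```
wrote 3000-frame bundle to demo/bundle
report written to demo/report
        closed:  35.57%
  intermediate:  39.40%
          open:  25.03%
```

The three percentages are the fractions of frames whose D1 distance falls
in the closed (< 9.5 Å), intermediate (9.5–12 Å) and open (≥ 12 Å)
intervals; for this generator configuration the numerically integrated
Boltzmann weights of the three wells are 37.5 / 39.4 / 23.1 %, so a
3000-frame run recovers the equilibrium populations to within about two
percentage points. `demo/report/` also contains the descriptor series
(`descriptor_D1.csv`, …), `dccm.csv`, `hbond_occupancy.csv` (the scheduled
K42–E295 pair reads exactly its 50% duty cycle), the 1-D and 2-D
free-energy grids, per-state occupancies, representative-frame PDBs and a
provenance block. `clampmd compare` summarizes several such reports into
mean ± SD tables and a D1 ranking; `clampmd metadyn` runs the toy
well-tempered metadynamics engine and writes its FES.

The same steps work on real trajectories: pass your topology with
`--topology` and one `--trajectory` per replicate.

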