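# Methods

`clampmd` analyzes the hinge ("clamshell") motion of two-lobed proteins —
the motivating case is the SET- and MYND-domain methyltransferase SMYD3,
whose C-terminal domain (CTD) swings between closed, intermediate and open
poses — from MD trajectories supplied as multi-model PDB or XYZ frame
series. This note records the models, conventions and numerical choices
behind each stage, and what the bundled synthetic generator does and does
not emulate.

## Structures, trajectories and selections

Structures are parsed with biotite and held as flat atom records: author
residue numbering is kept verbatim (all monitored residue ranges — 42–48,
183, 209–227, 239, 298–302, 363–365 — are author numbers of the SMYD3
crystal structure lineage), coordinates are Å, masses are standard atomic
weights in amu. Alternate locations are resolved to the highest-occupancy
conformer, ties to altloc `A`. Elements missing from PDB columns 77–78 are
inferred from the atom name. HETATM records (cofactors, zinc, waters) are
parsed but excluded from selections unless a selection opts in, since every
monitored descriptor is protein-only. Selections are declarative (chain,
closed residue intervals, atom-name whitelist, atom class `all` / `heavy` /
`backbone` / `sidechain`) and resolve deterministically in topology order;
the `sidechain` class means heavy atoms excluding N, CA, C, O, so
sidechain-centroid descriptors are identical with and without hydrogens
present.

## Geometric descriptors

* **Superposition** is weighted Kabsch (via
  `scipy.spatial.transform.Rotation.align_vectors`), reflections excluded.
  Fewer than three or collinear fit atoms raise an error.
* **RMSD** is the mass-weighted form `sqrt(sum m_i |X_i − Y_i|^2 / M)`. By
  default the mobile frame is first best-fitted (mass-weighted, CA atoms)
  onto the reference: without fitting, RMSD conflates diffusion with
  conformational change.
* **D1 / D2 / D3** are centroid–centroid distances: D1 between residues
  42–48 (MYND) and 298–302 (CTD), D2 between 209–227 (SET) and 363–365
  (CTD), D3 between the sidechain centroids of residues 183 and 239
  (lysine-channel width). Centroids are mass-weighted over heavy atoms by
  default, with a geometric (unweighted) mode available. The reference
  crystal structure is not redistributed with the package, so this default
  could not be arbitrated against its printed descriptor values; it follows
  the convention of the common trajectory-analysis toolchains, and the mode
  is configurable per call.
* **Torsions** are IUPAC-signed angles mapped to [0°, 360°), so the
  flipped tyrosine-239 rotamer near 270° is representable without a branch
  cut; a torsion is invariant under reversing the atom order, and mirror
  reflection maps θ to 360° − θ.
* **RMSF** is the per-residue CA fluctuation about the iterated average
  structure: fit every frame to frame 0, average, refit to the average.
  The static-trajectory and rigid-motion invariants hold under any
  reference choice; one refinement pass is standard practice.

## Ensemble statistics

* **DCCM**: after superposing frames onto the average structure,
  `C_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)` over CA displacement
  vectors. Zero-variance residues are flagged and reported as 0.
* **Hydrogen bonds** use geometric criteria: heavy-atom donor–acceptor
  distance ≤ 3.5 Å and donor–H–acceptor angle ≥ 135° (both configurable).
  Hydrogens are identified by name and ≤ 1.2 Å proximity to the donor
  heavy atom; structures without hydrogens (crystal structures) fall back
  to the distance criterion alone. A residue pair counts as bonded in a
  frame if any donor/acceptor candidate combination in either direction
  satisfies the criteria, matching how interface pairs such as K42–E295
  are labelled in the field. Occupancy is the exact percentage of frames
  bonded. Absolute occupancies are only comparable across systems analyzed
  with one fixed criterion set, which a pipeline run enforces.
* **Representative frames** come from deterministic 1-D k-means on a
  descriptor series (farthest-point seeding from a seeded draw, Lloyd
  iterations to 1e-6 or 100 rounds); the representative is the frame
  nearest its cluster mean, ties to the earliest frame.

## Free-energy landscapes and states

The potential of mean force over one or two descriptors is Boltzmann
inversion of the normalized histogram, `ΔG = −k_B T ln g`, with
`k_B = 0.0019872041 kcal mol⁻¹ K⁻¹`, default 0.1 Å bins and 300 K, and the
minimum over occupied bins shifted to zero. Empty bins are stored as
flagged infinities and exported blank — capping them would fabricate
barrier heights. States partition D1 into closed [0, 9.5), intermediate
[9.5, 12.0) and open [12.0, ∞) Å by default: the observed state centers
sit near 8.5, 10.5 and 13.5 Å, and the default boundaries cut the gaps at
their midpoints; boundary values belong to the upper state. The population
free-energy gap between two states is `−k_B T ln(p_b/p_a)`.

## Synthetic three-state dynamics

The generator exists so the whole pipeline can be exercised, end to end,
at desk scale with known ground truth.

* **Potential**: a C¹ piecewise-cubic Hermite triple well through the well
  minima and barrier tops (zero slope at each knot), continued
  quadratically outside. Defaults: minima at 8.5 / 10.5 / 13.5 Å with
  energies 0.0 / 0.1 / 0.5 kcal/mol (closed and intermediate
  near-degenerate, open slightly up) and 1.5 kcal/mol barrier tops, so all
  three states are visited in short runs at 300 K. These are plausible,
  not fitted, values: the real system's landscape is not reproduced, only
  its assumed three-state structure.
* **Integrator**: overdamped (Brownian) Euler,
  `x ← x − (Δt/γ_f) U′(x) + sqrt(2 k_B T Δt/γ_f) η`, with friction
  coefficient γ_f = 0.5 kcal mol⁻¹ ps Å⁻² and Δt = 0.01 ps by default
  (stability requires Δt·max|U″|/γ_f < 2, checked at run time). Only
  equilibrium statistics matter downstream, so inertial dynamics are not
  modelled. Forces are tabulated on a 2×10⁻⁴ Å grid and linearly
  interpolated inside a numba kernel; one normal deviate is drawn per step
  from a seeded generator, making runs bit-reproducible from
  (config, seed).
* **Embedding**: a coarse two-lobe structure (one CA per residue 1–428,
  anchor rings for the preset ranges, minimal sidechains and donor/H/
  acceptor triads for the five monitored pairs) realizes a D1 series as
  rigid rotation of the C-lobe (residues ≥ 270) about a hinge axis. The
  hinge angle per frame is solved by bisection so that D1 recomputed from
  the coordinates reproduces the driving value to 1e-6 Å, and the geometry
  places the D2 anchor on the opposite rotational side, so D2 narrows as
  D1 widens — the clamp signature. Scheduled hydrogen-bond pairs have
  their acceptor atom placed collinearly at 2.8 Å (on) or 6.0 Å (off)
  from the donor each frame, so recovered occupancy equals the schedule's
  duty cycle exactly.
* **What is not emulated**: solvent, force fields, inertia, secondary
  structure, realistic RMSF profiles, correlated side-chain motion, or the
  actual free-energy surface of any protein. Passing tests demonstrate
  that the analysis recovers known statistical structure from data shaped
  like MD output, not that the biology is reproduced.

## Toy well-tempered metadynamics

The biased engine shares the Langevin kernel (a zero-height run is
bit-identical to the unbiased engine at the same seed and timestep).
Defaults follow common practice for a distance collective variable:
Gaussian height 1.0 kJ/mol, width 0.5 Å, deposition every 1 ps, bias
factor γ = 15, half-harmonic walls at 6 and 20 Å with
k = 5000 kJ mol⁻¹ Å⁻² (a printed force constant of this magnitude with a
missing length power is read as Å⁻², the dimensionally consistent
convention), grid 5–25 Å at 0.1 Å, 300 K. Deposited heights are tempered
as `h·exp(−V/( (γ−1) k_B T ))`. The default metadynamics timestep is
0.0005 ps because the wall stiffness dominates the stability bound. The
free-energy estimate is `F = −(γ/(γ−1)) V̄`, min-shifted, where V̄ is the
bias time-averaged over the second half of the depositions: the final-bias
snapshot carries hill-sized ripple of several tenths of a kcal/mol, and
time-averaging is the standard low-variance estimator; the final
`V(x, t_end)` is returned alongside. FES values within ~2 Gaussian widths
of a wall include the wall potential and kernel-boundary bias and should
not be interpreted.

## Pipeline conventions

A run computes, in order: RoG, D1, D2, D3, the residue-239 torsion, RMSD
vs frame 0, RMSF, DCCM, hydrogen-bond occupancies, 1-D (D1) and 2-D
(D1 × RMSD, CA-based) landscapes, state labels and occupancies, and
RoG-cluster representative frames. Replicates are analyzed independently
and pooled; both views are written. Reports are written atomically (a
temporary directory renamed into place), carry a provenance block (config
hash, seed, package version, machine-readable warnings), and format
numbers to 6 significant digits so identical inputs give byte-identical
files. Missing preset residues skip that preset with a logged warning;
topology/trajectory mismatches fail before any output. Problem sizes used
in the bundled checks (10⁵-sample landscapes, 10⁶-step unbiased runs,
50 ns-equivalent biased runs, a few thousand embedded frames) were chosen
as the smallest that give stable statistics for the stated tolerances.

## Known limitations

* PDB and XYZ only; no binary trajectory formats, no mmCIF, no
  connectivity perception or protonation assignment. Input trajectories
  are assumed imaged/whole (no periodic-boundary handling).
* Hydrogen-bond criteria are geometric; occupancies are not comparable to
  analyses run with different cutoffs.
* The landscape module does not reweight biased trajectories; metadynamics
  output is analyzed only through its own FES estimator.
* The synthetic generator's hydrogen-bond scheduling moves acceptor atoms
  non-physically by construction; those atoms should not be used for
  other descriptors (the preset selections avoid them).
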