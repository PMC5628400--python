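# Methods

This note records the models implemented in `ltk`, the conventions and
default parameters that matter, what the synthetic generators do and do
not emulate, and the numerical choices made where the design was open.
Units throughout: coordinates in Å, energies in kcal/mol, temperatures
in K, charges in elementary charges. k_B = 0.0019872041 kcal/(mol·K).

## Hard-sphere tunnel model

Tunnel detection is purely steric: atoms are hard spheres of van der
Waals radius (packaged default: the Bondi element radii, overridable per
run; elements missing from Bondi's table, mainly metals, carry commonly
used supplementary values). The *free radius* of a point is its
distance to the nearest atom surface, clamped at zero, evaluated on a
regular grid spanning the structure's bounding box plus padding.

- **Defaults**: grid spacing 0.6 Å, padding 4 Å, probe radius 1.2 Å
  (an O₂-sized probe), cost exponent ν = 2. The padding guarantees
  boundary voxels lie in solvent, so "surface" is simply any boundary
  voxel wide enough for the probe.
- **Search**: voxels narrower than the probe are impassable; edge cost
  between 26-connected neighbors is `step_length / r_mid^ν` with r_mid
  the mean free radius of the two voxels; Dijkstra from the seed; the
  cheapest surface voxel wins, with ties broken on the smaller flat
  voxel index so output is deterministic. A tunnel's throughput is
  e^(−cost), its curvature arc-length over straight seed-to-exit
  distance (1 = straight), its bottleneck the minimum node radius.
- **Multiple tunnels**: after each accepted path, voxels within
  (bottleneck + probe) of its nodes are blocked — except within that
  same distance of the seed, so distinct tunnels sharing the active-site
  entrance (e.g. opposite exits of a channel) remain findable.
- **Snapshot clustering**: tunnels are arc-length resampled to 20
  nodes; the distance between two tunnels is the mean node-to-node
  distance; single-linkage clusters merge below 2 Å by default. A
  cluster's occurrence is the fraction of snapshots contributing at
  least one member, the natural reading of "this tunnel is available in
  X% of snapshots".

The grid approximation means bottlenecks are accurate only to about
half a grid spacing, and costs carry an O(spacing) discretization error;
the refinement test halves the spacing and checks the bottleneck moves
by less than the coarse spacing.

## Umbrella sampling and WHAM

The reaction coordinate is a ligand–site distance. Windows are
restrained by U = c·k(x − x₀)² where the **bias convention** c is an
explicit, logged flag: `full` (c = 1, the AMBER restraint form) or
`half` (c = ½, assumed by the widely used external WHAM code). Files
loaded without a convention header default to `half`; windows written by
this package always carry the header. Mixing conventions silently
halves or doubles every bias; a regression test asserts that a
mislabeled solve visibly distorts a flat profile, because this is the
single easiest way to corrupt a PMF.

- **Solver**: standard self-consistent iteration in log space
  (logsumexp), gauge-fixed by f₁ = 0, converged when max|Δfᵢ| < 10⁻⁶
  kcal/mol (max 10⁵ iterations; non-convergence raises with the final
  residual). Default binning: 4 bins per window over the pooled sample
  range. Empty bins are reported as NaN, never as zeros, and are
  excluded from anchoring. The displayed profile is anchored at its
  minimum; temperature defaults to 300 K.
- **Bins beyond the outermost window centers** are covered only by
  window tails and are legitimately noisy; recovery statistics are
  therefore assessed over the designed window span.
- **Bootstrap**: each replicate resamples every window's samples with
  replacement (same sizes), re-solves, re-anchors; the per-bin standard
  deviation across replicates is the uncertainty, and the reported
  profile is the solution on the original samples. More than 10% failed
  replicates is an error.
- **Anchoring gauge for calibration**: a free energy is defined up to a
  constant. Min-anchoring (the display convention) shifts every bin by
  the most negative noise excursion — at 100 bins roughly +2.5σ — so
  ±1σ intervals can never cover a flat truth in that gauge. Interval
  calibration is therefore assessed in the mean-anchored gauge
  (`anchor="mean"`), where measured coverage averages 0.67 over many
  suites. Because all bins share the window offsets fᵢ, single-suite
  coverage is far noisier than a binomial at 100 bins (measured sd
  ≈ 0.24); the calibration check averages over independent suites.
- **Overlap diagnostics**: adjacent windows (ordered by center) are
  compared by the overlap Σⱼ min(ĥᵢ, ĥᵢ₊₁) of their unit-normalized
  histograms; pairs below 0.02 are flagged as sampling gaps.

## Flooding-trajectory transport analysis

Distances are measured from the **ligand centroid** (symmetric for a
homonuclear diatomic like O₂) to the site reference point (a single
atom, or the centroid of the site selection), with minimum-image
displacements whenever the trajectory carries an orthorhombic box. An
entrance event is a maximal run of consecutive frames with distance
below the threshold (default 6 Å, the complete-entrance criterion for
a ligand reaching the catalytic metal); the default minimum event
length is 1 frame, so any sub-threshold excursion counts. Event
detection is exact integer logic and is tested against a brute-force
run-length scan on random series.

Occupancy maps use binary per-frame voxel occupancy (≥ 1 selected atom
center in the voxel), averaged over frames — the 0-to-1 scale on which
an isovalue like 0.006 is meaningful. Replicate maps average voxel-wise
weighted by frame counts. Maps export as OpenDX scalar fields readable
by VMD and PyMOL.

Molar concentration is (n/N_A)/(V·10⁻²⁷ L/Å⁻³); 10 molecules in a
520 000 Å³ box give 0.0319 M.

## Energy decomposition

For a target residue, per-partner-residue nonbonded energies are plain
pairwise sums over all cross-residue atom pairs, per frame: Coulomb
C·q_aq_b/r with C = 332.0636 kcal·Å/(mol·e²), Lennard-Jones
4ε[(σ/r)¹² − (σ/r)⁶] under Lorentz–Berthelot combining (arithmetic σ,
geometric ε). Excluded pairs are skipped; scaled-1-4 pairs multiply by
their factors (AMBER's 1/1.2 and 1/2.0 when unspecified); intra-residue
pairs are never counted. No cutoff and no Ewald by default — the
decomposition is a diagnostic of direct pair interactions, not a
periodic lattice energy; an optional cutoff exists. Minimum-image
displacements apply when a box is present. Per-partner SEMs come from
per-frame values; the total's SEM comes from per-frame totals (summing
partner SEMs would ignore their correlation). Differences between
variants subtract partner-matched means (mutant − wild type) and
combine SEMs in quadrature; replicate-to-replicate spread is a separate
question from frame-SEM and is left to the caller's replicate design.

## Ensemble dynamics

Superposition is rigid-body least squares (Kabsch, via rotation
fitting) on a selection of ≥ 3 non-collinear atoms, applied to all
atoms; an independent quaternion (Kearsley-matrix) oracle cross-checks
the minimized RMSD in the tests. RMSF is the per-atom root-mean-square
deviation from the time-mean position of an already-superposed
trajectory; per-residue reduction uses the Cα atom when present,
otherwise the unweighted mean over the residue's atoms. Cross-
correlations are C_ij = ⟨Δrᵢ·Δrⱼ⟩/√(⟨|Δrᵢ|²⟩⟨|Δrⱼ|²⟩). Hydrogen bonds
are geometric: donor–acceptor distance ≤ 3.0 Å and donor–hydrogen–
acceptor angle ≥ 135°, per frame; occupancy is the present-frame
fraction, with a default report filter at 30%. Distances honor minimum
image; angles use local unwrapped geometry.

## Synthetic generators — what they emulate, and what they do not

All generators are bit-reproducible from (spec, seed).

- **Channel systems**: a tube of wall atoms (center-line radius
  inner_radius + wall_atom_radius, so the on-axis free radius equals
  inner_radius) inside a quasi-random spherical shell; open caps extend
  the tube through a hole in the shell, closed caps are sealed with an
  atom disk. Defaults: inner radius 3 Å, length 20 Å, wall atoms of
  radius 1.5 Å every 0.8 Å (dense enough that a 1.2 Å probe cannot
  leak). `ChannelSpec` requires wall_atom_radius > 0; a zero-radius
  wall has no physical counterpart here.
- **Umbrella windows**: Metropolis Monte Carlo on F(x) + bias with
  proposal width 0.2 Å, 1000-step burn-in, stride 10 between kept
  samples — run as many independent walkers in parallel (up to 256,
  each with its own burn-in), which leaves the sampled law unchanged
  while making 5×10⁴-sample windows a sub-second operation. Measured
  kept-sample autocorrelation: ρ₁ ≈ 0.05, integrated time ≈ 1.1.
  Supported true profiles: constant, linear, harmonic a(x−x₀)², and
  double-well a(x²−b²)² (barrier a·b⁴ between wells at ±b).
- **Ligand diffusion**: scripted residence intervals keep the ligand
  centroid ≥ 1 Å inside the entrance threshold during events and ≥ 1 Å
  outside it otherwise, so threshold detection recovers the script
  exactly; between those constraints the radial coordinate random-walks
  and the direction is drawn from a shuffled sphere covering. Ligands
  are rigid O₂ diatomics (1.21 Å bond) around a fixed Fe site atom.
- **Fluctuation ensembles**: i.i.d. multivariate-Gaussian frames with
  per-atom, per-axis standard deviations and optional pair correlations
  applied on every axis (correlation matrix must be positive
  semi-definite).

What passing these suites shows: the estimators are correct on data
whose generating law is exactly the model each estimator assumes. What
it does not show: robustness to what real MD adds — autocorrelated and
non-Gaussian fluctuations, conformational gating of tunnels, anisotropic
ligand diffusion, force-field error. In particular, study-scale numbers
(tunnel occurrence percentages over trajectory snapshots, kcal-scale
PMF barriers for a real protein, per-residue energies of a real mutant
series) require microsecond-scale solvated MD and are out of scope
here; the package is the analysis layer one would point at such
trajectories.

## Problem sizes used in the shipped checks

The acceptance script and test suite run: WHAM recovery at 30 windows ×
5×10⁴ samples for each profile form; bootstrap calibration at 100 bins ×
50 replicates averaged over 8–10 independent suites of 30 windows ×
5×10³ samples; tunnel searches on ≈ 0.3-million-voxel grids of ≈ 2 500
atom systems; and second-scale closed-form checks elsewhere. These
sizes keep the full suite in the minutes range on one CPU while leaving
every statistical tolerance comfortably resolvable.

## Known limitations

- Grid-based tunnel search (no Voronoi construction): costs and
  bottlenecks carry O(spacing) error, and very narrow side channels
  below the grid resolution are invisible.
- 1D WHAM only; no MBAR, no 2D coordinates, no autocorrelation-based
  inefficiency weighting of samples.
- The bootstrap treats samples within a window as exchangeable; for
  strongly autocorrelated input series the uncertainties are
  underestimates unless the series is pre-thinned.
- EDA is a fixed-charge pairwise decomposition: no polarization, no
  solvent screening, no reciprocal-space electrostatics.
- PDB support covers ATOM/HETATM/MODEL records (coordinates, identity,
  insertion codes); exotic records (altloc averaging, SCALE matrices)
  are ignored.
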