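# ltk — ligand transport toolkit

`ltk` analyzes how small gas molecules such as O₂ reach buried enzyme
active sites. Many O₂-consuming enzymes (the Fe(II)/2-oxoglutarate
dioxygenases among them) admit their co-substrate not through the
substrate cleft but through transient intramolecular tunnels lined by
hydrophobic residues. Deciding whether such a tunnel exists, how easily
a ligand passes it, and what controls the ligand's residence near the
catalytic metal requires a chain of analyses that this package
implements as one tested library:

- **Tunnel detection and ranking** (`ltk.tunnels`). The protein is a set
  of hard spheres with van der Waals radii (Bondi table by default). On
  a regular grid of *free radii* r(v) = min_i(|v − cᵢ| − Rᵢ), tunnels
  from an active-site seed to the surface are lowest-cost Dijkstra paths
  under the CAVER-style cost `step / r_mid^ν` (ν = 2), ranked by
  throughput e^(−cost), curvature (arc length / straight distance) and
  bottleneck radius, and clustered across snapshots into occurrence
  fractions.
- **Umbrella-sampling WHAM** (`ltk.wham`). Given windows restrained by
  U = c·k(x − x₀)² (an explicit flag distinguishes the AMBER `full`
  convention c = 1 from the Grossfield-WHAM `half` c = ½), the solver
  iterates the standard self-consistency equations

      p_j = Σᵢ n_ij / Σᵢ Nᵢ exp[(fᵢ − Uᵢ(x_j))/k_BT]
      fᵢ  = −k_BT ln Σⱼ p_j exp(−Uᵢ(x_j)/k_BT)

  to a potential of mean force F_j = −k_BT ln p_j, with bootstrap
  per-bin uncertainties and adjacent-window histogram-overlap
  diagnostics.
- **Flooding-trajectory transport analysis** (`ltk.transport`):
  ligand–site distance series, entrance events as maximal runs below a
  6 Å threshold, residence statistics, per-voxel occupancy density maps
  (OpenDX output), and molarity bookkeeping for the flooding setup.
- **Per-residue energy decomposition** (`ltk.eda`): ensemble-averaged
  Coulomb (C·q_aq_b/r, C = 332.0636) and Lennard-Jones (Lorentz–
  Berthelot) interactions between a target residue and every other
  residue, with frame-SEM errors and wild-type/mutant differences.
- **Ensemble dynamics** (`ltk.dynamics`): Kabsch superposition, RMSD,
  RMSF and RMSF differences, cross-correlation matrices, and geometric
  hydrogen-bond occupancy with a 30% report filter.
- **Synthetic data with known ground truth** (`ltk.synthetic`):
  channel-in-shell atom clouds, Metropolis-sampled umbrella windows for
  a stated true F(x), scripted ligand-diffusion trajectories,
  multivariate-Gaussian fluctuation ensembles, and point-charge systems
  — every analysis above has an analytic or constructed oracle.

## Worked example

Recover a double-well free-energy profile from umbrella windows exactly
as one would from a real sampling run (30 windows spaced 0.3 Å,
k = 10 kcal mol⁻¹ Å⁻², 300 K):

```python
import numpy as np
from ltk.synthetic import PMFSpec, simulate_umbrella_windows
from ltk.wham import wham_solve

truth = PMFSpec("double_well", {"a": 1.5 / 16, "b": 2.0}, x_range=(-4.5, 4.5))
centers = -4.35 + 0.3 * np.arange(30)
windows = simulate_umbrella_windows(truth, centers, k=10.0,
                                    n_samples=50_000, seed=101)
profile = wham_solve(windows, x_range=(-4.35, 4.35), temperature=300.0)
barrier = profile.free_energy[np.argmin(np.abs(profile.bin_centers))] \
          - np.nanmin(profile.free_energy)
print(f"barrier: {barrier:.2f} kcal/mol (true 1.50)")
```

which prints

```
barrier: 1.50 kcal/mol (true 1.50)
```

i.e. the solver recovers the 1.5 kcal mol⁻¹ barrier between the wells at
x = ±2 Å to within sampling noise. The same windows round-trip through
the standard metadata/time-series file convention
(`ltk.wham.write_window_data` / `load_window_data`), so the module works
identically on files produced by a real MD engine.

A configuration-driven demonstration of the whole pipeline (channel →
tunnels → flooding events and density map → windows → PMF → EDA → RMSF
differences) runs from the CLI:

```
ltk --seed 1 --outdir demo run
```

Every CSV it writes carries a provenance header (version, config hash,
seed) and reruns with the same seed are byte-identical.

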