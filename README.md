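# glycopmf

Analysis machinery for biased molecular-dynamics studies of glycosidase-style
reactions: umbrella-sampling WHAM with per-conformation reweighting,
Gibbs-energy projections onto reaction and collective coordinates,
Cremer–Pople ring-puckering itineraries, and RMSd-based conformational
clustering. A built-in synthetic biased-dynamics generator with analytically
known ground truth makes the whole pipeline testable offline — no enzyme
trajectories required.

Units throughout: Å, ps, kcal·mol⁻¹, K (kB = 0.0019872041 kcal·mol⁻¹·K⁻¹,
default temperature 310 K).

## Modules

| Module | Contents |
| --- | --- |
| `glycopmf.synthetic` | Overdamped Langevin sampling on analytic potentials (`PotentialSpec`, `BiasSpec`), umbrella-window generation, ideal six-ring conformer geometries, Gaussian-mixture active-site distance series |
| `glycopmf.puckering` | Cremer–Pople (Q, φ, θ), the programmatically generated 38-vertex canonical conformer table, nearest-vertex classification, per-trajectory occupancy summaries |
| `glycopmf.collective_variables` | Heavy-atom pair/min-pair distances, nearest-solvent distances, the reaction coordinate `d_glyc − d_acid`, composites `d_actsite` and `d_acid − d_glyc_WAT + d_nuc`, contact occupancies |
| `glycopmf.free_energy` | Histogram ΔG projections (`ΔG_i = −kBT·ln(k_i/k₀)`), binned self-consistent WHAM, globally normalized per-sample weights, reweighted projections, direct/reverse cumulative-block convergence, Eyring barrier↔rate conversion |
| `glycopmf.conformations` | Least-squares superposition, RMSd series, Gromos neighbor-counting clustering with occupancy-gated seed selection, k-means representatives |
| `glycopmf.io` / `glycopmf.pipeline` / `glycopmf.cli` | Multi-model PDB / XYZ trajectories, tab-separated CV tables and profiles, YAML run configs, the two chained workflows, and the `glycopmf` CLI |

## CLI

```sh
# sample a double-well as 26 umbrella windows, 0.10 Å apart
glycopmf simulate --potential double_well --barrier 5.0 --wells 1.0 \
    --domain -2:2 --windows -1.25:1.25:0.1 --k 150 --steps 20000 \
    --seed 42 --out windows/

# WHAM + convergence diagnostics + per-sample weights
glycopmf wham --manifest windows/manifest.yaml --bins 200 --t-eq 2.0 --out wham_out/

# project ΔG onto CV columns of a table, optionally reweighted
glycopmf project --table cvs.tsv --axes d_acid,d_glyc --bins auto --out profile.tsv

# puckering itinerary of a ring trajectory
glycopmf pucker --traj traj.pdb --ring-atoms O5,C1,C2,C3,C4,C5 --out pucker.tsv

# CV extraction and Gromos clustering
glycopmf cvs --traj traj.pdb --config cvs.yaml --out cvs.tsv
glycopmf cluster --traj traj.pdb --method gromos --cutoff 1.2 --out clusters.tsv

# full configured workflow (cmd_projection or umbrella_wham)
glycopmf run --config config.yaml --out run_out/
```

Exit codes: 0 success, 2 validation/config error, 3 numerical failure.

## Conventions worth knowing

- Ring-atom order is ring oxygen (O5) first, then C1…C5; this pins the ⁴C₁
  chair to θ = 0. Rings with Q < 0.01 Å are reported `planar`.
- Trajectory frames are assumed whole and unwrapped; no minimum-image
  handling is applied to distances.
- All emitted free-energy profiles are anchored so the minimum finite ΔG is
  exactly 0; empty bins carry `inf` and are flagged, never zeroed.
- Every generator is a pure function of its seed.
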