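# npmicroenv

Microenvironment analysis of self-assembled block-copolymer nanoparticles
from coarse-grained bead trajectories.

Amphiphilic diblock copolymers such as PEG–PLGA self-assemble into
core–shell nanoparticles that solubilize therapeutic cargo — hydrophobic
PLGA blocks form the core, hydrophilic PEG the corona, and peptide cargo
ends up either deep in the core (often at a trapped-water nucleus) or at
the core–corona interface. Understanding *which polymer conformations*
the cargo prefers in each location is central to rational carrier design.
This package implements that analysis chain for anyone with a
coarse-grained trajectory (GRO / PDB / extended-XYZ plus a per-bead
topology table):

- **Structure** — largest-aggregate detection, mass-weighted COM and
  radius of gyration, spherical density profiles on an interface-relative
  axis, core-radius estimation, core composition, stationarity/burn-in
  detection, and cargo location classification (core / interface /
  corona).
- **Contacts** — cargo–environment contact counting (periodic k-d tree,
  strict cutoff), per-residue hydration/polymer contact differences
  between cargo locations, species-level contact enrichment
  `e_s = (n_s/Σn)/(B_s/ΣB)` with moving-block-bootstrap 90% CIs, and the
  Jaccard autocorrelation of each peptide's local polymer environment.
- **Conformations** — per-(frame, polymer) block end-to-end distance
  features `(d_PEG, d_PLGA)`, UMAP embedding + HDBSCAN clustering (with a
  bypass that clusters the 2-D feature plane directly),
  population-normalized intrinsic density profiles per cluster, and the
  fractional enrichment of cargo contacts among conformational clusters

      eps_i = (n_i / n_total) / (N_i / N_environment)

  where `n_i` counts contacts with cluster-i polymers and `N_i` counts
  cluster-i polymers in the cargo's local environment; `eps_i > 1` means
  the cargo prefers that conformation beyond its local abundance.
- **Synthetic systems** — a generator that builds core–shell particles
  with *planted, recoverable* ground truth: conformational cluster labels,
  core radius, cargo locations, and contact-enrichment factors. It is the
  package's validation instrument and a reusable test bed for any of these
  estimators.

## Worked example

```python
from npmicroenv import (
    scaled_params, generate_trajectory, radial_density_profile,
    estimate_core_radius, core_composition, classify_peptide_location,
    build_conformation_table, embed_and_cluster, fractional_enrichment,
    plant_contact_enrichment,
)

params = scaled_params(seed=1)              # desk-scale particle, ~5,900 beads
traj, truth = generate_trajectory(params)   # 60 frames + planted ground truth
topo = traj.topology

groups = {s: topo.select(species=s) for s in ("LA", "GA", "EO", "W")}
profile = radial_density_profile(traj, groups, bin_width=2.0)
core = estimate_core_radius(profile)
print(f"core radius: {core.core_radius:.1f} A (planted {truth.true_core_radius:.1f} A)")

comp = core_composition(traj, core.core_radius)
print("core composition (%):", comp.round(1).to_dict())

locations = classify_peptide_location(traj, core.core_radius)
print("cargo locations:", locations.value_counts().to_dict())

table = build_conformation_table(traj)
assignment = embed_and_cluster(table, use_embedding=False)
print(f"clusters: {assignment.k}, noise: {assignment.noise_pct:.2f}%")
print(assignment.populations.round(1).to_string(index=False))

biased = plant_contact_enrichment(traj, truth, target_cluster=4, factor=2.0)
peps = topo.molecules_of_class("peptide")
eps = fractional_enrichment(biased, assignment, peps,
                            {int(m): l for m, l in locations.items()})
row = eps.table.query("location == 'core' and label == 4").iloc[0]
print(f"eps(core, cluster 4) = {row.value:.2f}  90% CI [{row.ci_low:.2f}, {row.ci_high:.2f}]")
```

prints

```
core radius: 39.8 A (planted 40.0 A)
core composition (%): {'PLGA': 84.2, 'PEG': 8.7, 'peptide': 5.9, 'water': 1.2, 'ions': 0.0}
cargo locations: {'interface': 13, 'core': 2}
clusters: 4, noise: 0.04%
 label  population_pct  mean_d_PEG_A  mean_d_PLGA_A
     1            40.0          12.2           20.1
     2            25.0          28.4            8.5
     3            25.0          12.0            7.9
     4            10.0          30.1           24.5
eps(core, cluster 4) = 1.99  90% CI [1.93, 2.03]
```

Reading the output: the core boundary is recovered within 0.2 A of the
planted radius; the core is dominated by PLGA beads with a trace of
trapped water; 2 of 15 peptides are classified as core-resident; the four
planted conformational states are found with their exact populations and
mean block extensions; and after planting a 2× contact preference of the
core cargo for cluster 4 (the extended-PEG, extended-PLGA state at the
water nucleus), the fractional-enrichment estimate recovers it with a CI
that excludes 1 (no preference).

## Command line

```sh
npmicro synth --seed 1 --out synthetic/        # emit coordinates + topology + truth
npmicro run --config config.yaml --out results # full pipeline on files or synthetic
npmicro structure|contacts|conform --coords trajectory.gro --topology topology.csv
```

`npmicro run` executes the whole chain — burn-in detection, frame
discard, structure, contacts, conformations — and writes CSV tables plus
a `manifest.json` recording every parameter and seed; a rerun with the
same master seed is byte-identical.

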