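# Methods

`npmicroenv` analyzes coarse-grained bead trajectories of self-assembled
core–shell nanoparticles — a PEG–PLGA diblock micelle carrying peptide
cargo is the motivating system — and quantifies where the cargo sits, what
it touches, and which polymer conformations it prefers. Because no public
trajectory of the motivating system exists, the package ships a synthetic
configuration generator whose every recoverable quantity is planted
explicitly; the test suite demonstrates recovery of that planted truth by
the analysis chain.

All lengths are Angstrom internally (GRO input in nm is converted at the
boundary), times are ns, and all distances use the orthorhombic
minimum-image convention. Contacts are bead pairs strictly within a cutoff
(default 6 A, a conventional coarse-grained contact distance); the strict
inequality makes counts reproducible across floating-point orderings, and
every result object records the cutoff that produced it.

## Structural analysis

**Nanoparticle definition.** The NP is the largest connected component of
polymer+peptide molecules, two molecules being linked when any
inter-molecular bead pair lies within a link cutoff. Its center of mass is
mass-weighted and minimum-image unwrapped, so a particle near the box edge
is handled correctly.

**Radial density and core boundary.** Per frame, bead distances to the NP
COM are binned into spherical shells; density = count / shell volume,
averaged over frames. The reported axis may be shifted by a constant
interface offset so the core–corona interface sits near zero (interior
negative). A per-frame instantaneous-surface construction is deliberately
out of scope; the constant-offset convention is recorded in output
metadata. The core radius is estimated as the radius where the combined
core-monomer (LA+GA) density first falls below 50% of its core-plateau
median (plateau = inner 60% of the region above 10% of maximum — all three
thresholds configurable). The secondary estimate is the EO density maximum
*near the interface*: the search is windowed to 0.6–1.6 of the primary
estimate because chains wrapping a trapped-water nucleus can produce a
second, deeper EO maximum. The conservation identity
`sum(density x shell volume) = mean bead count in range` holds exactly by
construction and is asserted in the tests.

**Stationarity / burn-in.** The fraction of LA+GA monomers instantaneously
inside concentric shells (quartiles of the core radius by default) is
tracked per frame. The burn-in is the earliest frame `t0` such that, for
every shell, the mean over `[t0, T]` lies within a tolerance (default
0.01) of the reference mean over the final half. Note a property of this
running-mean criterion: it admits up to `eps*(T-t0)/delta` pre-transition
frames (`delta` = shell-fraction step), so for sharp transitions detection
can precede the transition by a frame or two at the default tolerance;
tightening the tolerance recovers exact localization.

**Cargo location.** Each peptide is classified core / interface / corona
from the *median* over frames of its COM distance to the NP COM (the
median resists transient excursions): core if `d < R - margin`, interface
if `|d - R| <= margin` (default margin 10 A).

## Contact statistics

**Species-level contact enrichment.** Within an environment region
(typically a radial shell around the cargo's location),
`e_s = (n_s/Σn) / (B_s/ΣB)` compares the species' share of cargo contacts
with its share of region beads, per frame; the reported value is the time
average. Frames with zero contacts are skipped (not scored 0) to avoid
0/0. The abundance-weighted mean of `e_s` is identically 1 per frame.

**Environment ACF.** The local environment of a peptide is the set of
polymer beads within the cutoff; its autocorrelation at lag `tau` is the
mean Jaccard index of the sets at `t` and `t+tau` (two empty sets count as
identical). Jaccard is symmetric, bounded, identity-normalized, and
invariant under bead relabeling; the estimator choice is recorded in
output metadata.

**Confidence intervals.** All enrichment CIs are moving-block bootstrap
percentile intervals over frames (defaults: block 10 frames, 1000
resamples, 90%, seeded). Molecular time series are autocorrelated; an iid
bootstrap would understate the width.

## Conformational clustering and fractional enrichment

A polymer conformation is the pair of block end-to-end distances
`(d_PEG, d_PLGA)` of one polymer in one frame, computed after unwrapping
the chain bond-by-bond across periodic boundaries. The clustering unit is
the (frame, polymer) row, so a polymer may change cluster over time and
population percentages are per-conformation.

Features are z-scored, embedded with UMAP (n_neighbors 15, min_dist 0.1,
2 components, seeded) and clustered with HDBSCAN
(min_cluster_size = max(25, 1% of rows)). Because the feature space is
already two-dimensional, an option bypasses the embedding and clusters the
standardized plane directly; on well-separated planted states both routes
give identical K and near-identical partitions (asserted in tests).
Departures from HDBSCAN's library defaults: `allow_single_cluster=True`,
`min_samples=10`, `cluster_selection_epsilon=0.5`. Without these a
homogeneous (single-state) ensemble is shattered into spurious
sub-clusters plus ~90% noise, which is scientifically wrong for this
featurization; with them a single Gaussian yields one cluster with <5%
noise while well-separated multi-state data are unaffected. Clusters are
renumbered 1..K by descending population, so labels are stable; noise rows
carry the label −1.

**Intrinsic density.** Each (frame, polymer) is located by its PEG–PLGA
junction midpoint (the natural amphiphilic anchor; polymer COM available
as an option); its signed distance to the interface is histogrammed per
cluster, divided by shell volumes and the cluster's row count, so each
cluster's profile integrates to 1 — comparable across clusters of
different populations.

**Fractional enrichment.** Per frame and cargo location,
`eps_i = (n_i/n_total) / (N_i/N_environment)` where `n_i` counts contacts
between the location's peptides and beads of polymers currently labelled
cluster i, and `N_i` counts distinct such polymers with at least one bead
in the local environment. Values above 1 mean the cargo prefers that
conformation beyond its local abundance. The N-weighted mean of `eps_i`
is identically 1 per frame. Unclustered (noise) polymers are excluded
from numerator and denominator; their contact share is reported
separately. A cluster is flagged statistically unreliable when its total
contact count is below 50 or it appears in fewer than 10% of usable
frames (a cluster present in one frame can accumulate hundreds of
contacts yet carry no meaningful time average). Per-frame `eps_i` for a
cluster absent from that frame's environment (`N_i = 0`) is undefined and
excluded from the average rather than scored zero.

## The synthetic generator

The generator emulates the assembled state, not the assembly process: no
force field, no kinetics. Defaults mirror the motivating formulation —
200 diblock copolymers (PEG ≈ 114 EO monomers from Mn 5000/44; PLGA ≈ 108
monomers from Mn 7000 at 1:1 LA:GA, mean residue mass ≈ 65), 15 peptides,
a 580 A box, core radius 70 A, trapped-water nucleus 12 A. Water is
single-site and deliberately sparse (configurable density, plus a capped
exterior count) to keep desk-scale bead counts near 10^4–10^5 rather than
the ~6x10^5 of the full system. The 16-bead cargo uses a generic
amphiphilic residue pattern (GLU/LYS/ALA/LEU repeated); it is a stand-in,
not a claim about any real peptide's sequence.

**Chains.** Polymers are pinned random bridges with *exact* planted block
end-to-end distances (Brownian-bridge noise vanishes at the endpoints),
radially clamped into their regions; only analysis-relevant observables
are realistic. Interface polymers anchor their junction at the core
radius, PLGA inward, PEG outward. Core-interior polymers (the planted
state whose extended PEG shields the nucleus) anchor at radii spread over
a band just outside the nucleus, with both blocks tilted outward just
enough to fit inside the core — a single thin shell of junctions would
saturate the core cargo's entire local environment with that one cluster
and make any planted enrichment geometrically unattainable. Chain
directions are drawn in antithetic (±) pairs within each cluster so the
particle's mass distribution stays centrosymmetric and the COM stays at
the construction center.

**Planted conformational states.** Four states (fractions 0.40 / 0.25 /
0.25 / 0.10, descending so planted labels match population-rank labels):
collapsed-PEG+extended-PLGA, extended-PEG+collapsed-PLGA, both collapsed,
and the core-interior both-extended state. Pairwise mean separations are
at least 8 per-dimension standard deviations, so density clustering
recovers them essentially perfectly. Planted PLGA lengths that cannot fit
between nucleus and core are clipped per polymer (the realized distance is
what downstream sees); the feature sampler assigns exact per-cluster
counts by largest remainder.

**Cargo placement and contact planting.** Peptides anchor at junction
points of their region's polymers (so their local environment is never
empty). With frame noise present, each frame re-attaches every peptide to
a nearby polymer — modelling environment exchange, which is also what
gives the environment ACF its decay. The attachment is chosen by a
feedback controller that (1) proposes several candidate placements,
(2) scores each by the per-frame enrichment vector it would induce —
contacts *and* environment membership, incidental neighbors included —
against the planted targets (1.0 everywhere by default), and (3) updates
its state from the realized statistics, measured with the *same*
per-frame routine the analysis uses. A catch-up term aims subsequent
frames beyond the target by the accumulated shortfall, so the time
average converges to the planted value with O(1/T) tracking error.
`plant_contact_enrichment` re-runs only this placement with a non-unit
target for one cluster; polymer coordinates are untouched, so the
conformational ground truth is preserved. For hard factors the warm-up
re-anchors the cargo at the junctions whose neighborhoods give the most
headroom (ratio of the target cluster's bead share to its molecule
share); a requested factor beyond the best attainable ratio (with a 1.3
headroom allowance for frame-by-frame freedom) raises an error listing
the attainable range. A factor of 0 is enforced as a hard exclusion for
all cargo. With a zero-noise, zero-drift configuration the trajectory is
strictly frozen (frames are exact copies), which takes precedence over
re-attachment.

**Non-stationarity.** Optional drift applies a radial inflation
`1 + A exp(-t/tau)` to polymer and water beads, emulating the compaction
tail of self-assembly. With `A = 1` (initial radius twice the relaxed
one) and `tau = 10` frames over 60 frames, the burn-in detector lands at
23–27 frames across seeds — inside the `[2 tau, 5 tau]` window that the
construction is designed to satisfy (derivable from the running-mean
criterion with the ~0.4 outer-shell fraction step this inflation
produces).

**What the generator does not emulate.** Chain-level physics (bond/angle
distributions, excluded volume, solvent structure), realistic water
density, assembly kinetics, cargo diffusion between regions, and box-edge
wrapping of the particle (it is centered). Passing recovery tests
therefore validate the *statistical machinery* — estimators, clustering,
enrichment, intervals — on geometry resembling the real system, not the
physics of any force field.

## Problem sizes and determinism

Tests and the acceptance script run a geometrically similar particle at
roughly one-third linear scale (80 polymers of 30+30 monomers, core 40 A,
box 160 A, 15 peptides, 60 frames — about 5,900 beads), the package's
standard desk-scale configuration. Clustering validation uses 8,000
planted conformations; CI coverage uses 50 independent replicates. One
master seed spawns per-stage sub-streams (generator, embedding,
bootstrap); the full pipeline is byte-identical across reruns with the
same seed, and all CSV output uses a fixed float format to keep that
property.

## Known limitations

- Planted enrichment factors are attainable only within a geometric range
  set by the local cluster mixture; near the edge of that range a small
  fraction of replicates converges slightly below the target (the 90% CI
  covers the planted factor in ~86% of replicates at factor 2).
- The core-radius estimator assumes a plateau-then-drop core profile; it
  is not designed for hollow or multi-lobed aggregates.
- The constant interface offset ignores per-frame shape fluctuations;
  asphericity metrics are out of scope.
- PDB output requires a constant box across frames (the format carries one
  CRYST1 record); GRO/XYZ carry per-frame boxes.
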