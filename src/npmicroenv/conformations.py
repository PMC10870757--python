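"""Polymer conformational states and cargo preference among them.

A polymer conformation is the pair of block end-to-end distances
(d_PEG, d_PLGA) of one polymer in one frame.  Conformations are embedded
with UMAP and clustered with HDBSCAN (clusters plus a noise label); because
the feature space is already two-dimensional the embedding can be bypassed.

The fractional enrichment of cluster i,

    eps_i = (n_i / n_total) / (N_i / N_environment)

compares the share of cargo-polymer contacts attributed to cluster i with
the cluster's abundance among polymers in the cargo's local environment;
values above 1 mean the cargo preferentially contacts that conformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import BootstrapSpec, frame_cluster_contact_stats, moving_block_bootstrap_ci
from .pbc import min_image_distance, minimum_image
from .topology import Topology
from .trajectory import Frame, Trajectory

__all__ = [
    "NOISE_LABEL",
    "EmbedParams",
    "ClusterParams",
    "ClusterAssignment",
    "IntrinsicDensityProfile",
    "FractionalEnrichmentResult",
    "block_end_to_end",
    "build_conformation_table",
    "embed_and_cluster",
    "intrinsic_density",
    "fractional_enrichment",
]

#: Label assigned to conformations left unclustered by HDBSCAN.
NOISE_LABEL = -1


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def block_end_to_end(
    frame: Frame, topology: Topology, polymer_id: int, block: str
) -> float:
    """End-to-end distance of one block of one polymer (Angstrom).

    The chain is unwrapped across periodic boundaries by accumulating
    minimum-image bond vectors along the monomer sequence, so a chain
    crossing the box edge gives the same value as its unwrapped copy.
    """
    beads = topology.beads_of_molecule(polymer_id)
    in_block = beads[topology.block[beads] == block]
    if len(in_block) < 2:
        raise ValueError(f"polymer {polymer_id} has <2 beads in block {block!r}")
    order = np.argsort(topology.monomer_index[in_block])
    pos = frame.positions[in_block[order]]
    bonds = minimum_image(np.diff(pos, axis=0), frame.box)
    return float(np.linalg.norm(bonds.sum(axis=0)))


def build_conformation_table(
    trajectory: Trajectory, frames: Sequence[int] | None = None
) -> pd.DataFrame:
    """One row of (frame, polymer_id, d_PEG, d_PLGA) per polymer per frame.

    Vectorized over polymers (all chains of a block share a bead count in
    the systems this package targets; ragged cases fall back to per-chain
    computation).
    """
    topo = trajectory.topology
    polymers = topo.molecules_of_class("polymer")
    if len(polymers) == 0:
        raise ValueError("no polymers in topology")
    frame_ids = list(range(trajectory.n_frames)) if frames is None else list(frames)

    # per-polymer ordered bead indices for each block
    block_beads: dict[str, list[np.ndarray]] = {"PEG": [], "PLGA": []}
    for m in polymers:
        beads = topo.beads_of_molecule(m)
        for blk in ("PEG", "PLGA"):
            sel = beads[topo.block[beads] == blk]
            sel = sel[np.argsort(topo.monomer_index[sel])]
            if len(sel) < 2:
                raise ValueError(f"polymer {m} lacks block {blk}")
            block_beads[blk].append(sel)

    rows = []
    uniform = {
        blk: len({len(s) for s in sel_list}) == 1
        for blk, sel_list in block_beads.items()
    }
    stacked = {
        blk: np.stack(block_beads[blk]) if uniform[blk] else None for blk in block_beads
    }
    for t in frame_ids:
        frame = trajectory.frames[t]
        d = {}
        for blk in ("PEG", "PLGA"):
            if stacked[blk] is not None:
                pos = frame.positions[stacked[blk]]          # (n_poly, n_mono, 3)
                bonds = minimum_image(np.diff(pos, axis=1), frame.box)
                d[blk] = np.linalg.norm(bonds.sum(axis=1), axis=1)
            else:
                d[blk] = np.array(
                    [block_end_to_end(frame, topo, m, blk) for m in polymers]
                )
        for k, m in enumerate(polymers):
            rows.append((t, int(m), d["PEG"][k], d["PLGA"][k]))
    return pd.DataFrame(rows, columns=["frame", "polymer_id", "d_PEG", "d_PLGA"])


# ---------------------------------------------------------------------------
# embedding + clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbedParams:
    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    seed: int = 0


@dataclass(frozen=True)
class ClusterParams:
    """HDBSCAN settings.  ``min_cluster_size=None`` resolves to
    max(25, 1% of rows).  ``allow_single_cluster`` and a small selection
    epsilon keep a homogeneous conformational ensemble from being shattered
    into spurious sub-clusters plus noise."""

    min_cluster_size: int | None = None
    min_samples: int = 10
    cluster_selection_epsilon: float = 0.5
    allow_single_cluster: bool = True


@dataclass
class ClusterAssignment:
    """Per-(frame, polymer) cluster labels (1..K, noise = -1) and summaries."""

    table: pd.DataFrame               # frame, polymer_id, label
    k: int
    noise_pct: float
    populations: pd.DataFrame         # label, population_pct, mean_d_PEG_A, mean_d_PLGA_A
    embedding: np.ndarray | None = field(repr=False, default=None)
    params: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def labels_for_frame(self, frame: int) -> dict[int, int]:
        sub = self.table[self.table["frame"] == frame]
        return dict(zip(sub["polymer_id"].astype(int), sub["label"].astype(int)))


def embed_and_cluster(
    table: pd.DataFrame,
    embed_params: EmbedParams = EmbedParams(),
    cluster_params: ClusterParams = ClusterParams(),
    use_embedding: bool = True,
) -> ClusterAssignment:
    """Cluster per-(frame, polymer) conformations.

    Features (d_PEG, d_PLGA) are z-scored, embedded with UMAP (unless
    ``use_embedding=False``, which clusters the standardized feature plane
    directly -- it is already two-dimensional) and clustered with HDBSCAN.
    Clusters are renumbered 1..K by descending population; unassigned rows
    carry :data:`NOISE_LABEL`.
    """
    from sklearn.cluster import HDBSCAN
    from sklearn.preprocessing import StandardScaler

    X = table[["d_PEG", "d_PLGA"]].to_numpy(dtype=float)
    n_rows = len(X)
    min_size = cluster_params.min_cluster_size
    if min_size is None:
        min_size = max(25, int(0.01 * n_rows))
    if n_rows < min_size:
        raise ValueError(f"{n_rows} rows < min_cluster_size {min_size}")
    Xs = StandardScaler().fit_transform(X)
    emb = None
    if use_embedding:
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_neighbors=embed_params.n_neighbors,
                min_dist=embed_params.min_dist,
                n_components=embed_params.n_components,
                random_state=embed_params.seed,
                n_jobs=1,
            )
            emb = reducer.fit_transform(Xs)
        space = emb
    else:
        space = Xs
    try:
        raw = HDBSCAN(
            min_cluster_size=min_size,
            min_samples=cluster_params.min_samples,
            cluster_selection_epsilon=cluster_params.cluster_selection_epsilon,
            allow_single_cluster=cluster_params.allow_single_cluster,
        ).fit_predict(space)
    except TypeError:
        # scikit-learn's epsilon search can fail on some condensed trees when
        # combined with allow_single_cluster; the epsilon smoothing only
        # matters for near-homogeneous data, so drop it and refit
        raw = HDBSCAN(
            min_cluster_size=min_size,
            min_samples=cluster_params.min_samples,
            allow_single_cluster=cluster_params.allow_single_cluster,
        ).fit_predict(space)

    # renumber clusters 1..K by descending population (ties by raw label)
    uniq, counts = np.unique(raw[raw >= 0], return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = np.array([mapping.get(int(r), NOISE_LABEL) for r in raw])
    k = len(order)
    noise_pct = 100.0 * np.mean(labels == NOISE_LABEL)

    out = table[["frame", "polymer_id"]].copy()
    out["label"] = labels
    pops = []
    for lab in range(1, k + 1):
        m = labels == lab
        pops.append({
            "label": lab,
            "population_pct": 100.0 * m.mean(),
            "mean_d_PEG_A": float(X[m, 0].mean()),
            "mean_d_PLGA_A": float(X[m, 1].mean()),
        })
    populations = pd.DataFrame(pops, columns=["label", "population_pct",
                                              "mean_d_PEG_A", "mean_d_PLGA_A"])
    return ClusterAssignment(
        table=out,
        k=k,
        noise_pct=float(noise_pct),
        populations=populations,
        embedding=emb,
        params={
            "use_embedding": use_embedding,
            "n_neighbors": embed_params.n_neighbors,
            "min_dist": embed_params.min_dist,
            "n_components": embed_params.n_components,
            "embed_seed": embed_params.seed,
            "min_cluster_size": min_size,
        },
    )


# ---------------------------------------------------------------------------
# intrinsic density
# ---------------------------------------------------------------------------

@dataclass
class IntrinsicDensityProfile:
    """Per-cluster density versus signed distance to the core-corona
    interface, normalized per cluster so that density x shell volume
    integrates to 1."""

    bin_edges: np.ndarray            # signed axis, Angstrom
    densities: dict[int, np.ndarray]
    core_radius: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def shell_volumes(self) -> np.ndarray:
        r = np.clip(self.bin_edges + self.core_radius, 0.0, None)
        return 4.0 / 3.0 * np.pi * (r[1:] ** 3 - r[:-1] ** 3)

    def mode_position(self, label: int) -> float:
        return float(self.bin_centers[int(np.argmax(self.densities[label]))])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab, dens in self.densities.items():
            for c, d in zip(self.bin_centers, dens):
                rows.append({"signed_r_A": c, "label": lab, "density": d})
        return pd.DataFrame(rows)


def intrinsic_density(
    trajectory: Trajectory,
    assignment: ClusterAssignment,
    core_radius: float,
    bin_width: float = 2.0,
    r_max: float | None = None,
    representative: str = "junction",
) -> IntrinsicDensityProfile:
    """Spatial distribution of each conformational cluster within the NP.

    Each (frame, polymer) is located by a representative point -- by
    default the PEG-PLGA junction (midpoint of the last PLGA bead and the
    first PEG bead); ``representative="com"`` uses the polymer COM.  Its
    signed distance to the interface (distance-to-NP-COM minus
    ``core_radius``) is histogrammed per cluster, divided by shell volumes
    and by the cluster's row count inside the profiled range.
    """
    from .structure import center_of_mass, np_center_of_mass

    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    topo = trajectory.topology
    box = trajectory.frames[0].box
    if r_max is None:
        r_max = float(box.min()) / 2.0
    edges = np.arange(np.ceil(r_max / bin_width) + 1) * bin_width - core_radius
    clusters = sorted(set(assignment.table["label"]) - {NOISE_LABEL})
    counts = {lab: np.zeros(len(edges) - 1) for lab in clusters}

    # representative-point bead pairs per polymer
    polymers = topo.molecules_of_class("polymer")
    junction: dict[int, tuple[int, int]] = {}
    for m in polymers:
        beads = topo.beads_of_molecule(m)
        plga = beads[topo.block[beads] == "PLGA"]
        peg = beads[topo.block[beads] == "PEG"]
        if len(plga) and len(peg):
            junction[int(m)] = (
                int(plga[np.argmax(topo.monomer_index[plga])]),
                int(peg[np.argmin(topo.monomer_index[peg])]),
            )

    by_frame = dict(tuple(assignment.table.groupby("frame")))
    for t, frame in enumerate(trajectory.frames):
        sub = by_frame.get(t)
        if sub is None:
            continue
        com = np_center_of_mass(frame, topo)
        for _, row in sub.iterrows():
            lab = int(row["label"])
            if lab == NOISE_LABEL:
                continue
            m = int(row["polymer_id"])
            if representative == "junction":
                b0, b1 = junction[m]
                p0 = frame.positions[b0]
                p1 = p0 + minimum_image(frame.positions[b1] - p0, frame.box)
                point = 0.5 * (p0 + p1)
            else:
                point = center_of_mass(frame, topo, topo.beads_of_molecule(m))
            signed = float(min_image_distance(point, com, frame.box)) - core_radius
            idx = int(np.searchsorted(edges, signed, side="right")) - 1
            if 0 <= idx < len(edges) - 1:
                counts[lab][idx] += 1
    vols = 4.0 / 3.0 * np.pi * (
        np.clip(edges[1:] + core_radius, 0, None) ** 3
        - np.clip(edges[:-1] + core_radius, 0, None) ** 3
    )
    densities = {}
    for lab in clusters:
        total = counts[lab].sum()
        if total == 0:
            warnings.warn(f"cluster {lab} has no rows inside the profiled range; omitted")
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            d = counts[lab] / (vols * total)
        d[vols == 0] = 0.0
        densities[lab] = d
    return IntrinsicDensityProfile(
        bin_edges=edges, densities=densities, core_radius=core_radius
    )


# ---------------------------------------------------------------------------
# fractional enrichment
# ---------------------------------------------------------------------------

@dataclass
class FractionalEnrichmentResult:
    """Fractional enrichment per cluster per cargo location.

    ``table`` columns: location, label, value, ci_low, ci_high, n_contacts,
    unreliable (flagged when a cluster's total contact count is below
    ``min_contacts``).  ``noise_contact_share`` is the share of contacts
    with unclustered polymers, reported separately because noise rows are
    excluded from the statistic.  ``per_frame`` maps location to the
    (T, K) per-frame enrichment samples.
    """

    table: pd.DataFrame
    noise_contact_share: dict[str, float]
    cutoff: float
    bootstrap: BootstrapSpec
    min_contacts: int
    per_frame: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    counts: pd.DataFrame | None = field(repr=False, default=None)

    def value(self, location: str, label: int) -> float:
        t = self.table
        row = t[(t["location"] == location) & (t["label"] == label)]
        return float(row["value"].iloc[0])

    def ci(self, location: str, label: int) -> tuple[float, float]:
        t = self.table
        row = t[(t["location"] == location) & (t["label"] == label)]
        return float(row["ci_low"].iloc[0]), float(row["ci_high"].iloc[0])


def enrichment_from_counts(n: Mapping[int, float], N: Mapping[int, float]) -> dict[int, float]:
    """Fractional enrichment from raw per-cluster counts.

    ``n[i]`` are cargo contacts attributed to cluster i and ``N[i]`` the
    cluster's polymers in the local environment;
    ``eps_i = (n_i / n_total) / (N_i / N_environment)``.  Clusters with
    ``N_i == 0`` are omitted.
    """
    n_tot = float(sum(n.values()))
    N_env = float(sum(N.values()))
    if n_tot <= 0 or N_env <= 0:
        raise ValueError("n_total and N_environment must be positive")
    return {
        lab: (n.get(lab, 0) / n_tot) / (Ni / N_env)
        for lab, Ni in N.items()
        if Ni > 0
    }


def fractional_enrichment(
    trajectory: Trajectory,
    assignment: ClusterAssignment,
    peptides: Sequence[int],
    location_labels: Mapping[int, str],
    cutoff: float = 6.0,
    ci: BootstrapSpec = BootstrapSpec(),
    min_contacts: int = 50,
) -> FractionalEnrichmentResult:
    """Cargo preference for polymer conformational clusters, by location.

    Per frame and cargo location, ``n_i`` counts contacts between the
    location's peptides and beads of polymers currently labelled cluster i,
    and ``N_i`` counts distinct polymers of cluster i with at least one bead
    in the peptides' local environment (same cutoff).  The per-frame
    ``eps_i = (n_i/n_total) / (N_i/N_env)`` is time averaged with a
    moving-block bootstrap CI.  Unclustered (noise) polymers are excluded
    from numerator and denominator; their contact share is reported
    separately.  Clusters whose total contact count stays below
    ``min_contacts`` are flagged unreliable.
    """
    topo = trajectory.topology
    locations: dict[str, list[int]] = {}
    for pep in peptides:
        loc = location_labels.get(int(pep))
        if loc is None:
            raise ValueError(f"peptide {pep} has no location label")
        locations.setdefault(loc, []).append(int(pep))
    clusters = sorted(set(assignment.table["label"]) - {NOISE_LABEL})
    T = trajectory.n_frames
    rows = []
    per_frame_by_loc: dict[str, np.ndarray] = {}
    noise_share: dict[str, float] = {}
    count_rows = []
    for loc, peps in sorted(locations.items()):
        pep_beads = np.concatenate([topo.beads_of_molecule(m) for m in peps])
        per_frame = np.full((T, len(clusters)), np.nan)
        total_n = np.zeros(len(clusters))
        noise_contacts = 0.0
        all_contacts = 0.0
        n_skipped = 0
        for t, frame in enumerate(trajectory.frames):
            labels_t = assignment.labels_for_frame(t)
            n, N = frame_cluster_contact_stats(frame, topo, pep_beads, labels_t, cutoff)
            noise_contacts += n.pop(NOISE_LABEL, 0)
            N.pop(NOISE_LABEL, None)
            n_tot = sum(n.values())
            N_env = sum(N.values())
            all_contacts += n_tot + 0.0
            if n_tot == 0 or N_env == 0:
                n_skipped += 1
                continue
            eps = enrichment_from_counts(n, N)
            for k, lab in enumerate(clusters):
                Ni = N.get(lab, 0)
                ni = n.get(lab, 0)
                total_n[k] += ni
                count_rows.append({"location": loc, "frame": t, "label": lab,
                                   "n_i": ni, "N_i": Ni,
                                   "n_total": n_tot, "N_environment": N_env})
                if lab in eps:
                    per_frame[t, k] = eps[lab]
        if n_skipped == T:
            warnings.warn(f"location {loc!r}: all frames skipped")
            continue
        if n_skipped:
            warnings.warn(f"location {loc!r}: {n_skipped} frame(s) skipped")
        values = np.nanmean(per_frame, axis=0)
        lo, hi = moving_block_bootstrap_ci(per_frame, ci)
        usable = T - n_skipped
        present = (~np.isnan(per_frame)).sum(axis=0)
        for k, lab in enumerate(clusters):
            # a cluster is statistically unreliable here when its total
            # contact count is small or it appears in too few frames for a
            # time average to mean anything
            shaky = (total_n[k] < min_contacts) or (present[k] < max(5, 0.1 * usable))
            rows.append({
                "location": loc,
                "label": lab,
                "value": values[k],
                "ci_low": np.atleast_1d(lo)[k],
                "ci_high": np.atleast_1d(hi)[k],
                "n_contacts": int(total_n[k]),
                "n_frames_present": int(present[k]),
                "unreliable": bool(shaky),
            })
        per_frame_by_loc[loc] = per_frame
        denom = noise_contacts + sum(total_n)
        noise_share[loc] = float(noise_contacts / denom) if denom else 0.0
    table = pd.DataFrame(rows, columns=["location", "label", "value", "ci_low",
                                        "ci_high", "n_contacts",
                                        "n_frames_present", "unreliable"])
    return FractionalEnrichmentResult(
        table=table,
        noise_contact_share=noise_share,
        cutoff=cutoff,
        bootstrap=ci,
        min_contacts=min_contacts,
        per_frame=per_frame_by_loc,
        counts=pd.DataFrame(count_rows),
    )
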