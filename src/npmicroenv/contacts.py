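"""Cargo-environment contact statistics.

Contacts are bead pairs strictly within a cutoff distance (minimum image).
The default cutoff of 6 A is a conventional coarse-grained contact distance
and is surfaced in every result object, since enrichment values are only
meaningful alongside the cutoff that produced them.

Confidence intervals on time-averaged enrichment values use a moving-block
bootstrap over frames: molecular time series are autocorrelated, and an iid
resample would understate the interval width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pbc import pairs_within
from .topology import Topology
from .trajectory import Frame, Trajectory

__all__ = [
    "BootstrapSpec",
    "ContactEnrichmentResult",
    "EnvironmentACF",
    "moving_block_bootstrap_ci",
    "count_contacts",
    "contact_records",
    "per_residue_contact_difference",
    "contact_enrichment",
    "local_environment",
    "environment_acf",
    "radial_shell_region",
    "frame_cluster_contact_stats",
]


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapSpec:
    """Moving-block bootstrap parameters for time-series CIs."""

    block_length: int = 10
    n_resamples: int = 1000
    confidence: float = 0.90
    seed: int = 0


def moving_block_bootstrap_ci(
    samples: np.ndarray, spec: BootstrapSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile CI of the time mean of per-frame samples.

    ``samples`` has shape (T,) or (T, k); NaN entries (frames where a
    quantity is undefined) are ignored via nanmean.  Returns (low, high)
    arrays of shape () or (k,).
    """
    samples = np.asarray(samples, dtype=float)
    T = samples.shape[0]
    L = max(1, min(spec.block_length, T))
    n_blocks = int(np.ceil(T / L))
    rng = np.random.default_rng(spec.seed)
    starts = rng.integers(0, T - L + 1, size=(spec.n_resamples, n_blocks))
    idx = (starts[:, :, None] + np.arange(L)[None, None, :]).reshape(spec.n_resamples, -1)
    idx = idx[:, :T]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN resample columns
        means = np.nanmean(samples[idx], axis=1)
    alpha = (1.0 - spec.confidence) / 2.0
    lo = np.nanpercentile(means, 100 * alpha, axis=0)
    hi = np.nanpercentile(means, 100 * (1 - alpha), axis=0)
    return lo, hi


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ContactEnrichmentResult:
    """Per-species contact enrichment with bootstrap CI.

    ``table`` columns: species, value, ci_low, ci_high.  ``per_frame`` holds
    the underlying per-frame enrichment samples (T, n_species), NaN where a
    frame was skipped.
    """

    location: str
    table: pd.DataFrame
    n_frames: int
    cutoff: float
    bootstrap: BootstrapSpec
    per_frame: np.ndarray = field(repr=False, default=None)

    def value(self, species: str) -> float:
        return float(self.table.set_index("species").loc[species, "value"])


@dataclass
class EnvironmentACF:
    """Autocorrelation of a peptide's local polymer environment identity."""

    peptide: int
    lags: np.ndarray
    acf: np.ndarray
    cutoff: float
    lag_times: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"peptide": self.peptide, "lag": self.lags, "acf": self.acf}
        )


# ---------------------------------------------------------------------------
# contact counting
# ---------------------------------------------------------------------------

def count_contacts(
    frame: Frame,
    topology: Topology,
    group_a,
    group_b,
    cutoff: float,
) -> int:
    """Number of (a, b) bead pairs strictly within ``cutoff`` (min image).

    Groups must be disjoint.  Uses a periodic k-d tree, not an all-pairs
    scan, so it scales to large bead counts.
    """
    a = np.asarray(sorted(group_a) if isinstance(group_a, set) else group_a, dtype=int)
    b = np.asarray(sorted(group_b) if isinstance(group_b, set) else group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise ValueError("contact groups must be disjoint")
    ii, _ = pairs_within(frame.positions[a], frame.positions[b], frame.box, cutoff)
    return int(len(ii))


def contact_records(
    trajectory: Trajectory,
    peptides: Sequence[int],
    counterpart_beads,
    cutoff: float,
    label_of_bead: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame, per-peptide contact counts with counterpart beads.

    ``label_of_bead`` optionally maps counterpart bead positions to a label
    (species or cluster); counts are then split by label.  Returns a tidy
    frame (frame, peptide, label, count).
    """
    topo = trajectory.topology
    cp = np.asarray(sorted(counterpart_beads) if isinstance(counterpart_beads, set)
                    else counterpart_beads, dtype=int)
    rows = []
    for t, frame in enumerate(trajectory.frames):
        for pep in peptides:
            pb = topo.beads_of_molecule(pep)
            ii, jj = pairs_within(
                frame.positions[pb], frame.positions[cp], frame.box, cutoff
            )
            if label_of_bead is None:
                rows.append({"frame": t, "peptide": pep, "label": "all",
                             "count": len(ii)})
            else:
                labels = label_of_bead[cp[jj]]
                for lab, cnt in zip(*np.unique(labels, return_counts=True)):
                    rows.append({"frame": t, "peptide": pep, "label": lab,
                                 "count": int(cnt)})
    return pd.DataFrame(rows, columns=["frame", "peptide", "label", "count"])


# ---------------------------------------------------------------------------
# per-residue differences
# ---------------------------------------------------------------------------

def per_residue_contact_difference(
    trajectory: Trajectory,
    peptides_core: Sequence[int],
    peptides_interface: Sequence[int],
    counterpart: str = "water",
    cutoff: float = 6.0,
) -> pd.Series:
    """Difference of time-averaged per-residue contacts, core - interface.

    For each residue label, the mean contact count per residue bead over
    core peptides minus the same over interface peptides.  Positive values
    mean more contacts for the core-resident cargo.  All peptides must
    share one residue-label sequence.
    """
    topo = trajectory.topology
    core = sorted(peptides_core)
    interface = sorted(peptides_interface)
    if not core or not interface:
        raise ValueError("both peptide groups must be non-empty")
    if counterpart == "water":
        cp = topo.select(molecule_class="water")
    elif counterpart == "polymer":
        cp = topo.select(molecule_class="polymer")
    else:
        raise ValueError("counterpart must be 'water' or 'polymer'")
    seqs = {m: tuple(topo.species[topo.beads_of_molecule(m)]) for m in core + interface}
    ref_seq = seqs[core[0]]
    if any(s != ref_seq for s in seqs.values()):
        raise ValueError("peptides do not share a common residue-label sequence")

    def group_mean(group):
        # mean contacts per bead, averaged over frames and group members,
        # aggregated by residue label
        per_bead = np.zeros(len(ref_seq))
        for frame in trajectory.frames:
            for m in group:
                pb = topo.beads_of_molecule(m)
                ii, _ = pairs_within(
                    frame.positions[pb], frame.positions[cp], frame.box, cutoff
                )
                np.add.at(per_bead, ii, 1)
        per_bead /= len(group) * trajectory.n_frames
        return per_bead

    diff = group_mean(core) - group_mean(interface)
    out = pd.Series(diff, index=list(ref_seq), name="contact_difference")
    return out.groupby(level=0, sort=False).mean()


# ---------------------------------------------------------------------------
# contact enrichment (species level)
# ---------------------------------------------------------------------------

def radial_shell_region(r_min: float, r_max: float, beads=None):
    """Region predicate: beads whose distance to the NP COM lies in
    ``[r_min, r_max)``; optionally restricted to a base bead selection."""
    from .structure import np_center_of_mass
    from .pbc import min_image_distance

    base = None if beads is None else np.asarray(sorted(beads) if isinstance(beads, set)
                                                 else beads, dtype=int)

    def region(frame: Frame, topology: Topology) -> np.ndarray:
        sel = topology.bead_id if base is None else base
        com = np_center_of_mass(frame, topology)
        d = min_image_distance(frame.positions[sel], com, frame.box)
        return sel[(d >= r_min) & (d < r_max)]

    return region


def contact_enrichment(
    trajectory: Trajectory,
    peptides: Sequence[int],
    environment_region,
    species_list: Sequence[str],
    cutoff: float = 6.0,
    ci: BootstrapSpec = BootstrapSpec(),
    location: str = "",
) -> ContactEnrichmentResult:
    """Per-species contact enrichment of cargo within an environment region.

    Per frame, ``e_s = (n_s / sum n) / (B_s / sum B)`` where ``n_s`` is the
    number of peptide contacts with beads of species ``s`` in the region and
    ``B_s`` the number of region beads of that species.  Values above 1 mean
    the cargo contacts the species more than its local abundance predicts.
    Frames with zero total contacts are skipped with a warning; the reported
    value is the time average with a moving-block bootstrap CI.
    """
    topo = trajectory.topology
    peptides = sorted(peptides)
    species_list = list(species_list)
    pep_beads = np.concatenate([topo.beads_of_molecule(m) for m in peptides])
    T = trajectory.n_frames
    per_frame = np.full((T, len(species_list)), np.nan)
    n_skipped = 0
    for t, frame in enumerate(trajectory.frames):
        env = np.asarray(environment_region(frame, topo), dtype=int) \
            if callable(environment_region) else np.asarray(
                sorted(environment_region) if isinstance(environment_region, set)
                else environment_region, dtype=int)
        env = np.setdiff1d(env, pep_beads, assume_unique=False)
        env_species = topo.species[env]
        B = np.array([np.sum(env_species == s) for s in species_list], dtype=float)
        if B.sum() == 0:
            n_skipped += 1
            continue
        ii, jj = pairs_within(
            frame.positions[pep_beads], frame.positions[env], frame.box, cutoff
        )
        contact_species = env_species[jj]
        n = np.array([np.sum(contact_species == s) for s in species_list], dtype=float)
        if n.sum() == 0:
            n_skipped += 1
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            e = (n / n.sum()) / (B / B.sum())
        e[B == 0] = np.nan  # species absent from the region this frame
        per_frame[t] = e
    if n_skipped:
        warnings.warn(f"{n_skipped} frame(s) skipped (no contacts or empty region)")
    if np.all(np.isnan(per_frame)):
        raise ValueError("all frames skipped: no contacts in any frame")
    values = np.nanmean(per_frame, axis=0)
    lo, hi = moving_block_bootstrap_ci(per_frame, ci)
    table = pd.DataFrame(
        {"species": species_list, "value": values, "ci_low": lo, "ci_high": hi}
    )
    return ContactEnrichmentResult(
        location=location,
        table=table,
        n_frames=T - n_skipped,
        cutoff=cutoff,
        bootstrap=ci,
        per_frame=per_frame,
    )


# ---------------------------------------------------------------------------
# local environment and its ACF
# ---------------------------------------------------------------------------

def local_environment(
    frame: Frame, topology: Topology, peptide: int, cutoff: float
) -> set[int]:
    """Polymer bead ids strictly within ``cutoff`` of any bead of a peptide."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pb = topology.beads_of_molecule(peptide)
    poly = topology.select(molecule_class="polymer")
    if len(poly) == 0:
        return set()
    _, jj = pairs_within(frame.positions[pb], frame.positions[poly], frame.box, cutoff)
    return set(int(b) for b in poly[np.unique(jj)])


def environment_acf(
    trajectory: Trajectory,
    peptide: int,
    cutoff: float = 6.0,
    max_lag: int = 20,
) -> EnvironmentACF:
    """Autocorrelation of the local-environment identity over lag time.

    ``A(tau)`` is the mean Jaccard index between the polymer-bead-id sets
    at times ``t`` and ``t + tau`` (two empty sets count as identical);
    1 means a frozen environment, 0 complete exchange.
    """
    if max_lag >= trajectory.n_frames:
        raise ValueError("max_lag must be smaller than the number of frames")
    envs = [
        local_environment(frame, trajectory.topology, peptide, cutoff)
        for frame in trajectory.frames
    ]
    lags = np.arange(max_lag + 1)
    acf = np.empty(len(lags))
    for k, tau in enumerate(lags):
        vals = []
        for t in range(len(envs) - tau):
            a, b = envs[t], envs[t + tau]
            union = len(a | b)
            vals.append(1.0 if union == 0 else len(a & b) / union)
        acf[k] = float(np.mean(vals))
    times = trajectory.times
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    return EnvironmentACF(
        peptide=peptide, lags=lags, acf=acf, cutoff=cutoff, lag_times=lags * dt
    )


# ---------------------------------------------------------------------------
# shared per-frame cluster contact statistics
# ---------------------------------------------------------------------------

def frame_cluster_contact_stats(
    frame: Frame,
    topology: Topology,
    peptide_beads: np.ndarray,
    polymer_labels: Mapping[int, int],
    cutoff: float,
) -> tuple[dict[int, int], dict[int, int]]:
    """Per-cluster contact counts and environment membership in one frame.

    Returns ``(n, N)``: ``n[i]`` is the number of peptide-polymer bead
    contacts with polymers labelled ``i``; ``N[i]`` the number of distinct
    polymers labelled ``i`` having at least one bead strictly within
    ``cutoff`` of the peptide selection.  Used by both the fractional
    enrichment statistic and the synthetic planting machinery so the two
    sides share one definition.
    """
    poly_beads = topology.select(molecule_class="polymer")
    ii, jj = pairs_within(
        frame.positions[peptide_beads], frame.positions[poly_beads], frame.box, cutoff
    )
    mol_of = topology.molecule_id
    n: dict[int, int] = {}
    env_mols: set[int] = set()
    for j in jj:
        mol = int(mol_of[poly_beads[j]])
        env_mols.add(mol)
        lab = polymer_labels.get(mol)
        if lab is None:
            continue
        n[lab] = n.get(lab, 0) + 1
    N: dict[int, int] = {}
    for mol in env_mols:
        lab = polymer_labels.get(mol)
        if lab is None:
            continue
        N[lab] = N.get(lab, 0) + 1
    return n, N
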