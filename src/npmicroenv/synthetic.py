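"""Synthetic core-shell nanoparticle configurations with planted ground truth.

The generator emulates the assembled state of a PEG-PLGA micelle carrying
peptide cargo: PLGA blocks fill a spherical hydrophobic core around a small
trapped-water nucleus, PEG blocks extend outward into the corona (or wrap
the nucleus, for polymers assigned to a planted core-interior state),
peptides sit at the nucleus surface or at the core-corona interface, and
water beads occupy the nucleus and the exterior.  Every recoverable
quantity -- conformational cluster labels, core radius, cargo locations,
contact-enrichment factors -- is planted explicitly so the downstream
analysis modules can be validated against known truth.

Polymers are built as pinned random bridges with prescribed block
end-to-end distances, not physical chains: only the observables the
analysis measures need to be realistic.  Peptide cargo is re-attached to a
nearby polymer every frame by a feedback controller that steers the
realized per-cluster contact enrichment toward its planted value (1.0
everywhere by default), using the very same contact definitions the
analysis applies; this is what makes planted enrichment factors
recoverable rather than merely approximate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .contacts import frame_cluster_contact_stats
from .pbc import min_image_distance, pairs_within, periodic_tree, wrap_positions
from .topology import DEFAULT_BEAD_MASS, Topology
from .trajectory import Frame, Trajectory

import pandas as pd

__all__ = [
    "ClusterState",
    "SyntheticParams",
    "GroundTruth",
    "GenerationError",
    "default_cluster_spec",
    "scaled_params",
    "sample_conformations",
    "generate_configuration",
    "generate_trajectory",
    "plant_contact_enrichment",
]


class GenerationError(ValueError):
    """Raised when a configuration cannot be generated as requested."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterState:
    """One planted conformational state.

    ``location`` says where polymers of this state anchor their PEG-PLGA
    junction: at the core-corona interface, or at the trapped-water nucleus
    surface (``core_interior``, the state whose extended PEG shields the
    nucleus).
    """

    fraction: float
    mean_d_peg: float
    mean_d_plga: float
    sd: float
    location: str = "interface"

    def __post_init__(self):
        if self.location not in ("interface", "core_interior"):
            raise GenerationError(f"unknown cluster location {self.location!r}")


def default_cluster_spec() -> tuple[ClusterState, ...]:
    """Four planted states: collapsed/extended PEG x PLGA combinations.

    Fractions descend so planted labels match the population-rank labels the
    clustering module assigns.  The least frequent state anchors at the
    water-nucleus surface.
    """
    return (
        ClusterState(0.40, 20.0, 45.0, 2.0, "interface"),
        ClusterState(0.25, 50.0, 18.0, 2.0, "interface"),
        ClusterState(0.25, 20.0, 18.0, 2.0, "interface"),
        ClusterState(0.10, 55.0, 45.0, 2.0, "core_interior"),
    )


def _scaled_cluster_spec() -> tuple[ClusterState, ...]:
    return (
        ClusterState(0.40, 12.0, 20.0, 1.2, "interface"),
        ClusterState(0.25, 28.0, 8.0, 1.2, "interface"),
        ClusterState(0.25, 12.0, 8.0, 1.2, "interface"),
        ClusterState(0.10, 30.0, 24.0, 1.2, "core_interior"),
    )


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults mirror the reference formulation
    (200 diblock copolymers, 15 peptides, 58 nm box, PEG ~114 EO monomers
    from Mn 5000, PLGA ~108 monomers from Mn 7000 at 1:1 LA:GA)."""

    n_polymers: int = 200
    n_peptides: int = 15
    n_peg_monomers: int = 114
    n_plga_monomers: int = 108
    core_radius: float = 70.0
    corona_thickness: float = 30.0
    water_nucleus_radius: float = 12.0
    box: float = 580.0
    cluster_spec: tuple = field(default_factory=default_cluster_spec)
    peptide_placement: tuple | None = None   # None -> 2 core_center + rest interface
    contact_bias: float = 1.0
    bias_cluster: int | None = None
    species_bias: tuple | None = None        # (species, factor)
    species_bias_location: str = "interface"
    n_frames: int = 50
    frame_noise: float = 1.0
    drift_amplitude: float = 0.0
    drift_tau: float = 10.0                  # frames
    frame_dt_ns: float = 1.0
    water_density: float = 0.008             # beads/A^3 in the nucleus
    n_exterior_water: int = 1500
    contact_cutoff: float = 6.0              # used by the placement controller
    peptide_sequence: tuple = ("GLU", "LYS", "ALA", "LEU") * 4
    seed: int = 0

    def normalized_cluster_spec(self) -> tuple[ClusterState, ...]:
        out = []
        for c in self.cluster_spec:
            out.append(c if isinstance(c, ClusterState) else ClusterState(*c))
        return tuple(out)

    def resolved_placement(self) -> tuple[str, ...]:
        if self.peptide_placement is not None:
            return tuple(self.peptide_placement)
        n_core = min(2, self.n_peptides)
        return ("core_center",) * n_core + ("interface",) * (self.n_peptides - n_core)

    def validate(self) -> list[str]:
        """Parameter-domain violations (empty list when valid)."""
        v = []
        for name in ("n_polymers", "n_peptides", "n_frames", "n_exterior_water"):
            if getattr(self, name) < 0:
                v.append(f"{name} must be >= 0")
        if self.n_frames < 1:
            v.append("n_frames must be >= 1")
        for name in ("n_peg_monomers", "n_plga_monomers"):
            if getattr(self, name) < 2:
                v.append(f"{name} must be >= 2")
        for name in ("core_radius", "corona_thickness", "water_nucleus_radius",
                     "box", "contact_cutoff", "frame_dt_ns"):
            if getattr(self, name) <= 0:
                v.append(f"{name} must be > 0")
        if self.frame_noise < 0:
            v.append("frame_noise must be >= 0")
        if self.drift_amplitude < 0:
            v.append("drift_amplitude must be >= 0")
        if self.drift_tau <= 0:
            v.append("drift_tau must be > 0")
        if self.core_radius + self.corona_thickness >= self.box / 2:
            v.append("core_radius + corona_thickness must be < box/2")
        if self.water_nucleus_radius >= self.core_radius:
            v.append("water_nucleus_radius must be < core_radius")
        if self.contact_bias < 0:
            v.append("contact_bias must be >= 0")
        spec = self.normalized_cluster_spec()
        if self.n_polymers > 0:
            if not spec:
                v.append("cluster_spec must be non-empty when polymers are present")
            elif abs(sum(c.fraction for c in spec) - 1.0) > 1e-9:
                v.append("cluster_spec fractions must sum to 1")
            # PLGA lengths exceeding the nucleus-to-core span are clipped at
            # generation (only the realized distances matter downstream), so
            # they are not validation errors; impossible values are
            for i, c in enumerate(spec, start=1):
                if c.mean_d_plga <= 0 or c.mean_d_peg <= 0 or c.sd < 0:
                    v.append(f"cluster {i}: distances must be positive, sd >= 0")
                if not 0 < c.fraction <= 1:
                    v.append(f"cluster {i}: fraction must be in (0, 1]")
        placement = self.resolved_placement()
        if len(placement) != self.n_peptides:
            v.append("peptide_placement length must equal n_peptides")
        if any(p not in ("core_center", "interface") for p in placement):
            v.append("peptide_placement entries must be core_center or interface")
        if self.bias_cluster is not None and self.n_polymers > 0:
            if not (1 <= self.bias_cluster <= len(spec)):
                v.append("bias_cluster out of range")
        return v


def scaled_params(**overrides) -> SyntheticParams:
    """Desk-scale configuration used throughout the test-suite examples.

    A geometrically similar particle at roughly one-third linear scale:
    80 polymers of 30+30 monomers, core radius 40 A, nucleus 10 A,
    box 160 A, 15 peptides (2 at the nucleus, 13 at the interface).
    """
    base = dict(
        n_polymers=80,
        n_peptides=15,
        n_peg_monomers=30,
        n_plga_monomers=30,
        core_radius=40.0,
        corona_thickness=18.0,
        water_nucleus_radius=10.0,
        box=160.0,
        cluster_spec=_scaled_cluster_spec(),
        n_frames=60,
        frame_noise=0.8,
        n_exterior_water=800,
    )
    base.update(overrides)
    return SyntheticParams(**base)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted truth for one generated system."""

    polymer_labels: np.ndarray              # (n_polymers,) labels 1..K
    peptide_locations: list[str]            # "core" | "interface" per peptide
    enrichment_factor: dict                 # {cluster label: planted factor}
    true_core_radius: float
    seed: int
    # plumbing needed to re-run cargo placement (plant_contact_enrichment)
    peptide_anchors: np.ndarray = field(repr=False, default=None)
    peptide_templates: np.ndarray = field(repr=False, default=None)
    cluster_locations: dict = field(default_factory=dict)
    polymer_junctions: np.ndarray = field(repr=False, default=None)

    def junctions_by_region(self) -> dict:
        """PEG-PLGA junction points grouped by cargo region (core/interface)."""
        out: dict[str, list] = {"core": [], "interface": []}
        if self.polymer_junctions is None:
            return {k: np.empty((0, 3)) for k in out}
        for lab, j in zip(self.polymer_labels, self.polymer_junctions):
            loc = self.cluster_locations.get(int(lab), "interface")
            key = "core" if loc == "core_interior" else "interface"
            out[key].append(j)
        return {k: np.asarray(v, dtype=float).reshape(-1, 3) for k, v in out.items()}

    def to_json(self, path) -> None:
        obj = {
            "polymer_labels": np.asarray(self.polymer_labels).tolist(),
            "peptide_locations": list(self.peptide_locations),
            "enrichment_factor": {str(k): v for k, v in self.enrichment_factor.items()},
            "true_core_radius": self.true_core_radius,
            "seed": self.seed,
            "peptide_anchors": np.asarray(self.peptide_anchors).tolist()
            if self.peptide_anchors is not None else None,
            "peptide_templates": np.asarray(self.peptide_templates).tolist()
            if self.peptide_templates is not None else None,
            "cluster_locations": {str(k): v for k, v in self.cluster_locations.items()},
            "polymer_junctions": np.asarray(self.polymer_junctions).tolist()
            if self.polymer_junctions is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            polymer_labels=np.asarray(obj["polymer_labels"], dtype=int),
            peptide_locations=list(obj["peptide_locations"]),
            enrichment_factor={int(k): v for k, v in obj["enrichment_factor"].items()},
            true_core_radius=float(obj["true_core_radius"]),
            seed=int(obj["seed"]),
            peptide_anchors=np.asarray(obj["peptide_anchors"], dtype=float)
            if obj.get("peptide_anchors") is not None else None,
            peptide_templates=np.asarray(obj["peptide_templates"], dtype=float)
            if obj.get("peptide_templates") is not None else None,
            cluster_locations={int(k): v for k, v in obj.get("cluster_locations", {}).items()},
            polymer_junctions=np.asarray(obj["polymer_junctions"], dtype=float)
            if obj.get("polymer_junctions") is not None else None,
        )


# ---------------------------------------------------------------------------
# low-level geometry
# ---------------------------------------------------------------------------

def _unit_vectors(rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _bridge_chain(a: np.ndarray, b: np.ndarray, n: int, wiggle: float, rng) -> np.ndarray:
    """Random bridge of ``n`` beads pinned exactly at ``a`` and ``b``."""
    base = np.linspace(a, b, n)
    if wiggle > 0 and n > 2:
        w = rng.normal(0.0, wiggle, size=(n, 3)).cumsum(axis=0)
        w -= np.outer(np.linspace(0.0, 1.0, n), w[-1])
        w[0] = 0.0
        base = base + w
    return base


def _clamp_radial(pts: np.ndarray, center: np.ndarray, rmin: float, rmax: float) -> np.ndarray:
    """Clamp interior beads into a radial shell; endpoints untouched."""
    if len(pts) <= 2:
        return pts
    rel = pts[1:-1] - center
    r = np.linalg.norm(rel, axis=1)
    r_safe = np.where(r < 1e-12, 1.0, r)
    scale = np.clip(r, rmin, rmax) / r_safe
    pts[1:-1] = center + rel * scale[:, None]
    return pts


def sample_conformations(
    cluster_spec: Sequence[ClusterState],
    n_samples: int,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (d_PEG, d_PLGA) features and labels from the planted mixture.

    Label counts are deterministic (fractions x n, largest-remainder) so the
    planted populations are exact; the assignment of labels to rows is a
    random permutation.
    """
    spec = [c if isinstance(c, ClusterState) else ClusterState(*c) for c in cluster_spec]
    fracs = np.array([c.fraction for c in spec])
    counts = np.floor(fracs * n_samples).astype(int)
    remainder = n_samples - counts.sum()
    if remainder > 0:
        order = np.argsort(-(fracs * n_samples - counts), kind="stable")
        counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(1, len(spec) + 1), counts)
    labels = labels[rng.permutation(n_samples)]
    feats = np.empty((n_samples, 2))
    for k, c in enumerate(spec, start=1):
        m = labels == k
        feats[m, 0] = rng.normal(c.mean_d_peg, c.sd, size=m.sum())
        feats[m, 1] = rng.normal(c.mean_d_plga, c.sd, size=m.sum())
    np.clip(feats, 2.0, None, out=feats)
    return feats, labels


# ---------------------------------------------------------------------------
# structure assembly
# ---------------------------------------------------------------------------

class _Structure:
    """Base configuration (frame-0 coordinates, topology, planted truth)."""

    def __init__(self, params: SyntheticParams):
        violations = params.validate()
        if violations:
            raise GenerationError("; ".join(violations))
        self.params = params
        ss = np.random.SeedSequence(params.seed)
        (self.rng_labels, self.rng_chains, self.rng_peptides,
         self.rng_water, self.rng_frames, self.rng_controller) = [
            np.random.default_rng(s) for s in ss.spawn(6)
        ]
        self.center = np.full(3, params.box / 2.0)
        self.spec = params.normalized_cluster_spec()
        self._build()

    # -- assembly ---------------------------------------------------------
    def _build(self) -> None:
        p = self.params
        rows_class: list[str] = []
        rows_species: list[str] = []
        rows_block: list[str] = []
        rows_mono: list[int] = []
        rows_mol: list[int] = []
        coords: list[np.ndarray] = []
        mol_id = 0

        # polymers
        if p.n_polymers > 0:
            feats, labels = sample_conformations(self.spec, p.n_polymers, self.rng_labels)
            self.polymer_labels = labels
            self.polymer_features = feats
        else:
            self.polymer_labels = np.empty(0, dtype=int)
            self.polymer_features = np.empty((0, 2))
        self.polymer_mol_ids = []
        self.junction_positions = []
        # antithetic direction pairs within each cluster keep the particle's
        # mass distribution centrosymmetric, so the NP COM stays at the
        # construction center
        directions = np.empty((p.n_polymers, 3))
        for lab in np.unique(self.polymer_labels) if p.n_polymers else []:
            idx = np.flatnonzero(self.polymer_labels == lab)
            half = _unit_vectors(self.rng_chains, (len(idx) + 1) // 2)
            paired = np.empty((len(idx), 3))
            paired[0::2] = half[: len(paired[0::2])]
            paired[1::2] = -half[: len(paired[1::2])]
            directions[idx] = paired
        for k in range(p.n_polymers):
            state = self.spec[self.polymer_labels[k] - 1]
            d_peg, d_plga = self.polymer_features[k]
            pos_plga, pos_peg, junction = self._build_polymer(
                state, d_peg, d_plga, directions[k]
            )
            n_pl, n_pe = p.n_plga_monomers, p.n_peg_monomers
            coords.append(pos_plga)
            coords.append(pos_peg)
            rows_class += ["polymer"] * (n_pl + n_pe)
            rows_species += ["LA" if i % 2 == 0 else "GA" for i in range(n_pl)]
            rows_species += ["EO"] * n_pe
            rows_block += ["PLGA"] * n_pl + ["PEG"] * n_pe
            rows_mono += list(range(n_pl)) + list(range(n_pe))
            rows_mol += [mol_id] * (n_pl + n_pe)
            self.polymer_mol_ids.append(mol_id)
            self.junction_positions.append(junction)
            mol_id += 1

        # peptides
        placement = p.resolved_placement()
        self.peptide_mol_ids = []
        self.peptide_locations = []
        self.peptide_anchors = np.empty((p.n_peptides, 3))
        n_pb = len(p.peptide_sequence)
        self.peptide_templates = np.empty((p.n_peptides, n_pb, 3))
        core_junctions = [
            self.junction_positions[k]
            for k in range(p.n_polymers)
            if self.spec[self.polymer_labels[k] - 1].location == "core_interior"
        ]
        iface_junctions = [
            self.junction_positions[k]
            for k in range(p.n_polymers)
            if self.spec[self.polymer_labels[k] - 1].location == "interface"
        ]
        for j, place in enumerate(placement):
            anchor = self._peptide_anchor(place, core_junctions, iface_junctions)
            self.peptide_anchors[j] = anchor
            self.peptide_templates[j] = self._peptide_template(n_pb)
            self.peptide_locations.append("core" if place == "core_center" else "interface")
            coords.append(self.peptide_templates[j] + anchor)  # provisional
            rows_class += ["peptide"] * n_pb
            rows_species += list(p.peptide_sequence)
            rows_block += ["none"] * n_pb
            rows_mono += list(range(n_pb))
            rows_mol += [mol_id] * n_pb
            self.peptide_mol_ids.append(mol_id)
            mol_id += 1

        # water: nucleus + exterior
        nuc_vol = 4.0 / 3.0 * np.pi * p.water_nucleus_radius**3
        n_nuc = int(round(p.water_density * nuc_vol)) if p.n_polymers > 0 else 0
        water = []
        if n_nuc > 0:
            dirs = _unit_vectors(self.rng_water, n_nuc)
            radii = p.water_nucleus_radius * self.rng_water.random(n_nuc) ** (1 / 3)
            water.append(self.center + dirs * radii[:, None])
        if p.n_exterior_water > 0:
            water.append(self._exterior_water(p.n_exterior_water))
        if not water and p.n_polymers == 0 and p.n_peptides == 0:
            raise GenerationError("empty system: no polymers, peptides or water")
        for w in water:
            n_w = len(w)
            coords.append(w)
            rows_class += ["water"] * n_w
            rows_species += ["W"] * n_w
            rows_block += ["none"] * n_w
            rows_mono += [0] * n_w
            rows_mol += list(range(mol_id, mol_id + n_w))
            mol_id += n_w

        self.positions0 = np.concatenate(coords) if coords else np.empty((0, 3))
        n_beads = len(self.positions0)
        self.topology = Topology(pd.DataFrame({
            "bead_id": np.arange(n_beads),
            "molecule_id": rows_mol,
            "molecule_class": rows_class,
            "species": rows_species,
            "block": rows_block,
            "monomer_index": rows_mono,
            "mass": DEFAULT_BEAD_MASS,
        }))
        self.peptide_beads = [
            self.topology.beads_of_molecule(m) for m in self.peptide_mol_ids
        ]

    def _build_polymer(self, state: ClusterState, d_peg: float, d_plga: float,
                       u: np.ndarray):
        p = self.params
        rng = self.rng_chains
        wiggle = 0.8
        gap = 2.0
        if state.location == "interface":
            r_j = p.core_radius
            d_plga = min(d_plga, p.core_radius - p.water_nucleus_radius - 2.5)
            junction = self.center + r_j * u
            # PLGA terminus sits just inside the boundary so the block stays
            # within the core; PEG starts just outside it
            plga_end = self.center + (r_j - 1.5) * u
            inner = self.center + (r_j - 1.5 - d_plga) * u
            pos_plga = _bridge_chain(inner, plga_end, p.n_plga_monomers, wiggle, rng)
            _clamp_radial(pos_plga, self.center,
                          p.water_nucleus_radius + 0.5, p.core_radius - 0.5)
            peg_start = junction + gap * u
            peg_end = junction + (gap + d_peg) * u
            pos_peg = _bridge_chain(peg_start, peg_end, p.n_peg_monomers, wiggle, rng)
            _clamp_radial(pos_peg, self.center, p.core_radius,
                          p.core_radius + p.corona_thickness + d_peg)
        else:
            # core_interior: junctions spread over a band just outside the
            # nucleus (a single thin shell would blanket the core cargo's
            # whole local environment); both blocks head outward, tilted
            # just enough to fit their full end-to-end distance in the core
            r_j = p.water_nucleus_radius + 3.0 + rng.uniform(0.0, 6.0)
            junction = self.center + r_j * u
            v = self._fit_tilt(rng, u, r_j, d_plga, p.core_radius - 1.0)
            outer = junction + d_plga * v
            pos_plga = _bridge_chain(outer, junction, p.n_plga_monomers, wiggle, rng)
            _clamp_radial(pos_plga, self.center,
                          p.water_nucleus_radius + 0.5, p.core_radius - 0.5)
            w = self._fit_tilt(rng, u, r_j, gap + d_peg, p.core_radius - 1.0)
            peg_start = junction + gap * w
            peg_end = junction + (gap + d_peg) * w
            pos_peg = _bridge_chain(peg_start, peg_end, p.n_peg_monomers, wiggle, rng)
            _clamp_radial(pos_peg, self.center,
                          p.water_nucleus_radius + 0.5, p.core_radius - 0.5)
        return pos_plga, pos_peg, junction.copy()

    @staticmethod
    def _fit_tilt(rng, u: np.ndarray, r_j: float, d: float, r_max: float) -> np.ndarray:
        """Direction for a block of length ``d`` leaving a junction at radius
        ``r_j`` (along ``u``) such that its far end stays inside ``r_max``;
        tilted off the radial direction by a small random extra angle."""
        t1 = np.cross(u, _unit_vectors(rng, 1)[0])
        t1 /= max(np.linalg.norm(t1), 1e-12)
        cos_max = (r_max**2 - r_j**2 - d**2) / (2.0 * r_j * d)
        cos_a = min(1.0, cos_max) - rng.uniform(0.0, 0.15)
        cos_a = float(np.clip(cos_a, -0.3, 1.0))
        sin_a = float(np.sqrt(max(0.0, 1.0 - cos_a**2)))
        return cos_a * u + sin_a * t1

    def _peptide_anchor(self, place: str, core_junctions, iface_junctions) -> np.ndarray:
        """Anchor the cargo where its planted location's polymers live, so
        the local environment is never empty.  Among a few random candidate
        junctions the one that best balances the running anchor dipole is
        chosen, keeping the cargo's contribution to the NP COM small."""
        p = self.params
        rng = self.rng_peptides
        if not hasattr(self, "_anchor_dipole"):
            self._anchor_dipole = np.zeros(3)
        if place == "core_center":
            r_default = p.water_nucleus_radius + 2.5
            junctions = core_junctions
        else:
            r_default = p.core_radius
            junctions = iface_junctions
        if junctions:
            # nest the cargo at a junction point (the amphiphilic anchor of a
            # polymer of its own region) so its local environment is never
            # empty and always attachable
            n_cand = min(5, len(junctions))
            cand_idx = rng.choice(len(junctions), size=n_cand, replace=False)
            best, best_norm = None, np.inf
            for ci in cand_idx:
                d = junctions[ci] - self.center
                d /= max(np.linalg.norm(d), 1e-12)
                norm = np.linalg.norm(self._anchor_dipole + d)
                if norm < best_norm:
                    best, best_norm = junctions[ci], norm
            anchor = np.asarray(best, dtype=float)
        else:
            anchor = self.center + r_default * _unit_vectors(rng, 1)[0]
        d = anchor - self.center
        self._anchor_dipole += d / max(np.linalg.norm(d), 1e-12)
        return anchor

    def _peptide_template(self, n_beads: int) -> np.ndarray:
        steps = _unit_vectors(self.rng_peptides, n_beads - 1) * 2.5
        pts = np.concatenate([[np.zeros(3)], steps.cumsum(axis=0)])
        pts -= pts.mean(axis=0)
        rmax = np.linalg.norm(pts, axis=1).max()
        if rmax > 3.5:
            pts *= 3.5 / rmax
        return pts

    def _exterior_water(self, n: int) -> np.ndarray:
        p = self.params
        r_excl = p.core_radius + p.corona_thickness
        out = np.empty((n, 3))
        filled = 0
        guard = 0
        while filled < n:
            guard += 1
            if guard > 1000:
                raise GenerationError("cannot place exterior water (box too small)")
            cand = self.rng_water.random((2 * (n - filled) + 8, 3)) * p.box
            d = np.linalg.norm(cand - self.center, axis=1)
            cand = cand[d > r_excl]
            take = min(len(cand), n - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
        return out

    def ground_truth(self) -> GroundTruth:
        spec = self.spec
        factors = {}
        if self.params.bias_cluster is not None:
            factors[int(self.params.bias_cluster)] = float(self.params.contact_bias)
        return GroundTruth(
            polymer_labels=self.polymer_labels.copy(),
            peptide_locations=list(self.peptide_locations),
            enrichment_factor=factors,
            true_core_radius=self.params.core_radius,
            seed=self.params.seed,
            peptide_anchors=self.peptide_anchors.copy(),
            peptide_templates=self.peptide_templates.copy(),
            cluster_locations={k + 1: c.location for k, c in enumerate(spec)},
            polymer_junctions=np.asarray(self.junction_positions, dtype=float).reshape(-1, 3),
        )


# ---------------------------------------------------------------------------
# cargo placement controller
# ---------------------------------------------------------------------------

class _PlacementController:
    """Re-attaches cargo peptides to nearby polymers, frame by frame,
    steering realized contact statistics toward planted targets.

    Per frame and cargo location group the controller (1) finds candidate
    polymers near each peptide's anchor, (2) picks an attachment cluster
    with probabilities proportional to candidate abundance times the
    planted enrichment target, multiplied by a feedback correction from the
    running mean of the realized per-frame enrichment, (3) translates the
    peptide next to a bead of the chosen polymer, then (4) measures the
    realized enrichment with the exact per-frame statistics the analysis
    uses and updates the feedback state.
    """

    R_CAND = 16.0        # candidate search radius around the anchor, A
    R_BEAD = 14.0        # attachment-bead search radius, A (mostly tangential)
    DR_MAX = 5.0         # max radial offset of attachment bead vs anchor, A
    OFFSET = 2.5         # peptide-to-bead placement distance, A

    def __init__(
        self,
        topology: Topology,
        polymer_mol_ids: Sequence[int],
        polymer_labels: np.ndarray,
        peptide_beads: Sequence[np.ndarray],
        peptide_locations: Sequence[str],
        anchors: np.ndarray,
        templates: np.ndarray,
        cluster_locations: dict,
        box: np.ndarray,
        center: np.ndarray,
        cutoff: float,
        rng,
        cluster_bias: dict | None = None,     # {cluster: factor}
        species_bias: tuple | None = None,    # (species, factor)
        species_bias_location: str = "interface",
        anchor_candidates: dict | None = None,  # {location: (n,3) junctions}
    ):
        self.topo = topology
        self.box = np.asarray(box, float)
        self.center = center
        self.cutoff = cutoff
        self.rng = rng
        self.anchors = anchors
        self.templates = templates
        self.peptide_beads = list(peptide_beads)
        self.locations = list(peptide_locations)
        self.cluster_bias = dict(cluster_bias or {})
        self.species_bias = species_bias
        self.species_bias_location = species_bias_location
        self.anchor_candidates = anchor_candidates or {}
        self.labels_by_mol = {
            int(m): int(l) for m, l in zip(polymer_mol_ids, polymer_labels)
        }
        self.poly_beads = topology.select(molecule_class="polymer")
        self.poly_mol_of_bead = topology.molecule_id[self.poly_beads]
        self.poly_species = topology.species[self.poly_beads]
        self.poly_label_of_bead = np.array(
            [self.labels_by_mol[int(m)] for m in self.poly_mol_of_bead], dtype=int
        ) if len(self.poly_beads) else np.empty(0, dtype=int)
        loc_of_cluster = cluster_locations
        # enrichment targets per location group
        self.groups: dict[str, list[int]] = {}
        for j, loc in enumerate(self.locations):
            self.groups.setdefault(loc, []).append(j)
        self.targets: dict[str, dict[int, float]] = {}
        for loc in self.groups:
            t = {}
            for lab, c_loc in loc_of_cluster.items():
                t[int(lab)] = 1.0
            for lab, f in self.cluster_bias.items():
                lab = int(lab)
                c_loc = loc_of_cluster.get(lab)
                matches = (c_loc == "core_interior" and loc == "core") or (
                    c_loc == "interface" and loc == "interface")
                # an exclusion plant (factor 0) means no contacts anywhere;
                # a preference plant applies in the cluster's own region
                if matches or f == 0.0:
                    t[lab] = float(f)
            self.targets[loc] = t
        self.targets_flat: dict[int, float] = {}
        for t in self.targets.values():
            for lab, f in t.items():
                if abs(f - 1.0) > 1e-9:
                    self.targets_flat[lab] = f
        # feedback state: running sums of realized per-frame enrichment
        self.e_sum = {loc: {} for loc in self.groups}
        self.e_cnt = {loc: {} for loc in self.groups}
        self.sp_sum = {loc: {} for loc in self.groups}
        self.sp_cnt = {loc: {} for loc in self.groups}

    # -- feedback helpers -------------------------------------------------
    def _mean_e(self, loc: str, lab: int, default: float) -> float:
        c = self.e_cnt[loc].get(lab, 0)
        if c == 0:
            return default
        return self.e_sum[loc][lab] / c

    def _correction(self, loc: str, lab: int, target: float) -> float:
        m = self._mean_e(loc, lab, target)
        if target <= 0:
            return 0.0
        c = self.e_cnt[loc].get(lab, 0)
        if c == 0:
            return 1.0
        # catch-up control: aim the next frame beyond the target by the
        # accumulated shortfall of the running mean, so the time average
        # converges to the planted value with O(1/T) tracking error
        gain = 0.5 * min(c, 12)
        t_eff = target + (target - m) * gain
        t_eff = float(np.clip(t_eff, 0.1 * target, 3.0 * target))
        return t_eff / target

    # -- placement --------------------------------------------------------
    def warm_up(self, positions: np.ndarray, n_passes: int = 6) -> None:
        """Converge the feedback state on scratch copies of one frame.

        For planted (non-unit) targets the anchor neighborhood itself may be
        unattainable (the target cluster too scarce or the local bead soup
        too dense); in that case the affected cargo is re-anchored at
        alternative junctions of its region and the best anchor set kept.
        Afterwards only the running means are retained, so the real frames
        start from a converged correction with no scratch-weight advantage.
        """
        self._run_passes(positions, n_passes)
        for loc, tmap in self.targets.items():
            biased = [lab for lab, f in tmap.items() if abs(f - 1.0) > 1e-9 and f > 0]
            cands = np.asarray(self.anchor_candidates.get(loc, np.empty((0, 3))))
            if not biased or len(cands) == 0:
                continue
            lab, target = biased[0], tmap[biased[0]]
            # deterministic first guess: junctions where the target cluster's
            # local bead share is most favorable for the requested factor
            self._greedy_anchors(positions, loc, lab, target, cands)
            self._reset_state(loc)
            self._run_passes(positions, n_passes)
            best_anchors = self.anchors.copy()
            best_err = abs(self._mean_e(loc, lab, 0.0) - target)
            for _ in range(4):
                if best_err <= 0.08 * target:
                    break
                for j in self.groups[loc]:
                    self.anchors[j] = cands[self.rng.integers(len(cands))]
                self._reset_state(loc)
                self._run_passes(positions, 4)
                err = abs(self._mean_e(loc, lab, 0.0) - target)
                if err < best_err:
                    best_anchors, best_err = self.anchors.copy(), err
            self.anchors = best_anchors
            self._reset_state(loc)
            self._run_passes(positions, n_passes)
        self._collapse_state()

    def _run_passes(self, positions: np.ndarray, n: int) -> None:
        for _ in range(n):
            self.place_frame(positions.copy())

    def _greedy_anchors(self, positions, loc, lab, target, cands) -> None:
        """Anchor the group's cargo at the junctions whose neighborhoods give
        the most headroom for the planted factor: high target-cluster bead
        share for factor > 1, low (but nonzero presence) for factor < 1."""
        tree = periodic_tree(positions[self.poly_beads], self.box)
        scores = np.empty(len(cands))
        for i, c in enumerate(cands):
            idx = np.asarray(tree.query_ball_point(
                wrap_positions(c, self.box), r=10.0), dtype=np.intp)
            labs = self.poly_label_of_bead[idx]
            nt = int((labs == lab).sum())
            tot = len(labs)
            mols = np.unique(self.poly_mol_of_bead[idx])
            mol_labs = np.array([self.labels_by_mol[int(m)] for m in mols])
            n_mols_t = int((mol_labs == lab).sum())
            if tot == 0 or nt == 0 or n_mols_t == 0:
                scores[i] = -np.inf
                continue
            bead_share = nt / tot
            mol_share = n_mols_t / len(mols)
            if target >= 1.0:
                # attainable per-frame enrichment is bounded by the ratio of
                # achievable contact share (~bead share when attached) to the
                # cluster's molecule share in the environment
                scores[i] = bead_share / mol_share
            else:
                scores[i] = -bead_share
        order = np.argsort(-scores, kind="stable")
        members = self.groups[loc]
        # concentrate the cargo on the few best neighborhoods (several
        # peptides may share one junction region)
        k_top = max(1, min(len(cands), (len(members) + 1) // 2))
        for rank, j in enumerate(members):
            self.anchors[j] = cands[order[rank % k_top]]

    def _reset_state(self, loc: str) -> None:
        self.e_sum[loc] = {}
        self.e_cnt[loc] = {}
        self.sp_sum[loc] = {}
        self.sp_cnt[loc] = {}

    def _collapse_state(self) -> None:
        for loc in self.groups:
            for lab in list(self.e_cnt[loc]):
                c = self.e_cnt[loc][lab]
                if c:
                    self.e_sum[loc][lab] = self.e_sum[loc][lab] / c
                    self.e_cnt[loc][lab] = 1
            for sp in list(self.sp_cnt[loc]):
                c = self.sp_cnt[loc][sp]
                if c:
                    self.sp_sum[loc][sp] = self.sp_sum[loc][sp] / c
                    self.sp_cnt[loc][sp] = 1

    def place_frame(self, positions: np.ndarray) -> None:
        """Set peptide coordinates in ``positions`` (modified in place)."""
        if len(self.poly_beads) == 0 or not self.groups:
            for j in range(len(self.anchors)):
                self._put(positions, j, self.anchors[j])
            return
        tree = periodic_tree(positions[self.poly_beads], self.box)
        for loc, members in self.groups.items():
            targets = self.targets[loc]
            forbidden = {lab for lab, f in targets.items() if f == 0.0}
            accum_n: dict[int, int] = {}
            accum_mols: set[int] = set()
            for j in members:
                self._place_peptide(
                    positions, tree, j, loc, targets, forbidden, accum_n, accum_mols
                )
            self._measure(positions, loc, members)

    def _candidates(self, tree, positions, anchor):
        idx = tree.query_ball_point(wrap_positions(anchor, self.box), r=self.R_CAND)
        idx = np.asarray(idx, dtype=np.intp)
        if len(idx) == 0:
            return {}
        mols = self.poly_mol_of_bead[idx]
        by_mol: dict[int, np.ndarray] = {}
        for m in np.unique(mols):
            by_mol[int(m)] = idx[mols == m]
        return by_mol

    N_TRIES = 10         # candidate placements evaluated per peptide per frame

    def _place_peptide(self, positions, tree, j, loc, targets, forbidden,
                       accum_n, accum_mols) -> None:
        """Choose, among candidate placements, the one whose induced
        per-frame enrichment vector (contacts AND environment membership,
        accumulated over the group's already-placed peptides) best tracks
        the feedback-corrected targets."""
        anchor = self.anchors[j]
        by_mol = self._candidates(tree, positions, anchor)
        if not by_mol:
            self._put(positions, j, anchor)
            return
        by_cluster: dict[int, list[int]] = {}
        for m in by_mol:
            lab = self.labels_by_mol[m]
            by_cluster.setdefault(lab, []).append(m)
        labs = [l for l in by_cluster if l not in forbidden]
        if not labs:
            self._put(positions, j, anchor)
            self._avoid_forbidden(positions, j, forbidden)
            return
        t_eff = {
            l: targets.get(l, 1.0) * self._correction(loc, l, targets.get(l, 1.0))
            for l in labs
        }
        counts = np.array([len(by_cluster[l]) for l in labs], dtype=float)
        w = counts / counts.sum() * np.array([t_eff[l] for l in labs])
        p_attach = w / w.sum() if w.sum() > 0 else np.full(len(labs), 1 / len(labs))
        best = None
        best_score = np.inf
        for trial in range(self.N_TRIES):
            # half the candidates follow the target-weighted draw, half
            # explore uniformly so the optimizer always has alternatives
            if trial % 2 == 0:
                lab = labs[self.rng.choice(len(labs), p=p_attach)]
            else:
                lab = labs[self.rng.integers(len(labs))]
            mol = by_cluster[lab][self.rng.integers(len(by_cluster[lab]))]
            bead_idx = self._pick_bead(positions, by_mol[mol], anchor, loc)
            bead_pos = positions[self.poly_beads[bead_idx]]
            u_off = _unit_vectors(self.rng, 1)[0]
            rot = _random_rotation(self.rng)
            pts = bead_pos + self.OFFSET * u_off + self.templates[j] @ rot.T
            cand_n, cand_mols = self._contact_profile(tree, pts)
            score = self._score(cand_n, cand_mols, accum_n, accum_mols,
                                t_eff, forbidden)
            if score < best_score:
                best, best_score = (pts, cand_n, cand_mols), score
        pts, cand_n, cand_mols = best
        positions[self.peptide_beads[j]] = pts
        for lab, cnt in cand_n.items():
            accum_n[lab] = accum_n.get(lab, 0) + cnt
        accum_mols |= cand_mols
        if forbidden:
            self._avoid_forbidden(positions, j, forbidden)

    def _contact_profile(self, tree, pts):
        """Per-cluster contact counts and contacted molecule set of candidate
        peptide coordinates (inclusive at the radius; adequate for scoring)."""
        lists = tree.query_ball_point(wrap_positions(pts, self.box), r=self.cutoff)
        idx = [i for sub in lists for i in sub]
        n: dict[int, int] = {}
        mols: set[int] = set()
        if not idx:
            return n, mols
        idx = np.asarray(idx, dtype=np.intp)
        for lab, cnt in zip(*np.unique(self.poly_label_of_bead[idx], return_counts=True)):
            n[int(lab)] = int(cnt)
        for m in np.unique(self.poly_mol_of_bead[idx]):
            mols.add(int(m))
        return n, mols

    def _score(self, cand_n, cand_mols, accum_n, accum_mols, t_eff, forbidden) -> float:
        """Squared relative deviation of the predicted frame enrichment from
        the effective targets."""
        n_tot = sum(accum_n.values()) + sum(cand_n.values())
        if n_tot == 0:
            return 100.0
        env = accum_mols | cand_mols
        N: dict[int, int] = {}
        for m in env:
            lab = self.labels_by_mol[m]
            N[lab] = N.get(lab, 0) + 1
        bad = sum(cnt for lab, cnt in cand_n.items() if lab in forbidden)
        N_env = sum(c for lab, c in N.items() if lab not in forbidden)
        if N_env == 0:
            return 100.0
        score = 0.0
        for lab, Ni in N.items():
            if lab in forbidden:
                continue
            t = t_eff.get(lab, 1.0)
            ni = accum_n.get(lab, 0) + cand_n.get(lab, 0)
            e = (ni / n_tot) / (Ni / N_env)
            ref = max(t, 0.25)
            # planted (non-unit) targets dominate the trade-off against the
            # remainder-sharing unit-target clusters
            weight = 4.0 if abs(self.targets_flat.get(lab, 1.0) - 1.0) > 1e-9 else 1.0
            score += weight * ((e - t) / ref) ** 2
        if bad:
            score += 50.0 * bad / n_tot
        return float(score)

    def _pick_bead(self, positions, cand_idx, anchor, loc) -> int:
        """Attachment bead among a molecule's candidate beads; radially
        compatible with the anchor, species-steered when a species bias is
        planted for this location."""
        pos = positions[self.poly_beads[cand_idx]]
        r_bead = np.linalg.norm(pos - self.center, axis=1)
        r_anchor = np.linalg.norm(anchor - self.center)
        ok = np.abs(r_bead - r_anchor) <= self.DR_MAX
        d = min_image_distance(pos, anchor, self.box)
        ok &= d <= self.R_BEAD
        pool = cand_idx[ok] if ok.any() else cand_idx
        if self.species_bias is not None and loc == self._bias_loc():
            sp, f = self.species_bias
            is_sp = self.poly_species[pool] == sp
            if is_sp.any() and (~is_sp).any():
                corr = self._sp_correction(loc, sp, f)
                share = float(np.mean(is_sp))
                p_sp = float(np.clip(f * share * corr, 0.0, 1.0))
                chosen = pool[is_sp] if self.rng.random() < p_sp else pool[~is_sp]
                return int(chosen[self.rng.integers(len(chosen))])
        dpool = min_image_distance(positions[self.poly_beads[pool]], anchor, self.box)
        return int(pool[int(np.argmin(dpool))])

    def _bias_loc(self) -> str:
        return "core" if self.species_bias_location == "core" else "interface"

    def _sp_correction(self, loc, sp, target) -> float:
        c = self.sp_cnt[loc].get(sp, 0)
        if c == 0 or target <= 0:
            return 1.0
        m = self.sp_sum[loc][sp] / c
        if m <= 1e-9:
            return 4.0
        return float(np.clip(target / m, 0.25, 4.0))

    def _put(self, positions, j, com_target) -> None:
        rot = _random_rotation(self.rng)
        positions[self.peptide_beads[j]] = com_target + self.templates[j] @ rot.T

    def _avoid_forbidden(self, positions, j, forbidden) -> None:
        """Push the peptide until it has zero contacts with forbidden-cluster
        beads (exclusion planting, factor = 0)."""
        if not forbidden:
            return
        bad_beads = self.poly_beads[np.isin(self.poly_label_of_bead, list(forbidden))]
        if len(bad_beads) == 0:
            return
        for _ in range(25):
            pb = self.peptide_beads[j]
            ii, jj = pairs_within(
                positions[pb], positions[bad_beads], self.box, self.cutoff + 0.5
            )
            if len(ii) == 0:
                return
            pep_com = positions[pb].mean(axis=0)
            away = pep_com - positions[bad_beads[jj[0]]]
            norm = np.linalg.norm(away)
            away = away / norm if norm > 1e-9 else _unit_vectors(self.rng, 1)[0]
            positions[pb] += away * 2.0

    # -- measurement ------------------------------------------------------
    def _measure(self, positions, loc, members) -> None:
        pep_beads = np.concatenate([self.peptide_beads[j] for j in members])
        frame = Frame(0.0, positions, self.box)
        n, N = frame_cluster_contact_stats(
            frame, self.topo, pep_beads, self.labels_by_mol, self.cutoff
        )
        n_tot = sum(n.values())
        N_env = sum(N.values())
        if n_tot > 0 and N_env > 0:
            for lab, Ni in N.items():
                if Ni == 0:
                    continue
                e = (n.get(lab, 0) / n_tot) / (Ni / N_env)
                self.e_sum[loc][lab] = self.e_sum[loc].get(lab, 0.0) + e
                self.e_cnt[loc][lab] = self.e_cnt[loc].get(lab, 0) + 1
        if self.species_bias is not None and loc == self._bias_loc():
            self._measure_species(positions, loc, pep_beads)

    def _measure_species(self, positions, loc, pep_beads) -> None:
        r_anchor = float(np.mean([
            np.linalg.norm(self.anchors[j] - self.center) for j in self.groups[loc]
        ]))
        r_bead = np.linalg.norm(positions[self.poly_beads] - self.center, axis=1)
        region = self.poly_beads[np.abs(r_bead - r_anchor) <= 12.0]
        if len(region) == 0:
            return
        species = self.topo.species[region]
        ii, jj = pairs_within(
            positions[pep_beads], positions[region], self.box, self.cutoff
        )
        if len(jj) == 0:
            return
        for sp in np.unique(species):
            B = float(np.mean(species == sp))
            nsh = float(np.mean(species[jj] == sp))
            if B > 0:
                e = nsh / B
                self.sp_sum[loc][sp] = self.sp_sum[loc].get(sp, 0.0) + e
                self.sp_cnt[loc][sp] = self.sp_cnt[loc].get(sp, 0) + 1


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def _make_controller(structure: _Structure, params: SyntheticParams,
                     rng=None) -> _PlacementController:
    bias = {}
    if params.bias_cluster is not None:
        bias[int(params.bias_cluster)] = float(params.contact_bias)
    junctions = np.asarray(structure.junction_positions, dtype=float).reshape(-1, 3)
    locs = [structure.spec[l - 1].location for l in structure.polymer_labels]
    anchor_candidates = {
        "core": junctions[[i for i, l in enumerate(locs) if l == "core_interior"]],
        "interface": junctions[[i for i, l in enumerate(locs) if l == "interface"]],
    }
    return _PlacementController(
        topology=structure.topology,
        polymer_mol_ids=structure.polymer_mol_ids,
        polymer_labels=structure.polymer_labels,
        peptide_beads=structure.peptide_beads,
        peptide_locations=structure.peptide_locations,
        anchors=structure.peptide_anchors,
        templates=structure.peptide_templates,
        cluster_locations={k + 1: c.location for k, c in enumerate(structure.spec)},
        box=np.full(3, params.box),
        center=structure.center,
        cutoff=params.contact_cutoff,
        rng=rng if rng is not None else structure.rng_controller,
        cluster_bias=bias,
        species_bias=params.species_bias,
        species_bias_location=params.species_bias_location,
        anchor_candidates=anchor_candidates,
    )


def generate_configuration(params: SyntheticParams) -> tuple[Trajectory, GroundTruth]:
    """One assembled frame plus its planted ground truth.

    Deterministic under a fixed seed.  Raises :class:`GenerationError` for
    geometrically infeasible parameters.
    """
    structure = _Structure(params)
    positions = structure.positions0.copy()
    if params.n_peptides > 0 and params.n_polymers > 0:
        controller = _make_controller(structure, params)
        controller.warm_up(positions)
        controller.place_frame(positions)
    frame = Frame(0.0, positions, np.full(3, params.box))
    traj = Trajectory(structure.topology, [frame])
    return traj, structure.ground_truth()


def generate_trajectory(params: SyntheticParams) -> tuple[Trajectory, GroundTruth]:
    """Multi-frame synthetic trajectory with planted ground truth.

    Frame 0 is the assembled configuration; later frames add iid Gaussian
    jitter (sd ``frame_noise``) to polymer and water beads and re-attach
    the cargo peptides via the placement controller.  With
    ``drift_amplitude > 0`` an exponentially decaying radial inflation
    (factor ``1 + A exp(-t/tau)``) makes early frames non-stationary for
    burn-in testing.  With zero noise and zero drift all frames are exact
    copies of frame 0.
    """
    structure = _Structure(params)
    p = params
    box = np.full(3, p.box)
    frozen = p.frame_noise == 0.0 and p.drift_amplitude == 0.0
    controller = (
        _make_controller(structure, params)
        if p.n_peptides > 0 and p.n_polymers > 0
        else None
    )
    non_pep = structure.topology.select(
        molecule_class=("polymer", "water", "ion"))
    if controller is not None:
        controller.warm_up(structure.positions0.copy())
    frames: list[Frame] = []
    base = structure.positions0
    for t in range(p.n_frames):
        if frozen and t > 0:
            fr = frames[0].copy()
            fr.time = t * p.frame_dt_ns
            frames.append(fr)
            continue
        pos = base.copy()
        scale = 1.0 + p.drift_amplitude * np.exp(-t / p.drift_tau)
        if p.drift_amplitude > 0:
            pos[non_pep] = structure.center + (pos[non_pep] - structure.center) * scale
        if p.frame_noise > 0 and t > 0:
            pos[non_pep] += structure.rng_frames.normal(
                0.0, p.frame_noise, size=(len(non_pep), 3)
            )
        if controller is not None:
            controller.anchors = structure.peptide_anchors * 1.0
            if p.drift_amplitude > 0:
                controller.anchors = (
                    structure.center
                    + (structure.peptide_anchors - structure.center) * scale
                )
            controller.place_frame(pos)
        elif p.n_peptides > 0:
            for j in range(p.n_peptides):
                pos[structure.peptide_beads[j]] = (
                    structure.peptide_templates[j] + structure.peptide_anchors[j]
                )
        frames.append(Frame(t * p.frame_dt_ns, pos, box.copy()))
    return Trajectory(structure.topology, frames), structure.ground_truth()


def plant_contact_enrichment(
    trajectory: Trajectory,
    ground_truth: GroundTruth,
    target_cluster: int,
    factor: float,
    cutoff: float = 6.0,
    seed: int | None = None,
) -> Trajectory:
    """Re-place cargo so the contact-share-to-abundance ratio of one
    conformational cluster equals ``factor`` in time average.

    Peptide positions are locally adjusted frame by frame by the placement
    controller; polymer coordinates are untouched, so conformational ground
    truth is preserved.  ``factor=1`` reproduces the generator's unbiased
    placement; ``factor=0`` guarantees zero contacts with the target
    cluster.  Raises :class:`GenerationError` with the attainable range if
    the requested factor is geometrically infeasible.
    """
    if factor < 0:
        raise GenerationError("factor must be >= 0")
    if int(target_cluster) not in set(int(l) for l in ground_truth.polymer_labels):
        raise GenerationError(f"cluster {target_cluster} not present in ground truth")
    topo = trajectory.topology
    polymer_mols = topo.molecules_of_class("polymer")
    peptide_mols = topo.molecules_of_class("peptide")
    labels = np.asarray(ground_truth.polymer_labels, dtype=int)
    c_loc = ground_truth.cluster_locations.get(int(target_cluster), "interface")
    pep_loc = "core" if c_loc == "core_interior" else "interface"

    # feasibility: best attainable enrichment over the region's junction
    # neighborhoods (cargo can be re-anchored anywhere the region's polymers
    # anchor, so the check looks at the most favorable neighborhoods)
    if factor > 0:
        attainable = _attainable_factor(
            trajectory, ground_truth, labels, polymer_mols, int(target_cluster), pep_loc
        )
        if attainable <= 0:
            raise GenerationError(
                f"cluster {target_cluster} never occurs near the {pep_loc} cargo; "
                "attainable factor range is [0, 0]"
            )
        if factor > attainable:
            raise GenerationError(
                f"factor {factor} infeasible for cluster {target_cluster}: "
                f"attainable range is [0, {attainable:.2f}]"
            )

    rng = np.random.default_rng(
        seed if seed is not None else (ground_truth.seed + 7919) % (2**31)
    )
    controller = _PlacementController(
        topology=topo,
        polymer_mol_ids=list(polymer_mols),
        polymer_labels=labels,
        peptide_beads=[topo.beads_of_molecule(m) for m in peptide_mols],
        peptide_locations=list(ground_truth.peptide_locations),
        anchors=np.asarray(ground_truth.peptide_anchors, float),
        templates=np.asarray(ground_truth.peptide_templates, float),
        cluster_locations=dict(ground_truth.cluster_locations),
        box=trajectory.frames[0].box,
        center=trajectory.frames[0].box / 2.0,
        cutoff=cutoff,
        rng=rng,
        cluster_bias={int(target_cluster): float(factor)},
        anchor_candidates=ground_truth.junctions_by_region(),
    )
    controller.warm_up(trajectory.frames[0].positions.copy())
    new_frames = []
    for fr in trajectory.frames:
        pos = fr.positions.copy()
        controller.place_frame(pos)
        new_frames.append(Frame(fr.time, pos, fr.box.copy()))
    return Trajectory(topo, new_frames)


def _attainable_factor(
    trajectory, ground_truth, labels, polymer_mols, target, pep_loc
) -> float:
    """Upper bound on the plantable enrichment factor for a cluster: the
    best, over the region's junction neighborhoods, of the ratio of the
    cluster's bead share (achievable contact share when the cargo attaches
    there) to its molecule share (its environment abundance)."""
    topo = trajectory.topology
    frame = trajectory.frames[0]
    junctions = ground_truth.junctions_by_region().get(pep_loc, np.empty((0, 3)))
    poly_beads = topo.select(molecule_class="polymer")
    mol_of = topo.molecule_id[poly_beads]
    label_of_mol = {int(m): int(l) for m, l in zip(polymer_mols, labels)}
    label_of_bead = np.array([label_of_mol[int(m)] for m in mol_of])
    tree = periodic_tree(frame.positions[poly_beads], frame.box)
    best = 0.0
    for c in junctions:
        idx = np.asarray(tree.query_ball_point(
            wrap_positions(np.asarray(c, float), frame.box), r=10.0), dtype=np.intp)
        if len(idx) == 0:
            continue
        labs = label_of_bead[idx]
        nt = int((labs == target).sum())
        mols = np.unique(mol_of[idx])
        n_mols_t = sum(1 for m in mols if label_of_mol[int(m)] == target)
        if nt == 0 or n_mols_t == 0:
            continue
        bead_share = nt / len(idx)
        mol_share = n_mols_t / len(mols)
        best = max(best, bead_share / mol_share)
    # the static snapshot underestimates what frame-by-frame placement can
    # reach (jitter and environment pruning add headroom)
    return float(1.3 * best)
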