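"""End-to-end analysis pipeline: ingest or synthesize a trajectory, discard
the pre-stationary segment, then run the structural, contact and
conformational analyses and write all tables plus a reproducibility
manifest.

Every random stage draws its seed from the master seed through a seed
sequence, and all tables are written with a fixed float format, so a rerun
with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import (
    BootstrapSpec,
    contact_enrichment,
    environment_acf,
    per_residue_contact_difference,
    radial_shell_region,
)
from .conformations import (
    ClusterParams,
    EmbedParams,
    build_conformation_table,
    embed_and_cluster,
    fractional_enrichment,
    intrinsic_density,
)
from .structure import (
    classify_peptide_location,
    core_composition,
    detect_burn_in,
    estimate_core_radius,
    radial_density_profile,
    radius_of_gyration,
)
from .synthetic import SyntheticParams, generate_trajectory, scaled_params
from .topology import read_topology
from .trajectory import Trajectory, read_coordinates

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger("npmicroenv")

_FLOAT_FMT = "%.8g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``coordinates``+``topology`` point at input files, or (when both
    are None) a trajectory is synthesized from ``synthetic``.
    """

    coordinates: str | None = None
    topology: str | None = None
    coordinate_format: str | None = None
    synthetic: SyntheticParams = field(default_factory=scaled_params)
    burn_in: str | int = "auto"          # "auto" | fixed frame index
    contact_cutoff: float = 6.0
    bin_width: float = 2.0
    shells: tuple = (0.25, 0.5, 0.75, 1.0)
    stationarity_tolerance: float = 0.01
    location_margin: float = 10.0
    max_lag: int = 15
    use_embedding: bool = True
    embed: EmbedParams = field(default_factory=EmbedParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    seed: int = 0
    outdir: str = "results"

    def resolved(self) -> "RunConfig":
        """Config with all random stages tied to the master seed."""
        ss = np.random.SeedSequence(self.seed)
        s_synth, s_embed, s_boot = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
        return dataclasses.replace(
            self,
            synthetic=dataclasses.replace(self.synthetic, seed=s_synth),
            embed=dataclasses.replace(self.embed, seed=s_embed),
            bootstrap=dataclasses.replace(self.bootstrap, seed=s_boot),
        )


def validate_config(config: RunConfig) -> list[str]:
    """Parameter-domain violations; empty list iff the config is runnable."""
    v: list[str] = []
    if (config.coordinates is None) != (config.topology is None):
        v.append("coordinates and topology must be given together")
    if config.coordinates is not None and not Path(config.coordinates).exists():
        v.append(f"coordinates: no such file: {config.coordinates}")
    if config.topology is not None and not Path(config.topology).exists():
        v.append(f"topology: no such file: {config.topology}")
    if config.coordinates is None:
        v += [f"synthetic.{msg}" for msg in config.synthetic.validate()]
    if config.contact_cutoff <= 0:
        v.append("contact_cutoff must be > 0")
    if config.bin_width <= 0:
        v.append("bin_width must be > 0")
    if config.stationarity_tolerance <= 0:
        v.append("stationarity_tolerance must be > 0")
    if config.location_margin <= 0:
        v.append("location_margin must be > 0")
    if config.max_lag < 1:
        v.append("max_lag must be >= 1")
    if not all(0 < s <= 2.0 for s in config.shells):
        v.append("shells must be positive fractions of the core radius")
    if list(config.shells) != sorted(config.shells):
        v.append("shells must be increasing")
    if isinstance(config.burn_in, int) and config.burn_in < 0:
        v.append("burn_in frame must be >= 0")
    elif isinstance(config.burn_in, str) and config.burn_in != "auto":
        v.append("burn_in must be 'auto' or a frame index")
    if config.bootstrap.block_length < 1 or config.bootstrap.n_resamples < 1:
        v.append("bootstrap block_length and n_resamples must be >= 1")
    if not 0 < config.bootstrap.confidence < 1:
        v.append("bootstrap confidence must be in (0, 1)")
    if config.embed.n_neighbors < 2:
        v.append("embed.n_neighbors must be >= 2")
    return v


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write outputs to ``config.outdir``.

    Returns the manifest/summary dictionary (also written as JSON).
    Stage failures propagate with the stage name; outputs written before
    the failure are retained alongside a failure marker.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    config = config.resolved()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "setup"
    summary: dict = {
        "version": __version__,
        "parameters": _config_dict(config),
    }
    try:
        # ---- ingest / synthesize ----------------------------------------
        stage = "input"
        if config.coordinates is not None:
            frames = read_coordinates(config.coordinates, config.coordinate_format)
            topo = read_topology(config.topology)
            traj = Trajectory(topo, frames)
            ground_truth = None
            summary["input"] = {
                "coordinates": config.coordinates,
                "coordinates_sha256": _digest(config.coordinates),
                "topology": config.topology,
                "topology_sha256": _digest(config.topology),
            }
        else:
            traj, ground_truth = generate_trajectory(config.synthetic)
            ground_truth.to_json(outdir / "ground_truth.json")
            summary["input"] = {"synthetic_seed": config.synthetic.seed}
        topo = traj.topology
        _log(stage, t_start, f"{traj.n_frames} frames, {topo.n_beads} beads")

        # ---- structure ---------------------------------------------------
        stage = "structure"
        species_groups = {
            s: topo.select(species=s) for s in ("LA", "GA", "EO", "W")
            if len(topo.select(species=s))
        }
        pep_beads = topo.select(molecule_class="peptide")
        if len(pep_beads):
            species_groups["peptide"] = pep_beads
        profile0 = radial_density_profile(traj, species_groups,
                                          bin_width=config.bin_width)
        core = estimate_core_radius(profile0)
        trace = detect_burn_in(traj, core.core_radius, shells=config.shells,
                               tolerance=config.stationarity_tolerance)
        burn = trace.burn_in_frame if config.burn_in == "auto" else int(config.burn_in)
        post = traj.sliced(burn) if burn > 0 else traj
        _write(trace.to_frame(), outdir / "stationarity.csv")
        _log(stage, t_start, f"core radius {core.core_radius:.1f} A, burn-in frame {burn}")

        profile = radial_density_profile(
            post, species_groups, bin_width=config.bin_width,
            interface_offset=core.core_radius,
        )
        _write(profile.to_frame(), outdir / "density_profile.csv")
        comp = core_composition(post, core.core_radius)
        comp.rename_axis("category").reset_index().pipe(
            _write, outdir / "core_composition.csv")
        np_beads = topo.select(molecule_class=("polymer", "peptide"))
        rg = np.array([radius_of_gyration(fr, topo, np_beads) for fr in post.frames])

        locations = None
        if len(pep_beads):
            locations = classify_peptide_location(
                post, core.core_radius, margin=config.location_margin)
            locations.rename_axis("peptide").reset_index().pipe(
                _write, outdir / "peptide_locations.csv")

        summary["structure"] = {
            "core_radius_A": core.core_radius,
            "eo_peak_radius_A": core.eo_peak_radius,
            "interface_width_A": core.interface_width,
            "burn_in_frame": int(burn),
            "burn_in_time_ns": float(traj.frames[burn].time),
            "rg_mean_A": float(rg.mean()),
            "rg_sd_A": float(rg.std(ddof=1)) if len(rg) > 1 else 0.0,
            "composition_pct": {k: float(v) for k, v in comp.items()},
            "peptide_locations": (
                {str(k): v for k, v in locations.items()} if locations is not None else {}
            ),
        }

        # ---- contacts ----------------------------------------------------
        stage = "contacts"
        if locations is not None and len(pep_beads):
            poly_beads = topo.select(molecule_class="polymer")
            species_list = [s for s in ("LA", "GA", "EO") if s in set(topo.species)]
            enrich_rows = []
            R = core.core_radius
            m = config.location_margin
            regions = {
                "core": radial_shell_region(0.0, R, beads=poly_beads),
                "interface": radial_shell_region(R - m, R + m, beads=poly_beads),
            }
            acf_rows = []
            for loc, region in regions.items():
                peps_here = [int(p) for p, l in locations.items() if l == loc]
                if not peps_here:
                    continue
                res = contact_enrichment(
                    post, peps_here, region, species_list,
                    cutoff=config.contact_cutoff, ci=config.bootstrap, location=loc,
                )
                tab = res.table.copy()
                tab.insert(0, "location", loc)
                enrich_rows.append(tab)
                acf = environment_acf(post, peps_here[0],
                                      cutoff=config.contact_cutoff,
                                      max_lag=min(config.max_lag, post.n_frames - 1))
                a = acf.to_frame()
                a.insert(0, "location", loc)
                acf_rows.append(a)
            if enrich_rows:
                _write(pd.concat(enrich_rows, ignore_index=True),
                       outdir / "contact_enrichment.csv")
            if acf_rows:
                _write(pd.concat(acf_rows, ignore_index=True),
                       outdir / "environment_acf.csv")
            core_peps = [int(p) for p, l in locations.items() if l == "core"]
            iface_peps = [int(p) for p, l in locations.items() if l == "interface"]
            if core_peps and iface_peps:
                for counterpart in ("water", "polymer"):
                    if counterpart == "water" and not len(topo.select(molecule_class="water")):
                        continue
                    diff = per_residue_contact_difference(
                        post, core_peps, iface_peps, counterpart,
                        cutoff=config.contact_cutoff,
                    )
                    diff.rename_axis("residue").reset_index().assign(
                        counterpart=counterpart).pipe(
                        _write, outdir / f"residue_contact_difference_{counterpart}.csv")
        _log(stage, t_start, "contact statistics written")

        # ---- conformations -----------------------------------------------
        stage = "conformations"
        summary["conformations"] = {}
        if len(topo.molecules_of_class("polymer")):
            table = build_conformation_table(post)
            _write(table, outdir / "conformations.csv")
            assignment = embed_and_cluster(
                table, config.embed, config.cluster,
                use_embedding=config.use_embedding,
            )
            _write(assignment.table, outdir / "cluster_assignment.csv")
            _write(assignment.populations, outdir / "cluster_summary.csv")
            if assignment.embedding is not None:
                emb = pd.DataFrame(assignment.embedding, columns=["umap_1", "umap_2"])
                emb.insert(0, "label", assignment.labels)
                _write(emb, outdir / "embedding.csv")
            idp = intrinsic_density(post, assignment, core.core_radius,
                                    bin_width=config.bin_width)
            _write(idp.to_frame(), outdir / "intrinsic_density.csv")
            summary["conformations"] = {
                "k": assignment.k,
                "noise_pct": assignment.noise_pct,
                "populations": assignment.populations.to_dict(orient="records"),
            }
            if locations is not None and len(pep_beads):
                fe = fractional_enrichment(
                    post, assignment, [int(p) for p in locations.index],
                    {int(p): l for p, l in locations.items()},
                    cutoff=config.contact_cutoff, ci=config.bootstrap,
                )
                _write(fe.table, outdir / "fractional_enrichment.csv")
                summary["conformations"]["noise_contact_share"] = fe.noise_contact_share
        _log(stage, t_start, "conformational analysis written")

        _log("done", t_start, "all outputs written")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return summary
    except Exception as exc:
        marker = {"failed_stage": stage, "error": str(exc)}
        with open(outdir / "FAILED.json", "w") as fh:
            json.dump(marker, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # keep the manifest independent of where it lives
    spec = d["synthetic"].get("cluster_spec")
    if spec is not None:
        d["synthetic"]["cluster_spec"] = [
            c if isinstance(c, (list, tuple, dict)) else dataclasses.asdict(c)
            for c in config.synthetic.normalized_cluster_spec()
        ]
    return d


def _log(stage: str, t_start: float, msg: str) -> None:
    logger.info("[%7.2fs] %s: %s", time.time() - t_start, stage, msg)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
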