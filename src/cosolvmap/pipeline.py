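"""End-to-end pipeline: fit -> PMAP per run -> max-PMAP -> surface ->
environments -> profile -> optional stability filter, with a JSON manifest
recording parameters and per-stage counts for auditability."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import __version__
from .config import ConfigError, RunConfig
from .grid import write_dx
from .pmap import (
    MaxPMAP,
    PMAP,
    PreferableSurface,
    compute_max_pmap,
    compute_pmap,
    grid_geometry_for,
    preferable_surface,
)
from .probes import ProbeDefinition, get_probe
from .profile import (
    InteractionProfile,
    ResidueEnvironment,
    ResidueTypeScheme,
    build_profile,
    extract_environments,
    profile_geometry_for,
)
from .stability import filter_environments, stable_mask
from .trajectory import Trajectory, fit_protein_to_reference, read_multimodel_pdb

__all__ = ["PipelineResult", "PipelineError", "probe_from_config", "run_pipeline", "load_protein_list"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    pmaps: list[PMAP]
    max_pmap: MaxPMAP
    surface: PreferableSurface
    environments: list[ResidueEnvironment]
    profile: InteractionProfile
    filtered_profile: InteractionProfile | None
    manifest: dict = field(default_factory=dict)


def probe_from_config(config: RunConfig) -> ProbeDefinition:
    pc = config.probe
    if pc.atoms:
        return ProbeDefinition(
            name=pc.preset,
            resname=pc.resname or "PRB",
            atoms={k: np.asarray(v) for k, v in pc.atoms.items()},
            alignment_atom_names=pc.alignment_atoms or list(pc.atoms),
            symmetry_mappings=pc.symmetry_mappings or [],
        )
    probe = get_probe(pc.preset)
    if pc.resname:
        probe.resname = pc.resname.upper()
    return probe


def load_protein_list() -> list[dict[str, str]]:
    """The packaged 15-protein selection list (PDB code, chain, name)."""
    text = resources.files("cosolvmap.data").joinpath("protein_list.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    trajectories: list[Trajectory] | None = None,
) -> PipelineResult:
    """Execute every analysis stage and write artifacts to ``outdir``.

    ``trajectories`` may be supplied directly (e.g. from the synthetic
    generator); otherwise ``config.runs.paths`` is read as multi-model PDB.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = probe_from_config(config)
    scheme = ResidueTypeScheme.default()
    th = config.thresholds

    if trajectories is None:
        if not config.runs.paths:
            raise ConfigError("runs.paths is empty and no trajectories were passed")
        trajectories = []
        for path in config.runs.paths:
            if not Path(path).exists():
                raise PipelineError("load", f"trajectory file not found: {path}")
            trajectories.append(
                read_multimodel_pdb(
                    path,
                    probe.resname,
                    timestep=config.schedule.interval_ps,
                    t_start=config.schedule.t_start_ps,
                )
            )

    # --- fit: common frame = first run's first snapshot
    reference_ca = trajectories[0].snapshots[0].protein_ca_coords()
    for traj in trajectories:
        try:
            fit_protein_to_reference(traj, reference_ca)
        except Exception as exc:
            raise PipelineError("fit", f"run {traj.run_id}: {exc}") from exc

    # --- per-run PMAPs on a shared grid and shell mask
    geometry = grid_geometry_for(
        trajectories[0],
        spacing=config.grid.spacing,
        margin=config.grid.margin,
        align_point=(
            np.asarray(config.grid.align_point)
            if config.grid.align_point is not None
            else None
        ),
    )
    pmaps: list[PMAP] = []
    mask = None
    for traj in trajectories:
        try:
            pmap = compute_pmap(
                traj,
                geometry,
                probe.resname,
                surface_cutoff=th.shell_cutoff,
                mask=mask,
            )
        except Exception as exc:
            raise PipelineError("pmap", f"run {traj.run_id}: {exc}") from exc
        mask = pmap.mask
        pmaps.append(pmap)
        write_dx(pmap.grid, outdir / f"pmap_{traj.run_id}.dx")

    max_pmap = compute_max_pmap(pmaps)
    write_dx(max_pmap.grid, outdir / "max_pmap.dx")

    surface = preferable_surface(max_pmap, th.surface_theta)
    _write_surface_tsv(surface, max_pmap, outdir / "surface.tsv")
    _write_surface_pdb(surface, outdir / "surface_voxels.pdb")

    environments: list[ResidueEnvironment] = []
    for traj in trajectories:
        environments.extend(
            extract_environments(traj, surface, probe, cutoff=th.environment_cutoff)
        )
    if not environments:
        raise PipelineError("environments", "no probe pose ever reached the surface")

    profile_geom = profile_geometry_for(
        probe, spacing=config.grid.spacing, margin=config.profile.margin
    )
    profile = build_profile(
        environments,
        profile_geom,
        probe,
        scheme,
        atom_selector=config.profile.atom_selector,
    )
    for rtype, grid in profile.grids.items():
        write_dx(grid, outdir / f"profile_{rtype}.dx")
    _write_reference_probe_pdb(probe, outdir / "reference_probe.pdb")

    filtered_profile = None
    removed_fractions: dict[str, float] = {}
    if config.profile.apply_stability_filter:
        kept_all: list[ResidueEnvironment] = []
        for traj in trajectories:
            verdicts = stable_mask(traj, th.stability_lag_ps, th.stability_cutoff)
            run_envs = [e for e in environments if e.run_id == traj.run_id]
            kept, removed, _ = filter_environments(run_envs, verdicts)
            removed_fractions[traj.run_id] = removed
            kept_all.extend(kept)
        if kept_all:
            filtered_profile = build_profile(
                kept_all,
                profile_geom,
                probe,
                scheme,
                atom_selector=config.profile.atom_selector,
            )
            for rtype, grid in filtered_profile.grids.items():
                write_dx(grid, outdir / f"profile_{rtype}_stable.dx")
        else:
            log.warning("stability filter removed every environment")
        with open(outdir / "stability_removed.tsv", "w") as fh:
            fh.write("run_id\tremoved_fraction\n")
            for run_id, frac in removed_fractions.items():
                fh.write(f"{run_id}\t{frac:.6f}\n")

    manifest = {
        "version": __version__,
        "probe": probe.name,
        "probe_resname": probe.resname,
        "parameters": config.model_dump(mode="json"),
        "n_runs": len(trajectories),
        "n_snapshots": [t.n_snapshots for t in trajectories],
        "pmap_masked_sums": [p.masked_sum() for p in pmaps],
        "max_pmap_masked_sum": max_pmap.masked_sum(),
        "n_surface_voxels": surface.n_voxels,
        "n_environments": len(environments),
        "profile_totals": profile.total_counts(),
        "stability_removed_fractions": removed_fractions,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    # per-type aggregation report
    with open(outdir / "profile_report.tsv", "w") as fh:
        fh.write("residue_type\tn_binned\n")
        for rtype, n in profile.n_binned.items():
            fh.write(f"{rtype}\t{n}\n")
        fh.write(f"__environments__\t{profile.n_environments}\n")
        fh.write(f"__missing_atom__\t{profile.n_missing_atom}\n")
        fh.write(f"__out_of_bounds__\t{profile.n_out_of_bounds}\n")

    return PipelineResult(
        pmaps=pmaps,
        max_pmap=max_pmap,
        surface=surface,
        environments=environments,
        profile=profile,
        filtered_profile=filtered_profile,
        manifest=manifest,
    )


def _write_surface_tsv(surface: PreferableSurface, max_pmap: MaxPMAP, path: Path) -> None:
    idx = surface.voxel_indices()
    with open(path, "w") as fh:
        fh.write("i\tj\tk\tvalue\n")
        for i, j, k in idx:
            fh.write(f"{i}\t{j}\t{k}\t{max_pmap.grid.values[i, j, k]:.9f}\n")


def _write_surface_pdb(surface: PreferableSurface, path: Path) -> None:
    idx = surface.voxel_indices()
    centers = surface.origin + (idx + 0.5) * surface.spacing
    with open(path, "w") as fh:
        for n, c in enumerate(centers, start=1):
            fh.write(
                f"HETATM{n % 100000:>5d}  C   VOX X{n % 10000:>4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"           C\n"
            )
        fh.write("END\n")


def _write_reference_probe_pdb(probe: ProbeDefinition, path: Path) -> None:
    with open(path, "w") as fh:
        for n, name in enumerate(probe.atom_names, start=1):
            c = probe.atoms[name]
            element = name.rstrip("0123456789")[:1].upper()
            pdb_name = name if len(name) >= 4 else f" {name:<3s}"
            fh.write(
                f"HETATM{n:>5d} {pdb_name:<4.4s} {probe.resname:<3.3s} X   1    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2.2s}\n"
            )
        fh.write("END\n")
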