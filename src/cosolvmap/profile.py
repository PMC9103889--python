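"""Residue-environment extraction and the per-residue-type interaction profile.

For every snapshot, each probe copy found on the preferable surface is
extracted together with the residues having at least one heavy atom within
4 Å of any probe heavy atom.  Each such environment is rigidly superposed
onto the reference probe (minimum RMSD over the probe's symmetry-equivalent
atom orderings), and the Cβ atoms (or any selected atom) of the surrounding
residues are binned per residue type into 1 Å voxel grids around the probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .grid import Grid3D, bin_points, create_grid
from .pmap import PreferableSurface
from .probes import ProbeDefinition
from .superpose import RigidTransform, UnderdeterminedFitError, fit_rigid
from .trajectory import ProbeInstance, ResidueRecord, Trajectory

__all__ = [
    "ResidueTypeScheme",
    "ResidueEnvironment",
    "InteractionProfile",
    "UnknownResidueError",
    "EXCLUDED",
    "probe_on_surface",
    "residues_within",
    "classify_residue",
    "superpose_probe",
    "extract_environments",
    "build_profile",
    "profile_geometry_for",
]

log = logging.getLogger(__name__)

DEFAULT_ENVIRONMENT_CUTOFF = 4.0
DEFAULT_PROFILE_MARGIN = 8.0
EXCLUDED = "excluded"


class UnknownResidueError(KeyError):
    pass


@dataclass
class ResidueTypeScheme:
    """Mapping from 3-letter residue codes to one of five categories."""

    mapping: dict[str, str]
    excluded: frozenset[str] = frozenset({"GLY"})

    @classmethod
    def default(cls) -> "ResidueTypeScheme":
        text = resources.files("cosolvmap.data").joinpath("residue_types.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, raw: dict) -> "ResidueTypeScheme":
        mapping: dict[str, str] = {}
        excluded = frozenset(str(r).upper() for r in raw.get(EXCLUDED, []))
        for rtype, members in raw.items():
            if rtype == EXCLUDED:
                continue
            for res in members:
                mapping[str(res).upper()] = str(rtype)
        return cls(mapping=mapping, excluded=excluded)

    @property
    def types(self) -> list[str]:
        seen: list[str] = []
        for t in self.mapping.values():
            if t not in seen:
                seen.append(t)
        return seen


def classify_residue(
    resname: str, scheme: ResidueTypeScheme, *, strict: bool = True
) -> str:
    """Return the category of ``resname``, or ``"excluded"``.

    Unknown codes raise by default; with ``strict=False`` (for modified
    residues) they are warned about and treated as excluded.
    """
    code = resname.strip().upper()
    if code in scheme.excluded:
        return EXCLUDED
    if code in scheme.mapping:
        return scheme.mapping[code]
    if strict:
        raise UnknownResidueError(f"residue code {code!r} is not in the type scheme")
    log.warning("unknown residue %s treated as excluded", code)
    return EXCLUDED


def probe_on_surface(probe: ProbeInstance, surface: PreferableSurface) -> bool:
    """True iff at least one probe heavy atom lies inside a member voxel."""
    coords = probe.heavy_coords()
    if coords.size == 0:
        raise ValueError(f"probe {probe.copy_id} has no heavy atoms")
    return bool(surface.contains_points(coords).any())


def residues_within(
    probe: ProbeInstance,
    protein: list[ResidueRecord],
    cutoff: float = DEFAULT_ENVIRONMENT_CUTOFF,
) -> list[ResidueRecord]:
    """Residues with >=1 heavy atom within ``cutoff`` Å (inclusive) of any
    probe heavy atom."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    probe_coords = probe.heavy_coords()
    if probe_coords.size == 0:
        return []
    tree = cKDTree(probe_coords)
    selected = []
    for res in protein:
        coords = res.heavy_coords()
        if coords.size == 0:
            continue
        dist, _ = tree.query(coords, k=1)
        if np.min(dist) <= cutoff:
            selected.append(res)
    return selected


#: Two mappings whose RMSDs differ by less than this are considered tied;
#: the earlier mapping in the list then wins.  For a geometrically symmetric
#: probe several mappings fit equally well to machine precision, and without
#: a deterministic tie-break the chosen frame would flip with femtometre
#: coordinate perturbations.
SYMMETRY_TIE_TOLERANCE = 1e-6


def superpose_probe(
    mobile_probe: ProbeInstance,
    reference: ProbeDefinition,
) -> tuple[RigidTransform, float]:
    """Best rigid fit of a probe pose onto the reference template.

    Each symmetry-equivalent ordering of the alignment atoms is tried; the
    one with minimal RMSD wins (ties broken deterministically in favour of
    earlier mappings).  Reflections are never allowed, so a fit that would
    require one simply reports its (honest, larger) RMSD.
    """
    ref_coords = reference.alignment_coords()
    best: tuple[RigidTransform, float] | None = None
    for mapping in reference.symmetry_mappings:
        mobile_coords = mobile_probe.coords_of(mapping)
        transform, rmsd = fit_rigid(mobile_coords, ref_coords)
        if best is None or rmsd < best[1] - SYMMETRY_TIE_TOLERANCE:
            best = (transform, rmsd)
    assert best is not None  # at least the identity mapping exists
    return best


@dataclass
class ResidueEnvironment:
    """One on-surface probe pose plus its surroundings, in the reference frame."""

    run_id: str
    time: float
    probe_id: str
    probe_atoms: list  # AtomRecord copies, transformed
    residues: list[ResidueRecord]  # deep copies, transformed
    alignment_rmsd: float


def _transform_residue(res: ResidueRecord, transform: RigidTransform) -> ResidueRecord:
    from .trajectory import AtomRecord  # local import to avoid cycle at module load

    atoms = [
        AtomRecord(a.name, a.element, transform.apply(a.coords)) for a in res.atoms
    ]
    return ResidueRecord(res.resname, res.chain, res.resseq, atoms)


def extract_environments(
    traj: Trajectory,
    surface: PreferableSurface,
    reference: ProbeDefinition,
    *,
    cutoff: float = DEFAULT_ENVIRONMENT_CUTOFF,
) -> list[ResidueEnvironment]:
    """Collect every on-surface probe pose with its surrounding residues.

    Superposition failures (degenerate alignment atoms in a pose) skip that
    environment with a log message rather than aborting the run.
    """
    from .trajectory import AtomRecord

    environments: list[ResidueEnvironment] = []
    for snap in traj.snapshots:
        for probe in snap.probes:
            if not probe_on_surface(probe, surface):
                continue
            nearby = residues_within(probe, snap.protein, cutoff)
            try:
                transform, rmsd = superpose_probe(probe, reference)
            except UnderdeterminedFitError as exc:
                log.warning(
                    "run %s t=%.1f probe %s: superposition failed (%s); skipped",
                    traj.run_id, snap.time, probe.copy_id, exc,
                )
                continue
            probe_atoms = [
                AtomRecord(a.name, a.element, transform.apply(a.coords))
                for a in probe.atoms
            ]
            residues = [_transform_residue(r, transform) for r in nearby]
            environments.append(
                ResidueEnvironment(
                    run_id=traj.run_id,
                    time=snap.time,
                    probe_id=probe.copy_id,
                    probe_atoms=probe_atoms,
                    residues=residues,
                    alignment_rmsd=rmsd,
                )
            )
    return environments


@dataclass
class InteractionProfile:
    """Per-residue-type count grids around the reference probe."""

    grids: dict[str, Grid3D]
    reference_coords: np.ndarray
    atom_selector: str
    n_environments: int
    n_binned: dict[str, int] = field(default_factory=dict)
    n_out_of_bounds: int = 0
    n_missing_atom: int = 0

    def total_counts(self) -> dict[str, float]:
        return {t: float(g.values.sum()) for t, g in self.grids.items()}


def profile_geometry_for(
    reference: ProbeDefinition,
    *,
    spacing: float = 1.0,
    margin: float = DEFAULT_PROFILE_MARGIN,
) -> Grid3D:
    """Cubic grid of ±margin Å around the reference probe centroid."""
    center = reference.centroid()
    n = int(np.ceil(2 * margin / spacing))
    origin = center - margin
    return create_grid(origin, (n, n, n), spacing)


def build_profile(
    environments: list[ResidueEnvironment],
    geometry: Grid3D,
    reference: ProbeDefinition,
    scheme: ResidueTypeScheme | None = None,
    *,
    atom_selector: str = "CB",
    strict: bool = False,
) -> InteractionProfile:
    """Bin the selected atom of every surrounding residue, per residue type.

    Residues whose selected atom is absent (e.g. Gly Cβ) are tallied in
    metadata but not binned; so are selected atoms falling outside the grid.
    """
    if not environments:
        raise ValueError("cannot build a profile from zero environments")
    if scheme is None:
        scheme = ResidueTypeScheme.default()
    if not atom_selector or not atom_selector.strip():
        raise ValueError("atom selector must be a non-empty atom name")

    points: dict[str, list[np.ndarray]] = {t: [] for t in scheme.types}
    n_missing = 0
    for env in environments:
        for res in env.residues:
            rtype = classify_residue(res.resname, scheme, strict=strict)
            if rtype == EXCLUDED:
                continue
            atom = res.atom(atom_selector)
            if atom is None:
                n_missing += 1
                continue
            points[rtype].append(atom.coords)

    grids: dict[str, Grid3D] = {}
    n_binned: dict[str, int] = {}
    n_oob = 0
    for rtype in scheme.types:
        pts = np.array(points[rtype]) if points[rtype] else np.empty((0, 3))
        result = bin_points(geometry.zeros_like(), pts)
        grids[rtype] = result.grid
        n_oob += result.n_out_of_bounds
        n_binned[rtype] = len(pts) - result.n_out_of_bounds

    return InteractionProfile(
        grids=grids,
        reference_coords=reference.template_coords(),
        atom_selector=atom_selector,
        n_environments=len(environments),
        n_binned=n_binned,
        n_out_of_bounds=n_oob,
        n_missing_atom=n_missing,
    )
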