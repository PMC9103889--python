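"""Synthetic protein+probe trajectories with planted, recoverable truth.

The generator plants geometry, not physics: a compact pseudo-fold, probe
copies that either sit at a declared hotspot (with a declared visit
probability, small rigid jitter, and a random symmetry relabel) or diffuse
far from the protein, and residues whose Cβ sits at a declared offset from
the hotspot.  Every downstream stage can therefore be tested against known
ground truth at desk scale, without MD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .probes import ProbeDefinition, get_probe
from .trajectory import (
    AtomRecord,
    ProbeInstance,
    ResidueRecord,
    Snapshot,
    Trajectory,
)

__all__ = [
    "PlantedResidue",
    "Hotspot",
    "PlantedTruth",
    "PackingInfeasibleError",
    "generate_toy_protein",
    "random_probe_placement",
    "generate_msmd_trajectory",
    "build_planted_residue",
    "reference_configuration",
    "make_reference_system",
    "generate_reference_runs",
]

_BACKBONE = ("N", "CA", "C", "O")

#: Map from residue-type names to their member codes (used to expand
#: type-level composition weights).
_TYPE_MEMBERS = {
    "acidic": ["ASP", "GLU"],
    "basic": ["ARG", "HIS", "LYS"],
    "hydrophilic": ["ASN", "CYS", "GLN", "SER", "THR"],
    "hydrophobic": ["ALA", "ILE", "LEU", "MET", "PRO", "VAL"],
    "aromatic": ["PHE", "TRP", "TYR"],
}


class PackingInfeasibleError(RuntimeError):
    """Random placement could not satisfy the separation constraint."""


@dataclass(frozen=True)
class PlantedResidue:
    resname: str
    cb_offset: np.ndarray  # Å, from the hotspot center


@dataclass(frozen=True)
class Hotspot:
    center: np.ndarray  # Å
    occupancy: float  # visit probability per frame, in (0, 1]
    residues: tuple[PlantedResidue, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")


@dataclass
class PlantedTruth:
    hotspots: list[Hotspot]
    box: np.ndarray  # orthorhombic box lengths, Å
    seed: int

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)


def _expand_composition(composition: dict[str, float]) -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    weights: list[float] = []
    for key, w in composition.items():
        if w < 0:
            raise ValueError(f"composition weight for {key!r} is negative")
        members = _TYPE_MEMBERS.get(key.lower(), [key.upper()])
        for m in members:
            names.append(m)
            weights.append(float(w) / len(members))
    total = sum(weights)
    if total <= 0:
        raise ValueError("composition weights must sum to a positive value")
    return names, np.array(weights) / total


def generate_toy_protein(
    n_residues: int,
    composition: dict[str, float] | None = None,
    seed: int = 0,
) -> list[ResidueRecord]:
    """A compact helical pseudo-fold with N/CA/C/O/CB atoms per residue.

    Residue names are drawn from ``composition`` (weights keyed by 3-letter
    code or by residue-type name); glycine is emitted without a CB atom.
    Deterministic under ``seed``.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if composition is None:
        composition = {"hydrophobic": 0.4, "hydrophilic": 0.3, "basic": 0.2, "aromatic": 0.1}
    names, weights = _expand_composition(composition)
    rng = np.random.default_rng(seed)
    resnames = rng.choice(names, size=n_residues, p=weights)

    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    residues: list[ResidueRecord] = []
    for i in range(n_residues):
        angle = i * turn
        ca = np.array([radius * np.cos(angle), radius * np.sin(angle), i * rise])
        axis_out = np.array([np.cos(angle), np.sin(angle), 0.0])
        tangent = np.array([-np.sin(angle), np.cos(angle), 0.0])
        res = ResidueRecord(str(resnames[i]), "A", i + 1)
        res.atoms.append(AtomRecord("N", "N", ca - 1.46 * tangent + [0, 0, -0.4]))
        res.atoms.append(AtomRecord("CA", "C", ca))
        res.atoms.append(AtomRecord("C", "C", ca + 1.52 * tangent + [0, 0, 0.4]))
        res.atoms.append(AtomRecord("O", "O", ca + 1.52 * tangent + 1.23 * axis_out + [0, 0, 0.6]))
        if res.resname != "GLY":
            res.atoms.append(AtomRecord("CB", "C", ca + 1.53 * axis_out))
        residues.append(res)
    return residues


def random_probe_placement(
    box: np.ndarray,
    n_probes: int,
    min_separation: float,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Rejection-sampled positions with pairwise minimum-image separation.

    Mirrors the anti-aggregation constraint of cosolvent system builders.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_probes:
        if attempts >= max_attempts:
            raise PackingInfeasibleError(
                f"placed {len(positions)}/{n_probes} probes in {max_attempts} attempts"
            )
        attempts += 1
        candidate = rng.uniform(0, box)
        ok = True
        for p in positions:
            delta = candidate - p
            delta -= box * np.round(delta / box)
            if np.linalg.norm(delta) < min_separation:
                ok = False
                break
        if ok:
            positions.append(candidate)
    return np.array(positions)


def build_planted_residue(
    resname: str,
    cb_position: np.ndarray,
    away_direction: np.ndarray,
    resseq: int = 900,
    chain: str = "Z",
) -> ResidueRecord:
    """A residue whose CB sits exactly at ``cb_position``.

    The backbone is placed further along ``away_direction`` so that the CB
    is the residue's closest heavy atom to whatever the direction points
    away from.
    """
    cb = np.asarray(cb_position, dtype=float)
    u = np.asarray(away_direction, dtype=float)
    u = u / np.linalg.norm(u)
    # any vector perpendicular to u
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)

    ca = cb + 1.53 * u
    res = ResidueRecord(resname.upper(), chain, resseq)
    res.atoms.append(AtomRecord("N", "N", ca + 1.46 * (0.7 * u + 0.7 * v)))
    res.atoms.append(AtomRecord("CA", "C", ca))
    res.atoms.append(AtomRecord("C", "C", ca + 1.52 * (0.7 * u - 0.7 * v)))
    res.atoms.append(AtomRecord("O", "O", ca + 1.52 * (0.7 * u - 0.7 * v) + 1.23 * u))
    if res.resname != "GLY":
        res.atoms.append(AtomRecord("CB", "C", cb))
    return res


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


def _small_rotation(rng: np.random.Generator, degrees: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(scale=degrees))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _probe_element(name: str) -> str:
    return name.rstrip("0123456789")[:1].upper() or "C"


def _hotspot_pose(
    probe: ProbeDefinition,
    center: np.ndarray,
    rng: np.random.Generator,
    jitter: float,
    wobble_deg: float,
) -> dict[str, np.ndarray]:
    """Probe coordinates with the anchor (first alignment atom) at ``center``.

    A random symmetry relabel keeps the atom *sites* fixed while exercising
    the symmetry-mapping alignment path downstream; a small wobble rotation
    about the anchor and a rigid translation jitter perturb the pose.
    """
    anchor_name = probe.alignment_atom_names[0]
    base = {n: probe.atoms[n] - probe.atoms[anchor_name] + center for n in probe.atoms}
    if set(probe.alignment_atom_names) == set(probe.atoms):
        mapping = probe.symmetry_mappings[rng.integers(len(probe.symmetry_mappings))]
        # atom mapping[i] takes the site of alignment atom i
        base = {mapping[i]: base[probe.alignment_atom_names[i]] for i in range(len(mapping))}
    rot = _small_rotation(rng, wobble_deg)
    anchor_pos = base[anchor_name]
    shift = rng.normal(scale=jitter, size=3) if jitter > 0 else np.zeros(3)
    return {n: rot @ (p - anchor_pos) + anchor_pos + shift for n, p in base.items()}


def _diffuse_pose(
    probe: ProbeDefinition,
    protein_coords: np.ndarray,
    truth: PlantedTruth,
    rng: np.random.Generator,
    clearance: float,
    max_attempts: int = 2_000,
) -> dict[str, np.ndarray]:
    centroid_local = probe.centroid()
    for _ in range(max_attempts):
        pos = rng.uniform(0, truth.box)
        if protein_coords.size:
            if np.min(np.linalg.norm(protein_coords - pos, axis=1)) < clearance:
                continue
        if any(np.linalg.norm(h.center - pos) < clearance for h in truth.hotspots):
            continue
        rot = _random_rotation(rng)
        return {n: rot @ (probe.atoms[n] - centroid_local) + pos for n in probe.atoms}
    raise PackingInfeasibleError("could not place a diffuse probe copy")


def generate_msmd_trajectory(
    protein: list[ResidueRecord],
    truth: PlantedTruth,
    n_frames: int,
    probe: ProbeDefinition,
    *,
    n_probes: int = 5,
    timestep: float = 10.0,
    t_start: float = 0.0,
    jitter: float = 0.3,
    wobble_deg: float = 4.0,
    clearance: float = 7.0,
    seed: int = 0,
    run_id: str = "run1",
) -> Trajectory:
    """Generate one pseudo-run with planted hotspot statistics.

    Probe copy ``k`` is bound to hotspot ``k`` (while hotspots last): on
    each frame it visits its hotspot with the hotspot's occupancy
    probability and otherwise diffuses far from the protein, as do all
    remaining copies.  The planted residues are appended to the protein,
    which is otherwise static.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    full_protein = list(protein)
    for hotspot in truth.hotspots:
        for planted in hotspot.residues:
            offset = np.asarray(planted.cb_offset, dtype=float)
            full_protein.append(
                build_planted_residue(
                    planted.resname,
                    hotspot.center + offset,
                    offset,
                    resseq=900 + len(full_protein),
                )
            )
    protein_coords = (
        np.vstack([r.heavy_coords() for r in full_protein])
        if full_protein
        else np.empty((0, 3))
    )

    snapshots: list[Snapshot] = []
    for frame in range(n_frames):
        probes: list[ProbeInstance] = []
        for k in range(n_probes):
            if k < len(truth.hotspots) and rng.random() < truth.hotspots[k].occupancy:
                coords = _hotspot_pose(
                    probe, truth.hotspots[k].center, rng, jitter, wobble_deg
                )
            else:
                coords = _diffuse_pose(probe, protein_coords, truth, rng, clearance)
            instance = ProbeInstance(
                copy_id=f"P{k + 1}",
                atoms=[
                    AtomRecord(n, _probe_element(n), coords[n]) for n in probe.atom_names
                ],
                alignment_atom_names=list(probe.alignment_atom_names),
                symmetry_mappings=[list(m) for m in probe.symmetry_mappings],
            )
            probes.append(instance)
        # per-frame copies: fitting transforms snapshots in place, so frames
        # must not alias each other's atom records
        frame_protein = [
            ResidueRecord(
                r.resname,
                r.chain,
                r.resseq,
                [AtomRecord(a.name, a.element, a.coords.copy()) for a in r.atoms],
            )
            for r in full_protein
        ]
        snapshots.append(
            Snapshot(
                time=t_start + (frame + 1) * timestep,
                protein=frame_protein,
                probes=probes,
                box=truth.box.copy(),
            )
        )
    return Trajectory(run_id=run_id, snapshots=snapshots, timestep=timestep)


# ---------------------------------------------------------------------------
# Documented reference configuration for planted-truth recovery
# ---------------------------------------------------------------------------

def reference_configuration() -> dict:
    """Parameters of the documented planted-truth reference setup.

    20 pseudo-runs of 200 frames, 5 probe copies of the C2v test probe, one
    hotspot visited with probability 0.5 carrying a planted ASP whose CB
    sits 3.2 Å from the probe anchor along the twofold axis.  The profile
    grid margin of 8.5 Å places the planted CB target at a voxel center
    (the analysis grid is likewise center-aligned on the hotspot), so the
    recovery checks are not at the mercy of voxel-face ties.
    """
    return {
        "n_runs": 20,
        "n_frames": 200,
        "n_probes": 5,
        "n_residues": 20,
        "occupancy": 0.5,
        "probe_preset": "vprobe",
        "planted_resname": "ASP",
        "planted_offset": (0.0, 0.0, 3.2),
        "timestep": 10.0,
        "jitter": 0.3,
        "wobble_deg": 4.0,
        "clearance": 7.0,
        "grid_spacing": 1.0,
        "grid_margin": 8.0,
        "profile_margin": 8.5,
        "shell_cutoff": 5.0,
        "surface_theta": 0.2,
        "environment_cutoff": 4.0,
        "composition": {"hydrophobic": 0.4, "hydrophilic": 0.3, "basic": 0.2, "aromatic": 0.1},
    }


def make_reference_system(seed: int = 0) -> tuple[list[ResidueRecord], PlantedTruth, ProbeDefinition]:
    """Build the protein, planted truth, and probe of the reference setup."""
    cfg = reference_configuration()
    protein = generate_toy_protein(cfg["n_residues"], cfg["composition"], seed=seed)
    probe = get_probe(cfg["probe_preset"])
    coords = np.vstack([r.heavy_coords() for r in protein])
    center_xy = coords[:, :2].mean(axis=0)
    hotspot_center = np.array([center_xy[0], center_xy[1], coords[:, 2].max() + 6.0])
    box = np.ceil(coords.max(axis=0) - coords.min(axis=0)) + 36.0
    # keep all coordinates inside [0, box): shift handled by construction —
    # the toy fold sits near the origin, so recenter it into the box
    shift = box / 2 - coords.mean(axis=0)
    for res in protein:
        for atom in res.atoms:
            atom.coords = atom.coords + shift
    hotspot_center = hotspot_center + shift
    truth = PlantedTruth(
        hotspots=[
            Hotspot(
                center=hotspot_center,
                occupancy=cfg["occupancy"],
                residues=(
                    PlantedResidue(cfg["planted_resname"], np.array(cfg["planted_offset"])),
                ),
            )
        ],
        box=box,
        seed=seed,
    )
    return protein, truth, probe


def generate_reference_runs(
    seed: int = 0, n_runs: int | None = None, n_frames: int | None = None
) -> tuple[list[Trajectory], PlantedTruth, ProbeDefinition]:
    """Generate the documented reference pseudo-runs (seeds ``seed + k``)."""
    cfg = reference_configuration()
    n_runs = n_runs if n_runs is not None else cfg["n_runs"]
    n_frames = n_frames if n_frames is not None else cfg["n_frames"]
    protein, truth, probe = make_reference_system(seed)
    runs = [
        generate_msmd_trajectory(
            protein,
            truth,
            n_frames,
            probe,
            n_probes=cfg["n_probes"],
            timestep=cfg["timestep"],
            jitter=cfg["jitter"],
            wobble_deg=cfg["wobble_deg"],
            clearance=cfg["clearance"],
            seed=seed * 10_000 + k,
            run_id=f"run{k + 1}",
        )
        for k in range(n_runs)
    ]
    return runs, truth, probe
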