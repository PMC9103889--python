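"""Data model and I/O for protein+probe trajectories.

Trajectories arrive as multi-model PDB files (MODEL/ENDMDL blocks).  Probe
copies are identified by a configurable residue name and grouped by
(chain, residue number); every other standard amino-acid record forms the
protein.  Hydrogens are parsed and kept but flagged non-heavy, and every
distance or binning computation downstream uses heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .superpose import RigidTransform, UnderdeterminedFitError, fit_rigid

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ProbeInstance",
    "Snapshot",
    "Trajectory",
    "TrajectoryFormatError",
    "TrajectoryConsistencyError",
    "ProbeNotFoundError",
    "AVOGADRO",
    "STANDARD_AMINO_ACIDS",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "snapshot_schedule",
    "fit_protein_to_reference",
    "probe_count_for_concentration",
]

AVOGADRO = 6.02214076e23

#: Standard residue names accepted as protein, including common protonation
#: variants emitted by MD preparation tools (mapped onto their parent code).
RESNAME_ALIASES = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "CYX": "CYS", "CYM": "CYS",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
}

STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


class TrajectoryFormatError(ValueError):
    """The input file is not a usable multi-model PDB."""


class TrajectoryConsistencyError(ValueError):
    """Snapshots disagree on the atom inventory."""


class ProbeNotFoundError(ValueError):
    """The configured probe residue name never occurs in the file."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        self.element = self.element.strip().upper()

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class ResidueRecord:
    resname: str
    chain: str
    resseq: int
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def cbeta(self) -> AtomRecord | None:
        for atom in self.atoms:
            if atom.name == "CB":
                return atom
        return None

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(coords) if coords else np.empty((0, 3))


@dataclass
class ProbeInstance:
    copy_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    alignment_atom_names: list[str] = field(default_factory=list)
    symmetry_mappings: list[list[str]] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(coords) if coords else np.empty((0, 3))

    def heavy_centroid(self) -> np.ndarray:
        coords = self.heavy_coords()
        if coords.size == 0:
            raise ValueError(f"probe {self.copy_id} has no heavy atoms")
        return coords.mean(axis=0)

    def coords_of(self, names: Sequence[str]) -> np.ndarray:
        out = []
        for name in names:
            atom = self.atom(name)
            if atom is None:
                raise KeyError(f"probe {self.copy_id} has no atom named {name!r}")
            out.append(atom.coords)
        return np.array(out)


@dataclass
class Snapshot:
    time: float  # ps
    protein: list[ResidueRecord]
    probes: list[ProbeInstance]
    box: np.ndarray | None = None  # orthorhombic box lengths, Å

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("snapshot time must be non-negative")
        ids = [p.copy_id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("probe copy ids must be unique within a snapshot")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def protein_heavy_coords(self) -> np.ndarray:
        blocks = [r.heavy_coords() for r in self.protein]
        blocks = [b for b in blocks if b.size]
        return np.vstack(blocks) if blocks else np.empty((0, 3))

    def protein_ca_coords(self) -> np.ndarray:
        coords = []
        for res in self.protein:
            ca = res.atom("CA")
            if ca is not None:
                coords.append(ca.coords)
        return np.array(coords) if coords else np.empty((0, 3))

    def probe_heavy_coords(self) -> np.ndarray:
        blocks = [p.heavy_coords() for p in self.probes]
        blocks = [b for b in blocks if b.size]
        return np.vstack(blocks) if blocks else np.empty((0, 3))

    def apply_transform(self, transform: RigidTransform) -> None:
        for res in self.protein:
            for atom in res.atoms:
                atom.coords = transform.apply(atom.coords)
        for probe in self.probes:
            for atom in probe.atoms:
                atom.coords = transform.apply(atom.coords)


@dataclass
class Trajectory:
    run_id: str
    snapshots: list[Snapshot]
    timestep: float  # ps between consecutive snapshots

    def __post_init__(self) -> None:
        times = [s.time for s in self.snapshots]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def probe(self, snapshot: Snapshot, copy_id: str) -> ProbeInstance | None:
        for p in snapshot.probes:
            if p.copy_id == copy_id:
                return p
        return None

    def probe_ids(self) -> list[str]:
        return [p.copy_id for p in self.snapshots[0].probes] if self.snapshots else []


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    # two-letter elements common in proteins
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN", "SE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _parse_atom_line(line: str) -> tuple[str, str, str, int, np.ndarray, str]:
    name = line[12:16].strip()
    resname = line[17:20].strip().upper()
    chain = line[21].strip() or "A"
    resseq = int(line[22:26])
    coords = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return name, resname, chain, resseq, coords, element


def read_multimodel_pdb(
    path: str | Path,
    probe_resname: str,
    *,
    timestep: float = 10.0,
    t_start: float = 0.0,
    run_id: str | None = None,
) -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory`.

    Each MODEL block becomes one :class:`Snapshot`; snapshot times are
    assigned as ``t_start + k * timestep`` with ``k = 1, 2, ...`` (the file
    format itself carries no time information).  ATOM/HETATM records with
    ``probe_resname`` are grouped into probe copies by (chain, residue
    number); standard amino-acid records form the protein; everything else
    (waters, ions) is ignored.
    """
    path = Path(path)
    probe_resname = probe_resname.strip().upper()
    text = path.read_text()
    if "MODEL" not in text:
        raise TrajectoryFormatError(f"{path}: no MODEL records found")

    snapshots: list[Snapshot] = []
    box: np.ndarray | None = None
    probe_seen = False
    first_inventory: int | None = None

    current_protein: dict[tuple[str, int], ResidueRecord] = {}
    current_probes: dict[tuple[str, int], ProbeInstance] = {}
    in_model = False
    model_index = 0
    n_atoms = 0

    def flush() -> None:
        nonlocal first_inventory, n_atoms
        snap = Snapshot(
            time=t_start + (len(snapshots) + 1) * timestep,
            protein=list(current_protein.values()),
            probes=list(current_probes.values()),
            box=None if box is None else box.copy(),
        )
        if first_inventory is None:
            first_inventory = n_atoms
        elif n_atoms != first_inventory:
            raise TrajectoryConsistencyError(
                f"{path}: model {model_index} has {n_atoms} atoms, "
                f"expected {first_inventory}"
            )
        snapshots.append(snap)

    for line in text.splitlines():
        record = line[:6].strip()
        if record == "CRYST1":
            box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
        elif record == "MODEL":
            in_model = True
            model_index += 1
            current_protein = {}
            current_probes = {}
            n_atoms = 0
        elif record == "ENDMDL":
            if in_model:
                flush()
            in_model = False
        elif record in ("ATOM", "HETATM") and in_model:
            name, resname, chain, resseq, coords, element = _parse_atom_line(line)
            atom = AtomRecord(name, element, coords)
            if resname == probe_resname:
                probe_seen = True
                key = (chain, resseq)
                if key not in current_probes:
                    current_probes[key] = ProbeInstance(copy_id=f"{chain}{resseq}")
                current_probes[key].atoms.append(atom)
                n_atoms += 1
            else:
                canonical = RESNAME_ALIASES.get(resname, resname)
                if canonical in STANDARD_AMINO_ACIDS:
                    key = (chain, resseq)
                    if key not in current_protein:
                        current_protein[key] = ResidueRecord(canonical, chain, resseq)
                    current_protein[key].atoms.append(atom)
                    n_atoms += 1

    if not snapshots:
        raise TrajectoryFormatError(f"{path}: MODEL records present but none closed")
    if not probe_seen:
        raise ProbeNotFoundError(
            f"{path}: probe residue name {probe_resname!r} never occurs"
        )
    return Trajectory(run_id=run_id or path.stem, snapshots=snapshots, timestep=timestep)


def _format_atom_line(
    serial: int,
    atom: AtomRecord,
    resname: str,
    chain: str,
    resseq: int,
    hetatm: bool,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"{record}{serial:>5d} {name:<4.4s} {resname:<3.3s} {chain:1.1s}"
        f"{resseq:>4d}    "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}"
    )


def write_multimodel_pdb(
    traj: Trajectory, path: str | Path, probe_resname: str = "PRB"
) -> None:
    """Write a trajectory as a multi-model PDB readable by :func:`read_multimodel_pdb`."""
    path = Path(path)
    lines: list[str] = []
    box = traj.snapshots[0].box if traj.snapshots else None
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for i, snap in enumerate(traj.snapshots, start=1):
        lines.append(f"MODEL     {i:>4d}")
        serial = 1
        for res in snap.protein:
            for atom in res.atoms:
                lines.append(
                    _format_atom_line(serial, atom, res.resname, res.chain, res.resseq, False)
                )
                serial += 1
        for k, probe in enumerate(snap.probes, start=1):
            for atom in probe.atoms:
                lines.append(
                    _format_atom_line(serial, atom, probe_resname, "X", k, True)
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Schedule, fitting, setup arithmetic
# ---------------------------------------------------------------------------

def snapshot_schedule(t_start: float, t_end: float, interval: float) -> np.ndarray:
    """Snapshot times over the half-open window ``(t_start, t_end]``.

    Returns ``t_start + k * interval`` for ``k = 1 .. floor((t_end - t_start)
    / interval)``; the convention reproduces 2000 snapshots for a 20 ns
    window sampled every 10 ps.
    """
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    n = int(np.floor((t_end - t_start) / interval + 1e-9))
    return t_start + interval * np.arange(1, n + 1)


def fit_protein_to_reference(
    traj: Trajectory, reference_ca: np.ndarray | None = None
) -> Trajectory:
    """Rigidly superpose every snapshot onto a reference via protein Cα atoms.

    The same transform is applied to probe atoms so the probe-protein
    geometry is preserved.  By default the reference is the trajectory's own
    first snapshot; passing explicit reference Cα coordinates lets several
    runs share one frame (required before any cross-run voxelwise maximum).
    Transforms the trajectory in place and returns it.
    """
    if not traj.snapshots:
        raise ValueError("empty trajectory")
    if reference_ca is None:
        reference_ca = traj.snapshots[0].protein_ca_coords()
    reference_ca = np.asarray(reference_ca, dtype=float)
    if reference_ca.shape[0] < 3:
        raise UnderdeterminedFitError(
            f"need >=3 Calpha atoms to fit, got {reference_ca.shape[0]}"
        )
    for snap in traj.snapshots:
        mobile = snap.protein_ca_coords()
        if mobile.shape != reference_ca.shape:
            raise TrajectoryConsistencyError(
                f"snapshot at t={snap.time} ps has {mobile.shape[0]} Calpha atoms, "
                f"reference has {reference_ca.shape[0]}"
            )
        transform, _ = fit_rigid(mobile, reference_ca)
        snap.apply_transform(transform)
    return traj


def probe_count_for_concentration(box_volume: float, molarity: float) -> int:
    """Number of probe copies giving ``molarity`` in a box of ``box_volume`` ų."""
    if box_volume <= 0:
        raise ValueError(f"box volume must be positive, got {box_volume}")
    if molarity <= 0:
        raise ValueError(f"molarity must be positive, got {molarity}")
    return int(round(molarity * AVOGADRO * box_volume * 1e-27))
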