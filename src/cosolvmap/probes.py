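"""Probe definitions: template geometry, alignment atoms, symmetry mappings.

Presets for benzene, catechol, benzamidine, and a small synthetic C2v probe
ship as package data; users can supply their own definition in the run
configuration.  Symmetry mappings are explicit atom-name permutations of the
alignment list — no automatic symmetry perception is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ProbeDefinition", "ProbeDefinitionError", "load_presets", "get_probe"]


class ProbeDefinitionError(ValueError):
    pass


@dataclass
class ProbeDefinition:
    name: str
    resname: str
    atoms: dict[str, np.ndarray]
    alignment_atom_names: list[str]
    symmetry_mappings: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        missing = [n for n in self.alignment_atom_names if n not in self.atoms]
        if missing:
            raise ProbeDefinitionError(
                f"probe {self.name}: alignment atoms {missing} not in atom set"
            )
        if not self.symmetry_mappings:
            self.symmetry_mappings = [list(self.alignment_atom_names)]
        ref = sorted(self.alignment_atom_names)
        for mapping in self.symmetry_mappings:
            if sorted(mapping) != ref:
                raise ProbeDefinitionError(
                    f"probe {self.name}: mapping {mapping} is not a permutation "
                    f"of the alignment atoms"
                )

    @property
    def atom_names(self) -> list[str]:
        return list(self.atoms)

    def template_coords(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.atom_names
        return np.array([self.atoms[n] for n in names])

    def alignment_coords(self) -> np.ndarray:
        return self.template_coords(self.alignment_atom_names)

    def centroid(self) -> np.ndarray:
        return self.template_coords().mean(axis=0)

    @classmethod
    def from_dict(cls, name: str, payload: dict) -> "ProbeDefinition":
        try:
            return cls(
                name=name,
                resname=str(payload["resname"]).upper(),
                atoms={str(k): v for k, v in payload["atoms"].items()},
                alignment_atom_names=[str(n) for n in payload["alignment_atoms"]],
                symmetry_mappings=[
                    [str(n) for n in m] for m in payload.get("symmetry_mappings", [])
                ],
            )
        except KeyError as exc:
            raise ProbeDefinitionError(f"probe {name}: missing key {exc}") from exc


def load_presets(path: str | Path | None = None) -> dict[str, ProbeDefinition]:
    """Load the packaged probe presets (or an alternative YAML file)."""
    if path is None:
        text = resources.files("cosolvmap.data").joinpath("probes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: ProbeDefinition.from_dict(name, payload) for name, payload in raw.items()}


def get_probe(name: str) -> ProbeDefinition:
    presets = load_presets()
    if name not in presets:
        raise ProbeDefinitionError(
            f"unknown probe preset {name!r}; available: {sorted(presets)}"
        )
    return presets[name]
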