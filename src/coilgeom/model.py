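"""Lightweight hierarchical coordinate model.

Chains hold residues, residues hold heavy atoms.  Coordinates are plain
numpy arrays in Angstrom; residue numbering follows the depositors' (author)
numbering throughout, so residue windows given elsewhere in the package
(e.g. junction windows 1-12 and 150-161) refer to author numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Average atomic masses for mass-weighted centroids (heavy atoms only;
# crystal structures of proteins carry no hydrogens).
ATOMIC_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


@dataclass
class AtomRecord:
    """One heavy atom: name, element, position (Å), occupancy, B-factor."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)


@dataclass
class Residue:
    seqid: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def center_of_mass(self, weighted: bool = True) -> np.ndarray:
        xyz = self.coords()
        if not weighted:
            return xyz.mean(axis=0)
        w = np.array([a.mass for a in self.atoms])
        return (xyz * w[:, None]).sum(axis=0) / w.sum()


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqid: int) -> Residue | None:
        for r in self.residues:
            if r.seqid == seqid:
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ChainTrace:
    """Ordered Cα trace of one chain, with author residue numbers."""

    chain_id: str
    residue_numbers: np.ndarray
    ca_positions: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.ca_positions = np.asarray(self.ca_positions, dtype=float)
        if len(self.residue_numbers) != len(self.ca_positions):
            raise ValueError("residue_numbers and ca_positions lengths differ")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def reversed(self) -> "ChainTrace":
        return ChainTrace(self.chain_id, self.residue_numbers[::-1].copy(),
                          self.ca_positions[::-1].copy())


@dataclass
class StructureModel:
    """Protein chains plus optional crystallographic metadata.

    ``cell`` is (a, b, c, alpha, beta, gamma) in Å / degrees; ``meta`` carries
    provenance such as generator parameters for synthetic structures.
    """

    chains: list[Chain] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    meta: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        available = ", ".join(c.chain_id for c in self.chains)
        raise KeyError(f"chain {chain_id!r} not found; available chains: {available}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def validate(self) -> None:
        for c in self.chains:
            nums = [r.seqid for r in c.residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(f"chain {c.chain_id}: residue numbers not strictly increasing")
            for r in c.residues:
                if not r.atoms:
                    raise ValueError(f"chain {c.chain_id} residue {r.seqid}: no atoms")

    def all_atoms(self, chain_ids: list[str] | None = None):
        """Flat list of (chain_id, seqid, residue_name, AtomRecord)."""
        out = []
        for c in self.chains:
            if chain_ids is not None and c.chain_id not in chain_ids:
                continue
            for r in c.residues:
                for a in r.atoms:
                    out.append((c.chain_id, r.seqid, r.name, a))
        return out

    def coordinates(self, chain_ids: list[str] | None = None) -> np.ndarray:
        return np.array([a.position for _, _, _, a in self.all_atoms(chain_ids)])

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed deep copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_chains = []
        for c in self.chains:
            residues = [
                Residue(r.seqid, r.name,
                        [AtomRecord(a.name, a.element, R @ a.position + t,
                                    a.occupancy, a.b_factor, a.altloc)
                         for a in r.atoms])
                for r in c.residues
            ]
            new_chains.append(Chain(c.chain_id, residues))
        return StructureModel(new_chains, self.cell, self.space_group, dict(self.meta))

    def subset(self, chain_ids: list[str]) -> "StructureModel":
        chains = [c for c in self.chains if c.chain_id in chain_ids]
        missing = set(chain_ids) - {c.chain_id for c in chains}
        if missing:
            raise KeyError(f"chains not found: {sorted(missing)}")
        return StructureModel(chains, self.cell, self.space_group, dict(self.meta))
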