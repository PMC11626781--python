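"""Van-der-Waals contact counting, Shrake–Rupley SASA, and buried area.

Contacts between two atom sets are defined through the VdW overlap
(r_i + r_j) - d: pairs whose overlap falls in a band (default -0.4 to
0.6 Å) count as contacts — small positive overlaps are close packing,
larger ones are clashes and are excluded.  Solvent-accessible surface area
uses deterministic Fibonacci-sphere quadrature (Shrake–Rupley), and the
buried interface area is the SASA lost on complex formation:
SAS(A) + SAS(B) - SAS(AB).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import StructureModel

DEFAULT_BAND = (-0.4, 0.6)
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


class ContactError(ValueError):
    pass


@dataclass
class VdwRadiiTable:
    """Element -> VdW radius (Å) mapping with an optional fallback radius."""

    radii: dict[str, float]
    table_name: str = "custom"
    default: float | None = None

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not 1.0 < r < 2.5:
                raise ValueError(f"radius for {el} ({r} Å) outside the plausible (1.0, 2.5) Å")

    @classmethod
    def from_name(cls, name: str = "bondi", default: float | None = None) -> "VdwRadiiTable":
        path = resources.files("coilgeom").joinpath("data", f"vdw_{name}.tsv")
        if not path.is_file():
            raise FileNotFoundError(f"no packaged radii table named {name!r}")
        return cls.from_file(path, table_name=name, default=default)

    @classmethod
    def from_file(cls, path, table_name: str | None = None,
                  default: float | None = None) -> "VdwRadiiTable":
        radii = {}
        for line in Path(str(path)).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, r = line.split("\t")
            radii[el.upper()] = float(r)
        return cls(radii, table_name or Path(str(path)).stem, default)

    def radius(self, element: str) -> float:
        r = self.radii.get(element.upper(), self.default)
        if r is None:
            raise ContactError(
                f"no VdW radius for element {element!r} in table {self.table_name!r} "
                "and no default declared")
        return r

    def for_atoms(self, atoms) -> np.ndarray:
        return np.array([self.radius(a.element) for _, _, _, a in atoms])


@dataclass
class Contact:
    atom_i: str   # "chain:resnum:atom" in set A
    atom_j: str   # same, set B
    distance: float
    overlap: float


@dataclass
class ContactSet:
    contacts: list[Contact]
    band: tuple[float, float]
    table_name: str

    @property
    def count(self) -> int:
        return len(self.contacts)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(
            [(c.atom_i, c.atom_j, round(c.distance, 3), round(c.overlap, 3))
             for c in self.contacts],
            columns=["atom_i", "atom_j", "distance_A", "overlap_A"])


def _atom_label(chain_id: str, seqid: int, name: str) -> str:
    return f"{chain_id}:{seqid}:{name}"


def vdw_contacts(set_a: StructureModel, set_b: StructureModel,
                 radii: VdwRadiiTable | None = None,
                 band: tuple[float, float] = DEFAULT_BAND) -> ContactSet:
    """All cross pairs whose VdW overlap lies in the closed ``band``.

    Neighbor-list accelerated (KD-tree with the maximal reach of the band);
    exactly equivalent to the all-pairs definition.
    """
    if radii is None:
        radii = VdwRadiiTable.from_name("bondi")
    atoms_a = set_a.all_atoms()
    atoms_b = set_b.all_atoms()
    if not atoms_a or not atoms_b:
        raise ContactError("empty atom set")
    xyz_a = np.array([a.position for _, _, _, a in atoms_a])
    xyz_b = np.array([a.position for _, _, _, a in atoms_b])
    ra = radii.for_atoms(atoms_a)
    rb = radii.for_atoms(atoms_b)

    # overlap >= band_lo  <=>  d <= r_i + r_j - band_lo
    reach = ra.max() + rb.max() - band[0]
    tree = cKDTree(xyz_b)
    contacts = []
    for i, neighbors in enumerate(tree.query_ball_point(xyz_a, reach)):
        for j in neighbors:
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            overlap = ra[i] + rb[j] - d
            if band[0] <= overlap <= band[1]:
                ca, sa, _, aa = atoms_a[i]
                cb, sb, _, ab = atoms_b[j]
                contacts.append(Contact(_atom_label(ca, sa, aa.name),
                                        _atom_label(cb, sb, ab.name), d, overlap))
    contacts.sort(key=lambda c: (c.atom_i, c.atom_j))
    return ContactSet(contacts, band, radii.table_name)


# ---------------------------------------------------------------------------
# SASA


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa_atoms(xyz: np.ndarray, radii: np.ndarray, probe: float = DEFAULT_PROBE,
               n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom Shrake–Rupley solvent-accessible areas (Å²)."""
    if n_points < 100:
        raise ValueError("need n_points >= 100 for a meaningful quadrature")
    xyz = np.asarray(xyz, float)
    radii = np.asarray(radii, float)
    sphere = _fibonacci_sphere(n_points)
    R = radii + probe
    tree = cKDTree(xyz)
    areas = np.zeros(len(xyz))
    reach = 2.0 * R.max()
    for i in range(len(xyz)):
        pts = xyz[i] + R[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], reach) if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(-1)
            r2 = (R[nb] ** 2)[None, :]
            inside = d2 < r2 - 1e-7
            # boundary tie-break (exactly coincident/touching spheres): the
            # lower-index atom keeps the shared surface
            on_boundary = (np.abs(d2 - r2) <= 1e-7) & (nb < i)[None, :]
            frac = 1.0 - (inside | on_boundary).any(axis=1).mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * R[i] ** 2
    return areas


def sasa(model: StructureModel, radii: VdwRadiiTable | None = None,
         probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS) -> float:
    """Total solvent-accessible surface area of the model (Å²)."""
    if radii is None:
        radii = VdwRadiiTable.from_name("bondi")
    atoms = model.all_atoms()
    xyz = np.array([a.position for _, _, _, a in atoms])
    return float(sasa_atoms(xyz, radii.for_atoms(atoms), probe, n_points).sum())


def buried_area(c_dimer: StructureModel, n_dimer: StructureModel,
                radii: VdwRadiiTable | None = None, probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> float:
    """Interface area buried between two dimers: SAS(A) + SAS(B) - SAS(AB), Å²."""
    if radii is None:
        radii = VdwRadiiTable.from_name("bondi")
    merged = StructureModel(list(c_dimer.chains) + list(n_dimer.chains))
    a = sasa(c_dimer, radii, probe, n_points)
    b = sasa(n_dimer, radii, probe, n_points)
    ab = sasa(merged, radii, probe, n_points)
    return a + b - ab


def contact_density(count: int, buried: float) -> float:
    """Contacts per 1000 Å² of buried interface area."""
    if buried <= 0:
        raise ContactError("contact density undefined for non-positive buried area")
    return 1000.0 * count / buried
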