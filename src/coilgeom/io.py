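"""Read/write macromolecular coordinates and assemble lattice neighbors.

gemmi does the heavy lifting for PDB/mmCIF parsing and crystallographic
symmetry; this module converts to/from the package's own containers,
applies the protein-only / highest-occupancy-altloc filtering policy, and
exposes brute-force lattice-neighbor expansion so head-to-tail junctions
present only between crystal copies can be reconstructed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .model import AtomRecord, Chain, ChainTrace, Residue, StructureModel

log = logging.getLogger(__name__)

_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


class StructureError(ValueError):
    pass


def _from_gemmi(st: gemmi.Structure, include_hetero: bool = False) -> StructureModel:
    st.setup_entities()
    model = st[0]
    chains = []
    for gch in model:
        residues = []
        for gres in gch:
            het = gres.het_flag == "H" or gres.is_water()
            if het and not include_hetero:
                continue
            if gres.is_water():
                continue
            # altloc policy: highest occupancy wins, ties by altloc letter
            by_name: dict[str, gemmi.Atom] = {}
            for ga in gres:
                if ga.is_hydrogen():
                    continue
                prev = by_name.get(ga.name)
                if prev is None or (ga.occ, -ord(ga.altloc or "z")) > (prev.occ, -ord(prev.altloc or "z")):
                    by_name[ga.name] = ga
            atoms = [
                AtomRecord(ga.name, ga.element.name,
                           np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                           min(max(ga.occ, 0.0), 1.0), ga.b_iso, ga.altloc or "")
                for ga in by_name.values()
            ]
            if atoms:
                residues.append(Residue(gres.seqid.num, gres.name, atoms))
        if residues:
            chains.append(Chain(gch.name, residues))
    if not chains:
        raise StructureError("no protein chains found in structure")
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c,
                st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = st.spacegroup_hm or None
    return StructureModel(chains, cell, sg)


def read_structure(source: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Waters, hetero groups and hydrogens are dropped; for altloc duplicates
    only the highest-occupancy conformer is kept (ties broken by altloc
    letter).  ``format`` may be ``"pdb"`` or ``"mmcif"``; by default it is
    inferred from the file name.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb" or (format is None and path.suffix.lower() in {".pdb", ".ent"}):
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif" or (format is None and path.suffix.lower() in {".cif", ".mmcif"}):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    return _from_gemmi(st)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "coilgeom"
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
    if model.space_group:
        st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    for c in model.chains:
        gch = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seqid, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "pdb") -> Path:
    """Write the model as PDB (fixed-width; coordinates must fit %8.3f)."""
    if not model.chains:
        raise StructureError("refusing to write an empty model")
    path = Path(path)
    if format == "pdb":
        xyz = model.coordinates()
        if xyz.max() > _PDB_COORD_MAX or xyz.min() < _PDB_COORD_MIN:
            raise StructureError(
                "coordinates exceed the PDB fixed-width field range "
                f"[{_PDB_COORD_MIN}, {_PDB_COORD_MAX}]; write mmCIF instead")
        _to_gemmi(model).write_pdb(str(path))
    elif format == "mmcif":
        _to_gemmi(model).make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def select_chain_trace(model: StructureModel, chain_id: str) -> ChainTrace:
    """Ordered Cα trace for one chain; residues lacking Cα are skipped."""
    chain = model.chain(chain_id)
    numbers, positions = [], []
    for r in chain.residues:
        ca = r.atom("CA")
        if ca is None:
            log.warning("chain %s residue %d (%s) has no CA; skipped",
                        chain_id, r.seqid, r.name)
            continue
        numbers.append(r.seqid)
        positions.append(ca.position)
    if not numbers:
        raise StructureError(f"chain {chain_id} contains no CA atoms")
    return ChainTrace(chain_id, np.array(numbers), np.array(positions))


def expand_lattice_neighbors(model: StructureModel, max_distance: float):
    """Crystal-lattice copies of ``model`` with any atom within ``max_distance``.

    Brute force by construction: every space-group operator combined with
    every unit translation in {-1, 0, 1}^3 is applied; the identity placement
    is excluded.  Returns a list of (StructureModel copy, operator triplet,
    lattice shift) with each copy's ``meta`` also carrying the labels.
    """
    if model.cell is None:
        raise StructureError(
            "no unit-cell metadata; supply the two-dimer coordinates directly "
            "instead of using lattice expansion")
    cell = gemmi.UnitCell(*model.cell)
    sg = gemmi.find_spacegroup_by_name(model.space_group or "P 1")
    if sg is None:
        raise StructureError(f"unknown space group {model.space_group!r}")
    xyz = model.coordinates()
    frac = np.array([cell.fractionalize(gemmi.Position(*p)).tolist() for p in xyz])
    tree = cKDTree(xyz)
    orth = np.array(cell.orth.mat.tolist())  # fractional -> cartesian matrix

    results = []
    for op in sg.operations():
        rot = np.array(op.rot, float) / op.DEN
        tran = np.array(op.tran, float) / op.DEN
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    shift = np.array([i, j, k], float)
                    if np.allclose(rot, np.eye(3)) and np.allclose(tran + shift, 0):
                        continue
                    new_frac = frac @ rot.T + tran + shift
                    new_xyz = new_frac @ orth.T
                    dmin = tree.query(new_xyz, k=1)[0].min()
                    if dmin <= max_distance:
                        R_cart = orth @ rot @ np.linalg.inv(orth)
                        t_cart = orth @ (tran + shift)
                        copy = model.transformed(R_cart, t_cart)
                        copy.meta["symmetry_op"] = op.triplet()
                        copy.meta["lattice_shift"] = (i, j, k)
                        results.append((copy, op.triplet(), (i, j, k)))
    return results
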