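"""Head-to-tail overlap-junction geometry.

A junction is formed by the C-terminal end of one coiled-coil dimer and the
N-terminal end of the next dimer in a cable.  Its geometry is summarized by:

* the twist angle θ between two triangular planes spanned by residue-group
  centroids near the termini (P1–P3 on the C-dimer, P4–P6 on the N-dimer),
* the bend ω between the two dimers' central-axis directions at the junction,
* the overlap length (distance between the facing coiled-coil axis ends),
* the terminal width (residue-1 Cα–Cα separation within the N-dimer),
* per-residue minimum-distance maps across the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryError, coiled_coil_profile
from .io import select_chain_trace
from .model import Residue, StructureModel

# Anchor residues of the twist-angle planes (author numbering)
C_PLANE_EDGE = (157, 159)   # P1, P2: per-chain centroids of these residues
C_PLANE_APEX = 147          # P3: centroid over both chains
N_PLANE_EDGE = (4, 6)       # P4, P5
N_PLANE_APEX = 14           # P6


@dataclass
class JunctionModel:
    """C-terminal donor dimer plus N-terminal donor dimer with residue windows."""

    c_dimer: StructureModel
    n_dimer: StructureModel
    c_window: tuple[int, int] = (150, 161)
    n_window: tuple[int, int] = (1, 12)

    def __post_init__(self) -> None:
        if self.c_window[0] > self.c_window[1] or self.n_window[0] > self.n_window[1]:
            raise ValueError("residue windows must be (low, high)")
        if len(self.c_dimer.chains) < 2 or len(self.n_dimer.chains) < 2:
            raise ValueError("each dimer needs two chains")

    def c_chains(self):
        return self.c_dimer.chains[:2]

    def n_chains(self):
        return self.n_dimer.chains[:2]


@dataclass
class JunctionMetrics:
    twist_angle: float          # θ, deg
    bend: float                 # ω, deg
    overlap_length: float       # Å
    terminal_width: float       # Å
    buried_area: float | None = None      # Å²
    contact_count: int | None = None
    contact_density: float | None = None  # per 1000 Å²

    def to_dict(self) -> dict:
        return {
            "twist_angle_deg": round(self.twist_angle, 2),
            "bend_omega_deg": round(self.bend, 2),
            "overlap_length_A": round(self.overlap_length, 2),
            "terminal_width_A": round(self.terminal_width, 2),
            "buried_area_A2": None if self.buried_area is None else round(self.buried_area, 1),
            "contact_count": self.contact_count,
            "contacts_per_1000_A2": None if self.contact_density is None
            else round(self.contact_density, 1),
        }


class JunctionError(ValueError):
    pass


def _residue_centroid(residues: list[Residue], weighted: bool = True) -> np.ndarray:
    coords, weights = [], []
    for r in residues:
        for a in r.atoms:
            coords.append(a.position)
            weights.append(a.mass if weighted else 1.0)
    w = np.asarray(weights)
    return (np.asarray(coords) * w[:, None]).sum(axis=0) / w.sum()


def _gather(dimer: StructureModel, seqids, what: str):
    """Residues ``seqids`` from each of the two chains; error if any missing."""
    per_chain = []
    for chain in dimer.chains[:2]:
        found = []
        for s in seqids:
            r = chain.residue(s)
            if r is None:
                raise JunctionError(
                    f"{what}: residue {s} missing from chain {chain.chain_id}")
            found.append(r)
        per_chain.append(found)
    return per_chain


def junction_twist_angle(j: JunctionModel, weighted: bool = True) -> float:
    """Twist angle θ (deg, in [0, 180)) between the two terminal planes.

    P1, P2 are the centroids of residues 157–159 of each C-chain, P3 the
    joint centroid of residue 147 from both C-chains; P4, P5 the centroids
    of residues 4–6 of each N-chain, P6 the joint centroid of residue 14.
    θ is the angle between the normals of triangles (P1, P2, P3) and
    (P4, P5, P6), folded into [0, 180).  ``weighted`` selects mass-weighted
    (default) or geometric centroids.
    """
    edge_rng = list(range(C_PLANE_EDGE[0], C_PLANE_EDGE[1] + 1))
    c_edge = _gather(j.c_dimer, edge_rng, "twist-angle C plane")
    c_apex = _gather(j.c_dimer, [C_PLANE_APEX], "twist-angle C plane")
    p1 = _residue_centroid(c_edge[0], weighted)
    p2 = _residue_centroid(c_edge[1], weighted)
    p3 = _residue_centroid(c_apex[0] + c_apex[1], weighted)

    edge_rng = list(range(N_PLANE_EDGE[0], N_PLANE_EDGE[1] + 1))
    n_edge = _gather(j.n_dimer, edge_rng, "twist-angle N plane")
    n_apex = _gather(j.n_dimer, [N_PLANE_APEX], "twist-angle N plane")
    p4 = _residue_centroid(n_edge[0], weighted)
    p5 = _residue_centroid(n_edge[1], weighted)
    p6 = _residue_centroid(n_apex[0] + n_apex[1], weighted)

    n1 = np.cross(p2 - p1, p3 - p1)
    n2 = np.cross(p5 - p4, p6 - p4)
    for nv, name in ((n1, "r1"), (n2, "r2")):
        if np.linalg.norm(nv) < 1e-9:
            raise JunctionError(f"plane {name} is degenerate (collinear anchor points)")
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return theta % 180.0


def _axis_segment(dimer: StructureModel, terminal: str, window: int = 5):
    """Central-axis endpoint and outward-pointing direction at one terminus.

    The endpoint is the axis extrapolated to the projection of the terminal
    paired-Cα midpoint; the direction is the axis tangent there, oriented
    N-terminus -> C-terminus.
    """
    ta = select_chain_trace(dimer, dimer.chains[0].chain_id)
    tb = select_chain_trace(dimer, dimer.chains[1].chain_id)
    prof = coiled_coil_profile(ta, tb, window)
    idx = np.where(prof.defined)[0]
    if len(idx) < 10:
        raise JunctionError("too few defined axis points to locate the coiled-coil end")
    if terminal == "C":
        sel = idx[-min(8, len(idx)):]
        end_i = -1
    elif terminal == "N":
        sel = idx[:min(8, len(idx))]
        end_i = 0
    else:
        raise ValueError("terminal must be 'N' or 'C'")
    pts = prof.central_axis[sel]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    d = vt[0]
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d  # oriented N -> C

    # paired terminal Cα midpoint (first/last residue present in both chains)
    common = np.intersect1d(ta.residue_numbers, tb.residue_numbers)
    seq = common[end_i]
    mid = 0.5 * (ta.ca_positions[ta.residue_numbers == seq][0]
                 + tb.ca_positions[tb.residue_numbers == seq][0])
    base = pts.mean(axis=0)
    endpoint = base + np.dot(mid - base, d) * d
    return endpoint, d


def overlap_length(j: JunctionModel, window: int = 5) -> float:
    """Distance (Å) between the C-dimer's C-terminal and the N-dimer's
    N-terminal coiled-coil axis endpoints."""
    end_c, _ = _axis_segment(j.c_dimer, "C", window)
    end_n, _ = _axis_segment(j.n_dimer, "N", window)
    return float(np.linalg.norm(end_c - end_n))


def junction_bend_omega(j: JunctionModel, window: int = 5) -> float:
    """Bend ω (deg): angle between the C-dimer's terminal axis direction and
    the N-dimer's initial axis direction (both oriented N->C); 0 = collinear."""
    _, d_c = _axis_segment(j.c_dimer, "C", window)
    _, d_n = _axis_segment(j.n_dimer, "N", window)
    return float(np.degrees(np.arccos(np.clip(np.dot(d_c, d_n), -1.0, 1.0))))


def terminal_width(j: JunctionModel, residue: int = 1) -> float:
    """Cα–Cα distance (Å) between the two N-dimer chains at ``residue``
    (the first residue by default): the width of the overlap junction."""
    cas = []
    for chain in j.n_dimer.chains[:2]:
        r = chain.residue(residue)
        ca = r.atom("CA") if r is not None else None
        if ca is None:
            raise JunctionError(
                f"residue {residue} CA missing from N-dimer chain {chain.chain_id}")
        cas.append(ca.position)
    return float(np.linalg.norm(cas[0] - cas[1]))


# ---------------------------------------------------------------------------
# distance maps


MASKED = -1.0  # sentinel in TSV export; in-memory maps carry an explicit mask


@dataclass
class DistanceMap:
    """Minimum inter-residue heavy-atom distances across the junction.

    Rows are N-window residues, columns C-window residues, both labelled
    ``chain:resnum``.  Entries above the cutoff are masked (mask=True) and
    carry no numeric meaning.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    mask: np.ndarray
    cutoff: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)
        return df.mask(self.mask)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="")


def _window_residues(dimer: StructureModel, window: tuple[int, int]):
    out = []
    for chain in dimer.chains[:2]:
        for r in chain.residues:
            if window[0] <= r.seqid <= window[1]:
                out.append((f"{chain.chain_id}:{r.seqid}", r))
    return out


def distance_map(j: JunctionModel, cutoff: float = 6.0) -> DistanceMap:
    """Per-residue-pair minimum heavy-atom distance map, masked above cutoff."""
    rows = _window_residues(j.n_dimer, j.n_window)
    cols = _window_residues(j.c_dimer, j.c_window)
    values = np.zeros((len(rows), len(cols)))
    for i, (_, rn) in enumerate(rows):
        cn = rn.coords()
        for k, (_, rc) in enumerate(cols):
            cc = rc.coords()
            d2 = ((cn[:, None, :] - cc[None, :, :]) ** 2).sum(-1)
            values[i, k] = np.sqrt(d2.min())
    mask = values > cutoff
    return DistanceMap([lab for lab, _ in rows], [lab for lab, _ in cols],
                       values, mask, cutoff)


@dataclass
class DistanceChange:
    """Per-N-residue mean signed distance change between two maps."""

    labels: list[str]
    mean_change: np.ndarray       # NaN where undefined
    n_shared: np.ndarray
    n_excluded: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.labels,
                             "mean_change_A": self.mean_change,
                             "n_shared": self.n_shared,
                             "n_excluded": self.n_excluded})


def distance_change_map(map_a: DistanceMap, map_b: DistanceMap) -> DistanceChange:
    """Mean of (B - A) per N-window residue over entries unmasked in both maps."""
    if map_a.row_labels != map_b.row_labels or map_a.col_labels != map_b.col_labels:
        raise JunctionError("distance maps have different residue windows")
    shared = ~map_a.mask & ~map_b.mask
    diff = map_b.values - map_a.values
    n = len(map_a.row_labels)
    mean = np.full(n, np.nan)
    n_shared = shared.sum(axis=1)
    n_excl = (map_a.mask | map_b.mask).sum(axis=1)
    for i in range(n):
        if n_shared[i] > 0:
            mean[i] = diff[i, shared[i]].mean()
    return DistanceChange(list(map_a.row_labels), mean, n_shared, n_excl)


def measure_junction(j: JunctionModel, window: int = 5) -> JunctionMetrics:
    """All scalar geometry metrics of a junction (areas/contacts filled elsewhere)."""
    return JunctionMetrics(
        twist_angle=junction_twist_angle(j),
        bend=junction_bend_omega(j, window),
        overlap_length=overlap_length(j, window),
        terminal_width=terminal_width(j),
    )


def junctions_from_cable(cable: StructureModel,
                         c_window: tuple[int, int] = (150, 161),
                         n_window: tuple[int, int] = (1, 12)) -> list[JunctionModel]:
    """Split a cable of consecutive two-chain dimers into its junction models."""
    ids = cable.chain_ids()
    if len(ids) < 4 or len(ids) % 2:
        raise JunctionError("cable must contain an even number (>= 4) of chains")
    out = []
    for k in range(len(ids) // 2 - 1):
        c_dimer = cable.subset(ids[2 * k:2 * k + 2])
        n_dimer = cable.subset(ids[2 * k + 2:2 * k + 4])
        out.append(JunctionModel(c_dimer, n_dimer, c_window, n_window))
    return out
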