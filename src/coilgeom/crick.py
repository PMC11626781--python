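"""Ideal coiled-coil and cable generator from Crick parameters.

Builds two-stranded parallel coiled-coil dimers as Cα traces on the Crick
curves: a minor (α-helical) helix of radius R1 wound around a superhelical
axis of radius R0 and pitch P (sign of P encodes supercoil handedness,
negative = left-handed).  The two chains differ only by a 180° rotation
about the supercoil axis, so an unperturbed dimer is exactly C2-symmetric.

Head-to-tail cables are assembled by stacking dimers along the supercoil
axis with a controllable junction: twist angle (solved numerically through
the measurement module, so the generated cable reproduces the requested
value by construction), overlap length (axial endpoint gap), and terminal
width (residue-1 Cα–Cα separation, met by a radial flare of the first few
residues).

Default parameters emulate a ~161-residue tropomyosin-like dimer:
R0 = 4.9 Å, rise = 1.49 Å/residue, P = -130 Å (left-handed), minor helix
radius 2.26 Å at 3.5 residues per turn in the rotating frame (heptad).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .model import AtomRecord, Chain, ChainTrace, Residue, StructureModel

HEPTAD_PHASE_A = 25.714  # Crick phase (deg) of the 'a' position; see geometry.assign_heptad
STAMMER_PHASE_JUMP = 3.0 / 7.0 * 360.0   # register band shift of a stammer, deg
STAMMER_RAMP = 4                         # residues over which the jump is ramped
STAMMER_OVERTWIST = 20.0                 # extra supercoil rotation (deg) -> local pitch dip

_CA_MASS_ELEMENT = "C"


@dataclass(frozen=True)
class CrickParams:
    """Generator parameters of an ideal two-stranded coiled-coil."""

    superhelical_radius: float = 4.9       # R0, Å
    superhelical_pitch: float = -130.0     # P, Å; negative = left-handed supercoil
    helix_radius: float = 2.26             # R1, Å (Cα radius about the minor-helix axis)
    residues_per_helix_turn: float = 3.5   # minor-helix period in the rotating frame
    rise_per_residue: float = 1.49         # Å along the supercoil axis
    helix_phase: float = HEPTAD_PHASE_A    # φ1 at residue index 0, deg
    chain_phase_offset: float = 180.0      # deg; 180 for a two-stranded dimer

    def validate(self) -> None:
        if self.superhelical_radius < 0:
            raise ValueError("superhelical radius R0 must be >= 0")
        if self.helix_radius <= 0:
            raise ValueError("helix radius R1 must be > 0")
        if not 0.5 < self.rise_per_residue < 2.0:
            raise ValueError("rise per residue outside the realistic range (0.5, 2.0) Å")
        if self.superhelical_pitch == 0:
            raise ValueError("superhelical pitch must be nonzero (sign = handedness)")

    @property
    def omega0(self) -> float:
        """Supercoil rotation per residue, deg (signed; negative = left-handed)."""
        return 360.0 * self.rise_per_residue / self.superhelical_pitch

    @property
    def omega1(self) -> float:
        """Minor-helix rotation per residue in the rotating frame, deg."""
        return 360.0 / self.residues_per_helix_turn


@dataclass(frozen=True)
class JunctionSpec:
    """Target junction geometry for a generated cable."""

    twist_angle: float = 90.0    # deg, in [0, 180)
    overlap_length: float = 8.0  # Å, axial gap between facing coiled-coil ends
    junction_width: float = 15.0  # Å, residue-1 Cα–Cα separation in the N-dimer
    n_dimers: int = 2

    def validate(self, dimer_span: float | None = None) -> None:
        if self.n_dimers < 2:
            raise ValueError("a cable needs n_dimers >= 2")
        if not 0.0 <= self.twist_angle < 180.0:
            raise ValueError("twist angle must be in [0, 180)")
        if self.overlap_length < 0 or self.junction_width < 0:
            raise ValueError("overlap length and junction width must be >= 0")
        if dimer_span is not None and self.overlap_length >= dimer_span:
            raise ValueError(
                f"overlap length {self.overlap_length} Å is not shorter than the "
                f"dimer span {dimer_span:.1f} Å; geometrically impossible")


def _ramp(t: np.ndarray, position: float, width: int) -> np.ndarray:
    """Smoothly goes 0 -> 1 over ``width`` residues centered at ``position``."""
    return np.clip((t - (position - width / 2.0)) / width, 0.0, 1.0)


def _chain_coordinates(params: CrickParams, n: int, phase0: float,
                       stammer_at: float | None = None) -> np.ndarray:
    """Cα coordinates of one chain on the Crick curves.

    ``phase0`` is the supercoil phase of the chain at residue 0 (deg); the
    optional stammer advances the minor-helix phase by 3/7 turn and locally
    overtwists the supercoil (both ramped over STAMMER_RAMP residues).
    """
    t = np.arange(n, dtype=float)
    w0 = np.deg2rad(params.omega0)
    w1 = np.deg2rad(params.omega1)

    phi0 = np.deg2rad(phase0) + w0 * t
    phi1 = np.deg2rad(params.helix_phase) + w1 * t
    if stammer_at is not None:
        ramp = _ramp(t, stammer_at, STAMMER_RAMP)
        # overtwist in the supercoil sense (same sign as omega0)
        phi0 = phi0 + np.sign(w0) * np.deg2rad(STAMMER_OVERTWIST) * ramp
        # net Crick-phase advance of 3/7 turn as seen relative to the core
        phi1 = phi1 + np.deg2rad(STAMMER_PHASE_JUMP) * ramp

    R0, R1, h = params.superhelical_radius, params.helix_radius, params.rise_per_residue
    axis = np.column_stack([R0 * np.cos(phi0), R0 * np.sin(phi0), h * t])

    # local frame of the supercoil axis curve (analytic)
    dphi = np.gradient(phi0)  # rad/residue, handles the stammer bump
    tang = np.column_stack([-R0 * dphi * np.sin(phi0), R0 * dphi * np.cos(phi0),
                            np.full(n, h)])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-np.cos(phi0), -np.sin(phi0), np.zeros(n)])  # toward axis
    binorm = np.cross(tang, normal)

    return axis + R1 * (np.cos(phi1)[:, None] * normal + np.sin(phi1)[:, None] * binorm)


def _trace_to_chain(chain_id: str, xyz: np.ndarray, sequence: str | None,
                    start: int = 1) -> Chain:
    residues = []
    for i, pos in enumerate(xyz):
        name = "ALA" if sequence is None else _one_to_three(sequence[i])
        residues.append(Residue(start + i, name,
                                [AtomRecord("CA", _CA_MASS_ELEMENT, pos.copy())]))
    return Chain(chain_id, residues)


_THREE = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
          "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
          "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
          "W": "TRP", "Y": "TYR"}


def _one_to_three(letter: str) -> str:
    return _THREE.get(letter.upper(), "ALA")


def build_ideal_dimer(params: CrickParams, n_residues: int,
                      sequence: str | None = None,
                      stammer_at: float | None = None,
                      chain_ids: tuple[str, str] = ("A", "B"),
                      width_flare: float | None = None) -> StructureModel:
    """Two-chain parallel dimer on the Crick curves; exactly C2 unless flared.

    ``width_flare`` radially displaces the first six residues of both chains
    (linearly decaying) so that the residue-1 Cα–Cα separation equals the
    given width; used by :func:`build_cable` to meet a junction-width spec.
    """
    params.validate()
    if n_residues < 8:
        raise ValueError("need n_residues >= 8")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    if stammer_at is not None and not 4 <= stammer_at <= n_residues - 5:
        raise ValueError("register discontinuity must be interior to the chain")

    xyz_a = _chain_coordinates(params, n_residues, 0.0, stammer_at)
    xyz_b = _chain_coordinates(params, n_residues, params.chain_phase_offset, stammer_at)
    if width_flare is not None:
        xyz_a, xyz_b = _apply_width_flare(xyz_a, xyz_b, width_flare, params)

    model = StructureModel([
        _trace_to_chain(chain_ids[0], xyz_a, sequence),
        _trace_to_chain(chain_ids[1], xyz_b, sequence),
    ])
    model.meta["crick_params"] = params
    model.meta["n_residues"] = n_residues
    if stammer_at is not None:
        model.meta["stammer_at"] = stammer_at
    return model


_FLARE_RESIDUES = 6


def _apply_width_flare(xyz_a: np.ndarray, xyz_b: np.ndarray, width: float,
                       params: CrickParams):
    """Radially displace the first residues so chains are ``width`` apart at residue 1."""
    w0 = np.linalg.norm(xyz_a[0] - xyz_b[0])
    delta = (width - w0) / 2.0
    out = []
    for xyz in (xyz_a, xyz_b):
        xyz = xyz.copy()
        for i in range(_FLARE_RESIDUES):
            radial = xyz[i] - np.array([0.0, 0.0, xyz[i][2]])
            nr = np.linalg.norm(radial)
            if nr < 1e-9:
                continue
            scale = delta * (1.0 - i / _FLARE_RESIDUES)
            if nr + scale < 0.3:  # do not push a chain through the axis
                raise ValueError("requested junction width too small for these Crick parameters")
            xyz[i] = xyz[i] + (radial / nr) * scale
        out.append(xyz)
    return out[0], out[1]


def insert_register_discontinuity(model: StructureModel, position: int,
                                  kind: str = "stammer") -> StructureModel:
    """Rebuild a generated dimer with a stammer-like register discontinuity.

    The minor-helix (Crick) phase of both chains is advanced by 3/7 turn
    over four residues around ``position`` and the supercoil is locally
    overtwisted, reproducing the band shift and the local pitch decrease a
    stammer causes.  Only models carrying generator provenance can be
    rebuilt.
    """
    if kind != "stammer":
        raise ValueError(f"unsupported discontinuity kind {kind!r}")
    params = model.meta.get("crick_params")
    n = model.meta.get("n_residues")
    if params is None or n is None:
        raise ValueError("register discontinuities can only be inserted into "
                         "dimers built by build_ideal_dimer")
    if not 4 <= position <= n - 5:
        raise ValueError("discontinuity position must be interior to the chain")
    ids = tuple(model.chain_ids())[:2]
    return build_ideal_dimer(params, n, stammer_at=float(position), chain_ids=ids)


def perturb(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Add i.i.d. Gaussian noise (per-coordinate std ``sigma``) to every atom."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    new = model.transformed(np.eye(3), np.zeros(3))
    for c in new.chains:
        for r in c.residues:
            for a in r.atoms:
                a.position = a.position + rng.normal(0.0, sigma, 3)
    return new


def dimer_traces(model: StructureModel) -> tuple[ChainTrace, ChainTrace]:
    from .io import select_chain_trace
    ids = model.chain_ids()
    return select_chain_trace(model, ids[0]), select_chain_trace(model, ids[1])


def build_cable(params: CrickParams, junction: JunctionSpec,
                n_residues: int = 161, sequence: str | None = None) -> StructureModel:
    """Head-to-tail cable of identical dimers meeting ``junction`` by construction.

    Every dimer lies on the same supercoil axis (z); successive dimers are
    rotated about that axis by an angle solved numerically so the measured
    junction twist angle equals the spec, and shifted axially so the
    coiled-coil end gap equals the overlap length.  The junction width is
    met exactly by the generator's terminal flare.
    """
    params.validate()
    junction.validate(dimer_span=(n_residues - 1) * params.rise_per_residue)

    base = build_ideal_dimer(params, n_residues, sequence,
                             width_flare=junction.junction_width)
    # axial shift between dimers measured from the dimer's own coiled-coil
    # axis endpoints, so the generated overlap length is met by construction
    from .junction import _axis_segment
    end_c, _ = _axis_segment(base, "C")
    end_n, _ = _axis_segment(base, "N")
    shift = (end_c[2] - end_n[2]) - junction.overlap_length

    psi = _solve_twist_rotation(base, junction, shift)

    letters = string.ascii_uppercase
    chains: list[Chain] = []
    for k in range(junction.n_dimers):
        Rk = _rot_z(np.deg2rad(psi * k))
        tk = np.array([0.0, 0.0, shift * k])
        placed = base.transformed(Rk, tk)
        for idx, c in enumerate(placed.chains):
            c.chain_id = letters[2 * k + idx]
            chains.append(c)
    cable = StructureModel(chains)
    cable.meta.update({
        "crick_params": params, "n_residues": n_residues,
        "junction_spec": junction, "rotation_per_dimer_deg": psi,
    })
    return cable


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _solve_twist_rotation(base: StructureModel, junction: JunctionSpec,
                          shift: float) -> float:
    """Rotation about z between successive dimers giving the spec twist angle."""
    from .junction import JunctionModel, junction_twist_angle

    def measured(psi_deg: float) -> float:
        placed = base.transformed(_rot_z(np.deg2rad(psi_deg)),
                                  np.array([0.0, 0.0, shift]))
        for cid, c in zip(("C", "D"), placed.chains):
            c.chain_id = cid
        jm = JunctionModel(c_dimer=base, n_dimer=placed)
        return junction_twist_angle(jm)

    target = junction.twist_angle
    grid = np.linspace(0.0, 360.0, 181)
    vals = np.array([measured(p) for p in grid])
    best = None
    for a, b, fa, fb in zip(grid, grid[1:], vals, vals[1:]):
        if abs(fa - fb) > 90.0:   # fold wrap-around of the [0,180) angle
            continue
        if (fa - target) * (fb - target) <= 0.0:
            psi = brentq(lambda p: measured(p) - target, a, b, xtol=1e-6)
            best = psi
            break
    if best is None:
        i = int(np.argmin(np.abs(vals - target)))
        if abs(vals[i] - target) > 1.0:
            raise ValueError(
                f"cannot realise twist angle {target}° with these parameters "
                f"(reachable range {vals.min():.1f}–{vals.max():.1f}°)")
        best = grid[i]
    return float(best)
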