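"""Local coiled-coil parameterization, register assignment, and superposition.

The per-residue analysis follows the TWISTER idea: estimate each α-helix
axis locally from consecutive Cα positions, take the midpoint curve of the
two helix axes as the central coiled-coil axis, and derive local pitch,
residues per pitch, interhelical radius, curvature and Crick phase from the
rotation of the helix axes about that central curve.

Helix axis points are obtained from the bisector construction (the
normalized sum of the two bond vectors at a Cα points at the local helix
axis) with the radius from the exact four-point helix fit, then smoothed
with a Savitzky–Golay polynomial filter over the axis-fitting window, which
preserves the curvature of the supercoil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial.transform import Rotation

from .model import ChainTrace

HEPTAD_LETTERS = "abcdefg"
# Crick-phase spacing between adjacent register letters (deg): 7 letters on
# the circle, sequence-adjacent letters 2/7 turn apart.
_LETTER_PHASE_STEP = 360.0 / 7.0
_SEQ_PHASE_STEP = 2.0 * 360.0 / 7.0
#: Crick phase of the 'a' position (deg); calibrated on the ideal generator so
#: the core midline (phase 0, facing the partner helix) falls between a and d.
HEPTAD_ANCHOR_PHASE = 25.714
#: Sustained Crick-phase jump (deg) flagged as a register discontinuity:
#: a stammer shifts the register by three letter bands (3/7 turn = 154.3 deg);
#: the threshold sits below that by a measurement-slack margin.
DISCONTINUITY_JUMP_DEG = 135.0
_DISCONTINUITY_SPAN = 4  # residues over which the jump may be spread


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# helix axis estimation


@dataclass
class LocalAxes:
    """Per-residue local helix axis points/directions; NaN where undefined."""

    residue_numbers: np.ndarray
    points: np.ndarray       # (n, 3)
    directions: np.ndarray   # (n, 3) unit vectors along the chain direction
    defined: np.ndarray      # (n,) bool


def _signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (deg) from a to b about unit vector ``axis``."""
    ap = a - np.dot(a, axis) * axis
    bp = b - np.dot(b, axis) * axis
    return float(np.degrees(np.arctan2(np.dot(np.cross(ap, bp), axis),
                                       np.dot(ap, bp))))


def local_axes(trace: ChainTrace, window: int = 5) -> LocalAxes:
    """Local helix-axis point and direction for each interior residue."""
    if window % 2 == 0 or window < 3:
        raise GeometryError("window must be odd and >= 3")
    n = len(trace)
    if n <= window + 2:
        raise GeometryError(f"trace of {n} residues too short; need > window + 2 = {window + 2}")
    P = trace.ca_positions

    # bisectors point from each Cα toward the helix axis
    prev_v = P[:-2] - P[1:-1]
    next_v = P[2:] - P[1:-1]
    bis = prev_v / np.linalg.norm(prev_v, axis=1, keepdims=True) \
        + next_v / np.linalg.norm(next_v, axis=1, keepdims=True)
    bis /= np.linalg.norm(bis, axis=1, keepdims=True)  # for residues 1..n-2

    # four-point helix fit on consecutive bisector pairs -> local radius
    u = np.cross(bis[:-1], bis[1:])
    u_norm = np.linalg.norm(u, axis=1, keepdims=True)
    if np.any(u_norm < 1e-12):
        raise GeometryError("degenerate (collinear) Cα geometry in helix-axis fit")
    u /= u_norm
    chord = P[2:-1] - P[1:-2]
    flip = np.sign(np.einsum("ij,ij->i", u, chord))
    u *= flip[:, None]
    rise = np.einsum("ij,ij->i", chord, u)
    perp = chord - rise[:, None] * u
    twist = np.array([_signed_angle(bis[i], bis[i + 1], u[i]) for i in range(len(u))])
    with np.errstate(invalid="ignore"):
        radius = np.linalg.norm(perp, axis=1) / (2.0 * np.abs(np.sin(np.deg2rad(twist) / 2.0)))

    # per-residue radius = mean of adjacent pair estimates
    r_res = np.full(n, np.nan)
    r_res[1:-2] = radius
    r_res[2:-1] = np.where(np.isnan(r_res[2:-1]), radius, 0.5 * (r_res[2:-1] + radius))

    points = np.full((n, 3), np.nan)
    idx = np.arange(1, n - 1)
    points[idx] = P[idx] + r_res[idx, None] * bis

    # smooth the axis curve; quadratic Savitzky-Golay preserves supercoil curvature
    interior = points[1:n - 1]
    smooth = savgol_filter(interior, window_length=min(window, len(interior)),
                           polyorder=2, axis=0, mode="interp")
    deriv = savgol_filter(interior, window_length=min(window, len(interior)),
                          polyorder=2, axis=0, deriv=1, mode="interp")
    points[1:n - 1] = smooth
    directions = np.full((n, 3), np.nan)
    directions[1:n - 1] = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)

    margin = window // 2 + 1
    defined = np.zeros(n, bool)
    defined[margin:n - margin] = True
    points[~defined] = np.nan
    directions[~defined] = np.nan
    return LocalAxes(trace.residue_numbers.copy(), points, directions, defined)


# ---------------------------------------------------------------------------
# coiled-coil profile


@dataclass
class LocalCCProfile:
    """Per-residue local coiled-coil parameters for a paired two-chain dimer."""

    residue_numbers: np.ndarray
    axis_a: np.ndarray
    axis_b: np.ndarray
    central_axis: np.ndarray
    tangent: np.ndarray
    interhelical_radius: np.ndarray   # Å, averaged over the two chains
    local_pitch: np.ndarray           # Å
    residues_per_pitch: np.ndarray
    local_curvature: np.ndarray       # deg per residue
    crick_phase_a: np.ndarray         # deg, chain A
    crick_phase_b: np.ndarray         # deg, chain B
    rotation_per_residue: np.ndarray  # deg, signed; negative = left-handed
    defined: np.ndarray

    @property
    def crick_phase(self) -> np.ndarray:
        return self.crick_phase_a

    def to_dataframe(self) -> pd.DataFrame:
        letters, _ = assign_heptad(self)
        return pd.DataFrame({
            "residue": self.residue_numbers,
            "local_pitch_A": self.local_pitch,
            "residues_per_pitch": self.residues_per_pitch,
            "interhelical_radius_A": self.interhelical_radius,
            "local_curvature_deg": self.local_curvature,
            "crick_phase_deg": self.crick_phase_a,
            "heptad": list(letters),
        })


def _pair_traces(trace_a: ChainTrace, trace_b: ChainTrace):
    common, ia, ib = np.intersect1d(trace_a.residue_numbers, trace_b.residue_numbers,
                                    return_indices=True)
    if len(common) == 0:
        raise GeometryError(
            "traces share no residue numbers; cannot pair "
            f"(A: {trace_a.residue_numbers[[0, -1]]}, B: {trace_b.residue_numbers[[0, -1]]})")
    ta = ChainTrace(trace_a.chain_id, common, trace_a.ca_positions[ia])
    tb = ChainTrace(trace_b.chain_id, common, trace_b.ca_positions[ib])
    return ta, tb


def coiled_coil_profile(trace_a: ChainTrace, trace_b: ChainTrace,
                        window: int = 5) -> LocalCCProfile:
    """TWISTER-style per-residue coiled-coil parameters for a paired dimer."""
    ta, tb = _pair_traces(trace_a, trace_b)
    n = len(ta)
    ax_a = local_axes(ta, window)
    ax_b = local_axes(tb, window)
    defined = ax_a.defined & ax_b.defined

    central = np.full((n, 3), np.nan)
    central[defined] = 0.5 * (ax_a.points[defined] + ax_b.points[defined])
    idx = np.where(defined)[0]
    seg = central[idx]
    wl = min(window, len(seg))
    if wl % 2 == 0:
        wl -= 1
    tang_seg = savgol_filter(seg, window_length=wl, polyorder=min(2, wl - 1),
                             axis=0, deriv=1, mode="interp")
    tang_seg /= np.linalg.norm(tang_seg, axis=1, keepdims=True)
    tangent = np.full((n, 3), np.nan)
    tangent[idx] = tang_seg

    rad_a = np.linalg.norm(ax_a.points - central, axis=1)
    rad_b = np.linalg.norm(ax_b.points - central, axis=1)
    radius = 0.5 * (rad_a + rad_b)

    rot = np.full(n, np.nan)
    rise = np.full(n, np.nan)
    curv = np.full(n, np.nan)
    for j, i in enumerate(idx[:-1]):
        i2 = idx[j + 1]
        if i2 - i != 1:
            continue
        t_mid = tangent[i] + tangent[i2]
        t_mid /= np.linalg.norm(t_mid)
        da = _signed_angle(ax_a.points[i] - central[i], ax_a.points[i2] - central[i2], t_mid)
        db = _signed_angle(ax_b.points[i] - central[i], ax_b.points[i2] - central[i2], t_mid)
        rot[i] = 0.5 * (da + db)
        rise[i] = abs(np.dot(central[i2] - central[i], t_mid))
        curv[i] = np.degrees(np.arccos(np.clip(np.dot(tangent[i], tangent[i2]), -1, 1)))

    with np.errstate(divide="ignore", invalid="ignore"):
        res_per_pitch = 360.0 / np.abs(rot)
        pitch = res_per_pitch * rise

    phase_a = np.full(n, np.nan)
    phase_b = np.full(n, np.nan)
    for i in idx:
        for phase, ax, tr in ((phase_a, ax_a, ta), (phase_b, ax_b, tb)):
            u = ax.directions[i]
            ref = central[i] - ax.points[i]
            vec = tr.ca_positions[i] - ax.points[i]
            if np.linalg.norm(ref) < 1e-6:
                continue  # no supercoil: Crick phase undefined
            phase[i] = _signed_angle(ref / np.linalg.norm(ref), vec, u)

    return LocalCCProfile(ta.residue_numbers, ax_a.points, ax_b.points, central,
                          tangent, radius, pitch, res_per_pitch, curv,
                          phase_a, phase_b, rot, defined)


def pitch_summary(profile: LocalCCProfile) -> dict[str, float]:
    """Whole-molecule pitch statistics from aggregate axis rotation.

    The global estimate divides the total rotation of the helix axes about
    the central axis by the number of steps, which is far more robust to
    coordinate noise than averaging the per-residue ``local_pitch`` (a
    nonlinear 360/Δφ quantity whose mean is dominated by near-zero phase
    steps).
    """
    ok = profile.defined & np.isfinite(profile.rotation_per_residue)
    rot = float(np.mean(profile.rotation_per_residue[ok]))
    with np.errstate(invalid="ignore", divide="ignore"):
        rise = profile.local_pitch / profile.residues_per_pitch
    mean_rise = float(np.nanmean(rise[ok]))
    rpp = 360.0 / abs(rot) if rot != 0 else np.inf
    return {
        "mean_rotation_deg_per_residue": rot,
        "mean_rise_A": mean_rise,
        "residues_per_pitch": rpp,
        "pitch_A": rpp * mean_rise,
        "mean_interhelical_radius_A": float(np.nanmean(
            profile.interhelical_radius[profile.defined])),
    }


def chirality(profile: LocalCCProfile, min_radius: float = 0.8) -> str:
    """Supercoil handedness: ``"left"``, ``"right"`` or ``"no_supercoil"``.

    Determined by the sign of the mean rotation of the helix axes about the
    central axis; below ``min_radius`` Å mean interhelical radius there is no
    meaningful supercoil.
    """
    ok = profile.defined & np.isfinite(profile.rotation_per_residue)
    if not ok.any():
        raise GeometryError("profile has no defined positions")
    if np.nanmean(profile.interhelical_radius[profile.defined]) < min_radius:
        return "no_supercoil"
    mean_rot = float(np.mean(profile.rotation_per_residue[ok]))
    if abs(mean_rot) < 1e-3:
        return "no_supercoil"
    return "left" if mean_rot < 0 else "right"


# ---------------------------------------------------------------------------
# heptad register


def _circdiff(x):
    """Wrap angle(s) into (-180, 180]."""
    return (np.asarray(x, float) + 180.0) % 360.0 - 180.0


def assign_heptad(profile: LocalCCProfile,
                  anchor: float = HEPTAD_ANCHOR_PHASE,
                  jump_threshold: float = DISCONTINUITY_JUMP_DEG):
    """Heptad letters from Crick-phase bins, plus register discontinuities.

    Letters are assigned by the nearest ideal letter phase (anchor + the
    letter's offset on the 7-position circle).  A discontinuity is a
    sustained Crick-phase jump of about 3/7 turn completed within four
    residues (a stammer-like band shift); returned as residue numbers.
    """
    n = len(profile.residue_numbers)
    phases = profile.crick_phase_a
    letters = []
    # ideal phase of letter k (sequence order a..g): anchor + k * 2/7 turn
    ideal = _circdiff(anchor + np.arange(7) * _SEQ_PHASE_STEP)
    for i in range(n):
        if not profile.defined[i] or not np.isfinite(phases[i]):
            letters.append("-")
            continue
        d = np.abs(_circdiff(phases[i] - ideal))
        letters.append(HEPTAD_LETTERS[int(np.argmin(d))])

    ok = np.where(profile.defined & np.isfinite(phases))[0]
    discontinuities: list[int] = []
    if len(ok) > _DISCONTINUITY_SPAN + 2:
        ph = phases[ok]
        steps = _circdiff(np.diff(ph))
        baseline = np.median(steps)
        dev = _circdiff(steps - baseline)
        span = _DISCONTINUITY_SPAN
        cum = np.convolve(dev, np.ones(span), mode="valid")  # dev over 4-residue spans
        hits = np.where(np.abs(cum) >= jump_threshold)[0]
        # group adjacent hits into one discontinuity, report the span center
        group: list[int] = []
        for h in list(hits) + [None]:
            if h is not None and (not group or h - group[-1] <= span):
                group.append(h)
            elif group:
                center = int(round(np.mean(group))) + span // 2
                discontinuities.append(int(profile.residue_numbers[ok[min(center, len(ok) - 1)]]))
                group = [h] if h is not None else []
    return "".join(letters), discontinuities


# ---------------------------------------------------------------------------
# superposition


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns rotation/translation such that R @ b + t best matches a, with the
    Cα RMSD after superposition.  Point sets must be paired row-by-row.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise GeometryError("coordinate arrays must be matching (n, 3)")
    n = len(A)
    if n < 3:
        raise GeometryError("need at least 3 paired points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    sv = np.linalg.svd(A0.T @ B0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) point set; superposition ill-defined")
    rot, rssd = Rotation.align_vectors(A0, B0)
    R = rot.as_matrix()
    rmsd = rssd / np.sqrt(n)
    t = ca - R @ cb
    return SuperpositionResult(R, t, float(rmsd), n)


def superpose_traces(trace_a: ChainTrace, trace_b: ChainTrace) -> SuperpositionResult:
    """Kabsch superposition over residues present in both traces."""
    ta, tb = _pair_traces(trace_a, trace_b)
    return kabsch_superpose(ta.ca_positions, tb.ca_positions)


def symmetry_rmsd(trace_a: ChainTrace, trace_b: ChainTrace) -> float:
    """Cα RMSD of chain A superposed onto chain B of the same dimer (Å)."""
    return superpose_traces(trace_a, trace_b).rmsd


def rmsd_matrix(traces: list[ChainTrace], labels: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise Kabsch RMSDs over common residues (Å)."""
    k = len(traces)
    if labels is None:
        labels = [t.chain_id for t in traces]
    M = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            M[i, j] = M[j, i] = superpose_traces(traces[i], traces[j]).rmsd
    return pd.DataFrame(M, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# kink angle


def kink_angle(trace_a: ChainTrace, trace_b: ChainTrace,
               window_n: tuple[int, int] = (20, 70),
               window_c: tuple[int, int] = (95, 145),
               window: int = 5) -> float:
    """Angle (deg) between straight lines fitted to the central axis in two windows."""
    if window_n[1] >= window_c[0]:
        raise GeometryError("kink windows must be disjoint and ordered")
    prof = coiled_coil_profile(trace_a, trace_b, window)
    dirs = []
    for lo, hi in (window_n, window_c):
        sel = prof.defined & (prof.residue_numbers >= lo) & (prof.residue_numbers <= hi)
        pts = prof.central_axis[sel]
        if len(pts) < 10:
            raise GeometryError(
                f"window {lo}-{hi} has only {len(pts)} defined axis points (need >= 10); "
                "it may overlap the undefined terminal region")
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        d = vt[0]
        if np.dot(d, pts[-1] - pts[0]) < 0:  # orient along increasing residue number
            d = -d
        dirs.append(d)
    return float(np.degrees(np.arccos(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))))
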