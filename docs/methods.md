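# Methods

## The model

A two-stranded coiled-coil is parameterized by Crick's construction: a
minor (α-helical) helix of radius R₁ wound at ω₁ degrees per residue (in
the frame that rotates with the supercoil) around a superhelical axis of
radius R₀ and pitch P. The supercoil advances h Å per residue along its
axis and rotates ω₀ = 360·h/P degrees per residue about it; the sign of P
carries the handedness (negative = left-handed, the tropomyosin case). The
second chain of a parallel, unstaggered dimer is the first rotated 180°
about the supercoil axis, which makes a generated dimer exactly
C2-symmetric: superposing chain A onto chain B gives RMSD 0. Real
tropomyosin dimers are measurably asymmetric, so this zero is the
meaningful baseline for the asymmetry (chain-vs-chain) RMSD.

Generator defaults emulate a 161-residue tropomyosin-like dimer:

| parameter | default | unit | why |
|---|---|---|---|
| R₀ (superhelical radius) | 4.9 | Å | middle of the 4–5.5 Å interhelical-radius range of tropomyosin coiled-coils |
| P (superhelical pitch) | −130 | Å | left-handed, ~87–90 residues/pitch as measured on tropomyosin cables |
| R₁ (minor-helix radius) | 2.26 | Å | Cα radius of an α-helix |
| h (rise per residue) | 1.49 | Å | axial rise of a coiled-coil α-helix |
| residues per minor-helix turn | 3.5 | — | exact heptad periodicity in the rotating frame |
| chain phase offset | 180 | ° | parallel unstaggered two-stranded dimer |

These defaults are test conditions chosen to match the measured ranges of
the tropomyosin cable structures, not fitted claims about any specific
protein.

## Local coiled-coil parameterization

Per-residue helix axis points are estimated TWISTER-style: the normalized
sum of the two bond vectors at each Cα (the bisector) points at the local
helix axis; the local radius comes from the exact four-point helix fit on
consecutive bisector pairs; the resulting axis curve is smoothed with a
quadratic Savitzky–Golay filter over the axis window (default 5 residues).
A quadratic filter is used deliberately: a plain moving average of points
on a curved supercoil shrinks the apparent radius by ~0.5 % at these
curvatures, while the quadratic fit preserves it (recovery error ≤0.7 %
across the tested parameter grid).

The central coiled-coil axis is the midpoint curve of the two (residue-
paired) helix axes. From it: interhelical radius = mean distance of the
two helix axes from the central curve; local rotation Δφ(i) = signed angle
swept by the helix-axis radial vectors about the local central-axis
tangent; residues per pitch = 360/|Δφ|; local pitch = that times the local
rise; curvature = turning rate of the central tangent; handedness = sign
of the mean rotation. Profile values within half an axis window of either
terminus are undefined and explicitly marked.

**Whole-molecule pitch** is reported from the aggregate rotation (mean of
Δφ over all defined positions), not from averaging the per-residue pitch:
360/Δφ is strongly nonlinear in the noise, and near-zero increments make
the per-residue mean blow up. The aggregate estimator stays within 1 % of
the generator pitch at σ = 0.3 Å coordinate noise; the per-residue local
pitch is still reported for profile plots and stammer localization.

**Heptad register.** The Crick phase of residue i is the signed angle of
(Cα − helix axis point) about the local helix-axis direction, measured
from the direction toward the central axis (0° = facing the partner
helix). The seven letters live on a 360/7 = 51.43° grid with
sequence-adjacent letters 102.86° apart; the anchor places 'a' at +25.71°
so the hydrophobic core midline (phase 0) falls between the a and d bands,
calibrated on the ideal generator. A letter is the nearest grid phase.

**Stammer.** A stammer (register discontinuity equivalent to a 3-residue
insertion into the heptad) shifts the register by three letter bands — 3/7
of a turn, 154.3° of Crick phase — and locally overtwists the supercoil.
The generator emulates it by ramping a net 154.3° Crick-phase advance plus
a 20° supercoil overtwist over 4 residues, which reproduces the observed
signature (band shift plus a local pitch dip). The detector flags
sustained phase jumps ≥135° completed within 4 residues: the threshold
sits below the ideal 154.3° by a measurement-slack margin but far above
the per-residue phase fluctuations of intact coiled-coils, and localizes a
constructed stammer to ±2 residues.

## Junction metrics

Twist angle θ follows the triangular-plane construction: P₁/P₂ are
centroids of residues 157–159 of each C-terminal chain and P₃ the joint
centroid of residue 147; P₄/P₅ are centroids of residues 4–6 of each
N-terminal chain and P₆ the joint centroid of residue 14; θ is the angle
between the two plane normals (vertex ordering fixed as listed), folded
into [0, 180). Centroids are mass-weighted over heavy atoms by default; a
geometric-centroid mode exists for sensitivity checks (for Cα-only
synthetic structures the two coincide). Swapping chain labels in *both*
dimers flips both normals and leaves θ unchanged.

Bend ω is the angle between the C-dimer's terminal central-axis direction
and the N-dimer's initial central-axis direction, both oriented N→C, from
straight-line fits to the last/first eight defined axis points; a
collinear cable gives 0°. This is an explicit implementation definition:
the quantity is specified in the literature only as "the linearity of both
chains across the junction", so an axis-direction angle is the package's
choice and is validated on constructed hinges (20° built → 20.0° measured).

Overlap length is the Euclidean distance between the two coiled-coil axis
*endpoints*, each defined by extrapolating the fitted terminal axis
segment to the projection of the terminal paired-Cα midpoint. The
endpoint convention matters at the few-tenths-of-an-Å level (the terminal
Cα-pair midpoint does not lie exactly on the supercoil axis); the cable
generator therefore solves its axial shift through the same measurement,
so generated cables reproduce the requested overlap exactly.

Terminal width is the residue-1 Cα–Cα distance between the two N-dimer
chains. The generator meets a requested width by radially flaring the
first six residues (linearly decaying), mimicking the terminal spreading
seen in real junctions.

Distance maps hold the minimum heavy-atom distance for every (N-window
residue, C-window residue) pair — windows default to the 12 terminal
residues each side, rows/columns labelled `chain:resnum` — masked above a
6 Å cutoff with an explicit mask (exported TSV cells are empty, never a
sentinel number). Raising the cutoff can only unmask entries. The change
map between two junctions averages (B − A) per N-residue over entries
unmasked in both, counting exclusions.

## Contacts and areas

A contact is a cross-dimer heavy-atom pair whose VdW overlap
(rᵢ + rⱼ) − d lies in the closed band [−0.4, 0.6] Å: small positive
overlaps are productive packing, larger ones clashes. The packaged radii
table (`vdw_bondi.tsv`, Bondi 1964 with common extensions) is named in
every report; contact counts are radii-sensitive, so comparisons across
software should allow ~10 % on counts. The KD-tree search radius is set
from the maximal band reach, making it exactly equivalent to the all-pairs
definition (verified against brute force).

SASA is Shrake–Rupley with a deterministic Fibonacci-sphere quadrature
(960 points/atom, probe 1.4 Å by default; both logged). A single sphere
reproduces 4π(r+probe)² to well under 1 %, doubling the point count moves
totals by <0.5 %, and results agree with an independent implementation
(biotite) to ~2 %. Exactly coincident spheres share their boundary surface
once (lower atom index wins) so degenerate unions are not double-counted.
Buried interface area is SAS(A) + SAS(B) − SAS(AB); it is symmetric and
rigid-transform invariant to quadrature accuracy (the point set is fixed
in the lab frame, so invariance is ~quadrature noise, not machine
precision).

## Synthetic data: what it does and does not show

The generator produces Cα-only traces on exact Crick curves (one
pseudo-atom per residue, standard carbon radius). That is sufficient
ground truth for every geometric metric (axes, pitch, radius, register,
RMSDs, junction θ/ω/overlap/width, distance-map definitions) and for the
*definitions* of contacts and buried area. It does not emulate side
chains, sequence-dependent packing, real B-factors/altlocs, or the atom
density of a crystal structure — so absolute contact counts and buried
areas on synthetic cables are roughly an order of magnitude below the
full-atom values of real junctions, and passing synthetic tests validates
the machinery, not any claim about a particular protein. The
published-value checks run only when the deposited coordinate files are
supplied (`data/structures/`); network access is required once to fetch
them.

## Numerical choices and edge cases

- Axis window default 5 (odd, TWISTER-like locality); all default-window
  results are reported at this value.
- Kink windows default to residues 20–70 vs 95–145, flanking the central
  stammer region of a 161-residue chain; the windows are configurable and
  must be disjoint with ≥10 defined axis points each.
- Degenerate inputs: R₀ = 0 (straight helix) yields "no supercoil"
  handedness and undefined Crick phase rather than a sign; collinear point
  sets make superposition an error; zero buried area makes contact density
  an error, not 0.
- Altloc policy: highest occupancy wins, ties by altloc letter; hydrogens,
  waters and hetero groups are excluded from all metrics.
- Angles pass through arccos, so rigid-transform reproducibility of
  near-0°/180° angles is limited to ~1e-4 degrees.
- Lattice expansion enumerates all space-group operators × unit
  translations in {−1,0,1}³ by construction (no pruning), so it is its own
  brute force; copies are labelled with operator triplet and shift.
- Problem sizes: analyses and tests run on 120–161-residue dimers and
  2–3-dimer cables (≈1000 atoms Cα-only), where the full suite completes
  in well under a minute.

## Known limitations

- ω's literature definition is by citation only; a different axis-segment
  convention could shift real-structure values by a few degrees.
- The exact radii set behind published contact counts is not stated;
  reproducing a specific count may require matching that tool's radii.
- The coiled-coil "end" behind overlap length is likewise convention-bound;
  the axis-endpoint rule above is this package's documented choice.
- Register letters are geometric (Crick-phase) assignments; no
  knobs-into-holes packing classification is attempted.
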