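# Methods

This note documents the models and procedures implemented in `septah`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Scope and units

The package analyses multi-frame coordinate sets of peptide(s) plus a
planar two-leaflet bilayer. Lengths are Ångström, times nanoseconds;
angles are reported in degrees (radians internally). Boxes are
orthorhombic only, and all cutoff-based analyses use the orthorhombic
minimum-image convention. Residue numbering is 1-based with ranges
inclusive on both ends; the default region definitions on the 34-residue
extended AH are N-patch 1–8, AH core 9–26, C-patch 27–34 and "second
half" 17–34. "Heavy atom" always means element ≠ H; synthetic scenes
are generated hydrogen-free.

## Constructs and charges

Constructs are assembled from four canonical Cdc12-derived segments:
N-flank `ERIRLNGD`, AH core `LEEIQGKVKKLEEQVKSL`, C-flank `QVKKSHLK`
and Gly/Ser linker `GSGSRSGSGS`. "Flipping" a domain in the CN
variants is residue-order reversal only — no D-amino-acid chemistry —
which makes CN-NC a palindromic arrangement. The charge model is
integer-valued at pH 7.4: D/E −1, K/R +1, His neutral (consistent with
the +3 of `QVKKSHLK`, which contains His); fractional
Henderson–Hasselbalch charges are out of scope. Termini default to
capped/neutral, matching the simulated constructs; a free C-terminus
subtracts one unit, a free N-terminus adds one.

## Helix axis and bending

The axis polyline is built from sliding 4-residue centroids of the CA
positions. A plain 4-residue centroid retains a ±0.26 Å helical ripple
(four residues at 100°/residue span 400°, not exactly one turn), which
would leak ~5° of spurious bending signal, so two additional
same-length averaging passes (`BendingParams.smooth_passes`, default 2)
damp the ripple to < 0.1 Å without changing the axis point count. Axis
points are labelled by the first residue of their window.

The local bending angle at an axis point is the turning angle between
two chords of arc length `side` (default 7.2 Å ≈ one helical turn of
CA–CA chord) anchored at that point, with chord endpoints found by
linear interpolation along the polyline; 0° means straight, and the
local radius of curvature is `side / angle_rad`. On an exact arc of
radius R this construction returns `s/R` rad, within 0.1% of the chord
closed form `2·arcsin(s/2R)` for the radii of interest; on arc-bent
synthetic helices the generator radius is recovered within 1% for
R ∈ [30, 200] Å. Points closer than `side` (arc length) to either end
cannot carry a full chord pair and are reported as NaN.

The global curvature fit projects CA positions onto the plane of their
two leading principal components, performs an algebraic (Kåsa) circle
fit and refines it with a geometric least-squares pass (run to
convergence; the refinement is a small correction on top of the
algebraic solution). Collinear input (second singular value < 1e-8 of
the first) raises a degenerate-geometry error — the radius is
unbounded. Estimator note: with 0.5 Å coordinate noise the fitted
radius of a short arc is intrinsically noisy (~6% scatter for a 0.8-rad
arc of 34 points); reliable 2%-level recovery needs roughly a 2.4-rad
arc, which the validation uses.

Helicity uses a dihedral-basin criterion instead of DSSP: a residue is
helical in a frame when (φ, ψ) ∈ [−100°, −30°] × [−80°, −5°]. This
avoids a third-party dependency and is adequate for the synthetic
fixtures; terminal residues lack one dihedral and are reported missing.

## Membrane organisation

The membrane normal is fixed to +z (planar patches; no local-normal
estimation). The phosphate atom anchors each lipid: leaflets split by
the sign of phosphate z against the global phosphate mean, the midplane
is the mean of the two leaflet means, and a single-plane input degrades
to one leaflet with a warning.

Area per lipid is an exact periodic 2-D Voronoi partition of the
leaflet's phosphate XY positions (seeds tiled over the 8 periodic
images; cell areas by the shoelace formula). The partition property —
areas summing to the box XY area — is asserted on every call.
Coincident XY seeds are split deterministically by 1e-6 Å with a
warning. An optional mode adds membrane-inserted peptide heavy atoms
(within 10 Å of the leaflet phosphate plane, on the leaflet's side) as
area-excluding seeds whose cells are discarded; it is off by default.
The raster map uses 2 Å bins (nearest periodic seed). This Voronoi
approach replaces neighbourhood-based APL algorithms because the
partition is exact and trivially conservation-testable; it reproduces
the qualitative near-peptide APL elevation the analyses look for.

The nematic order parameter of one lipid is
`S = ⟨(3 cos²θ_b − 1)/2⟩` over all consecutive tail-bead (C–C) bond
vectors of all its chains, θ against +z: S = 1 aligned, 0 at the magic
angle 54.7356° or isotropic, −0.5 in-plane. All tail bonds are used
(no glycerol-adjacent exclusion). Near/far histograms call a lipid
"near" when the lateral minimum-image distance from its phosphate to
the closest peptide heavy atom is ≤ 10 Å and "far" at ≥ 25 Å
(intermediate excluded); the 10/25 Å defaults are package choices,
exposed as options. Z-density histograms pool selected atoms' z minus
the per-frame midplane at 1 Å bins.

## Interactions and salt bridges

Residue contact maps: a pair is in contact in a frame when the minimum
selected-atom distance is ≤ cutoff — 7.5 Å on Cα (generous, to admit
side-chain-mediated contacts) or heavy-atom mode at a caller-chosen
cutoff. Region-level maps average the constituent residue-pair
frequencies over N-term/AH/C-term blocks in contiguous equal time
windows (default 4; the last window absorbs the remainder).
Residue-class contacts count residue pairs (once per frame, regardless
of how many atom pairs qualify) at 3.5 Å heavy-atom distance, and
aggregate by the class partition acidic {D,E}, basic {K,R,H}, polar
{S,T,N,Q,C,Y,G}, hydrophobic {A,V,L,I,M,F,W,P}.

Salt bridges: side-chain carboxylate O (Asp OD1/OD2, Glu OE1/OE2) to
basic side-chain N (Lys NZ; Arg NH1/NH2/NE) within 3.2 Å, deduplicated
to the residue pair. The 3.2 Å value is the common salt-bridge-plugin
default; His is excluded (neutral at pH 7.4). Occupancy is active
frames / total frames, aggregated as mean ± sd **across replicas** (sd
is NaN for a single replica). Lifetimes: maximal runs of consecutive
active frames become events of duration `run_length · dt`; runs
separated by ≤ `gap_tolerance` inactive frames (default 0 — no
smoothing) are merged. With zero gap tolerance, event durations sum
exactly to occupancy × total time. The 95th percentile uses linear
interpolation between order statistics (numpy's default), stated
because quantile conventions differ. Distance traces report the
per-frame minimum O–N distance for the k highest-occupancy pairs, ties
broken by acidic then basic residue index.

## Orientation classifier

Each peptide's axis vector is the unweighted heavy-atom centroid vector
from its N-patch to its C-patch (mass weighting is negligible for
heavy-atom peptides and is available as a flag-equivalent by supplying
custom regions). A and P count residue pairs — patch residue against
second-half residue of the other peptide, both directions summed — with
any heavy-atom pair strictly below 4.5 Å. The contact total is read as
T = A + P (the reading consistent with the definitions of A and P; an
all-pairs variant can be had from the contact-map module), and a frame
is interacting when T > 5, a strict inequality. Interacting frames are
labelled antiparallel_like (A > P), parallel_like (P > A) or mixed
(A = P, a case the source analyses never define; the tie label makes it
explicit). Z-positioning reports heavy-atom COM heights above the
midplane per peptide or per residue (min/Q1/median/Q3/max); systems
without lipids use z = 0 as the reference.

## Synthetic generators: what they emulate

All generators are seed-deterministic (same spec + seed → identical
coordinates) and emit a ground-truth manifest sufficient for closed-loop
recovery tests.

**Helices** are built from an internal-coordinate (NeRF) ideal α-helix
template (φ = −57°, ψ = −47°, ω = 180°) re-expressed in cylindrical
coordinates, so rise (1.5 Å), twist (100°) and CA radius (2.3 Å) are
exact dials. Backbone atoms N/CA/C/O are present per residue; side
chains are a single CB pseudo-heavy bead (1.53 Å, tetrahedral), and
charged residues carry one named charged-tip bead (OD1/OE1/NZ/NH1,
1.2 Å beyond CB) so salt-bridge criteria are testable without rotamer
modelling. Bending maps the helix axis onto a circular arc in the
xz-plane with the local frame parallel-transported — internal geometry
is preserved, so arc curvature is the only signal the bending analyser
sees.

**Bilayers** are square lattices (default 8 Å spacing) of bead lipids:
one phosphate plus ≥ 4 collinear tail beads (1.5 Å bonds) along a
single per-lipid director at a tilt drawn from a fixed, Gaussian
(untruncated — the order parameter only sees cos²θ, and the untruncated
normal admits the closed form `S = (1 + 3 e^{−2σ²} cos 2μ)/4`) or
isotropic-hemisphere distribution. One director per lipid makes the
per-lipid S an exact function of its tilt. Species are assigned
DOPC/PLPI with exact floor-then-fill counts (75:25 default) via a
seeded permutation, per leaflet. Default patches are smaller than the
~11 × 11 nm² systems the analyses target; no analytic property depends
on patch size, only statistical power.

**Two-peptide scenes** place two identical helices at a prescribed
inter-axis angle, axes 18 Å apart (the default keeps every non-forced
inter-peptide heavy-atom pair above the 4.5 Å classifier cutoff given
the ~4.8 Å radial reach of charged-tip beads). Forced contacts are
created by pulling the CB beads (carbonyl O for Gly) of monotonically
matched patch/second-half residue pairs onto a regular staggered seam
at half the axis gap, paired beads exactly 4.0 Å apart; partners are
drawn from the second half *excluding* the patches themselves so no
forced pair double-counts through the reverse peptide direction.
Because the pulls shift patch centroids slightly, the second peptide's
orientation is corrected iteratively until the realized patch-COM angle
is within 0.5° of the request. The generator then brute-force-verifies
its own manifest (A, P, cos θ) and refuses to emit a scene with
accidental contacts.

**Telegraph series** alternate exponential on/off dwell times sampled
on the frame grid, with stationary initial state; ground truth is the
stationary occupancy `τ_on/(τ_on + τ_off)` and the mean on-duration.
Statistical notes that matter for validation: the occupancy estimator's
variance is inflated by autocorrelation — the correct standard error is
`sqrt(2 τ_int p(1−p)/T)` with `τ_int = τ_on τ_off/(τ_on + τ_off)`, not
the binomial formula — and frame sampling misses events shorter than
dt, so lifetime validation uses dt = 0.25 ns where that bias is well
inside the 3-SE band.

What the generators deliberately do **not** emulate: force fields,
thermal fluctuations, solvent, lipid conformational disorder within a
tail, membrane undulations or curvature, and realistic side-chain
rotamers. Passing the closed-loop tests therefore demonstrates that the
estimators are correct and self-consistent on inputs with known truth —
not that real membranes behave like the fixtures.

## Problem sizes used in validation

The test suite and validation scripts run on deliberately small
systems: 34-residue helices (≈ 180 atoms), 10×10–16×16 lipids per
leaflet, two-peptide scenes under 500 atoms, and 10⁵-frame telegraph
series. These sizes make every statistical check well-powered while the
full suite completes in well under a minute.

## Known limitations

- PDB interchange truncates coordinates to 1e-3 Å and limits them to
  the fixed-width field range; both are enforced with explicit errors.
- Orthorhombic boxes only; triclinic input is rejected, not converted.
- The bending-axis construction is a documented reimplementation
  contract (centroid axis + chord-turning angles) validated against
  closed-form circle geometry, not against any specific visualization
  tool's output.
- Occupancy sd is defined across replicas; across-time-block variance
  is not implemented.
- No hydrogen-bond analysis, electrostatic energies, free-energy or
  lateral-pressure calculations, and no curved-membrane analyses.
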