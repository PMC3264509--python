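# Methods

## Scene model

A drawing is an ordered, immutable collection of atoms (element symbol, 2D
position in real-valued scene units with y up, charge, optional isotope
labels, RGB colour, opacity, optional concentric-shell decoration), bonds
(six kinds: single, double, triple, aromatic, wedge, hash), annotations
(arrows, brackets, ellipses, orbital club/banana shapes, text) and an
optional background raster with a brightness factor. Invariants — unique
atom ids, bond endpoints resolving to atoms, at most 100000 atoms — are
checked on construction, so they hold after every operation by construction.
Operations are functional (they return a new drawing), which lets morph
frames share atom objects safely.

The 100000-atom capacity is enforced as a hard error. The leftmost-atom rule
used for attachment ("atom with the smallest x-coordinate") needs a total
order to be deterministic; ties are broken by smallest y, then lowest id.

Opacity is a deliberate extension of the classical drawing state: it is the
mechanism by which the morphing engine realises cross-dissolve, and the
renderers carry it through to SVG `opacity` attributes and raster alpha.

## Molfile I/O

V2000 connection tables are parsed and emitted with the fixed-column layout
(coordinates `%10.4f`, counts `%3d`, 1-based atom indices). Choices:

- z coordinates are read and discarded, written as `0.0000` — this is a 2D
  program.
- Charges are written as `M  CHG` property lines (the modern convention);
  the legacy atom-block charge column is accepted on read, and an `M  CHG`
  line supersedes it, as the format prescribes. Isotope mass numbers travel
  in `M  ISO` lines.
- Wedge/hash stereo map to bond type 1 with stereo flags 1/6.
- The writer never enforces the 999-atom/999-bond record limit: it writes
  the full file and returns one machine-readable `CompatibilityWarning` per
  breached limit (code `V2000_ATOM_LIMIT` / `V2000_BOND_LIMIT`), leaving
  interoperability with stricter readers to the caller.

Attachment translates the guest so its coupling atom (leftmost) sits 1.5
scene units in +x of the chosen host atom and adds one single bond; guest
ids are renumbered to follow the host's. 1.5 units is the package's standard
bond length for generated content (the chain fixture uses the same spacing);
the convention only fixes *which* guest atom couples, not where the guest
lands, so the simplest deterministic placement was chosen. Insertion is the
same renumbering without translation beyond the requested offset and with no
bond created.

Because the native binary format of interactive editors in this space is
undocumented, the second interchange format is a versioned JSON scene
mirroring the data model field-for-field (`format_version: 1`).

## Mappings

`affine_from_triplet` solves the two independent 3×3 linear systems for the
six coefficients (numpy dense solve). `square_to_quad` is the closed-form
unit-squares construction: with corner sums sx = x0−x1+x2−x3 (sy likewise),
a parallelogram (sx = sy = 0) yields an exactly affine map — the projective
row is set to zero, not merely near zero — and otherwise the two projective
coefficients come from a 2×2 solve on corner differences.
`projective_from_quads` composes square→quad maps through the unit square.
The test suite checks both constructions against independent dense solves
(6×6 for affine, 8×8 direct linear transform for homographies), keeping the
closed form and its oracle on separate code paths.

Degeneracy (collinear control points, singular matrices, evaluation on the
horizon line of a homography) is detected at an absolute threshold of 1e−12
on areas/determinants/denominators. This is matched to scene coordinates of
magnitude ~1–100; it is not scale-invariant, so extremely small or large
scenes should be normalised first — a documented limitation.

Region tessellation is a regular n×n grid over a bounding box: quads, or
triangles by splitting each square along its main diagonal. A grid split was
chosen over Delaunay triangulation of atom positions because it is
deterministic, cheap, and independent of the structures being morphed;
Delaunay would adapt the mesh to atom density and is a possible extension.

## Morphing

Frames are evaluated on the grid t_k = k/(n_frames−1), n_frames ≥ 2.

**Correspondence.** How atom areas of the two images are paired is a design
choice: the engine groups atoms by element symbol and pairs greedily by
smallest Euclidean distance (ties by lowest source id, then target id),
leaving leftovers unmatched; bonds pair when both endpoint atoms pair,
preferring equal bond kinds but accepting a sole candidate of another kind.
This is deterministic, symmetric under role swap for generic positions, and
can always be overridden with an explicit `Correspondence`. It is a greedy
assignment, not a global optimum (Hungarian matching); for the intended use
— small perturbations of similar depictions — the two coincide.

**Interpolation.** Positions and opacity are linear in t; RGB channels are
blended in linear RGB and rounded half-up at output. Discrete fields
(element label, charge, isotope labels, bond kind, shell) switch from
source to target at t = 0.5: there is no meaningful textual interpolation.

**Cross-dissolve.** Unmatched source elements keep their position and fade
with opacity (1−t); unmatched target elements fade in with opacity t, their
ids shifted past the source ids so frames never clash. A paired
leaving/arriving couple therefore always sums to opacity 1. Alternatively
(`fade_mode=shrink`) annotation outlines scale toward their centroid by the
fade factor while fading. Elements whose opacity reaches exactly 0 are
dropped from the frame (unless a visible bond still references the atom), so
frame 0 equals the source and the last frame equals the target *exactly*,
structurally and not just visually.

**Region modes.** In `triangles`/`squares` modes, annotation outlines and
the background are warped through per-cell maps (affine for triangles,
projective for quads) built between tessellations of the source and target
bounding boxes, with the frame's mesh interpolated between the two. Bond
areas themselves are interpolated pointwise at their endpoints in every
mode; warping each bond as a 2D quad region is not implemented, as endpoint
interpolation produces the identical line for straight bonds.

**Sequences.** Steps chain when step i's target matches step i+1's source
(ids, elements, positions within 1e−9); junction frames are deduplicated, so
a sequence yields Σ n_frames − (steps − 1) frames.

**Vibration presets** require a bent triatomic (three atoms, two bonds, one
2-bonded central atom). Symmetric stretch lengthens both bonds by the
amplitude (scene units) along their axes; asymmetric stretch lengthens the
lower-id terminal and shortens the other; scissoring rotates each terminal
amplitude/2 radians away from the other at fixed bond length, opening the
angle by exactly the amplitude. Each preset returns the two-step
there-and-back sequence source → displaced → source so the animation
oscillates. Amplitude and frame count are user parameters; defaults
(0.2 units / 0.2 rad, 9 frames per step) are chosen to be clearly visible at
typical depiction scale without distorting the structure. A single step can
also be eased `ping_pong` (t follows a triangle wave) for an oscillation
within one step.

## Rendering

SVG emission is raw XML with a fixed element order (defs, annotations,
shells, bonds, labels), fixed attribute order and `%.3f` floats — identical
drawings give byte-identical documents. The scene's y-up coordinates are
flipped to SVG's y-down at the last step. Short (skeletal) formula form
hides carbon labels, folds hydrogens bonded to carbon into the skeleton and
labels heteroatoms with their bonded-H count (`OH`, `NH2`); long form labels
every atom. Double/triple/aromatic bonds are parallel offset lines, a wedge
is a filled triangle, a hash is six ruled ticks widening toward the far
atom. Shells are concentric circles filled with a two-stop radial gradient;
annotation gradients are two-stop linear. Exact orbital (club/banana) shape
outlines are treated as user-supplied polygons; no particular silhouette is
asserted.

Rasterisation uses Pillow with one shared camera across all frames of an
animation (centre of the union bounding box) so frames align. Background
images are resized to the canvas and passed through the brightness
transform c → clamp(round(c·factor), 0, 255); factors above 1 wash the
image toward white, which is the watermark effect. GIF export uses Pillow's
encoder with per-frame delay ≥ 10 ms (the format's timing resolution) and
optional infinite loop. One encoder caveat: byte-identical consecutive
frames may be coalesced by the GIF writer; morph sequences of non-trivial
motion never produce such frames.

## Synthetic fixtures and what tests show

All test inputs are generated: water (O–H 1.0 units, H–O–H 104.5°), a
cross-shaped methane, n-atom carbon chains (1.5-unit spacing), the SN2
substitution endpoints (chloride approaching CH₃–Br; Cl–CH₃ formed with
bromide departed), and random drawings with bounded coordinates
(±50, 4 decimals, i.e. exactly representable in molfile columns). The
generators emulate depiction geometry only — they make no claim of chemical
realism (no force fields, no 3D), so passing tests demonstrate correctness
of the drawing, file-format and animation machinery, not of any chemistry.
The core library contains no randomness at all; stochastic test data is
seeded explicitly in the tests and the acceptance script.

## Known limitations

- Greedy correspondence can mis-pair atoms under large rearrangements;
  supply an explicit `Correspondence` in that case.
- Degeneracy thresholds are absolute (1e−12), tuned to scene scale ~1–100.
- Raster text rendering uses Pillow's default bitmap font; SVG output is the
  typographically faithful path.
- V3000, SDF multi-record files and R-group/S-group blocks are out of scope.
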