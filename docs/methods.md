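# Methods

`ocustim` simulates low-frequency transcranial alternating current
stimulation (tACS) around the eyes and scores how *locally* a candidate
electrode montage stimulates sub-regions of the lower ocular surface.  It
has four computational layers: a synthetic head/orbit phantom, a
quasi-static finite-element conduction solver with signed (phase)
superposition, an ocular-surface unwrapping and locality evaluation, and an
experiment layer that replays montage comparisons (same-phase vs
anti-phase, current rebalancing, current-path diagnostics).

## Physical model

At stimulation frequencies of ~10 Hz the tissue obeys the quasi-static
approximation: capacitive and inductive effects are negligible and at every
instant the potential solves the conduction equation

    div( sigma(x) grad V ) = 0

with no current through the free skin surface (homogeneous Neumann) and the
electrode pads imposing the drive.  An AC drive then reduces to a static
solve per electrode pair: a *same-phase* combination of two pairs is the
(+1, +1) vector sum of the per-pair element fields, an *anti-phase*
combination the (+1, -1) sum.  The combined |E| is the norm of the summed
vector, so anti-phase drives can cancel.

Two electrode models are implemented:

* **Equipotential pad (Dirichlet), the default.**  Each 42 mm x 42 mm pad
  is an equipotential footprint on the skin: the unit-potential solution is
  rescaled so the total current through the anode equals the programmed
  drive (in mA).  This is the idealized limit of a pad with a highly
  conductive gel layer; the gel thickness is retained as metadata only,
  because in this limit it does not affect the solution.
* **Uniform current density (injection).**  The pad current is injected as
  nodal sources weighted by nodal surface area.  Because every drive shares
  one system matrix, signed superposition of per-pair solutions is *exact*
  for this model up to solver error — this is the model used by the
  superposition/joint-solve consistency check.  (A sum of two Dirichlet
  pair solves cannot match a joint four-pad equipotential solve exactly:
  each solo solve ignores shunting through the other pair's pads.  The
  montage pipeline accepts this approximation deliberately, because
  per-pair solves plus superposition is precisely how multi-pair phase
  studies are normally carried out.)

The solver uses P1 (piecewise-linear) tetrahedral elements, giving one
constant field vector per element — matching an evaluation that reads one
|E| value per element.  Linear systems are solved by sparse LU
factorization; the achieved relative residual (~1e-12) is recorded in every
`FieldSolution`.  The potential is reported in the zero-mean gauge.

Conductivities default to a 10 Hz table (S/m): white matter 0.027656, gray
matter 0.027512, CSF 2.0, bone 0.020028, head skin 0.0002, eyeball 0.41113.
The head-skin value is far below common literature values (which are
closer to 0.1–0.5 S/m); it is kept verbatim as the default because the
montage comparisons are defined relative to it, and it can be overridden in
the run configuration.  Note its consequences: the skin is by far the most
resistive tissue, so pads couple to deeper tissue essentially radially, and
the conductive eyeball behaves as an isolated conductor fed through the
thin resistive lid.

## Synthetic phantom

The phantom is a sphere of radius 80 mm: a 5 mm skin layer, a 6 mm bone
shell, brain-like interior (gray-matter conductivity), and two 12 mm-radius
eyeballs at +/-24 degrees azimuth.  Anatomical features that matter for
periocular current paths are modeled explicitly:

* **Protruding eyes under a thin lid.**  Each eye center sits 2 mm further
  out than the inner skin boundary would allow, so the anterior cap is
  covered by a thin, nearly constant-thickness resistive layer (like an eye
  bulging under the eyelid).  This is what makes the *entry point* of pad
  current follow the pad position; with a concentric eye the gap grows so
  quickly off-pole that every pad couples through the corneal pole.
* **Bone socket with anterior aperture.**  A 4 mm bone cup surrounds each
  eye except over the anterior 60-degree cap, and the concentric bone shell
  is open within 20 degrees of each orbital axis.
* **Structural point shells.**  Meshes are built from graded, jittered
  point sets (Fibonacci shells on every tissue interface, a lattice in the
  volume) tetrahedralized with Delaunay.  Three shells exist purely for
  numerical robustness: a *lid shell* 1.4 mm outside each eye guarantees at
  least one resistive element layer between skin-surface nodes and the
  eyeball (otherwise element-scale short circuits make pad-eye coupling
  fluctuate several-fold between random realizations); a *mid-skin shell*
  keeps the skin two element layers thick so pad contact impedance is
  stable (+-6% across seeds); and explicit in-plane rings resolve the same
  layering on the midsagittal plane.
* **Exact mirror symmetry.**  Points are generated on the x >= 0
  half-domain (with an explicitly sampled midsagittal plane), meshed, and
  reflected.  Left/right eyes and mirrored montages are therefore exact
  mirror images, and anti-phase drives of mirror pairs null the plane
  potential to solver precision — a strong end-to-end symmetry check.

Tissue labels are assigned per element from its centroid.  All randomness
derives from one integer seed recorded in the provenance block; identical
configurations reproduce byte-identical meshes.

Default resolution: 3 mm elements within 40 mm of the eyes (1.7 mm on the
eye surfaces and periocular skin), 8 mm elsewhere — about 180k tetrahedra,
which keeps a full montage comparison (two solves plus evaluation) under a
minute on one CPU.  These sizes were chosen as the coarsest that keep the
montage-level orderings stable across mesh realizations.

## Electrode sites and montage catalog

Pads are placed by projecting a square footprint onto the skin along the
tangent frame of a named site; sites are (azimuth, elevation) pairs on the
phantom, not transcribed coordinates, because pad positions on a real head
are anatomy-specific.  The catalog mirrors seven two-pair combinations of
five letter pairs (A/B: temporal right/left, C/D: central right/left, E:
nasal) plus revised and current-corrected variants:

* the *working* same-eye combination (temporal + central) runs parallel
  chords to nearly coincident low-medial cheek returns;
* the *degenerate* arrangement 4 crowds both active pads (~80% overlap)
  and swaps its overlapping returns sideways so the two current-path chords
  cross — driven anti-phase the two nearly coincident pairs cancel each
  other, reproducing the "cannot stimulate" failure;
* the nasal pair E sits on the midline below the nose-bridge level, which
  couples it weakly to either eye's nasal band — nasal stimulation is
  structurally harder, motivating the 0.8/1.5 mA current rebalancing
  variants;
* revised variants separate arrangement 4's returns and lower the
  temporal-right active pad to reduce upper-zone spill.

Site angles were calibrated by running candidate geometries across phantom
seeds 0–3 and validating the chosen set on held-out seeds 4–5, selecting
for stability of the qualitative orderings rather than any numeric target.

## Ocular-surface evaluation

Each eyeball surface triangle contributes one sample at its centroid,
inheriting |E| from its owning eyeball element.  Samples are mapped to
longitude/latitude in the eye's own frame: latitude 0 on the horizontal
meridian (positive up), longitude 0 at the temporal-most horizontal
direction, increasing across the anterior hemisphere toward the nose.
1.047 rad is read as exactly pi/3, so the anterior lower surface divides
into three equal 60-degree bands — temporal [0, pi/3], central
[pi/3, 2pi/3], nasal [2pi/3, pi] — each with an "upper" counterpart
(latitude > 0) and the posterior hemisphere as remainder.  The left eye's
frame is the mirror image of the right's, so band semantics are symmetric.

Scattered samples are interpolated piecewise-linearly (Delaunay of the
longitude/latitude scatter, samples replicated at +/-2 pi to close the
periodic seam) onto a regular grid, 1 degree per cell by default; no values
are extrapolated outside the sample hull.  Maxima are taken on the grid
(ties broken toward the smallest longitude, then latitude).  A
`LocalityReport` records the in-region maximum, the upper-zone and
adjacent-region maxima, and their differences; `delta_adjacent` may be
negative when stimulation peaks outside the intended region.

**Phase recommendation.**  For a montage, each target region is scored as
its in-region maximum minus the largest maximum over its upper zone and
those adjacent regions that are *not themselves montage targets* (spill
between two co-targeted neighbors is intended, not interference; when every
adjacent band is a target, the upper zone is the reference).  The
recommended phase maximizes the minimum score over target regions.

## Validation

* **Analytic oracle.**  The solver is cross-validated against the
  classical solution for a point current source/sink on an insulated
  homogeneous sphere.  The package evaluates both the truncated Legendre
  series (with convergence checks) and its closed-form sum, which is exact
  arbitrarily close to the boundary where the series converges slowly.
  The comparison injects +-1 mA at two antipodal surface nodes of a meshed
  50 mm sphere (3 mm elements, refined to 1.5 mm within 24 mm of each
  contact, ~210k tetrahedra) and compares per-element |E| at element
  centroids, excluding balls of 12 mm (three background element sizes,
  held fixed under refinement) around the contacts where the point
  singularity is not representable.  The volume-weighted relative L2 error
  is 4.2–4.4% across seeds and decreases under refinement.
* **Superposition exactness** is checked against a joint four-pad solve in
  the injection model (agreement ~1e-12).
* **Mirror symmetry** is checked via the anti-phase midsagittal null.
* The evaluation layer is checked against brute-force grid scans, a
  synthetic Gaussian bump, rotation invariance and round-trip mapping.

## What the phantom does and does not show

Passing results demonstrate that the pipeline solves the conduction
problem correctly, that phase superposition and its cancellation effects
are computed exactly, and that the evaluation layer scores locality as
specified.  The phantom reproduces the structural montage findings: the
crowded overlapping arrangement self-cancels under anti-phase while its
same-phase variant does not; the nasal band is harder to stimulate than
the temporal band at equal currents; and rebalancing to 0.8/1.5 mA
strictly reduces the temporal/nasal imbalance.

One finding does *not* reproduce: for the close-pair same-eye montage the
anti-phase drive does not beat same-phase on the adjacent-delta score in
this phantom — same-phase consistently scores higher (checked across four
seeds and sixteen return-geometry variants).  The two pairs' fields are
positively correlated everywhere on the smooth, homogeneously layered eye,
and more strongly correlated inside the target bands than outside, so the
same-phase sum gains in-region more than it spills.  Reproducing the
anti-phase advantage plausibly requires anatomical heterogeneity (orbital
muscles/fat, face relief) and electrical coupling between nearly touching
pads, neither of which exists here: per-pair solves ignore shunting
through the other pair's gel, and the phantom is a smooth sphere.  The
corresponding acceptance check is left failing by design rather than
weakened; the computed scores are reported as-is.

Other limitations: no CSF or white-matter layers by default (labels are
supported, layers are not meshed); no capacitive or electrode-interface
effects; per-element |E| readout at ~2 mm eye-surface resolution leaves
+-25–40% realization noise on *single-element maxima*, so only orderings
with comfortable margins are asserted; the paper-scale absolute field
values on a real head are out of reach of a spherical phantom, and all
montage comparisons are therefore orderings, not magnitudes.
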