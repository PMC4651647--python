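# Methods

## The problem

The two α-helices that flank the peptide-binding groove of class I MHC
molecules are the main contact surface for T-cell receptors.  Their shape —
bending of each helix, width and twist of the groove between them — changes
along an MD trajectory, and those changes are hypothesised to matter for
recognition.  `helixgeom` turns per-frame Cα coordinates into a small set of
geometric descriptors that can be monitored over time: the curvature
integral of each helix axis, the interhelical surface area, the distance
profile across the groove, and the surface torsion along the groove's
centre line.

## Axis extraction by fragment fitting

An ideal α-helical turn of four Cα atoms is generated from three constants:
pitch p = 0.15 nm (axial advance per residue), radius r = 0.23 nm, and
rotation per residue φ = 100°, with its axis on the x-axis.  The fragment
carries three of its own axis points: initial (0,0,0), intermediate
(1.5p, 0, 0) and final (3p, 0, 0).

For a helix of N Cα atoms the fragment is superimposed on each of the N−3
sliding windows of four consecutive atoms using the closed-form SVD (Kabsch)
solution with determinant correction, so reflections are never returned;
sequence order is preserved (fragment atom 1 ↔ lowest-index window atom).
On degenerate windows the SVD still yields a deterministic result, and the
condition is flagged.  Transforming the fragment's axis points by each
fitted rigid motion and adopting the first window's initial+intermediate
points, every other window's intermediate point, and the last window's
final point yields N−1 axis estimates, paired with the non-uniform grid
u = 1, 2.5, 3.5, …, N−1.5, N (the end points advance 1.5 pitch units,
matching the fragment-internal offsets).  For N = 5 — two windows, both
"first" and "last" — the same rule gives 4 points.

On an ideal helix this pipeline returns the generator's constants to
machine precision (interior spacing 0.15 nm, Cα-to-axis distance 0.23 nm,
100° per residue), which is the package's primary calibration check.

## Polynomial axis model

Separate least-squares polynomials of a common degree m are fitted to the
axis points per coordinate over the u grid above.  Internally the parameter
is centred and scaled to [−1, 1] before building the Vandermonde system
(degree 8 on a raw grid reaching u ≈ 30+ is numerically hopeless), and
coefficients are mapped back affinely for export; evaluation and the
analytic first/second derivatives always run in the scaled basis.
Evaluation outside [1, N] is refused — the model is an approximation of the
axis, not an extrapolator.

Degree 2 is the package-wide default (see Validation); degrees 1–8 are
supported.

## Descriptors

**Curvature.**  κ(u) = |c′ × c″| / |c′|³, a parametrization-invariant local
bending measure (1/nm).  The *curvature integral* is computed as the line
integral ∫ κ |c′| du = ∫ κ ds by composite trapezoid over 100 equidistant
parameter values.  For a planar curve this is the total tangent turning
angle: a straight axis gives 0, a circular arc gives its subtended angle, a
hinge of angle α gives ≈ α.  The arc-length weighting is what makes the
quantity dimensionless and directly comparable to an angle; an unweighted
∫ κ du would scale with the (arbitrary) parametrization.

**Ruled surface.**  L = min(N₁, N₂) reference points, equidistant in each
polynomial's own parameter, are joined by straight rulings X = c₂ − c₁.
When the end-to-end vectors of the two curves anti-align, helix 2's
parameter direction is reversed (policy `auto`), so both run N→C of
helix 1; the policy is idempotent under re-reversal and can be forced.
The rule for "corresponding" points is, as with any such matching,
partly conventional; equidistant-in-parameter is the one implemented.

**Area.**  Each quad between consecutive rulings is triangulated along both
diagonals and the two results averaged, removing the diagonal-choice
arbitrariness; degenerate triangles contribute zero.  A flat rectangular
band of length ℓ and separation d yields exactly ℓ·d.

**Surface torsion.**  Along the centre line m = ½(c₁ + c₂) (computed on
the common parameter after the orientation/matching step), with unit
tangent t:

τ = (X × X′) · t / |X|²,  T = ∫ τ du.

The derivative is X′ = c₂′ − c₁′, consistent with X = c₂ − c₁.  The
alternative form X′ = c₁′ + c₂′ is available behind
`convention="printed"`; note that it equals 2m′, is parallel to t, and
therefore makes τ vanish identically — it is kept only so the two
conventions can be compared explicitly.  τ > 0 means right-handed twist,
τ = 0 a locally developable surface (parallel rulings); mirror reflection
flips the sign of τ and T while leaving κ, distances and area unchanged.

## Synthetic benchmarks

The generators double as the package's ground truth:

- **Ideal helix** — the construction above for any N ≥ 4.
- **Hinged helix** — an ideal 31-atom helix whose atoms beyond a pivot Cα
  (index 5–15) are rigidly rotated about that atom by α ∈ [0, π/2] around
  an axis perpendicular to the helix axis (+z by default, overridable).
  The angle between the two analytic leg-axis directions equals α exactly.
  One caveat found during construction: because the rotation centre is the
  pivot *atom* (radius r off-axis), the two leg axes meet at a corner whose
  position depends on the pivot's radial phase; for phases near 180° the
  corner falls inside the first leg's occupied segment and the *extracted*
  axis polyline briefly backtracks there at large α.  The polynomial
  detector is insensitive to this, but unsigned turning-angle sums over the
  raw axis points are not.
- **Bent helix** — the straight axis x ↦ (x, 0, 0) is replaced by
  x ↦ (x, A·cos(2πx/λ), 0) (default: one period over the helix length);
  atoms are wound around the curved axis at arc-length spacing p using a
  parallel-transported (rotation-minimising) radial frame, preserving local
  pitch/radius/phase.  The reference curvature integral is the turning-angle
  sum of a dense (2·10⁴-point) polyline sampling of the analytic axis — a
  brute-force oracle independent of the detection pipeline.  An arc-bent
  variant (axis = circular arc of subtended angle θ, reference exactly θ)
  provides a closed-form cross-check.

What the generators do *not* emulate: side chains, hydrogen-bond geometry,
thermal disorder of real backbones, or helix irregularities (π-bulges,
fraying).  Passing the synthetic suites therefore shows the geometry layer
is correct and the degree choice sound, not that real MHC helices behave
like ideal ones.

## Validation: choosing the polynomial degree

For degrees 1–8 the relative error η = detector/reference − 1 is evaluated
on a hinge grid (pivot 5–15 × 10 equidistant angles in (0, π/2]) and a
bending grid (10 log-spaced amplitudes, 0.02–0.6 nm, giving reference
turning angles ≈ 0.1–3 rad).  Nothing about the motions dictates these
grids; they were fixed once as a reasonable coverage of the motion range
and are configurable.  Points with zero reference (α = 0, A = 0) are
excluded — η is a 0/0 limit there.

Findings, reproduced by the acceptance suite: degree 1 returns η = −1
identically (straight lines carry no curvature); mean |η| for the hinge is
smallest at degree 2 and increases monotonically through degree 8 (higher
degrees oscillate and overestimate the kink); hinge errors exceed bending
errors at degree 2 (a kink is non-smooth, a cosine bend is not).  Hence
degree 2 is the default for trajectory analysis.

## Residue selection and trajectory pipeline

Per-frame DSSP one-letter codes (ingested, not computed — from per-frame
strings or a classic `.dssp` file) give each residue's helical fraction;
Cα–Cα distances to the partner protein below 1.4 nm (the electrostatic
cutoff of the underlying simulations) give its contact fraction, with an
optional all-atom mode that averages atom-wise contact times per residue.
Both thresholds are inclusive ≥ 0.5, justified when the fraction
distributions are bimodal — a histogram diagnostic is provided so users can
check this on their data.  The intersection is assembled into contiguous
segments; runs shorter than 4 residues cannot support a fragment fit and
are dropped with a warning, and fragmented selections are warned about
rather than silently accepted.

`analyze_trajectory` runs extraction → degree-2 fit → descriptors per
frame; individual frame failures are logged and skipped, only an all-frame
failure raises.  Time series may be smoothed with a centred moving average
(default window 51 frames — the smoothing used in published plots is never
stated, so this is a package choice, recorded in output metadata).  Phase
comparison computes pairwise mutual-fit Kabsch RMSD within and between two
frame sets; a change is flagged when the between-phase median exceeds both
within-phase medians.

## Numerical choices and edge cases

- Quadrature: composite trapezoid; 100 points for curvature integrals,
  the L-point grid for τ.  Doubling the resolution moves smooth degree-2
  results by < 0.1 %.
- Kabsch ties (collinear/degenerate windows): the SVD output is
  deterministic and the result is flagged `degenerate`.
- Zero-length rulings and vanishing tangents raise `SingularGeometryError`
  naming the offending parameter values.
- All lengths are nm internally; PDB files are Å at the boundary
  (× 0.1 in, × 10 out).  PDB coordinates carry 3 decimals in Å, i.e.
  10⁻⁴ nm round-trip resolution.
- Problem sizes: synthetic benchmarks use 31-atom helices (a realistic MHC
  groove-helix length) and the full 11 × 10 × 8 hinge grid; these run in
  seconds and are the sizes exercised by the test suite.

## Known limitations

- The ruled surface ignores the bound peptide lying between the helices.
- Surface torsion depends on the chosen path (centre line) and on the
  point-correspondence rule; values are comparable within one convention
  only.
- Degree-2 axes cannot represent two independent bends per helix; trends,
  not fine detail, are the target.
- The hinge benchmark's extracted-axis turning-angle artifact described
  above (pivot phase ≈ 180°, large α) is inherent to rotating about an
  off-axis atom.
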