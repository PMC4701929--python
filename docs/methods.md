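# Methods

This note records the models, conventions and numerical choices behind
`remodkit`, including the places where the design was genuinely open and
a convention had to be picked.

## The morphology model

An SWC reconstruction is held as a rooted tree of sample points
(id, type code, x/y/z in μm, radius in μm, parent).  Validation demands
a single root, resolvable parents, no cycles and positive radii;
comments, blank lines, unsorted or non-contiguous ids and
child-before-parent ordering are tolerated on input (the last with a
warning).  Output is canonical: ids renumbered 1..N in pre-order,
floats at six decimals.  Round-tripping a file through
parse → write → parse preserves topology exactly and geometry to the
serialized precision; a second round trip is the byte-level identity.

**Soma.** All contiguous type-1 samples reachable from a type-1 root
form the soma cluster.  Its coordinate centroid is the soma center used
for Sholl analysis and as the scaling origin — the common convention
when a format does not define a soma center for multi-point contours.
Edges internal to the cluster are excluded from every dendritic metric
so soma contours cannot contaminate length, surface or volume.

**Sections.** The unit of analysis and editing is the *section*: the
maximal unbranched path from the soma (or a branch point) to the next
branch point or terminal tip — what is loosely called a "dendrite" when
one speaks of removing or extending terminal dendrites.  A section's
node path includes its proximal landmark (shared with its parent
section) so geometry is continuous, but the landmark's edge to *its*
parent belongs to the parent section; lengths are therefore partitioned
without double counting, and the sum of section lengths equals the
total dendritic length identically.  Nodes with three or more children
are allowed (each child starts its own section).  Centrifugal branch
order counts branch points between the soma and the section's proximal
end; stems have order 0.

## Morphometrics

Every inter-sample edge is a conical frustum between the parent radius
r₁ and child radius r₂ over its Euclidean length L (lateral surface
π(r₁+r₂)√(L²+(r₁−r₂)²), volume (π/3)L(r₁²+r₁r₂+r₂²)).  Zero-length
edges contribute nothing.  Region membership of an edge follows the
child sample's type code.

**Sholl profiles** use Euclidean (radial) distance from the soma
centroid — not path distance — in half-open shells [kΔr, (k+1)Δr), with
Δr configurable (default 20 μm; published radial plots use coarse bins
but no specific width is canonical).  Three variants:

* *intersections*: crossings of the sphere at each shell's outer
  boundary, found by solving the segment–sphere quadratic
  |p + t·d| = R per edge.  An edge that enters and leaves a sphere
  counts twice; tangencies are ignored; a sample lying exactly on a
  boundary is attributed to the proximal edge (t = 1 counts, t = 0 does
  not), so shared nodes are never double-counted.
* *branch points*: branch points binned by radial distance.
* *length*: each edge is clipped exactly at every shell boundary it
  straddles (same quadratic, roots in (0,1)) and the pieces assigned by
  midpoint distance, so the shell values sum to the total dendritic
  length to machine precision — a conservation law the test suite
  asserts.

**Diameter taper** is defined per section as (proximal diameter −
distal diameter) / section path length, a deliberately simple
end-to-end rate rather than a per-sample regression; no standard
formula exists, and the simple definition is exactly testable.  For
soma-attached stems the proximal sample is the first dendritic node, so
the soma radius never inflates the rate.

## Remodeling actions

All actions are pure: they return an edited copy plus an edit log
(action, target section, requested and achieved magnitude, warnings).
An impossible request (e.g. shrinking a section by its full length)
skips the section with a warning rather than failing the run.
Magnitudes may be percentages of each target's current length or
absolute micrometers.  A magnitude of zero is the identity for shrink
and extend: the percentage bound (0, 100] applies to actual removals,
and treating zero as a no-op keeps pipelines composable.

**Shrink** deletes whole samples tip-inward and places the new distal
endpoint by linear interpolation (coordinates and radius) along the
last crossed edge, so the achieved reduction is exact rather than
quantized to sample spacing.  For a non-terminal target the distal
subtree is reparented to the new tip and rigidly translated by the tip
displacement — its internal geometry is preserved, its radial position
changes — and the log says so.

**Remove** deletes the section and its entire distal subtree.  A branch
point left with one child becomes a continuation node, so flanking
sections merge on the next decomposition; removing every dendrite is
allowed but flagged as a degenerate cell.

**Extend** appends a chain of new samples at the target tip.  Step
lengths are gamma-distributed; by default the gamma is moment-matched
to the host cell's own inter-sample edge lengths (its empirically
"realistic" sampling-step distribution), with a gamma(shape 2, scale
1.5 μm) fallback for hosts too small to fit.  Each step direction is
drawn uniformly within a cone (default half-angle 30°) around the
current growth axis — initialized from the tip's last edge — and
redrawn while it points back towards the soma (negative dot product
with the soma-to-tip radial unit vector at the original tip).  This
cone-plus-radial-rejection kernel is the simplest that makes the new
cable radiate away from both the parent dendrite and the soma while
staying fully parameterized.  The final step is truncated so the added
length is exact.  Appended samples take the tip's type code and
continue the section's linear diameter taper, with radii floored at
0.1 μm to avoid degenerate geometry.  Extending a non-terminal section
inserts the cable at the tip and translates the distal subtree to its
far end (warned, as this is an interpretation of an operation usually
applied to terminals).

**Branch** grows two daughters from the target's distal tip with the
same kernel, each to daughter_fraction × the parent section's length.
Initial daughter directions are the tip direction rotated ±the
divergence half-angle (default 40°) within a uniformly random plane
containing it, taken exactly on the first step, so the daughters open
by twice the divergence angle.  "Branching at 80 percent of the parent
length" is read as *daughter length = 0.8 × parent length*; the
alternative reading — attachment at the 80% position along the parent —
is available through the `attach_at` parameter, which inserts an
interpolated sample mid-section when needed.

**Scale** maps coordinates to `center + factor·(p − center)` about the
soma centroid (keeping the soma fixed, which is what "enlarging the
tree" should mean), optionally scaling radii; regional scaling moves
only samples of that type code, so stems stay attached and other
regions are bit-identical.

**Pipelines** apply ordered (selection, action) steps, re-resolving
each selection against the current edited morphology — "an additional
10% of the *remaining* terminal dendrites" is taken after earlier
removals.  Random selections are uniform over sections (not weighted by
length), without replacement, with counts rounded half away from zero.
Every stochastic step requires an integer seed, either its own or one
derived deterministically from the pipeline seed; identical inputs and
seeds reproduce byte-identical SWC output.

## Synthetic populations

The generator emulates the gross architecture of NeuroMorpho-style
pyramidal reconstructions, not any specific archive class: a soma point
at the origin; basal stems (type 3) into the z<0 hemisphere, apical
(type 4) into z>0, a fixed arrangement chosen for easy visual checks;
per stem a strictly bifurcating random topology with a prescribed
terminal count (so the Euler relation terminals = branch points + 1
holds exactly per stem); section lengths i.i.d. gamma with configurable
mean and CV (defaults 60 μm, 0.5 — a plausible scale for pyramidal
sections); sections polylined in ~4 μm steps with ≤12° per-step jitter
about the section axis; daughters diverging ±35° at branch points;
diameters starting at 2.5 μm and tapering 0.003 μm per μm of path,
floored at 0.2 μm.

The presets used throughout the examples and tests are scaled to the
two cell classes the stress recipes address: the CA3-like preset
(5 basal stems × 6 terminals, 1 apical stem × 30 terminals, 75 μm mean
sections) and the BLA-like preset (4 × 5 basal, 1 × 8 apical, 55 μm).

Because all section lengths share one gamma mean μ, expectations are
closed-form: a cell from a spec with S sections has expected total
length S·μ, and removing k₁ of the N sections of a subtree while
shrinking k₂ more by a fraction f removes an expected
(k₁ + f·k₂)/N of its length (exact for the removal term by
exchangeability).  The population tests verify the recipes against
these expectations within three Monte-Carlo standard errors.

What the generator deliberately does *not* reproduce: real terminal
sections are typically longer than internal ones, arbors are not
strictly bifurcating, section lengths correlate with branch order, and
somata are multi-point contours.  Passing tests therefore demonstrate
the correctness of the parsing/editing/measuring machinery and the
self-consistency of the statistics, not statistical realism against any
real archive — which is also why group-level percent changes obtained
on synthetic populations differ in magnitude from those published for
real CA3/BLA reconstructions, whose terminal dendrites carry a far
larger share of total length.

## Numerical conventions

* Achieved-vs-requested tolerance: 1e-6 μm (interpolation/truncation
  contract); internal snapping tolerance 1e-9.
* Sholl tie-breaks: tangencies ignored, boundary samples to the inner
  shell (via the t ∈ (0, 1] crossing rule).
* Percent change is computed on group means and rounded to two decimals
  half-even, matching how published comparison tables reconcile with
  their printed means; SEM uses the n−1 denominator and is 0 for
  singleton groups.  No inferential statistics are attached.
* Counts from fractions round half away from zero ("17% of 30
  terminals" → 5).
* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; population generation derives per-cell seeds from one
  master seed.

## Problem sizes

The test suite exercises ≤50-sample trees for the 100-seed property
suites, ~2000-sample cells for single-cell checks, and 25/26-cell
populations for the recipe statistics; these sizes give sub-second to
~10 s runtimes per suite while leaving Monte-Carlo standard errors
small enough for three-sigma checks to be meaningful.

## Known limitations

* Multi-neuron SWC files, Neurolucida/NeuroML formats and spines are
  out of scope.
* The growth kernel is phenomenological; it makes no claim about
  guidance cues, resource competition or any biological growth rule.
* Sections are the editing unit; operations on sub-section spans (other
  than `attach_at` branching) are not exposed.
* Regional scaling with factor ≠ 1 stretches the stem attachment edge
  for stems not anchored exactly at the soma centroid.
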