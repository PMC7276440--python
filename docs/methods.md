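# Methods

`corallum` reconstructs the internal record that a branching scleractinian
coral keeps of its own growth.  Each polyp sits in a cup-shaped calice and
repeatedly seals itself off from the chamber below with a tabula as it grows
outward, so the skeleton of a colony contains, for every polyp, a stack of
sealed inter-septal spaces running from the polyp's budding point to its
living calice at the colony surface.  Given a binary micro-CT volume of the
skeleton, the package recovers these chambers, quantifies them, groups them
into growth/mineralization sections, rebuilds the dichotomous growth-axis
topology, and profiles growth rings along the branch axis.  A synthetic
colony generator with exhaustive ground truth stands in for scan data
everywhere the pipeline is tested.

## Chamber segmentation

An internal inter-septal space is a void completely enclosed by mineral, so
within the colony interior, chamber recovery is connected-component
labeling of the void phase.  Two deliberate choices make this exact:

* **Connectivity.**  Voids are labeled with 6-connectivity and the mineral
  treated as 26-connected.  A pair of walls meeting at a one-voxel corner
  is then still a separating wall; with 26-connected voids a single
  diagonal gap would fuse two chambers.
* **The envelope.**  Living calices open to sea water, so before labeling
  the colony is morphologically closed ("envelope") to seal every mouth.
  The structuring element is the n-fold iterate of the unit cube (a
  Chebyshev ball, n = closing radius / voxel spacing, default radius
  0.6 mm against oral openings of at most 1.0 mm).  Iterated-element
  closings are nested by construction, so the envelope is monotone in the
  radius, and the element's flat faces rest on the calice rim instead of
  sinking into the mouth the way a Euclidean ball of comparable radius
  does.  The closing is computed on a grid padded by n voxels so border
  clipping cannot break the nesting, followed by a fill of fully enclosed
  background.

Candidate chamber voxels are envelope voxels that are neither mineral nor
exterior.  Two reconciliation steps then align the candidate set with the
calice apertures:

* **Aperture restoration.**  Whatever the element, a closing cannot follow
  a cup wall all the way to the rim on a tilted mouth; the lost cup top is
  still ringed by mineral in the cross-sectional plane perpendicular to
  the cup axis.  Each exterior-reachable component is therefore grown
  geodesically through void voxels whose in-plane rays (12 rays, 1.5 mm
  reach) all hit the skeleton, which restores the cup exactly up to its
  aperture plane.  Enclosure is evaluated lazily on the growth frontier.
* **Artifact suppression.**  The closing also creates void pockets between
  branches that are not chambers.  An exterior-reachable component that is
  mostly (>50%) *not* slice-wise enclosed by the original skeleton is such
  a pocket and is removed, unless it touches the volume border (a chamber
  cropped by the scan field of view is kept and flagged `truncated`).

Fused chambers — dissepiments between old inter-septal spaces thin with
age until the separations are no longer distinct — are split by marker-based watershed
on the negated interior distance transform.  Markers are h-maxima deeper
than `h_min` (default 0.05 mm, half the nominal tabula thickness).  The
distance field is smoothed with a two-voxel Gaussian first: a tilted flat
chamber's distance field carries staircase ripples that would otherwise
spawn spurious maxima, while a genuine two-lobe saddle (two chambers joined
through a vanished dissepiment) survives the smoothing.

A chamber is classified `surface_calice` iff it reaches the pre-closing
exterior background; everything else is `internal_space`.

## Morphometrics

The thirteen per-chamber features are voxel-exact where possible: volume is
the voxel count times spacing³, projection distances are bounding-box
extents, projected areas count occupied pixels of the axis projections, and
the equivalent diameter is the equivalent-sphere diameter from volume (it
must exist for sealed internal spaces, which have no opening).  Surface
area is reported from a triangulated isosurface; the indicator field is
smoothed by one voxel before marching cubes because a raw binary isosurface
carries the voxel staircase and overestimates area by roughly 7%.  The
exact exposed-face count is retained as `face_count` and is the oracle used
in tests.

Calice measurements (oral and aboral opening diameter, polyp height) are
taken along a per-calice growth axis.  The axis is estimated from the
stacking normal of the nearest clearly flat neighbour chamber — an
inter-septal space bounded by tabulae is a thin disk whose least-variance
principal direction is the growth direction to within a few degrees — with
the step direction toward the calice fixing the sign and rejecting lateral
same-ring neighbours.  The oral surface is the chamber's up-facing boundary
and the aboral its down-facing one, each projected onto the plane
perpendicular to the axis; diameters are equivalent-circle diameters of the
projected areas.  Two modes exist: the *sheet* mode keeps only boundary
voxels within 1.5 voxels of the axial extreme (the exact opening plane;
used when the axis is known exactly, and equal to counting the top/bottom
voxel slab in the axis-aligned case), while the *silhouette* mode projects
the whole facing surface and is robust to a misestimated axis; the batch
pipeline uses silhouette mode.  A slab-based measurement was rejected
because a tilt of only atan(spacing / mouth diameter) — under 2 degrees for
a 1 mm mouth at 25 um — reduces the top slab to a crescent.

## ISODATA clustering and sections

ISODATA is implemented from scratch in its classic split/merge form:
assignment to the nearest centroid, discarding of clusters below `n_min`,
centroid updates, splitting on odd iterations and merging of centroid
pairs closer than `d_merge` (closest first, at most `max_merge_pairs` per
pass) on even iterations.  A split perturbs the centroid ±0.5·`sigma_split`
along the cluster's widest dimension.  While k is below `k_desired` the
most diffuse splittable cluster is split unconditionally — the classic
drive toward the desired cluster count; beyond that, a cluster splits only
when its largest per-dimension standard deviation exceeds `sigma_split`,
its mean intra-cluster distance exceeds the overall mean, it can give
`n_min` members to each half, and k is below twice the desired count.
Initial centroids are points sampled without replacement from the seeded
generator, so runs are reproducible.  With splitting and merging disabled
and `n_min` = 1 the loop is exactly Lloyd k-means, which the tests exploit
as an oracle.

The split threshold deserves a note.  Features are z-scored, so any
feature that carries *no* cluster signal — for example a spatial
coordinate orthogonal to the section structure — has a within-cluster
standard deviation of about 1.0 by construction.  A threshold at exactly
1.0 therefore sits on a knife edge and k drifts upward indefinitely; the
default is `sigma_split` = 1.25, safely above that noise floor while still
below the ~1.4 spread of a two-section mixture.  Remaining defaults
(`k_init` 2, `k_desired` 4, `n_min` 20, `d_merge` 1.0 in z-scored units,
100 iterations) are standard settings for standardized features.

A known limitation follows from the same geometry: on whole-colony data
the three spatial coordinates are multimodal across branches, so while
ISODATA settles at four sections whose volume and light ordering match the
planted archetypes, the per-chamber agreement between recovered and
planted sections is only moderate (~50% on the default colony).  Section
recovery is sharper when the pipeline is applied to a single branchlet,
where coordinates do not carry colony-scale structure.

Features are z-scored column-wise (sample standard deviation); constant
columns are dropped with a warning.  The four clusters are mapped to the
conventionally ordered sections by mean chamber volume — mineral accumulation fills
inter-septal spaces, so the two lowest-volume clusters are the
mineralization areas — with the lit member of each pair identified by the
mean position along the light axis.  Between-section comparisons use the
pooled-variance independent-samples t test (Welch by flag), two-sided, with
significance flagged at p < 0.05.

## Growth topology

Chambers are chained into per-corallite trajectories by reciprocal
nearest-link matching: a link is admitted when the face-to-face gap
(centroid distance minus the half-thicknesses) is below twice the mean
chamber thickness and its direction lies within a 45-degree cone of both
chambers' stacking normals; each chamber keeps its nearest admissible link
per side, and only reciprocal links survive, so chains are simple paths.
Near-isotropic chambers (deep calices, budding-cone starters) inherit the
normal of the nearest clearly oriented chamber — without this, two
neighbouring calices would link laterally, since corallites are packed
tighter side-by-side (coenosteum) than axially (tabula).  Chains ending in
a surface calice are oriented toward it; interior chains are oriented away
from the nearest surface calice (the origin is the end deepest in the
skeleton).

Budding links assign each trajectory the nearest chamber of another
trajectory lying behind its origin — within a 55-degree cone around the
reverse growth axis, at least one chamber thickness deep, and within ten
mean thicknesses.  The cone matters: a parent chamber sits beneath its bud,
whereas chambers of a branch that merely grew alongside sit level with it.

Growth bundles are single-linkage clusters of trajectories on (origin
position, initial direction scaled by 5 mm, budding-parent position scaled
by 1 mm); all three are needed because branches born on neighbouring arms
of a crowded colony can converge in both position and direction but never
share parentage.  Bundles with at least three members are branch-level
nodes; smaller ones are minor buds, matching the observation that many
small buds branch from minor growth axes while the major branching stays
dichotomous.  Tree edges follow the majority of member budding links, and
the dichotomy report lists every internal node's out-degree — a
trifurcation is reported, never corrected.

Growth types follow the stated rules: a trajectory with a daughter is
`budding`; a childless one with at most `stunted_max` (default 5, from the
observation that deviating polyps stop after four or five inter-septal
spaces) chambers is `stunted`; longer childless ones are `nonbudding`.  A
budding origin is flagged when the equivalent diameter rises strictly and
by at least 20% over the first `budding_cone_chambers` chambers (the
inverted-cone signature of a new bud).

## Layers and growth rings

A branchlet is divided into N equal-width layers (default 48) along its
growth axis (given, or the first principal direction of the chamber
centroids).  Chambers are assigned by centroid so layer counts stay
additive; per-layer means and standard deviations of equivalent diameter
and volume form the growth profile, and per-layer unions of chamber voxels
form disjoint growth-ring masks.  Equal-width binning is a choice the data
does not force; dissepiment-aligned layering would be a natural extension.

## The synthetic colony

The generator builds a corymbose colony with pocilloporid morphology,
with every random draw taken from one seeded generator in documented order
(two child streams: tree, then rasterization), so output is bit-identical
for a given (spec, seed).

* A strictly dichotomous branch tree: sibling branches split side-by-side
  (offset by the bounding branch radius), and each generation fans
  radially outward to a ring wide enough that all of its branches keep
  coenosteum clearance (a configurable factor, default 1.2, above the bare
  sealing minimum).  A carving-time guard additionally clips any chamber
  voxel that would intrude into a foreign branch's corallite zone, so
  chamber voids of different branches always keep a wall between them.
* Each branch carries a ring of corallites seated so the radial wall to
  the branch surface is exactly the corallite-wall thickness (0.15 mm) and
  the mineral between neighbouring corallites equals the coenosteum
  thickness (0.075 mm) — corallite walls visibly thicker than coenosteum.  One ring
  slot per branch (when at least three slots exist) holds a short stunted
  corallite near the branch top.
* Chambers are circular frusta separated by 0.1 mm tabulae.  Oral
  diameters scatter log-normally (sigma 0.10) about the centre of the
  species range and are clipped to 0.5–1.0 mm; heights scatter
  (sigma 0.18) about 0.30 mm within 0.1–0.6 mm.  New buds open with an
  inverted cone: the first `budding_cone_chambers` chambers ramp linearly
  from half diameter to full.  Corallites of terminal branchlets end in an
  open calice (0.45–0.6 mm deep, its roof punched through the tip cap);
  roofed corallites of interior branches have no open calice, which is why
  the generated truth marks at most one surface calice per corallite
  rather than always exactly one.
* Sections: terminal branchlets are the growth areas and interior branches
  the mineralization areas, crossed with the lit (+x) versus shaded half
  relative to the colony axis — four contiguous zones of the skeleton.  Mineralization-region chambers are refilled with
  mineral from the floor up by `mineral_fill_fraction`, and section
  archetypes scale chamber volume (lit sections larger), always inside the
  species size range.
* Ground truth records the realized (post-rasterization) labels, per
  chamber values and corallite chamber sequences; chambers that collapse
  below 64 voxels (e.g. fully refilled ones) are removed and re-filled
  with mineral, and indices renumbered consecutively.

The default colony (three bifurcation generations, 25 um voxels, ~190–210
chambers, ~95M voxels) is the study condition used by the acceptance
script and the heavy tests; unit tests use a one-bifurcation colony at
50 um.  These sizes keep a full pipeline run around 1.5–3 minutes and
within a few GB of memory.

What the phantom does *not* emulate: septal microstructure (septa are
below the phantom's effective resolution), scanner noise and
beam-hardening, partial-volume gray levels, anastomosis or damage, and
polyp soft tissue.  Passing tests therefore demonstrate correctness of the
geometry pipeline on clean, well-sealed skeletons, not robustness to
acquisition artifacts; a global threshold option is the only concession to
real gray-scale scans.

## Numerical choices and degenerate inputs

* Axis order is (Z, Y, X), index 0 at the volume origin, voxel centers at
  (i + 0.5)·spacing; isotropic spacing only; all exported coordinates are
  physical millimetres.
* TIFF stacks carry spacing in an ImageDescription key; a file without
  spacing metadata requires an explicit value — mm-scale outputs are never
  silently defaulted.
* Label volumes are written as 32-bit integers so chamber counts beyond
  65535 survive round-trips.
* Chambers with fewer than 8 voxels are flagged degenerate and their
  calice measurements are null; empty candidate sets warn rather than
  raise; all-identical clustering inputs collapse to a single cluster.
* Ties in watershed marker competition follow the deterministic flooding
  order of the implementation; labels are renumbered in scan order, so
  segmentations are reproducible voxel-for-voxel.

## Known limitations

* Trajectory tracing assumes chambers of one corallite are closer
  axially than chambers of different corallites are laterally, which holds
  for tabula-stacked pocilloporids but not for meandroid corals.
* The bundle aggregation needs a handful of corallites per branch; a
  branch represented by one or two recovered chains is reported as a minor
  bud rather than a tree node.
* The section mapping presumes the expected volume ordering (growth >
  mineralization); a colony where mineralization areas hold the larger
  chambers would map inverted.
* Growth rings are geometric layers; no temporal calibration is attempted.
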