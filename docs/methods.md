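# Methods

## Problem setting

A singly-stained neuron imaged by confocal laser scanning microscopy is a
sparse, bright, tube-like structure in a 3-D stack with strongly anisotropic
voxels (default 0.36 × 0.36 μm pixels, 1 μm optical sections). The goal is a
rooted tree of centerline nodes with radii (SWC semantics) that reproduces
the neuron's branching topology and geometry. Two failure modes dominate in
practice: weak or fragmented staining (handled by volume filtering and
distance-threshold reconnection) and spatially overlapping arbors whose
foregrounds merge (handled by mask-based decomposition).

## Preprocessing

- **Deconvolution** (optional): Richardson–Lucy (`skimage.restoration`),
  with a PSF modelled as an anisotropic Gaussian — lateral
  σ = 0.21·λ/NA, axial σ = 0.66·λ·n/NA² (n = 1.515), the standard Gaussian
  fit to the widefield Born–Wolf PSF. Defaults: NA 0.8, λ 0.488 μm,
  20 iterations. The tracing core does not depend on this stage; it exists
  to sharpen blurred stacks before thresholding.
- **Binarization**: global threshold. The default rule, `"background"`,
  estimates the background level and scatter robustly (median, and
  1.4826 × median absolute deviation) and keeps voxels ≥ 5σ above
  background. This is the appropriate rule for neurite stacks, where
  foreground occupies a fraction of a percent of the volume; Otsu's method
  (also available as `"otsu"`) degenerates on such unbalanced histograms,
  placing the threshold inside the noise distribution. A numeric threshold
  can be given directly. When the background is exactly constant
  (noise-free synthetic stacks) the rule falls back to the midpoint between
  background and maximum.

## Segmentation core

1. **Connected components** at configurable connectivity (6/18/26,
   default 26 — thin neurites traverse voxel corners and fragment at 6).
   Components are ordered by volume descending, ties by smallest voxel
   index; all downstream tie-breaks are index-based, so the whole pipeline
   is deterministic.
2. **Volume threshold VT** (default 30): only fragments with volume
   strictly greater than VT voxels are kept. The strict inequality is
   deliberate and tested (a 30-voxel fragment is removed at VT = 30).
3. **Seed selection**: an endpoint of a longest geodesic path through the
   fragment, found by the double-sweep heuristic (geodesic sweep from the
   smallest-index voxel, then from the farthest voxel found). On tube-like,
   essentially tree-shaped foregrounds this endpoint attains the maximal
   geodesic eccentricity, i.e. it is a neurite terminal; ties resolve to
   the smallest (z, y, x) index.
4. **Centerline extraction** (cover-and-trace): Dijkstra distances from the
   seed over the foreground voxel graph, with edge costs = physical step
   length × a medialness penalty `1 + 10·(1 − d/d_max)²` where `d` is the
   Euclidean distance-to-background — paths therefore run along the tube
   centre. Repeatedly the farthest uncovered voxel is back-traced along
   shortest-path predecessors until it meets the existing skeleton, the new
   path's nodes are appended, and every foreground voxel within the local
   radius (+1 voxel) of the path is marked covered. Terminates when all
   voxels are covered; each branch tip of the foreground spawns exactly one
   path, so spurious bristles are rare without explicit pruning.
5. **Position smoothing**: voxel paths staircase on the anisotropic grid,
   inflating path lengths by up to tens of percent (worst for runs oblique
   to the section axis). Damped Laplacian smoothing (12 iterations,
   λ = 0.5) of every degree-2 node against its two neighbours recovers the
   smooth centerline; junctions, terminals and the root stay fixed. Node
   radii are the Euclidean distance-to-background (μm) at the original
   voxel, unsmoothed.
6. **Distance threshold DT** (default 30): remaining fragment trees are
   attached iteratively. The gap to the growing reconstruction is the
   minimum node-to-node Euclidean distance in voxel-index units, rounded to
   the nearest integer; a fragment qualifies iff the rounded gap is
   strictly < DT. The closest fragment attaches first, is rerooted at its
   closest node, and becomes a child of the nearest node of the main tree
   (sequential growth, so chains of fragments attach transitively).
   Unattached fragments are counted in the output metadata and dropped.
   The connecting edge spans the gap; no interpolated nodes are inserted.

## Mask-based arbor separation

`AND(I, M)` keeps image intensities where the mask is true; `EOR(I, P)`
zeroes voxels where the two stacks have equal values and keeps the first
image's value elsewhere. EOR is defined on intensity values, not on bit
patterns: with `P = AND(I, M)` this yields exactly the complement of the
extraction, and the identity `AND(I,M) + EOR(I, AND(I,M)) = I` holds
voxel-exactly — the decomposition loses no signal, which is why the manual
mask can be treated as objective, archivable documentation of the
separation decision. `separate` applies masks in order against the running
remainder and returns k+1 partial images with pairwise-disjoint supports
summing exactly to the input.

`trace_separated` traces each partial independently and re-merges the
partial trees largest-first (largest-first stabilises the junction choice);
each subsequent tree is rerooted at its node nearest to the growing
reconstruction before attachment. Because a mask boundary can cut the
complement arbor into pieces near the shared junction, the merge tolerance
is the larger of the morphology-level junction tolerance (2 × the in-plane
voxel spacing) and DT converted to physical units — i.e. partial
reconstructions may be joined across the same gaps the DT stage would
bridge. Node provenance (which partial each node came from) is recorded in
the tree metadata.

## Reconstruction comparison

The score is an independent implementation of the gold-centric matching
principles popularised by the DIADEM challenge, not a port of the Java
reference tool; exact numeric agreement with that tool is not claimed.
Critical nodes of the gold tree (bifurcations + terminals, root excluded)
are processed root-to-leaf. A gold node matches a test node when (a) the
test node lies within 1.2 μm laterally and 2.0 μm axially (defaults ≈ 3.3
pixels / 2 sections at the default spacing; dataset-specific and
overridable), nearest candidate first, one-to-one; and (b) if the gold node
has a matched critical ancestor, the test-tree path length to that
ancestor's match agrees with the gold path length within 5% relative plus
4 μm absolute slack. The absolute slack absorbs discretisation jitter on
short paths; the relative band catches the topological errors that matter
(paths routed through a false contact differ by tens of μm). Weights are
terminal-descendant counts, so missing a proximal bifurcation costs its
whole subtree's terminals. Excess test structure does not reduce the score
and is reported separately as unmatched cable length.

## Synthetic ground truth

The generator emulates the relevant features of a confocal acquisition of a
single stained neuron: a binary-branching tree grown from segment lengths
of 8–18 μm, branch angles 40–80°, root radius 1.4 μm tapering by 0.88 per
generation (clamped at 0.8 μm so distal neurites stay above ~2 in-plane
voxels), densely resampled to ≤ 1 voxel node spacing, rasterized as
sphere-swept segments (capsules) into a 256 × 256 × 64 grid at
0.36 × 0.36 × 1 μm — the published imaging geometry with the section count
scaled down to desk size. Signal 200 over background 20, additive Gaussian
noise with σ = signal/SNR at SNR 10. Everything derives from
`numpy.random.default_rng` seeded streams: fixed seed ⇒ bitwise-identical
trees and stacks.

The overlapping-pair scenario mirrors the hard biological case of two
sibling arbors (dorsal/ventral branches) leaving one primary neurite and
ramifying through the same territory: both arbors grow from a shared
bifurcation with directions biased toward a common target region, so their
distal bounding boxes overlap by ≥ 50% and their tubes genuinely touch.
The oracle mask — the rasterized support of one arbor dilated by one voxel
— stands in for the manual partial trace.

What the generator does *not* emulate: depth-dependent attenuation and
scattering, Poisson-dominated shot noise statistics, staining
inhomogeneity along neurites, and imaging artefacts (stitching seams,
bleaching). Passing round-trip tests therefore demonstrates correctness of
the algorithmic chain under realistic geometry and noise, not performance
on degraded real-world stacks.

## Numerical and design choices

- Axis order (z, y, x) with 0-based indices; SWC coordinates are physical,
  `index × spacing`, in (x, y, z) column order. Pinning this is what makes
  SWC/mask/TIFF interoperability testable.
- SWC dialect: 7 whitespace-separated columns, `#` comments; ids need not
  be consecutive on read, and are renumbered 1..N parent-before-child on
  write with 6-significant-digit coordinates. Structure type is emitted as
  0 (undefined) everywhere — the tracer has no basis for soma/axon/dendrite
  labels. Tree metadata round-trips through `# key: value` comment lines,
  making writes byte-stable under re-read.
- Self-contact limitation: when a single arbor's branches touch in the
  rendered volume, the geodesic back-trace can route through the contact
  and misplace a junction — the same failure mode as overlapping arbors.
  This is inherent to single-seed tracing of a merged foreground; the mask
  decomposition is the intended remedy, applied with a mask isolating
  either side of the contact.
- Problem sizes in tests: rendered volumes are 256 × 256 × 64 (the
  published in-plane size at a desk-scale section count); ten seeds per
  pipeline-level comparison. These sizes exercise every stage at realistic
  anisotropy while keeping the full suite fast.
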