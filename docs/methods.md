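# Methods

This note documents the image-analysis model implemented by `angioquant`,
the choices made where the procedure was genuinely open, and what the
synthetic test scenes do and do not establish about real microscopy data.

## The analysis model

Both assay pipelines share a vocabulary: a grayscale phase-contrast image
is reduced to a binary mask of pseudo-capillary structures, thinned to a
one-pixel, 8-connected skeleton, and converted into a planar vectorial
graph whose objects are counted and measured.

### Bead detection (FBA)

A microcarrier bead appears as a dark disk with a bright envelope.
Detection runs in three stages:

1. **Coarse mask.** The image is divided by its own Gaussian blur at scale
   σ (the nominal bead diameter) to level the illumination, log-
   transformed, and passed through a variance filter whose radius matches
   the apparent rim thickness.  An IsoData threshold plus a
   close / fill-holes / open / fill-holes cycle yields a solid blob per
   bead (or bead cluster).
2. **Interior mask.** The edge-enhanced image, rescaled by its own
   IsoData level so that "edge" sits near 1 regardless of scene contrast,
   is subtracted from the coarse mask.  Bead interiors stand out as the
   high mode of this difference image; a grayscale maximum filter
   (radius 2), Minimum threshold, hole filling and opening produce one
   connected component per bead even when rims touch.
3. **Circle fit.** Each interior component within the plausible diameter
   window is fitted with an algebraic (Kåsa) least-squares circle,
   refined by up to three passes that discard boundary pixels more than
   1.5 RMS deviations off the circle — sprout bases dent the interior
   boundary, and a plain fit is biased low by those dents.  Components
   whose final RMS residual exceeds 0.25 r, or that keep fewer than 70 %
   of their boundary pixels as inliers (crescents fit a clean circle to a
   majority arc), are rejected as clutter.  The radius is enlarged by the
   rim thickness so the circle covers the bead envelope.

### Network segmentation

Flat-field correction is followed by a band-pass that keeps structures
between v1 (≈ 1.5 px, the finest cellular extensions) and v2 (= σ) in
size, realized as a difference of Gaussian low-passes with
sigma = 0.4 × the structure size; the 0.4 factor places mid-band
wavelengths above 80 % transmission while structures four times larger
than v2 fall below 20 %.  A variance filter of radius 2 folds the paired
bright/dark halo bands of phase-contrast optics into a single ridge, the
histogram modal value is subtracted, and the result is thresholded at its
mean after quantization to 256 levels — the 8-bit convention of the
macro-based lineage of this method; thresholding the float image instead
lets the mean collapse to the noise floor on sparse fields.  A binary
closing and one dilation produce the final ribbon mask.  Holes smaller
than one cell cross-section (100 px²) are filled before thinning: a loop
smaller than a cell cannot be a capillary loop, only a segmentation
artifact at a bifurcation.

In bead mode the fitted circles are filled into the mask before thinning,
skeleton components that never touch a circle ring are discarded as
floating debris, and pixels strictly inside a circle are erased
afterwards, leaving each sprout as a tree anchored on the rim.

### Vectorization

Skeleton pixels with ≥ 3 neighbors are node pixels; a 7-px-diameter disk
is stamped on each, and connected blobs of disks become junctions (the
dots absorb the node-pixel clusters that thinning produces around a
single biological bifurcation).  Pixels with exactly one neighbor are
extremities.  The remaining pixels form simple paths traced into
branches, segments and isolated elements; lengths accumulate 1 per axial
and √2 per diagonal step.  Closed node-free loops become a self-loop
segment on a synthetic junction.

Cleanup then runs to a fixed point:

* **Fusion.** A segment shorter than 20 px joining junctions whose
  centroids are closer than 20 px is contracted (20 px ≈ two aligned
  endothelial cells); the contracted polyline is absorbed into the merged
  junction blob so the wall geometry stays connected.  Short self-loops
  (a junction touching itself around a sub-cell hole) are dropped.
* **Pruning.** Branches shorter than 10 px are deleted iteratively.
  Near-parallel pairs of short leaves at a blunt tip (< 45° apart) are
  thinning fishtails — only the longest survives; single leaves up to the
  20 px fusion scale whose junction's other edges run straight through
  (> 155° apart) are ribbon-boundary hair and are also removed (a real
  bifurcation in these data opens well below 155°).  A junction left
  with degree 2 dissolves and its edges concatenate across a drawn
  bridge; degree 1 degrades to an extremity; rim-touching stubs and
  junctions whose blob reaches a circle ring are left alone before
  anchorage classification, because they are anchorage junctions in
  waiting.
* **Anchorage (FBA).** Edges with ≥ 80 % of their pixels within 2 px of a
  circle ring are residual arcs of the circle and are deleted.  Junctions
  whose blob intercepts a ring, and extremities within 3.5 px of one
  (clearing cut plus ring rasterization each contribute about a pixel of
  slack), become anchorage junctions; anchorage junctions on the same
  circle closer than the fusion distance merge; anchored fragments that
  never leave the ring vicinity by more than the two-cell scale are dirt
  stuck to the bead and are removed.  Fusion and pruning run once more
  after promotion.
* **Isolated elements.** Fragments shorter than 10 px (the size of a
  single cell) are dropped; the comparison is strict, so a length of
  exactly 10 survives.
* **Meshes (ETFA).** Meshes are the connected components of the
  complement of the *final* vectorial geometry — edge polylines plus
  junction blobs and fusion bridges — that do not touch the image border
  and are at least one cell in area.  Working from the cleaned model
  rather than the raw thinned mask keeps the mesh count equal to the
  graph's cyclomatic number (E − V + C) after pruning and artifact-loop
  removal, and measuring on one-pixel walls makes the areas independent
  of how thick the segmented ribbon was.

### Measurements

Per image (ETFA): MMS (mean mesh area), TMA (summed mesh area), TSL
(summed segment length), JN (junction count) and TL (branches +
segments; isolated elements are excluded).  Per bead (FBA): the same
length/count measures restricted to the objects whose connected group
anchors on that bead (a group touching two beads is assigned to the
nearest center and flagged), plus AJN, the anchorage-junction count.  All
values are in pixels; an optional pixels-per-micron calibration is
applied only at output time, so TL = TSL + Σ branch lengths holds exactly
and per-bead sums partition the image totals.

## Parameters

| parameter | default | meaning |
|-----------|---------|---------|
| `sigma` | per image | nominal bead diameter / illumination scale (px); the one resolution-dependent parameter a user must set |
| `edge_radius` | 4 | apparent rim thickness (px); also the circle enlargement |
| `fft_v1`, `fft_v2` | 1.5, σ | band-pass bounds (px) |
| `tree_variance_radius` | 2 | variance radius for capillary enhancement |
| `node_dot_diameter` | 7 | disk stamped on node pixels |
| `junction_fusion_distance` | 20 | two-cell scale: fusion, hair removal, rim-debris extent |
| `min_object_size` | 10 | one-cell scale: isolated-element filter, sub-cell holes/meshes (as area 10²) |
| `prune_min_branch` | 10 | unconditional branch-pruning threshold |

## The synthetic scenes

The generator renders what the detector needs to be tested against, with
exact ground truth: dark bead disks with a bright rim (the truth radius
is the rim midline, since the fitted circle is enlarged to include the
envelope), radial sprouting trees with 4–5 trunks per bead and wide
(76–100°) bifurcations, jittered polygonal tilings with dangling spurs
and loose fragments for the network assay, difference-of-Gaussians ridge
profiles for the phase-contrast halo, multiplicative meniscus-style
shading, signal-proportional speckle (the high-count limit of shot
noise, so flat-field correction leaves a uniform noise floor), and faint
gel debris kept clear of the true structures.  Fields are framed the way
the assays are imaged: fewer beads means a closer view (one bead of
r ≈ 100 px fills a 704-px field; 3–4 beads of r ≈ 60 px sit on a 960-px
field), and network canvases grow with the tiling so cells keep a
realistic 90–170 px size.  These sizes are scaled-down but proportionate
versions of full-resolution assay images (where σ is typically 400 px).

What passing these scenes does **not** show: robustness to cellular
texture inside the tubes, to out-of-focus structures overlapping the
network, to bead clusters whose interiors merge, or to assay geometries
(very acute bifurcations, tortuous tubes) the generator does not draw.
A featureless field is outside the method's domain entirely: the Mean
threshold assumes structures are present, and on pure noise it
over-segments; the bead pipeline degrades gracefully there (no circles,
no records), but network measurements of empty wells are meaningless.

## Numerical conventions

Coordinates are 0-based (row, col); thresholded pixels are strictly above
the threshold; histogram methods use 256 bins over [min, max]; the
inter-mode valley of the Minimum threshold takes the middle bin of a flat
valley; division and log floors are 10⁻⁶ of the image maximum; the
variance filter uses a discrete circular neighborhood with edge
replication; thinning is topology-preserving with a deterministic
cleanup pass that removes redundant pixels of 2×2 blocks; all cleanup
passes process candidates shortest-first with id tie-breaks, so results
are deterministic and re-running any fixed-point operator changes
nothing.
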