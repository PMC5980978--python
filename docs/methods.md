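# Methods

## Problem and model

A capsule containing two co-encapsulated cell types — an islet-like
aggregate and PKH67-labelled MSCs — is imaged as a confocal z-stack with
three fluorescence channels: live nuclei (Hoechst), dead nuclei (PI), and
MSC cytosol (PKH67). The quantity of interest is, per cell type,

    viability = N_live / (N_live + N_dead)

where a nucleus belongs to the MSC type iff it colocalizes with the
cytosol dye, and to the islet type otherwise. The analysis is 2D per
optical section with a single 3D correction: a nucleus detected at the
same location on the immediately following section is treated as the same
physical nucleus (the *next-slide rule*). No true voxel-level 3D
segmentation is attempted; this keeps the method transparent and cheap
and matches how such stacks are counted manually, slice by slice.

## Pipeline stages and their assumptions

1. **Binarization.** Foreground iff `tmin <= I <= tmax` (closed interval).
   The window is a user dial, not an automatic threshold: stain
   concentration and detector gain vary between preparations, and a fixed,
   logged window makes runs reproducible and auditable. An Otsu-based
   helper (`otsu_window`) exists but is never applied implicitly. Default
   window 50–255 on the 8-bit scale.
2. **Debris filter.** 8-connected components with area `< min_area` px²
   are removed (default 20 px², i.e. anything smaller than a ~2.5 px
   radius disk). Applied to all three channels; per-channel overrides are
   available (`min_area_overrides`), since cytosol debris and nuclear
   debris need not be the same size.
3. **MSC ROIs.** The filtered green mask is dilated by a disk of radius
   `roi_dilation` px (default 3) and labelled. The dilation absorbs the
   fact that a nucleus sits inside a cell whose membrane dye traces the
   cytosol outline rather than the nuclear area; a "dilatation factor" is
   interpreted as a radius in pixels because the regions have arbitrary
   shapes, making a multiplicative scale ill-defined. Dilating the mask
   before labelling means ROIs whose dilations touch merge — intentional,
   as they represent contiguous MSC territory. ROIs are strictly 2D; the
   cytosol channel is re-segmented on every slice.
4. **Nucleus detection and splitting.** Touching nuclei are split by a
   watershed on the negated Euclidean distance transform. Seeds are the
   *regional maxima of the h-maxima reconstruction* of the distance map
   (depth `h`, default 2 px): two candidate peaks separated by a dip
   shallower than `h` remain one connected seed region and are not split.
   (The residue mask that `skimage.morphology.h_maxima` returns does not
   have this property — it can emit two disconnected dots for one logical
   maximum — which in testing split slightly elongated nuclei; hence the
   reconstruction-based seeding.) A component whose distance relief never
   reaches `h` still gets one fallback seed at its distance peak, so
   shallow objects are counted, never dropped. Watershed fragments below
   `min_area` are discarded.
5. **Seed pixel.** Each nucleus is represented by the component pixel
   nearest its exact centroid, ties broken by lowest (row, column). This
   subsumes "round the centroid, snap to the component if it falls on
   background" while being deterministic under floating-point ties — which
   matters because the seed drives both ROI membership and erasure.
6. **Compartment and erasure.** MSC iff the seed lies on a labelled ROI
   pixel of the same slice. MSC-assigned nuclei are then removed from the
   islet working mask by flood-fill deletion of the full 8-connected
   component under the seed (the MagicWand analog), in both nuclear
   channels, so the saved islet masks contain islet signal only.
7. **Dedup.** A record on slice z is a duplicate iff a record of the same
   vital state on slice z−1 matches it: footprint intersection (`overlap`
   mode, default — robust to ±1 px jitter) or seed distance ≤
   `dedup_tolerance` px (`centroid` mode, default 5). Matching is against
   *any* record on z−1, marked or not, so a chain over k consecutive
   slices collapses to its first occurrence; a reappearance after a
   one-slice gap is counted again, a documented consequence of the strict
   next-slide rule. Records are marked, never deleted, making the
   operation idempotent. The same rule is applied uniformly to islet and
   MSC nuclei.
8. **Double staining.** The two nuclear channels are processed
   independently; a nucleus visible in both (a dying cell taking up both
   dyes) is counted in both. No exclusivity rule is applied because the
   biological ground truth of such cells is genuinely ambiguous; the
   four-class partition invariant holds per channel.

## Statistics

Viability is a fraction in [0, 1] internally and a percentage on output.
A zero denominator yields an explicit "undefined" flag, never a silent 0
or 1. Method comparison reports mean ± SD per method (SD with n−1),
mean absolute difference in percentage points, and the Pearson
product-moment correlation with a two-sided p-value from the t transform
on n−2 degrees of freedom; a zero-variance input flags r as undefined.
When several stacks are measured, viability is computed per stack and
then averaged (not pooled across stacks), so each capsule contributes
equally regardless of its cell count.

## Synthetic scenes

The generator emulates the relevant structure of the real images, not
their optics. Defaults: 512 × 512 field, 15 sections, 80 islet + 20 MSC
nuclei (ellipses with radii 4–7 px), 10 cytosol blobs of radius 18–32 px
(blob size treated as a biological constant; the CLI scales *counts*, not
radii, with field area), nucleus intensity 200 and blob intensity 120 on
an 8-bit scale, additive Gaussian noise of sd 8, and 20 debris specks of
≤ 10 px each. A nucleus spans 1–3 consecutive sections with ≤ 1 px
lateral jitter per section, exercising the dedup rule in both directions.
Placement is rejection sampling under hard separation constraints: MSC
centers sit ≥ 3 px inside a blob, islet nuclei clear every blob by more
than the default ROI dilation, distinct nuclei never touch, and debris
stays clear of nuclei and of other debris so specks can never merge into
a supra-`min_area` component. An overcrowded spec raises a generation
error rather than silently degrading.

What this does and does not show: with the default noise level the
binarized masks are essentially noise-free (background N(0, 8) never
reaches the threshold window, nucleus pixels never leave it), so exact or
near-exact count recovery on these scenes validates the *logic* of the
pipeline — splitting, classification, erasure, dedup, accounting — not
its robustness to low signal-to-noise, uneven illumination, optical blur,
or densely fused nuclei, which real capsule images can exhibit. An
optional Gaussian blur (`blur_sigma`) and a 16-bit mode exist for harder
scenarios but are off by default.

## Problem sizes

The shipped acceptance computation uses 20 stacks of 512 × 512 × 15 with
~100 nuclei each (≈ 1 minute on one CPU); the test suite uses 256 × 256
scenes for recovery properties and 64 × 64 × 5 stacks for brute-force
equivalence, sizes at which the deliberately naive reference
implementation (per-pixel loops, BFS labelling, exhaustive pairwise
dedup) is still fast.

## Numerical and degenerate-input choices

* Contrast stretch: linear percentile stretch saturating 0.35% per tail
  (the classic "enhance contrast" default of 0.7% split across tails),
  monotone, dtype-preserving; constant images are returned unchanged.
* `min_area = 0` or 1 is the identity filter; an empty mask yields an
  empty record list; a blank green channel yields zero ROIs.
* Erasure of a seed that lands on background (possible after watershed
  boundary erosion) warns and skips rather than failing the run.
* All component labelling is 8-connected throughout, so masks, ROIs,
  erasure and the watershed agree on what "one object" means.
* Slice numbers are 1-based in filenames, 0-based in memory; pixel size
  and z-step are carried as metadata only (defaults 10 µm z-step) — every
  computation is in pixel units.

## Known limitations

* The dead-MSC output folder is named `Necrotic_MSC_Nucleus`, parallel to
  the islet layout.
* The next-slide rule re-counts a nucleus that skips a section (e.g. a
  segmentation dropout on one slice); `overlap` dedup cannot bridge gaps
  by design.
* Compartment assignment uses a single seed pixel; a nucleus straddling a
  ROI boundary is assigned wholly to one side.
* No PSF simulation, no illumination-field correction, no
  machine-learned segmentation — out of scope by design.
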