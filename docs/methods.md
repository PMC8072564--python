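# Methods

`neuritrace` quantifies neurite outgrowth in two-channel fluorescence
micrographs of neuronal cultures: a nuclear stain (DAPI) provides the cell
count and nucleus morphology, and a cytoskeletal/neuronal stain (e.g.
Alexa488-coupled beta-III-tubulin or TH) provides somata and neurites. The
primary readout is total neurite length per cell; secondary readouts are
branch counts, neurite and soma areas, nucleus areas and counts. This note
documents the model and procedure, the parameters that matter, the synthetic
data the tests run on, and the numerical choices behind reproducibility.

## Image model and calibration

Frames are 16-bit two-page TIFFs. Physical calibration is supplied
explicitly (not read from TIFF metadata, whose dialects vary); the default
is the reference acquisition geometry of 1376 x 1038 px imaging
884.89 x 667.52 um, i.e. 0.64309 um per pixel edge. Pixels are isotropic
(enforced to 1e-3 relative); coordinates are 0-based, row-major, with pixel
centres at integer positions. All unit conversions are exact linear maps;
10 px corresponds to 6.43 um at this calibration.

## Preprocessing

Both channels pass the same chain:

1. **Brightness reduction.** If more than `saturation_fraction` (0.5%) of
   pixels sit at or above the `clip_percentile` (99.9th) intensity, the
   image is linearly rescaled so that percentile maps to full scale.
   Overexposed frames are thereby tamed; normal frames pass unchanged.
2. **Phansalkar local thresholding**, `T = m (1 + p e^{-q m} + k (s/R - 1))`
   on intensities normalized to [0, 1], with the canonical coefficients
   p=2, q=10, k=0.25, R=0.5 and a 25 px window (~16 um: a neurite
   cross-section plus background). The exponential term keeps faint neurites
   above threshold where a plain mean-minus-k-sigma rule would drop them.
   Window statistics use edge-repeating reflective padding.
3. **Morphological closing** with a rounded disc of radius 1 px, bridging
   1-2 px binarization gaps along thin neurites. Radius 2 is configurable
   but merges distinct neurites running within 4 px of each other (common
   where they fan out of a soma), which collapses two medial lines into one
   and costs ~10% of total length — hence the default of 1.
4. **Plausibility filter.** 8-connected components with physical area at or
   below 82.71 um^2 are removed. That threshold is exactly 200 px at the
   reference calibration and is stored as the derived value
   `200 * (884.89/1376)^2` so that a 200 px component is removed and a
   201 px component kept; the filter respects the mask's scale factor.

## Nuclei

Clumped nuclei are separated by a marker-controlled watershed: markers are
regional maxima of the Euclidean distance transform, suppressing maxima
shallower than `h_depth` (0.2) of the global maximum or closer than
`min_peak_separation_px` (10 px) — robust for nucleus-scale blobs at this
pixel size. Components whose maxima were all suppressed get one marker at
their distance maximum, so every foreground pixel is assigned and region
areas sum exactly to the foreground area. Labels are renumbered in raster
order, making outputs order-independent. Per-region area, centroid,
bounding box and eccentricity are tabulated; no apoptotic/healthy
classifier is built in — the morphology columns exist so users can apply
their own rule.

## Skeletonization

The neurite mask is upsampled 3x (nearest neighbour) so structures one
source-pixel wide become three pixels wide and representable by interior
medial disks, then smoothed with a Gaussian of sigma 1.5 upscaled px
(re-thresholded at 0.5, area-preserving). Smoothing matters: the medial
axis of a blocky staircase boundary braids into hundreds of spurious
junction/cycle clusters; after smoothing a straight tube yields a single
clean segment.

The skeleton is the medial axis with per-point maximal-disk radii
(Euclidean distance to the shape boundary), pruned under one precision
parameter epsilon (default 10 px in the upscaled mask, configurable per
cell type — the right value scales with neurite width). The pruning
contract:

* A terminal branch supports a boundary protrusion. Its **outward extent**
  is measured per branch point, each along its own direction from the
  anchor junction: how far the point's maximal disk reaches beyond the
  anchor's boundary contacts. (A single tip direction would underestimate
  curved branches.)
* A branch is pruned iff its extent is below `2*epsilon` (minus a 1 px
  grid-quantization allowance) **and** at most twice the anchor's disk
  radius (plus 1 px). The first condition is the precision scale:
  protrusions smaller than two epsilon are uninformative boundary noise and
  create no branch; the second makes "protrusion" relative to the host
  structure, so the continuation of a thin branch beyond a spurious noise
  junction is never treated as a side protrusion of itself.
* Pruned branch points devolve onto their anchor and count in any later
  decision there; without this, a noisy branch could be eaten piecewise
  with unbounded accumulated reconstruction error.
* Free path ends are trimmed by at most a 2 px discretization allowance —
  except strictly tapering tails (radii shrinking towards the tip, the
  corner artifact of e.g. a rotated rectangle), which may be trimmed up to
  sigma < epsilon, since their disks remain covered by the remainder to
  within the precision scale.
* Degenerate plateau cycles (the 4-pixel diamond an even-diameter disk
  leaves) collapse to their largest-disk point.

Consequences, all covered by tests: a disk collapses to (near) a single
point; a 200 x 40 rectangle reduces to its 160 px central segment; a square
protrusion on a bar first generates a branch at outward extent exactly
2 epsilon; total length is monotone non-increasing in epsilon; and the
union of the retained maximal disks reconstructs the shape to within
epsilon (Hausdorff) for shapes whose boundary features are either at the
noise scale (pruned, residual well below epsilon) or genuine structure
beyond 2 epsilon (kept, residual zero). Features in the ambiguous band
between epsilon and 2 epsilon are absorbed by the 2-epsilon rule with
residual up to 2 epsilon — the price of the protrusion rule, worth stating:
for such features the epsilon certificate does not hold, by design.

Branch statistics come from node degrees (endpoints degree 1, branch points
degree >= 3, segments = maximal chains between nodes of degree != 2; a pure
cycle is one closed segment). Segment polylines are simplified
(Ramer-Douglas-Peucker, 1.5 px) before length summation so that length does
not inherit the ~8% overestimate of raw 8-connected pixel chains; a bar
rotated by 30 degrees then measures within 5% of the axis-aligned result.

**Tip correction.** The medial axis of a tube geometrically stops one
half-width short of its rounded end cap. The *neurite length readout* adds
the tip-disk radius at every free segment end, matching how a manual
tracing measures to the visible tip; the *geometric skeleton length* (used
by the shape contracts above) does not.

## Channel combination

A nucleus overlapping the neurite-channel mask marks a neuron (for mixed
cultures this is the automated analogue of a TH+ cell). Neurite-mask
components containing no neuron nucleus are staining artifacts or debris
and are removed. Somata are recovered by thresholding the distance
transform at `soma_radius_px` (8 px ~ 5.1 um, the half-width separating
somata from neurites at this pixel scale) and dilating the cores back by
the same radius within the mask (a geodesic opening), keeping only bodies
that contain a nucleus. Skeleton vertices inside the soma are deleted —
branches are clipped at the soma boundary rather than discarded whole, so
legitimate neurites passing near a soma keep their outside-soma length.
Neurite area is the mask area minus the soma area.

## Quantification and statistics

Per-frame metrics are normalized to a per-cell basis using either the
nuclei count (pure neuronal cultures) or the neuron count (mixed cultures),
then to the mean of the same experiment's solvent-control (DMSO) frames,
expressed as percent of control. Frames with a zero denominator are flagged
excluded, never raise, and never contribute to control means.

Dose-response curves are summarized by the variable-slope sigmoid
`y = bottom + (top - bottom) / (1 + 10^((log10 LD50 - log10 c) * h))` with
the top fixed at the solvent-control level (100%), bottom (>= 0) and hill
slope free; a falling lesion curve appears as a negative slope in this
parameterization. Controls (c = 0) are excluded from the fit — log 0 is
undefined — and enter only through the top constraint. The least-squares
fit is multi-started over log-spaced LD50 seeds and both slope signs; the
convergence flag is honest (constant responses do not converge). Method
comparison between automated and manual readouts uses closed-form OLS of
automated (y) on manual (x) with R^2. ANOVA-style group testing is
deliberately not implemented; the output tables are designed for export.

## Synthetic data

The generator emulates the features that matter to each stage: bright
elliptical nuclei (optionally in touching pairs — the hard case for
watershed), somata with arborized curvilinear neurites of exactly known
polyline length and branch count, staining artifacts on both sides of the
plausibility threshold, Gaussian intensity noise. Neurite polylines are
generated in micrometres and rasterized at the calibration's pixel size,
so ground-truth lengths are resolution-independent and exact by
construction. Non-neuron nuclei are kept clear of the neurite stain, as a
stain-free cell's nucleus would be in a real culture.

Default study conditions (chosen once): 512 x 384 px frames at the
reference pixel size, 5 neurons plus 5 other nuclei, soma radii 10-15 px,
nuclei radii 8-12 px, 2-4 neurites per neuron of 60-160 um, tubes 3 px
wide, background 1500 / neurite 20000 / nuclei 30000 on the 16-bit scale,
noise sigma 800. Dose-response plates follow a 100-5000 nM design with six
frames per condition; per-condition expected length follows a decreasing
four-parameter-logistic lesion model with 5% per-frame jitter.

What the generator does **not** emulate: point-spread blur, uneven
illumination, out-of-focus debris, neurite intensity variation along the
shaft, photobleaching. Passing tests therefore demonstrate the geometric
and statistical machinery, not robustness to real-world optics; on real
data the preprocessing parameters (window, closing, plausibility area) are
the knobs to revisit.

Measured recoveries on these conditions: nuclei counts exact without
clumping and within +-1 per frame at 30% clumping; neuron counts exact;
total neurite length per frame within 10% of ground truth for
well-separated neurites (within 15-20% when crossings are frequent, which
merge skeleton junctions); artifacts below 82.71 um^2 never survive the
filter; LD50 recovered within a few percent end to end at plate scale.
Branch-point counts exceed the generated branching events when neurites
cross (each crossing adds junctions), which is inherent to any
skeleton-based count.

## Determinism and batch behaviour

Every stage is deterministic: the medial-axis thinning's random
tie-breaking is pinned, watershed markers and labels are ordered, and batch
outputs are merged sorted by frame id — so results are byte-identical for
any worker count and any manifest ordering. A failing frame is logged,
flagged excluded, and does not abort the batch; metric rows are flushed to
disk as frames complete.

## Known limitations

* Per-cell attribution is global (totals divided by counts); individual
  neurite-to-neuron assignment is out of scope.
* The epsilon/2-epsilon band: boundary features between epsilon and
  2 epsilon in extent are pruned with reconstruction residual up to
  2 epsilon (see above).
* Overlapping neurites merge in the mask; lengths stay approximately
  additive but branch counts inflate at crossings.
* The soma detector assumes somata are at least twice `soma_radius_px`
  wide; very small or very elongated cell bodies need the radius adjusted.
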