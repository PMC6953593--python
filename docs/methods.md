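# Methods

`histocyto` reimplements a histocytometric analysis of multi-channel
immunofluorescence sections of regenerating bone: nuclei and myeloid-marker
objects are segmented per channel, grouped into cells by pixel
co-localization and gated on nuclear (DAPI) overlap, quantified inside
polygonal regions of interest, banded by distance to the Endomucin-positive
endothelium, and scored for proximal/distal spatial polarization around the
osteotomy gap. Because the microscopy data the procedure was designed for
are not publicly deposited, the package ships a synthetic scene generator
with exhaustive ground truth; every stage is validated by recovery of
planted structure rather than by re-measuring real sections.

## Physical scale

Nothing in the package assumes an acquisition pixel size. All physical
thresholds (object diameter gates, proximity cut points, scoring extents)
are given in micrometres and converted through the `pixel_size_um` metadata
of the image container. The synthetic scenes default to 0.5 um/px.

## Synthetic scenes

A scene is a set of 2-D channels (DAPI, CX3CR1, F4/80, Gr-1, Emcn, CD31)
on a shared grid, emulating a confocal tile of a longitudinal femur section:
a central osteotomy-gap band, proximal and distal gap-adjacent bands, and a
homeostatic-control band of unaffected marrow far from the injury.

* **Nuclei.** Non-overlapping discs placed by dart throwing with a
  maximum-attempts bound (`PackingError` on infeasible configurations,
  never silent truncation). Diameters are sampled from the central 80% of
  the configured envelope (default envelope 3.1–12.5 um): the envelope is
  the analyst's permissive size gate, not the biological size distribution,
  and sampling exactly at the gate edges would turn size filtering of
  correctly segmented nuclei into a coin flip.
* **Profiles.** Cells are rendered with a super-Gaussian radial profile
  `exp(-ln2 * rho^8)`: smooth edges, but the half-maximum footprint sits at
  the nominal radius, so measured equivalent diameters track planted
  diameters within a few percent. (A plain Gaussian's half-maximum
  footprint is ~0.6x the nominal diameter, which would decouple planted
  from measured sizes.)
* **Phenotypes.** Each cell draws a marker set from the configured
  frequency map (remainder = marker-negative). Marker (cytoplasmic)
  footprints are 1.3x the nuclear footprint; non-round cells are rendered
  as 4:1 stretched ellipses of equal area, giving the roundness classifier
  an unambiguous target. Default composition: 40% CX3CR1+F4/80+, 15%
  F4/80+, 10% CX3CR1+, 15% Gr-1+, 20% negative; 60% round.
* **Vessels.** Short random-walk skeleton fragments (20–80 um) dilated to
  5–15 um tubes, as expected for a 7 um section through a 3-D sinusoidal
  network. Default skeleton density 0.02 um/um^2 (~50 um sinusoid spacing),
  so every analysis band contains scoreable vessel signal, as in marrow
  tissue. A configurable fraction of tubes is rendered Emcn-hi at >= 3x the
  Emcn-lo intensity (and CD31-hi, the type-H phenotype), making hi/lo
  region annotation well defined.
* **Polarization.** `generate_polarized_pair(config, side)` scales the
  placement density of cells and vessel fragments in the favoured
  gap-adjacent band by `sqrt(ratio)` and the opposite band by
  `1/sqrt(ratio)`; the control band stays at the geometric-mean density and
  `ratio = 1` reduces exactly to the uniform scene. Density mass is
  allocated to bands *before* positions are drawn, so packing collisions
  cannot compress the configured ratio, and each vessel fragment is
  confined to the band it was allocated to. Marker and vessel brightness
  co-varies as the square root of the density weight, emulating the
  brighter staining observed in polarized regions; DAPI brightness is not
  modulated (nuclear staining does not brighten — cell density alone
  carries the DAPI asymmetry).
* **Corruptions.** A linear background ramp across the section and
  additive Gaussian noise (clipped at zero). Defaults: amplitude 200,
  gradient 20, noise SD 5.

What the generator does **not** emulate: point-spread blur, chromatic
shift, autofluorescence texture, spectral bleed-through, cell shape
irregularity beyond stretched ellipses, 3-D structure, or staining
batch effects. Passing recovery tests therefore demonstrate correctness of
the measurement logic under controlled conditions, not robustness to every
artefact of real microscopy.

## Segmentation

Primary objects are found per channel by Otsu thresholding. In three-class
mode the two-threshold (multi-)Otsu is computed and only the top class is
foreground — mid-level pixels count as background; a channel whose
histogram cannot support three classes falls back to two-class Otsu, and a
constant channel yields zero objects rather than an error. Thresholds are
computed on a lightly smoothed image (default sigma 0.5 um) so single-pixel
noise speckle cannot seed objects.

**Adaptive mode** is a spatially varying Otsu: a smooth background field is
estimated as the 10th percentile of overlapping square windows (default
50 um) interpolated to the full grid, and the Otsu threshold of the
background-flattened image is re-offset by that field. With a flat
background this reduces exactly to the global threshold (a window-wise
Otsu would not — its local thresholds differ wherever window content
differs, which breaks the equivalence on gradient-free images); with
ramped illumination the cut follows the local background level.

**Declumping** seeds a watershed on the inverted (smoothed) intensity with
local maxima at a minimum separation equal to the minimum object diameter;
components without a detected maximum are kept whole, and equal-intensity
saddles resolve deterministically towards the lower seed id. Declumping
re-partitions the foreground but never changes its union.

Border-touching objects (any pixel on the outermost ring) are removed when
configured, then an equivalent-diameter gate (diameter of the circle of
equal pixel area; 8-connectivity throughout) is applied and labels are
relabelled contiguously.

**Secondary objects** (used for the densely packed Gr-1 channel) grow one
object per nucleus seed into the channel's above-threshold territory by
intensity-guided watershed propagation, preserving seed ids; on a zero
channel the seeds are returned unchanged. Because a secondary object exists
for every seed, marker positivity is decided afterwards from intensity:
the pipeline keeps a Gr-1 object only when at least half of its *seed*
pixels clear the channel threshold. (Judging positivity over the grown
territory would be biased — that territory was selected by positivity.)

## Phenotyping

Marker objects from CX3CR1, F4/80 and Gr-1 are nodes of an overlap graph
with edges wherever two objects share at least one pixel; connected
components are cells. A component is kept only if it overlaps a nucleus
(at least 1 px, and at least `min_overlap_frac` of the cell's area —
default any overlap); its nucleus is the one with maximal overlap, ties
towards the lower label id. Optionally (and by default), nuclei that
neither anchor nor touch any marker group are reported as marker-negative
cells, so phenotype frequencies can be expressed over all nucleated cells.

Shape features are computed in physical units: area, perimeter (weighted
chain-code estimator, the CellProfiler convention — asymptotically
unbiased for smooth shapes, and the convention under which a digital disc's
form factor is ~1; a crack-length perimeter would give ~0.62), form factor
`4*pi*A/P^2`, minimum Feret diameter by rotating calipers on the convex
hull of the pixel corners (a 1-px bar measures exactly 1 px wide), maximum
Feret diameter, and maximum inscribed radius (EDT maximum). A single-pixel
object falls back to a 4-edge perimeter so the form factor is defined.

Roundness is a deterministic split: round iff form factor >= 0.6 **and**
minimum Feret >= 5 um. The features are the published ones; the cutoffs are
this package's defaults, validated against synthetic ground truth (>= 90%
agreement with planted flags at the default conditions) and exposed in
configuration — they are not asserted to be the original study's values.

## ROI quantification and proximity

ROIs are simple polygons in pixel coordinates, boundary-inclusive for
point-in-polygon counting and rasterised with a single convention for all
area measures. The fracture-gap ROI can be constructed from section
landmarks (cortical end points, osteotomy cut lines, lens-void outline) as
the landmark hull minus the void; collinear landmarks and interior voids
are rejected.

* Object counts: a cell is in an ROI iff its centroid is inside (boundary
  counted).
* Normalized mean intensity: ROI mean divided by the whole-image maximum
  (an all-zero image reports 0 with a warning). Invariant under positive
  rescaling.
* Positive-pixel area fraction: fraction of ROI pixels above a fixed
  threshold or the segmentation threshold strategy.
* Proximity bands: cell distance = minimum over its pixels of the exact
  Euclidean distance transform of the reference mask (default: union of
  Emcn primary objects), in um. Bands: direct <= 3.5 um, distant > 7 um,
  intermediate otherwise. The intermediate band is never singled out in the
  original analysis but is retained so the three bands always partition the
  population. Both cut points are inclusive/exclusive as written (<= and >)
  with strictness configurable; the difference is sub-pixel at 0.5 um/px.
  The implementation is tested for exact equality against a brute-force
  all-pairs pixel-distance oracle.

Emcn-hi/lo analysis regions are inputs (hand-annotated in the original
procedure); an optional helper derives them by three-class thresholding of
smoothed Emcn intensity and flags them `provenance="derived"`.

## Polarization scoring

Each sample is scored per channel (DAPI, F4/80, vessel/CD31) and side
(proximal, distal) on the ordinal scale -2..2 against a homeostatic-control
region. Classification uses only F4/80 and vessel:
`D = (distal F4/80 + distal vessel) - (proximal F4/80 + proximal vessel)`;
`D > 2` is polarized distal, `D < -2` polarized proximal, otherwise
neutral, and a card whose four rule scores are all zero is reported
separately as `all_zero`. Two deliberate decisions:

* `D = 2` exactly is neutral. The published rule (" > 2 polarized, < 2
  neutral") leaves the boundary unaddressed; the conservative choice avoids
  inflating polarization calls.
* The rule combines the two markers by their side sums. An alternative
  reading — each marker individually favouring the same side — is exposed
  as `mode="per_marker"`.

DAPI scores are recorded as an internal control and never enter the rule.

The **automated scorer** is a surrogate for the manual procedure, built for
synthetic validation only. It measures stained-signal density — summed
supra-threshold intensity per unit region area, which scales with both
staining brightness and abundance while excluding sub-threshold background
(so a shading gradient cannot masquerade as differential staining) — and
maps the side/control ratio `r` onto the scale: `r <= 0.1` -> -2 (absence
of staining), `r < 2/3` -> -1, `2/3 <= r <= 1.5` -> 0, and above that +2
when the positive signal runs along (>= 90% of) the contour between gap
and adjacent tissue at cell-scale (20 um) bins or extends beyond 400 um,
else +1. If the control region has no supra-threshold pixels at all, the
ratio falls back to background-subtracted means; a control with no signal
whatsoever is an error (nothing to normalize by). The scorer is
deterministic and invariant to global positive rescaling. It is validated
only against planted ground truth and makes no claim to replicate the
original manual scoring of real sections.

## Pipeline

`run_pipeline` composes the stages (load/generate -> segment -> phenotype
-> spatial quantification -> polarization), writes one CSV per stage plus
a JSON manifest (config, config hash, seed, package versions, per-stage
object counts), and is byte-identical under a fixed seed and config. Any
stage failure aborts with the stage named. The QC overlay (object outlines,
phenotype colours, ROI polygons) is pure reporting and feeds nothing back
into quantification. The `histocyto` CLI exposes
`simulate | segment | phenotype | quantify | polarize | run`.

## Validation problem sizes

The shipped validation uses: 20 scenes of 64–128 px for the exact
proximity-oracle comparison; all 625 score combinations for the decision
rule; 10 scenes of 1000 cells at 1280^2 px for phenotype-frequency
recovery; 3 noiseless and 3 SNR-5 scenes of 300 cells at 1024^2 px for
segmentation recovery; 10 + 10 polarized-pair scenes (density ratio 4 and
1) for end-to-end polarization detection. These sizes give the binomial
checks their stated power while keeping a full validation run in the
low minutes on one CPU.

## Known limitations

* The synthetic validation bounds correctness of the measurement logic,
  not performance on real sections (see the generator's non-goals above).
* The automated polarization scorer's per-side scores have sampling noise
  of roughly one ordinal step near the 2/3 and 1.5 ratio cutoffs at the
  default scene density; classifications are much more stable than
  individual scores because the rule differences four of them.
* Secondary-object positivity uses the seed footprint; a marker expressed
  only in a thin cytoplasmic rim with an unstained nucleus region would be
  under-called.
* ROIs must be simple polygons; regions with holes are not representable.
* The published per-sample scorecards were released only as supplementary
  material not redistributed here, so the printed classification tally of
  the original 20 samples cannot be recomputed from data by this package;
  the decision rule itself is validated exhaustively instead.
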