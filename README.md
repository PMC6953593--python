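# histocyto

Histocytometric quantification of multi-channel immunofluorescence images
of regenerating bone.

During fracture healing, myeloid cells (F4/80⁺, CX3CR1⁺, Gr-1⁺ subsets)
and newly formed vessels (CD31⁺/Emcn⁺, including the osteogenesis-coupled
CD31ʰⁱEmcnʰⁱ "type H" endothelium) reorganise around the osteotomy gap.
Quantifying that reorganisation from stained sections takes a chain of
image-analysis steps that are easy to get subtly wrong: adaptive
three-class Otsu segmentation with declumping, secondary-object
identification for densely packed channels, marker co-localization gated on
nuclear overlap, shape-based round/non-round partitioning, ROI
quantification, distance banding around the endothelium, and an ordinal
proximal-vs-distal polarization score. `histocyto` implements this chain as
a tested, reusable library for cell biologists and image analysts, together
with a synthetic scene generator that plants known cells, vessels and
asymmetries so every stage can be validated against ground truth.

## The measurements

* **Segmentation** — per-channel primary objects via (two- or
  three-class) Otsu with a spatially varying background correction;
  mid-level pixels go to background; clumps split at intensity saddles
  between local maxima; border-touching objects removed; objects gated by
  equivalent diameter (nuclei default 3.1–12.5 μm). Densely packed Gr-1 is
  segmented as secondary objects grown from nuclei and refined by
  intensity.
* **Phenotyping** — cells are connected components of the marker-object
  overlap graph, kept only when they overlap a DAPI nucleus; a cell is M⁺
  iff an M-channel object is in its group. Shape features (area, perimeter,
  form factor 4πA/P², min/max Feret diameter) feed a round/non-round split
  (round ⇔ form factor ≥ 0.6 ∧ min Feret ≥ 5 μm).
* **Spatial quantification** — per-ROI object counts (boundary-inclusive
  point-in-polygon), mean intensity normalized to the image maximum,
  positive-pixel area fractions, and proximity bands around the Emcn⁺
  endothelium: direct ≤ 3.5 μm (about half a nucleus), distant > 7 μm
  (beyond one cell layer), via the exact Euclidean distance transform.
* **Polarization** — ordinal scores s ∈ {−2…2} per channel and side
  against a homeostatic control; with
  D = (s_distal^F4/80 + s_distal^vessel) − (s_proximal^F4/80 + s_proximal^vessel),
  D > 2 ⇒ polarized distal, D < −2 ⇒ polarized proximal, else neutral
  (all-zero cards reported separately). An automated surrogate scorer maps
  control-normalized stained-signal density onto the scale for synthetic
  validation.

## Worked example

```python
from histocyto import PipelineConfig, SceneConfig, run_pipeline

config = PipelineConfig(
    scene=SceneConfig(n_nuclei=150, image_size_px=(512, 512)),
    seed=7,
    out_dir="results/demo",
)
bundle = run_pipeline(config)
print(len(bundle.cells), "cells")
print(bundle.proximity.head(4).to_string(index=False))
```

prints

```
144 cells
                roi    phenotype  n_total  n_direct  n_intermediate  n_distant  frac_direct  frac_intermediate  frac_distant
homeostatic_control          all       21         6               1         14     0.285714           0.047619      0.666667
homeostatic_control CX3CR1+F4/80       10         4               1          5     0.400000           0.100000      0.500000
homeostatic_control       CX3CR1        4         0               0          4     0.000000           0.000000      1.000000
homeostatic_control        F4/80        1         0               0          1     0.000000           0.000000      1.000000
```

144 of the 150 planted cells survive segmentation and the DAPI gate at the
default noise level; each row gives, for one ROI and phenotype, how many
cells lie within 3.5 μm of the endothelium (direct), beyond 7 μm (distant)
or between (intermediate), with fractions normalized to that population.
The run directory contains `cells.csv` (one row per cell with phenotype
flags, shape features, intensities and ROI membership), `proximity.csv`,
`roi_quant.csv` (normalized mean intensity, positive-pixel fraction and
counts per ROI), `polarization.csv` (scorecard plus classification) and
`manifest.json` (config hash, seed, versions) — re-running the manifest
reproduces all tables byte-identically.

The same pipeline runs from files: a multi-page TIFF (channel names in
metadata) plus a GeoJSON of ROI polygons via `PipelineConfig(image_path=...,
roi_path=...)`, or the `histocyto` command line
(`histocyto simulate | segment | phenotype | quantify | polarize | run`).

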