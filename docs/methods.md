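# Methods

## Assay model

`mifquant` treats a multiplexed immunofluorescence field as a registered
stack of 2-D intensity rasters addressed by biological role: nuclear stain
(DAPI), plasma-membrane marker (Na⁺/K⁺-ATPase), total MET, and pY1235-MET,
with an optional isotype-control role.  All readouts are *binary-area
fractions*: a pixel is marker-positive when its intensity strictly exceeds
a calibrated cutoff, and endpoints are areas or area ratios of positive
pixels inside compartment masks.  No intensity-weighted (H-score-like)
metrics are computed; the assay's contract is that positivity is a
thresholded, isotype-anchored call.

Areas are physical: `pixel_count × pixel_size_um²`.  Pixel size is a
required configuration input with no default, because acquisition
calibration varies by scanner and magnification and silently assuming one
would corrupt every μm² endpoint.

## Segmentation

* **Nuclei** — threshold the nuclear-stain channel (Otsu by default, fixed
  override available), fill holes, drop components smaller than
  `min_nucleus_area_um2` (default 10 μm², debris rejection), optionally
  split touching nuclei by distance-transform watershed (off by default:
  the non-overlapping default geometry does not need declumping and the
  simple path is exactly reproducible).  Components are counted under
  8-neighbour connectivity by default; 4-neighbour is available and is
  exercised by the connectivity oracle tests.  A constant-intensity channel
  under Otsu raises a "degenerate image" error rather than guessing.
* **Membrane** — thresholded membrane-marker channel (Otsu / fixed /
  control-derived).  No morphological post-processing by default: %MAP is a
  ratio within the mask, so mask morphology largely cancels; smoothing is
  therefore a tunable, not a default.
* **Tissue** — the tumour-cell denominator region: nuclear mask dilated by
  `tissue_dilation_um` (default 5 μm, approximating the cytoplasmic
  extent of the default 6–9 μm cells around their nuclei) united with the
  membrane mask.  The tissue mask is always a superset of the nuclear mask.
  This denominator is marker-agnostic; it does not attempt stromal/tumour
  classification, which real specimens may need upstream.

## Thresholding conventions

Cutoffs derive once from control pixels (isotype-stained section or a
biologically negative line) and are applied uniformly — no per-field
adaptation.  Conventions are chosen to be oracle-checkable:

* `mean_plus_k_sd`, default k = 3: population (1/N) SD; 3σ is the
  conventional Gaussian background-exclusion rule and at pixel-sample sizes
  the 1/N-vs-1/(N−1) difference is negligible, but the estimator is stated
  so hand computations agree exactly.
* `percentile`: nearest-rank (1-based index `ceil(p/100·N)` of the sorted
  sample), exactly reproducible by sorting.
* Positivity is strict `>`: a zero-noise control thresholded at its own
  mean is exactly 0% positive.

Derived thresholds serialise to YAML so a calibration can be frozen and
reused across staining batches; whether one threshold should serve per
batch or per experiment is left to the configuration.

## Endpoint metrics

Per field/ROI: marker area per cell (`|positive ∩ tissue|·s²/n` with n the
field's nucleus count), %MAP, dual %MAP (triple intersection with the
membrane mask), %NAP, and the phospho/total ratio computed from the two
area-per-cell values (nucleus count cancels, so this equals the raw-area
ratio; the area-per-cell definition is named as the contract).  Undefined
denominators (no membrane pixels, no nuclei, zero total MET) produce
missing values with QC notes and are excluded from group statistics —
zero-filling would bias treated-group means downward.  ROIs are rectangular
sub-windows; the nucleus count of an ROI is the number of components
intersecting its window.

Group summaries average per-ROI values (the unit of analysis is the
ROI/core by default, with an option to aggregate to per-specimen means
first, since multiple cores per animal are common in xenograft TMAs).
Evaluability: a specimen whose sections/ROIs sum to fewer than
`min_cells = 3000` nuclei is flagged non-evaluable, the standard
fit-for-purpose biopsy criterion; desk-scale synthetic fixtures relax this
in their generated configs because their fields hold tens of cells.

## Statistics

* **Mann-Whitney** (unpaired, two-sided).  U from mid-rank sums.  When the
  pooled sample is tie-free and `n_a + n_b ≤ 16`, the p-value is exact: the
  smaller tail probability of U over all `C(N, n_a)` rank assignments,
  doubled, capped at 1.  Otherwise a tie-corrected normal approximation
  with 0.5 continuity correction is used; the method is recorded on every
  result.  Identical groups necessarily contain ties, route to the
  approximation, and give z = 0 → p = 1.  The exact and approximate paths
  agree within 0.02 for tie-free n = 8 vs 8.
* **Spearman** — product-moment correlation of mid-ranks; p from the
  t approximation with n − 2 df (p = 0 at |ρ| = 1; constant input leaves ρ
  undefined/missing with a note).
* **Percent change from vehicle** — `100·(sample − vehicle mean)/vehicle
  mean`; the vehicle group transformed by its own mean averages to exactly 0.
* No multiple-testing correction by default (pairwise contrasts are
  reported unadjusted); Holm adjustment is available opt-in.

## Synthetic scenes

The generator emulates fields of disk-shaped cells: annular membrane
(1 μm), interior nucleus (0.55 of the cell radius), cytoplasm between, on
a 256×256 px field at 0.5 μm/px with 20 cells of radius 6–9 μm.
Intensities (16-bit scale): background 100; nuclear stain 3000 in nuclei;
membrane marker 3000 in membranes; marker channels 100 everywhere except
painted positive pixels at 2500.  Positivity is painted onto an *exact*
pixel subset — `floor(fraction × compartment size)` pixels drawn without
replacement — so ground-truth fractions are exact and recovery tests are
sharp.  Additive zero-mean Gaussian noise (default SD 50, ≈2% of the
2400-count contrast, clipped at 0) stresses the thresholds without
modelling full microscope physics; Poisson shot noise, point-spread
blurring, spectral bleed-through and 3-D structure are deliberately out of
scope, so passing recovery tests demonstrate correctness of the
quantitation arithmetic and calibration logic, not robustness to real
optical artefacts.

Geometry, painting, and noise consume three independent child streams of
the scene seed, so an isotype control (all positive fractions forced to 0)
from the same spec shares bit-identical geometry channels with its scene.
Cell placement is rejection sampling of non-overlapping disks (500
attempts per cell before an "unplaceable geometry" error).

Expression-tier presets fix (marker, compartment) fractions: *negligible*
(all 0, a MET-null line), *moderate* (total 0.35 membrane / 0.15
cytoplasm; phospho 0.15 / 0.05), *high* (total 0.70 / 0.40; phospho 0.55 /
0.25, a MET-amplified constitutively active line), and nuclear presets
with phospho nuclear fractions 0.30 vs 0.60 (ligand-driven nuclear
accumulation).  Dose-response series scale every phospho fraction by the
Hill factor `1/(1 + (dose/IC50)^h)` and leave total MET untouched; the
fixture uses doses (0, IC50, 10·IC50), Hill 1, and 4 replicate cores per
group, matching a small-animal-cohort design.  Replicate seeds derive
deterministically from the base seed by a running index.

## Numerical and design choices

* Rasters are row-major, origin top-left, shared by every mask.
* CSV tables write floats with shortest round-trip representation and are
  re-read with round-trip parsing, so write→read is lossless; missing
  values use the token `NA`.  Outputs contain no timestamps and are
  byte-identical across reruns of the same config.
* Channels may arrive as one multi-page TIFF or one file per channel; both
  map onto roles via the channel map.  8- and 16-bit unsigned inputs are
  supported.
* Per-field failures (missing/corrupt file) are logged and skipped; exit
  codes are 0 clean / 2 partial / 1 fatal.  The run log records package
  version, config hash, threshold provenance, and every QC exclusion.

## Problem sizes

Tests and the acceptance script use 128–256 px fields with 4–20 cells,
20-scene recovery sweeps, 100-trial counting-oracle sweeps, and the
3-dose × 4-replicate study — sizes chosen so the whole verification suite
runs in well under a minute while every compartment and endpoint is
exercised.

## Known limitations

* The tissue denominator does not separate tumour from stroma; on real
  sections %-per-cell endpoints therefore include any DAPI⁺ non-tumour
  cells unless an upstream classifier provides the ROI.
* The membrane compartment is quantified in aggregate per field, not
  assigned to individual cells.
* Proprietary scanner containers (SVS/ND2) and channel registration are
  out of scope; inputs are assumed registered TIFFs.
* The vendor software used in the assay this pipeline mirrors does not
  publish its segmentation rules; the defaults here are this package's own
  and are stated above rather than claimed equivalent.
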