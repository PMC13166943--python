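# mifquant

Quantitative multiplex immunofluorescence (IFA) for subcellular MET /
phospho-MET pharmacodynamics.

## The problem

MET-targeted therapies act by shutting down MET kinase signalling, which is
marked by phosphorylation of the activation-loop tyrosine Y1235.  Measuring
that pharmacodynamic effect in tumour tissue — and localising it to the
plasma membrane (canonical signalling) or the nucleus (cleavage-fragment
accumulation) — requires quantitative microscopy on multiplexed stains:
DAPI (nuclei), Na⁺/K⁺-ATPase (plasma membrane), an anti-total-MET antibody,
and an anti-pY1235-MET antibody.  `mifquant` implements that quantitation
as a reusable, fully tested pipeline for anyone analysing four-plex
membrane/nuclear marker panels on FFPE sections, xenograft cores, or cell
pellets.

## Endpoints

For each image field (or rectangular ROI) with compartment masks `M`
(membrane), `N` (nuclei, count `n`), `T` (tissue), and marker-positivity
masks `P_m` (intensity strictly above an isotype-control-derived cutoff):

- **Marker area positive per cell** `= |P_m ∩ T| · s² / n` (μm²/cell,
  pixel size `s` in μm/px)
- **%MAP** `= 100 · |P_m ∩ M| / |M|` — percent membrane area positive
- **dual %MAP** `= 100 · |P_tot ∩ P_pY ∩ M| / |M|` — membrane
  colocalisation of total MET and pY1235-MET
- **%NAP** `= 100 · |P_m ∩ N| / |N|` — percent nuclear area positive
- **pY/total ratio** — ratio of the two area-per-cell values

Undefined denominators give missing values (`NA`), never 0.  Specimens with
fewer than 3,000 summed nuclei are flagged non-evaluable (configurable).
Group statistics are unpaired two-sided Mann-Whitney tests (exact by
enumeration for small tie-free samples) and Spearman rank concordance;
treatment effects are expressed as `100·(sample − vehicle mean)/vehicle
mean`.

A seeded synthetic-scene generator (disk cells, annular membranes, interior
nuclei, exact painted positive fractions, Gaussian noise) provides ground
truth for every stage, including dose-response series in which the phospho
channel is suppressed by a Hill factor `1/(1 + (dose/IC50)^h)` while total
MET is untouched.

## Worked example

```sh
mifquant fixtures dose-response scratch/dr --seed 7
mifquant quantify scratch/dr/config.yaml
```

or equivalently `python analysis/02_dose_response.py --seed 7`, which prints:

```
phospho_met_area_per_cell_um2
  vehicle: mean=44.27 sd=1.12 n=4
  dose_ic50: mean=21.93 sd=0.64 n=4
  dose_10x: mean=4.45 sd=0.10 n=4
total_met_area_per_cell_um2
  vehicle: mean=62.78 sd=1.65 n=4
  dose_ic50: mean=61.55 sd=1.96 n=4
  dose_10x: mean=63.27 sd=0.77 n=4
  vehicle vs dose_ic50: U=16 p=0.02857 (exact)
  vehicle vs dose_10x: U=16 p=0.02857 (exact)
IFA vs orthogonal assay: Spearman rho=0.916 p=2.84e-05 n=12
```

Reading: phospho-MET area per cell falls ~50% at IC50 and ~90% at 10×IC50
while total MET stays flat — the signature of selective kinase inhibition —
and both vehicle-vs-dose contrasts are significant at the exact
Mann-Whitney level attainable with n = 4 vs 4 (p = 2/70).  The per-tumour
percent-change values rank-correlate strongly with a simulated orthogonal
lysate assay of the same tumours.

Outputs land in `results/dose_response/`: `endpoints.csv` (one row per
ROI; missing values written as `NA`), `group_summary.csv`,
`comparisons.csv`, `percent_change.csv`, and `run.log` (config hash,
threshold provenance, QC exclusions).

The other analysis drivers run the expression-tier contrast
(`analysis/01_expression_tiers.py`: negligible vs moderate vs high MET
tiers) and the nuclear-accumulation study
(`analysis/03_nuclear_localization.py`: 30% vs 60% nuclear phospho
fraction).

## Layout

- `src/mifquant/` — library: `image_io`, `segmentation`, `thresholding`,
  `quantitation`, `stats`, `synthetic`, `config`, `pipeline`, `cli`
- `analysis/` — numbered study drivers (thin orchestration only)
- `tests/` — unit, property, and end-to-end acceptance tests
- `docs/methods.md` — models, conventions, parameter rationale, limitations
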