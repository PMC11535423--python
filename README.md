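# cellquant

Single-cell quantification of gene expression in budding yeast, built around
the kind of combined smFISH / live-cell / qPCR experiment used to study how
transcript and protein amounts scale with cell size, nutrients and the cell
cycle. The package is aimed at microscopy labs that segment their cells with
an external tool (YeaZ, Cell-ACDC, …) and need the downstream quantification:
counting single mRNA molecules in 3D image stacks, staging cells by bud size,
extracting produced protein amounts from fluorescence time courses, fitting
mRNA half-lives and culture doubling times, and measuring how expression
scales with cell volume.

## What it computes

**3D smFISH spot calling** (`cellquant.spots`). Single mRNAs appear as
diffraction-limited spots. The caller runs five steps: (1) a mild 3D Gaussian
prefilter (σ = 0.75 voxel); (2) global automatic thresholding (triangle, Li
or Otsu); (3) 26-neighbour 3D local-maxima detection inside the segmented
signal; (4) merging of peaks that fall within a resolution-limited spheroid —
lateral radius r_xy = 0.61·λ/NA (0.291 µm at NA 1.4, λ 668 nm), axial radius
1 µm — keeping only the brightest; (5) iterative filtering on Glass' delta,

    Δ = (mean_peak − mean_background) / sd_background,

where the peak pixels are those inside the spheroid and the background is the
rest of the cell's footprint outside *all* detected peaks. Peaks with Δ below
a threshold τ (typically 0.2–1.0, chosen per experiment) are discarded, their
voxels rejoin the background, and the filter repeats until the spot count is
stable. The surviving peaks are the mRNA count per cell.

**Staging and concentrations** (`cellquant.staging`). Cell volume is
reconstructed from the 2D mask as a solid of revolution about the major axis;
cells are staged by bud state (unbudded + 1 nucleus → G1; bud-to-mother
volume ratio < 0.3 → S; ≥ 0.3 or two nuclei → G2/M); mRNA concentration is
spots per fL.

**Traces** (`cellquant.traces`): volume-dependent autofluorescence fits and
subtraction; produced amount = median(last 4 samples) − median(first 4);
production phase delimited by the last point below 1.1·P_G1 and the first
above 0.9·P_G2.

**Kinetics** (`cellquant.kinetics`): pooled single-exponential decay fits
(t½ = ln2/k) after transcription shut-off; doubling times DT = ln2/slope of
log OD600; protein stability normalized to the doubling time.

**Scaling statistics** (`cellquant.scaling`): ΔCq relative concentrations
(2^(Cq_ref − Cq_gene)) and fold changes; scaling exponents from log-log OLS
with 95% CI; linear fits with confidence bands and slope comparison; and a
Shapiro–Wilk-gated choice between the unpaired t-test and Mann–Whitney.

**Synthetic data** (`cellquant.synth`) generates all of these inputs with
known ground truth — simulated stacks with Gaussian-PSF spots and
Poisson+read noise, ramp traces, decay series, volume/count populations and
Cq tables — so every stage is testable end to end.

## Worked example

Simulate four cells with six transcripts each, call spots, and compute
per-cell concentrations:

```python
from cellquant import call_spots, SpotCallingConfig, count_spots_per_cell
from cellquant.synth import StackSimParams, generate_smfish_stack
from cellquant.staging import estimate_volume_from_mask, mrna_concentration

params = StackSimParams(n_cells=4, n_spots=6, spot_amplitude=100.0, seed=7)
stack, cells, nuclei, truth = generate_smfish_stack(params)
table = call_spots(stack, cells, config=SpotCallingConfig(effect_size_threshold=1.0))
for _, row in count_spots_per_cell(table, cells).iterrows():
    vol = estimate_volume_from_mask(cells == row.cell_id, params.pixel_size_xy)
    print(f"cell {row.cell_id}: {row.n_spots} spots, {vol:.1f} fL, "
          f"{mrna_concentration(row.n_spots, vol):.4f} spots/fL")
```

prints

```
cell 1: 6 spots, 52.5 fL, 0.1144 spots/fL
cell 2: 6 spots, 46.5 fL, 0.1290 spots/fL
cell 3: 6 spots, 50.6 fL, 0.1187 spots/fL
cell 4: 6 spots, 48.6 fL, 0.1236 spots/fL
```

— all 24 simulated transcripts recovered, at cell volumes in the realistic
40–60 fL range. A volume-proportional ("scaling") population generated with
exponent 1 and Poisson counting noise is recovered by the log-log regression
as `1.022 [95% CI 0.994, 1.050]` (n = 2000 cells).

Command-line wrappers exist for the routine steps, e.g.

```sh
cellquant call-spots --stack stack.tif --cells cells.tif --out spots.csv
cellquant decay --in decay.csv --out halflives.csv
cellquant qpcr --in cq.csv --reference YPD --out foldchanges.csv
```

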