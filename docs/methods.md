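# Methods

This note documents the models, parameter choices and numerical decisions
behind `cellquant`, and what the synthetic-data based tests do and do not
demonstrate about real data.

## Spot calling

### Model

An smFISH z-stack is modelled as isolated diffraction-limited emitters on a
per-cell background. The caller makes no attempt at sub-voxel localization
or spot-shape fitting: its output is a count and integer-voxel positions,
which is what concentration and scaling analyses consume.

### Resolution-limited spheroid

Two peaks closer than the optical resolution cannot be distinct molecules,
so peaks are merged inside a spheroid with lateral radius
r_xy = `lateral_coefficient`·λ/NA and axial radius `z_radius_um`. The
lateral coefficient defaults to 0.61 (the Rayleigh-criterion prefactor),
which gives 0.291 µm at NA 1.4 / λ 668 nm; it is exposed in the config
because conventions for the lateral resolution limit differ by constant
factor (0.5 for the Abbe two-point limit, 0.61 for Rayleigh). The axial
radius defaults to 1 µm — of the order of the widefield axial PSF extent and
several z-steps at 240 nm — rather than being derived from an axial
resolution formula, because axial elongation in practice is dominated by
focus and aberration rather than the ideal PSF.

Merging is greedy from the brightest peak down; ties in intensity are broken
by lexicographic (z, y, x) order so results are deterministic. Membership is
the ellipsoid inequality (Δx/r_xy)² + (Δy/r_xy)² + (Δz/r_z)² ≤ 1 evaluated
in physical units.

### Glass' delta and the iterative filter

The effect size of a peak is Glass' delta: the mean intensity inside the
peak's spheroid minus the mean of the background, divided by the standard
deviation of the background. Decisions fixed here:

- **Background is per cell**: pixels inside the cell's 2D footprint (on all
  z-planes) and outside every detected peak's spheroid. Peak pixels are
  likewise clipped to the stack bounds and to the peak's own cell footprint,
  so a spot at the cell edge is not contaminated by a neighbour.
- **Population (n-denominator) standard deviation.** The difference from the
  n−1 form is negligible at realistic background sizes but has to be pinned
  down for exact agreement with the brute-force oracle tests.
- A constant background (sd = 0) or a cell fully covered by peaks is an
  error, not a silent NaN.
- Candidate peaks that fall outside every segmented cell are dropped before
  filtering: without a cell there is no background population to compare
  against.

The filter discards peaks with Δ < τ, lets their voxels rejoin the
background, recomputes every surviving Δ, and repeats until the count is
stable. The count is strictly decreasing until the fixed point, so at most
(initial count + 1) iterations run; the returned deltas are the ones
computed at the converged peak set. τ is deliberately a per-run
configuration value (default 0.5, practical range 0.2–1.0): in real
experiments it is chosen by inspecting images and negative controls, and no
automatic selection is attempted here.

### Candidate intensities

Local maxima are detected, and their intensities read, on the *filtered*
stack (that is where the maxima are well defined); `intensity_source="raw"`
switches the reported intensity to the raw stack. A connected plateau of
equal-valued maxima collapses to its lexicographically smallest voxel so
flat-topped spots are counted once.

## Cell volume and staging

Budding yeast cells are near-solids of revolution, so volume is
reconstructed from the 2D mask: rotate the mask (nearest-neighbour, so it
stays binary) until its principal axis — from the eigenvectors of the pixel
covariance — is horizontal, then sum π·(h/2)² over 1-pixel columns of height
h and convert with the cubed pixel size. On rasterized test shapes the
estimator reproduces the closed-form sphere/cylinder volumes within 5% and
is rotation/translation invariant within 2%. Note that a rasterized disk of
nominal radius R has an effective radius of roughly R + 0.4 px; size-scaling
properties of the estimator are therefore measured against the mask's own
effective radius √(area/π), where the cube law holds to ±0.01.

Staging: unbudded cells with one nucleus are G1; budded cells with two
nuclei are G2/M; otherwise the bud-to-mother volume ratio decides, S below
0.3 and G2/M at or above. The boundary value 0.3 itself is assigned to G2/M
(the source rules are stated as strict "<" and ">", leaving equality open;
measure-zero in practice). Unbudded cells with ≠ 1 nucleus are flagged
`ambiguous` with a rationale string instead of silently guessed — in a real
analysis those are resolved by eye. Spots in a bud's footprint are credited
to the mother row by default (the bud is part of the mother's cycle until
division); this is switchable because the attribution convention is not
universal.

## Traces

Produced amount is median(last 4) − median(first 4) — robust to single
outlier frames. Production-phase timing needs plateau levels; the plateau
extent k = 4 samples matches the 4-point medians and is configurable, since
traces that extend well past division would need a different plateau rule.
Thresholds are strict inequalities: t_start is the *last* sampled time with
I < 1.1·P_G1 and t_end the *first* with I > 0.9·P_G2. A sample exactly at a
threshold does not satisfy the condition; this equality is enforced with a
relative tolerance of 1e-9 so that float round-off in the 1.1/0.9 factors
cannot flip it. Flat traces, where 0.9·P_G2 < 1.1·P_G1, raise a
"degenerate plateaus" error.

One sampling subtlety: if a threshold falls exactly on a noiseless sample
value (e.g. a ramp from 100 at t=30 to 200 at t=60 sampled every 3 min puts
1.1·P_G1 = 110 exactly at t=33), then under measurement noise that sample
sits below threshold with probability ½ and the detected boundary is a coin
flip between adjacent samples. This is inherent to any strict-threshold
rule, not an implementation artifact. The Monte-Carlo timing test therefore
uses a generic rise placement whose crossings fall between samples; under
that (generic) alignment the detected duration is within one sampling
interval of the noiseless-rule value in ≈96% of traces at noise sd 5.

Autofluorescence is a per-condition linear model α + β·V fitted on control
cells not expressing a fluorophore; if all control volumes coincide the
slope is unidentifiable and a constant model is returned. Corrected
intensities may go negative and are kept — clipping would bias the medians.

## Kinetics

Decay fits pool all replicate points (not replicate means) into one
nonlinear least-squares fit of N0·exp(−k·t), initialized from a log-linear
regression. N0 is free by default even though the data are normalized to
t=0, because the normalization divides by a noisy measurement; `fix_n0=True`
provides the constrained variant. A non-positive fitted rate is reported as
"no decay detected" (half-life undefined) rather than an error. At the test
conditions (7 time points over 0–60 min, 4 replicates, 10% multiplicative
noise) the half-life estimator's bias is < 2% and RMSE < 10% over 200 seeded
runs.

Doubling time is ln2 divided by the slope of log OD600 vs time. The
exponential window, when not given, is the contiguous stretch of ≥ 4 points
with the highest log-linear R² (longest on ties, so a perfect exponential
uses every point); a window must have positive slope. Protein stability is
reported as half-life divided by doubling time, which removes the trivial
dilution-by-growth component when comparing media with different growth
rates.

## Population statistics

Relative qPCR concentration is 2^(Cq_ref − Cq_gene), with technical
replicates averaged on the Cq scale first. Fold changes divide each
biological replicate's value by the *mean* of the reference condition, then
report mean ± SE of those ratios (mean-of-ratios); the alternative
ratio-of-means convention differs only at second order in the noise but the
choice is documented and kept fixed.

Scaling exponents come from OLS of log(y) on log(V) (natural logs;
exponents are base-invariant), with t-based 95% CIs. Slope comparison
between two datasets uses the standard interaction test on the pooled model
y ~ x + group + x·group. The two-group comparison first applies Shapiro–Wilk
to each sample at α; only if both pass is the unpaired two-tailed t-test
used, otherwise the two-sided Mann–Whitney U. On 2000 seeded null draws the
gated procedure's type-I error is consistent with α = 0.05. No
multiple-testing correction is applied; p-values are per comparison.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the real data: 20-plane stacks
at 240 nm z-steps with ~0.1 µm pixels; spots as separable 3D Gaussians
(σ_xy 0.10 µm, σ_z 0.35 µm — representative widefield values for a 1.4 NA
oil objective); per-cell constant background; Poisson noise on signal plus
background followed by additive Gaussian read noise, clipped at zero; cells
as extruded 2D ellipses with concentric nuclei; plateau–ramp–plateau traces
at 3-min sampling; single-exponential decay with multiplicative noise;
lognormal cell volumes with counts Poisson-distributed around c·V^a; and Cq
tables with technical triplicates. Simulated spots are placed ≥ 4 voxels
apart so that ground truth consists of resolvable molecules. With Poisson
noise off, population counts store the exact expectation c·V^a as floats
(possibly non-integer) — that is the input exact-recovery checks need;
integer counts hold in the Poisson branch.

It deliberately does **not** model: real optics (Airy rings, aberration,
depth-dependent PSF), camera gain/offset, segmentation errors or touching
cells, transcription-site clusters brighter than single molecules,
cell-cycle-correlated backgrounds, or qPCR primer-efficiency differences.
Passing tests therefore demonstrate the correctness of the *algorithms*
under the stated noise models, not detection performance on any particular
microscope's data — on real data, τ, the threshold method and the merge
radii still need to be validated against negative controls.

## Problem sizes

The seeded simulations used by the test suite are sized to be decisive yet
quick: 4–6 cells per 20×128×128 stack and 120 ground-truth spots for
detection performance; 200–500 Monte-Carlo repetitions for estimator bias
checks; 2000 draws for test-calibration rates; 2000 cells for scaling
recovery. These are the package's own verification conditions; all of them
are parameters, and larger runs only tighten the same checks.
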