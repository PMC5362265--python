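# Methods

`pictquant` quantifies PICT (Protein interactions from Imaging Complexes
after Translocation) live-cell imaging experiments. In the assay,
rapamycin-induced FKBP–FRB dimerization traps an FRB-tagged bait at an
RFP-labelled anchoring platform (Tub4 at the spindle pole body, one or two
per yeast cell); a GFP-tagged prey co-translocates to the anchor only if it
interacts with the bait. The readout is a per-replicate recruitment score
computed from two-channel fluorescence images. The package also implements
the companion analyses of such an experiment: nuclear-vs-cytosolic
classification of the recruited prey from inter-anchor intensity profiles,
assembly/disassembly kinetics of complex levels over time, and ChIP-qPCR
relative occupancy.

Because no raw imaging data accompanies this workflow, a synthetic-data
generator with exact ground truth is a first-class component: every
downstream stage is validated against either analytic expectations or
brute-force oracles on generated data.

## Spot segmentation

Both channels pass through the same four steps, with per-channel settings:

1. **Gaussian blur** (anchor σ = 1 px, prey σ = 1.5 px) attenuates shot
   noise; the prey channel gets stronger smoothing because its contrast is
   lower.
2. **White top-hat opening** with a disk structuring element (radius 8 px)
   removes everything wider than the expected spot, including constant
   offsets (exactly) and the smooth background field. All neighborhood
   operations use reflection boundary handling.
3. **Local mean threshold**: a pixel is foreground iff it strictly exceeds
   the mean of the preprocessed image within a disk (radius 8 px) centred on
   it, plus an offset. By default the offset auto-scales to 4× the MAD-based
   robust noise sigma of the preprocessed image. The multiplier was
   calibrated on the workflow's own operating conditions: over a scan of
   {2, 2.5, 3, 3.5, 4, 5}, spurious particles on pure-noise fields
   (Poisson background 100 photons + Gaussian read noise 5) fall from ~92
   to 0 per 256² field while recall at peak SNR 5 stays at 0.97.
4. **Cleanup**: binary median filter (disk radius 1), 8-connected labeling,
   area opening to [4, 200] px² (anchor) / [5, 200] px² (prey — the heavier
   prey blur lets 4-px correlated noise clusters through, so its minimum
   area is one pixel larger).

Region intensity statistics (mean, integrated intensity, brightest pixel)
are always measured on the raw channel, never the preprocessed one.

Because the threshold compares each pixel to its local mean plus a
noise-scaled offset, the mask is invariant to adding a constant to the image
and equivariant under intensity rescaling (when a fixed offset is scaled
along). Ties break toward background (strict inequality), so flat regions
are never foreground.

## Recruitment score

With segmented prey spots P and anchors A, the *yellow* pixels are
Y = P ∩ A, and the field score is

    score = mean(G_raw over Y) · |Y| / |A| = Σ_{Y} G_raw / |A|

where G_raw is the raw green channel and |A| the summed anchor area. The
identity `score · |A| = Σ_Y G_raw` holds exactly for every result and is
asserted throughout the tests. Fields with no segmented anchor are excluded
with a logged warning. Prey spots that do not touch an anchor contribute
nothing, which is what makes the score robust to false-positive prey
detections away from the sparse anchors.

A biological replicate pools all its fields by summing intensities and areas
*before* dividing — one measurement over tens of small regions — rather than
averaging per-field scores. Condition summaries report mean ± SD over
replicate scores (n = 3 by default), normalization to a named reference
condition (dividing replicate scores by the reference mean, no uncertainty
propagation from the reference), and a two-sided Welch t-test between
conditions at the replicate level.

The methods wording ("summed area of all segmented prey-GFP spots
overlapping with" anchors) and the worked segmentation figure (overlap-only
yellow area) disagree when prey spots extend beyond anchors; the overlap
reading is the default and `area_mode="whole_spot"` exposes the other.

## Nuclear vs non-nuclear localization

Cells with two anchoring platforms are selected by greedily pairing mutually
nearest segmented anchors with separation inside 1–4 µm (typical
spindle-pole-body separations; configurable). Both channels are
median-background-subtracted (field-wide median per channel; the source
protocol says only "background subtracted") and sampled with bilinear
interpolation at ~1 px spacing along the segment joining the two anchors'
brightest pixels.

The two red peaks are located as the argmax within 20% of each profile end,
and both must rise above the red profile's median + 3× its MAD sigma —
otherwise the call is `ambiguous (red_peaks_unresolved)`. The green global
maximum is `nuclear` iff it falls in the open interval between the red peaks
shrunk by a margin (default 0.15 of the inter-peak distance) on each side
*and* its prominence above the green median exceeds 3× the green MAD sigma;
it is `non_nuclear` when it sits within the margin of a red peak or outside,
and `ambiguous (low_prominence)` when the green profile has no credible
peak. The margin and prominence defaults operationalize what the source
workflow judged by eye; both are configurable. Reversing the profile
direction reverses the profiles and leaves the class unchanged.

## Complex-level dynamics

Time courses of the two Pol I complexes (Pol I–Rrn3, the
initiation-competent form, and the inactive Pol I homodimer) are normalized
to their highest measurement (max = 1 exactly). Rates are forward
differences between consecutive measurements, in level per minute, plotted
at interval midpoints; they satisfy Σ rate_k·Δt_k = v_last − v_first exactly
(telescoping).

Descriptive fits: `offset + amplitude·exp(−t/τ)` for the decaying complex
(initialized from the endpoints, τ from a log-linear regression, τ > 0
enforced) and a 4-parameter logistic `lo + (hi−lo)/(1+exp(−s(t−t50)))` for
the rising one (s unconstrained in sign, so time-mirrored data fit with the
same t50). Constant series are flagged degenerate rather than fitted. No
model selection is performed — the fits characterize shapes, not mechanism.

Stage labeling: an interval is `consolidation` when both complexes move
slower than `slow_threshold` (default 0.2) × the maximum |rate| observed
across both complexes; otherwise the complex with the larger |rate| claims
it; contiguous runs are merged. With the default synthetic scenario the
sequence is fast adjustment of Pol I–Rrn3 (0–15 min), fast adjustment of the
homodimer (15–35 min), then slow consolidation — the rule is an explicit,
testable operationalization of stage boundaries that the source presented
graphically.

## ChIP-qPCR occupancy

Standard curves are OLS lines of mean Ct vs log₁₀ relative quantity over a
serial 10-fold dilution (≥3 points); efficiency = 10^(−1/slope) − 1, and
curves with non-negative slope are rejected. Quantities are
10^((Ct−intercept)/slope). Technical replicates are averaged on the Ct
scale (the usual qPCR convention; geometric averaging on the quantity
scale). Per condition and biological replicate:

    r(locus)   = Q_IP / Q_input
    c(locus)   = r(locus) / r(chrVII non-transcribed control)
    occupancy  = c(target) / c(5S)
    fold       = occupancy / mean occupancy of the reference condition

The steps are all ratios, so their order is immaterial (and whether 5S is
itself control-normalized cancels); the listing order above follows the
protocol's sentence. With efficiency exactly 1 the chain reduces to 2-based
ΔΔCt arithmetic, asserted against a closed-form oracle. A constant added to
every Ct cancels exactly.

## Synthetic data generator

The generator emulates the assay's imaging design: non-overlapping
elliptical cells (semi-major axis 14–20 px at 0.1 µm/px, rejection-sampled
placement that errors out when the frame is too small), one or two anchors
per cell (two anchors 1.5–2.5 µm apart along the cell's major axis), a
diffuse prey-GFP level inside each cell, one wide nucleolar Gaussian blob
per cell offset perpendicular to the anchor axis, and — in the configurable
recruited fraction of cells — a prey spot centred on each anchor. All spots
are isotropic 2D Gaussians with σ = 1.5 px (a diffraction-limited spot at
~100 nm/px; the PSF itself is a modeling choice). Both channels share a
smoothly varying background: a Gaussian random field with correlation length
25 px, normalized to image mean exactly `background_mean` (100 photons) with
spatial SD 25. Noise is Poisson on the expected photon image followed by
additive Gaussian read noise (σ = 5), the standard CCD/sCMOS approximation.
Intensities are float photons internally and quantized to 16 bit only on
TIFF export, which keeps the analytic oracles exact.

**Seed policy.** Scene geometry (placement, anchors, recruited flags,
nucleolus) derives from `SceneParams.seed`; the background realization and
all noise derive from the call-time seed. Per-field seeds in
`simulate_condition` derive deterministically from (base seed, replicate,
field) via `numpy.random.SeedSequence`, so collections are reproducible and
all fields distinct. Identical (params, seed) gives bit-identical arrays.

**Analytic score oracle.** `expected_score` renders the noise-free
expectation of the green channel for the geometry of `params.seed` and
applies the score formula over ground-truth anchor footprints — disks of
radius round(2.5·σ_PSF) around each anchor centre, the radius at which a
diffraction-limited Gaussian spot falls to the local-mean threshold level,
so the analytic footprint is commensurate with what the segmentation labels.
Under the seed policy this is the exact expectation of the true-mask score
over noise realizations, which the tests verify by Monte Carlo (200
realizations within 3 SE) and end-to-end through segmentation (within 15%).

**Default study conditions** used by the validation suite: three biological
replicates of 6–10 fields per condition; 256² fields with 12 cells; anchor
amplitude 2000 photons (anchor segmentation should be nearly flawless);
prey amplitude 300 photons (peak SNR ≈ 25 over the background); recruited
fraction varied per condition. The kinetic defaults reproduce the
starvation narrative: Pol I–Rrn3 decays with amplitude 0.6, offset 0.4,
τ = 20 min (≈30% loss by 15 min, ≈60% total), and the homodimer rises
logistically with t50 = 25 min, steepness 0.25/min (fastest assembly inside
15–35 min), sampled at 12 timepoints over 0–120 min; measurement noise is
multiplicative Gaussian. Synthetic Ct tables draw Gaussian Ct noise with
SD 0.15 cycles.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: 3D structure (single 2D sections only),
photobleaching and chromatic shift between the sequentially acquired
channels, cell-cycle morphology, anchor clustering or motion, non-Gaussian
PSF tails, and camera fixed-pattern noise. Quantitative recovery statements
hold under the generator's conditions, not universally.

## Statistical calibration

Under the null (two conditions simulated from identical generator
parameters, 3 replicates × 2 small fields each, true-mask scoring), the
Welch test at the replicate level rejects at 5% in about 3.5–4.5% of 1000
simulated comparisons. Welch's approximation is intrinsically slightly
conservative at n = 3 (≈3.3% on exactly normal samples), so rates in that
range reflect the test, not the generator.

## Numerical choices and degenerate inputs

- Local-mean thresholding computes the disk sum and divides by the pixel
  count, so constant images sit exactly at their own mean and the strict
  inequality leaves them empty at offset 0.
- Labeling uses 8-connectivity everywhere; boundary handling is reflection
  for every neighborhood operation.
- `pool_replicate` and `relative_occupancy` raise on empty input, missing
  loci, or zero denominators rather than emitting NaN; zero-variance t-test
  inputs return p = 1 (identical means) or 0 (different means) instead of
  NaN.
- Gaussian spots render on square patches of half-width 5σ (truncation error
  < 10⁻⁵ of the spot mass), keeping photon accounting within 0.5%.
- Config files are YAML validated by explicit checks in
  `pipeline._validate_config`; every stage output can be traced to the
  config hash, seed and package version recorded in `provenance.json`
  (no timestamps, so reruns are byte-identical).

## Known limitations

- No watershed splitting of touching spots and no sub-pixel localization;
  dense anchor fields will merge.
- The stage classifier depends on the shared maximum rate; a complex with
  uniformly tiny rates never claims an interval.
- Pairing anchors is greedy closest-first; pathological geometries with
  near-equal distances may pair differently from a globally optimal
  matching (they agree on well-separated doublets, which is the selected
  use case).
- The logistic fit is unidentifiable on step-like data (steepness → ∞); the
  midpoint remains bracketed but its uncertainty is not reported.
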