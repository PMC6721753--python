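# Methods

## Sample and well model

A whole-blood sample is described by its object populations
(`PopulationSpec`: class, concentration per µL of undiluted blood,
physical diameter range, per-marker expression level, nucleated,
suspended). The default populations sit at typical adult hematology
values — leukocytes 4,500/µL (7–20 µm), red blood cells 5×10⁶/µL
(6–10 µm), platelets 2.5×10⁵/µL (2–5 µm) — plus ldEVs at 1,500/µL.
The ldEV diameter range defaults to 3.4–6.0 µm: large EVs have no
canonical size distribution, and at 0.64 µm/pixel the smallest
detectable object has an area of ~9 µm², i.e. an equivalent diameter of
~3.4 µm, so the class is bounded below by what the imaging itself can
resolve. Sub-resolution EVs exist physically but are outside the
operational class definition.

Well loading follows the counting-chamber geometry: `loaded_volume /
dilution_factor` µL of undiluted blood per well (0.02 µL at the default
10 µL of a 500× dilution), 55–65 frames per well (default 60), 4–6
technical replicates (default 5). Per-well counts of each class are
Poisson with mean `concentration × volume × retention`; positions and
frame assignments are uniform and particles do not interact, except for
the explicit clustering mechanism below. A configurable cap (default
10⁶ expected objects/well) rejects implausible configurations.

The EpCAM-enriched mode represents a full processed draw (default
7.5 mL ≙ `processed_volume_ul`) rather than a diluted aliquot.
Enrichment physics (ferrofluid capture, centrifugation, plasma
discard) is deliberately reduced to one Bernoulli retention probability
per class — default 10⁻³ for leukocytes and 0.5×10⁻³ for ldEVs, zero
for EpCAM-negative platelets/RBCs — because only the net carryover
matters downstream. The factor-two difference between the two
retentions is what produces the doubling of the leukocytes-per-ldEV
ratio (≈1:3 in whole blood → ≈1:6 after enrichment). A
`cluster_fraction` of retained leukocytes is re-placed within touching
distance of an already-settled leukocyte (movers attach to settled
particles only, so clusters are guaranteed even at fraction 1.0),
emulating cells aggregating along the magnetic field lines.

## Imaging model

Each marker-expressing particle is rendered, in each channel where its
expression is non-zero, as a disc of its physical diameter (soft
one-pixel edge) convolved with an isotropic Gaussian of per-particle
defocus sigma, scaled by a per-particle amplitude; frames add a flat
background (default 20 a.u.) and Gaussian pixel noise (default
σ = 2 a.u.). Intensity units are arbitrary and calibrated against the
gate thresholds, which are the only fixed points available: `positive`
expression has amplitude 400 (comfortably clearing background-subtracted
mean > 30 / max > 50 after detection), `low` is 45 (straddling the
thresholds), `negative` is exactly 0. Per-particle amplitudes carry
lognormal scatter (CV 0.10). Settled classes (leukocytes, RBCs) render
in focus; suspended classes (platelets, ldEVs) draw a defocus sigma
uniformly from the optics' range (default 0–2 px), which visibly
enlarges their thresholded footprint — perceived size in these images
is therefore not physical size, and small defocused objects can fall
below the detection/positivity limits, as real suspended vesicles do.
No physical optics (NA-derived PSF, exposure photometry) is modelled;
exposure times are metadata only.

Pixel pitch defaults to 0.64 µm. Frame shape is configurable and
defaults to 512×512; at that size the default RBC concentration tiles
frames far more densely than a full-size camera sensor would, so
whole-frame RBC counting at full concentration is dominated by merging
— an exaggerated form of the RBC-aggregation undercount this approach
genuinely has. Quantitative recovery tests therefore use sparse
configurations where the merge correction is enumerable from ground
truth.

## Detection

Background per channel is a block-median surface (medians of
128-px blocks on a 2× decimated grid, bilinearly interpolated; a
decimated median is unbiased and fast) with noise estimated as
1.4826×MAD of a pixel-strided residual sample. Foreground is
`value > background + k·σ` per channel (k = 5 by default; flat frames
with σ = 0 fall back to background + 1), unioned across channels so an
object positive in any channel is one object, labeled with 8-connectivity.
Components with ≤4 pixels are discarded (strict inequality). Border
objects are kept by default since frames tile a well. No watershed
splitting: touching particles merge into one object by design.

Features are computed by a single vectorized pass (sorted-label
`reduceat` reductions) rather than per-region crops, for throughput;
tests verify them to 10⁻⁹ relative against a brute-force per-object
loop, and eccentricity additionally against the standard region-props
implementation. Conventions that were genuinely open and are therefore
fixed here: intensity statistics are computed on background-subtracted
values; std is the population (ddof = 0) definition; perimeter is the
exposed 4-neighbor pixel-edge count (the >5 px gate is insensitive to
the estimator choice for objects clearing the 4-pixel filter);
eccentricity is the fitted-ellipse √(1 − (b/a)²) from second central
moments; `integrated = mean × area` exactly; coordinates are 0-based
row/col.

## Gating

Gate sets are conjunctions of `feature(channel_role) {>, ≤} threshold`
criteria, with comparators exactly as printed (strict `>`, inclusive
`≤`). Criteria reference channel *roles* (nuclear, CD45, CD61, CD235a,
CK, extra); metadata maps roles to channel names, so the same gate
works whether the nuclear dye is DAPI (enriched panel) or Hoechst
(whole-blood panel). Morphology criteria (size, perimeter,
eccentricity) describe the whole object; the role they are filed under
is preserved for transcription fidelity but does not affect evaluation.
The `extra` channel is a noise-only channel whose `std ≤ 5` criterion
guards against autofluorescent artifacts; the simulator always renders
it. The bundled libraries are bit-exact JSON transcriptions of the
published gate table; the duplicated platelet negativity row in the
printed table is transcribed as one criterion per channel, and the
enriched-panel ldEV size cap (printed without units) is read as µm²
like its whole-blood counterpart. Objects matching no gate are
`unclassified`; objects matching more than one are `ambiguous` and
reported separately — never assigned by priority — because overlap
resolution was never specified and hiding it would be worse than
surfacing it.

## Quantification

Counts extrapolate linearly (`count × target/sampled` volume, reported
as a rate, never rounded). The leukocytes-per-ldEV relative frequency
is undefined (NaN) at zero ldEVs rather than infinite. Replicate
statistics use the sample SD (n−1) and report `SE% = 100·(SD/√n)/mean`;
cohort averages of SE% are means of per-donor values. Box-plot
quartiles use linear interpolation between order statistics (recorded
here because only the whisker formulas, `Q1 − 1.5·IQR` and
`Q3 + 1.5·IQR`, were fixed externally). Correlation against reference
counts is ordinary least squares on per-donor replicate means, with
`R² = 1 − SSres/SStot` and a per-class underestimation factor
`mean(imaging)/mean(reference)`. No uncertainty propagation beyond the
replicate SD is attempted.

## What the simulator does and does not establish

Passing recovery tests show the detection/gating/statistics chain is
correct with respect to a known ground truth under this forward model:
flat background, Gaussian noise and blur, disc-shaped objects, ideal
marker specificity. Real images add structured background, RBC
absorbance shadowing, dye bleed-through, granulocyte CD45 dimness, and
broad CD235a intensity ranges; the simulator does not emulate these, so
test results bound algorithmic, not biological/instrumental, error.
Cohort-scale reference quantities that depend on real donor images
(absolute patient distributions, instrument-level R², exact SE
percentages) are checked as structural properties (ratio recovery
within Monte-Carlo bounds, enrichment doubling, Poisson-limited SE) at
simulation scale instead.

## Problem sizes and determinism

The test suite runs one full-scale cohort (10 donors × 5 wells × 60
frames of 512×512, 4 markers + extra channel, ~10⁵ objects/well) as a
throughput check (~6 min on one CPU), and uses sparse 256² wells with
8–12 frames for quantitative recovery, where touching-cluster
corrections can be enumerated exactly. All randomness flows from
`numpy.random.SeedSequence(seed, (well, stream))`, so a (seed, config)
pair reproduces truth tables bit-identically; donors derive independent
sub-seeds. Hypothesis-based property tests run derandomized.

## Known limitations

- Merged mixed-class objects are unclassified rather than split;
  cluster-heavy regimes (default-density RBC frames, enriched
  leukocyte clusters) undercount by design.
- Defocused small objects can fail positivity gates, biasing ldEV and
  platelet recovery at non-zero defocus ranges; recovery guarantees
  hold for in-focus rendering.
- The nuclear signal fills the whole cell disc rather than a nucleus;
  nuclear-size gating is therefore equivalent to cell-size gating in
  simulation.
- Retention probabilities and the clustering fraction are free
  parameters expressing net effects; they make no mechanistic claim.
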