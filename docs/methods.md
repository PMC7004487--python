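# Methods

`gustaquant` re-implements, as a tested pipeline over synthetic data with
known ground truth, the quantification procedures used to compare taste-bud
composition, innervation, geniculate-ganglion marker expression,
nerve/calcium responses and ATP release between mouse genotypes (e.g.
Skn-1a/Pou2f3 knockouts, which lack Type II taste cells, versus wild type).
No raw images or recordings are public for this class of experiment, so the
package pairs every measurement stage with a simulator whose stored truth
the tests recover.

## Image conditioning

Confocal stacks are conditioned with the standard ImageJ-style chain, in a
fixed order: rolling-ball background subtraction (radius 50 px), 2D median
filtering (disk, radius 2 px), and Otsu binarization on the histogram pooled
over all z-slices of a channel.

* **Rolling ball.** Implemented as a per-slice grey-scale morphological
  opening with a non-flat, ball-shaped structuring element of height
  `sqrt(r² − d²)`; the opening is the background and is subtracted
  (a top-hat). This is the exactly specifiable form of "rolling a ball
  under the intensity surface", in contrast to the sliding-paraboloid
  approximation some tools use, and it is what the brute-force oracle in
  the tests computes. Edge handling duplicates the border sample
  (scipy's `reflect`); the implementation is an exact shift-and-reduce
  over the footprint offsets, batched across slices.
* **Median filter.** Per-slice disk neighbourhood (`x²+y² ≤ r²`), same edge
  convention, via `scipy.ndimage.median_filter`.
* **Otsu.** 256 histogram bins spanning the declared bit-depth range for
  integer data (min–max for float data); the between-class variance
  `w0·w1·(µ0−µ1)²` over bin centres is maximized; plateau ties break
  toward the smallest threshold; foreground is *strictly greater* than the
  threshold, and for integer data the threshold is reported as the largest
  background grey level so the split is bit-exact. A constant channel has
  no threshold and raises.

Binarizing a signal-free (noise-only) channel is meaningless for a global
threshold — Otsu will split the noise distribution itself. The profile
counter therefore treats a *constant* channel as an empty mask, and the
bud simulator always gives each fiber channel genuine structure (see
below); a blank channel in the ganglion normalization raises.

## Volumetric measurements

Per taste-bud ROI (an integer label volume):

* **Innervation density** `D` = labeled voxels / total voxels inside the
  ROI, pooled over the optical sections the ROI spans; per-section area,
  labeled area and mean are recorded alongside. Volumes are reported in
  voxels and µm³ (anisotropic voxel size); fractions use voxel counts.
* **Colocalization** `F = |A∩B∩ROI| / |B∩ROI|`, with A the reporter (GFP)
  mask and B the reference fiber (P2X3) mask. `|B∩ROI| = 0` yields NaN
  with an `undefined` flag, never a silent zero.
* **Profile counts.** Single planes at the 25/50/75 % quantiles of each
  bud's z-extent (floor-rounded onto its own planes) stand in for "a plane
  from the lower, middle and upper quadrants"; sampling one plane per
  quadrant avoids recounting cells that persist through adjacent sections.
  On each plane, 8-connected components of the binarized marker channel
  with area ≥ 20 px containing at least one nucleus-positive pixel count
  as one cell profile. The nucleus must be visible in the same plane. The
  area floor and the detector are configurable.

## Ganglion-cell scoring

Maximal z-projections of consecutive non-overlapping 10 µm substacks
(⌈thickness/z-step⌉ slices; a trailing remainder of at least half a
substack becomes its own substack, otherwise it merges into the previous
one). Per cell ROI and channel, the mean intensity is measured on the
projection, background-subtracted (median of non-ROI pixels of that image)
and normalized by the 99th percentile of the background-subtracted cell
values of that image — a convention chosen so that the normalized values
are invariant to multiplying the image by any positive constant; the
constants used are recorded.

Thresholds per channel: 1- and 2-component Gaussian mixtures are fitted by
EM (k-means initialization, fixed seed, deterministic), and the modality is
chosen by BIC. For a bimodal histogram each value is assigned to its
maximum-responsibility component and `T = m_low + 2·s_low`, where `m_low`
and `s_low` are the median and SD of the values assigned to the lower
component ("median of the lower peak" is a statistic of values, so its SD
is read the same way; the fitted-σ alternative is available by flag). For
a unimodal histogram `T = mean + 2·SD` of the single fit, flagged as
extrapolated. Scoring is strict (`value > T`); combination percentages
partition 100 % within each group. Thresholds are fitted on values pooled
per channel (per-image fitting is the caller's choice by fitting per
subset).

At the simulated study conditions (components N(0.2, 0.05²) and
N(0.8, 0.05²)) the 2-SD rule itself misclassifies ≈1.4 % of cells in
expectation (the upper tail of the negative component crosses T); the
recovery tests therefore bound aggregate misclassification, not per-seed
counts.

## Trace analysis

* **Nerve.** Integrated whole-nerve recordings on a 30 s stimulus / 40 s
  rinse schedule. Per stimulus, baseline `B` = mean of the 10 s
  immediately before onset, response `S` = mean over the stimulus window,
  and `R = (S − B)/B`. R is invariant to rescaling the trace; an optional
  mode re-normalizes to a reference stimulus (e.g. NH4Cl). Non-positive
  baselines and overlapping windows raise.
* **Calcium.** Fura-2 340/380 ratio traces sampled at ~1 Hz. `B` = mean of
  the first 10–15 s (default 10). Visual responder judgment is
  operationalized reproducibly: the trace is smoothed with a 5-sample
  moving average and a response is "visible" when the smoothed trace
  exceeds `B + 3·SD` (SD of the raw baseline) inside the stimulus window;
  the peak `P` is then the smoothed maximum over the window, otherwise the
  raw value 30 s after onset (flagged). `ΔR = P − B`; the normalized
  response is `ΔR/P` per trace (`ΔR`/max-P across stimuli by flag, since
  the convention is ambiguous between the two).

  Reading a peak off a noisy trace is a maximum statistic and carries a
  positive bias of order the (smoothed) noise SD; with the 5-sample
  default and 1 Hz sampling the measured bias is ≈2 % of a ΔR = 0.3
  response at noise SD 0.01. The Monte-Carlo recovery tests therefore
  compare the replicate mean against truth at 3 replicate SDs (the
  precision of a single recovered value), not 3 SEM — an unbiased-mean
  criterion is unattainable for any max-based estimator, because the SEM
  shrinks as 1/√n while the bias does not. An unsmoothed peak is worse in
  both respects: at 1 Hz × 30 s windows, the raw max exceeds 3 baseline
  SDs in ≈30 % of pure-noise traces, which is why detection operates on
  the smoothed trace.

## ATP calibration

RLU = intercept + slope·[ATP] is fitted by ordinary least squares on ≥3
distinct standard concentrations (luciferase output is linear over the nM
range used); conversion inverts the line, clipping negative
back-calculations to 0 with a flag and flagging extrapolation outside the
fitted range. Stimulated wells are paired to the artificial-saliva well of
the same preparation (per-trial pairing); the comparison is a two-sided
paired t test on concentrations. Constant nonzero differences make t
undefined; the summary row is flagged `degenerate` with NaN rather than
reporting an infinite statistic.

## Statistics

All statistics are computed from their defining formulas; scipy,
statsmodels and pingouin appear only as cross-check oracles in the tests.

* Kruskal–Wallis H with tie correction `1 − Σ(t³−t)/(N³−N)`, p from
  χ²(k−1).
* Dunn pairwise z with tie-corrected pooled rank variance
  `N(N+1)/12 − Σ(t³−t)/(12(N−1))`; raw two-sided normal p by default
  (per-pair p-values are conventionally reported unadjusted next to a KW
  test), Holm or Bonferroni on request. For k = 2, z² equals the
  tie-corrected H.
* Two-way ANOVA: Type II sums of squares via nested least-squares model
  comparisons for (possibly unbalanced) fixed-effects layouts — the
  standard choice for unbalanced counts when no interaction is assumed a
  priori. With a subject identifier, a repeated-measures decomposition is
  used instead: a factor constant within subjects is treated as
  between-subjects (split-plot; its error term is subjects-within-groups),
  within-subject factors are tested against their factor×subject
  interaction; sphericity is assumed and flagged, and the within-subject
  layout must be complete. Holm–Šidák step-down adjustment
  (`1−(1−p)^(m−i+1)`, monotonized) for the pairwise factor-level
  comparisons.
* Pearson χ² on contingency tables (expected counts reported, zero margins
  rejected) and the paired t test, with the degenerate zero-variance
  nonzero-mean case raised as an error.

Null calibration: simulated type-I error at α = 0.05 over 1,000 replicates
per test is required to fall in [0.03, 0.07] by the acceptance suite.

## Synthetic data: what it emulates, and what it does not

* **Bud stacks** (default 16×96–256 voxels at 0.2×0.2×1 µm): ellipsoidal
  buds (semi-axes ≈6×8–10 µm) containing elongate cells modeled as
  vertical columns with spherical nuclei (radius 1.6 µm, depth-jittered),
  and fibers as persistent random-walk tubes (radius 0.4 µm) clipped to
  the bud. Tubes are grown until the per-channel voxel-count target is met
  exactly (trimming the last stamp, so stored fractions hit the target to
  one-voxel quantization). The GFP channel consists of a prescribed
  fraction of the P2X3 voxels (shared, in tube order) plus GFP-only tubes
  grown outside P2X3 up to its own density target — so F is controllable
  over [0, 1] while both channels always contain real structure.
  Rendering: structure intensities over a background with a linear
  gradient, anisotropic Gaussian PSF (σ = 0.1/0.1/0.35 µm, a realistic
  confocal scale), then Poisson noise (gain 1) plus Gaussian read noise
  (SD 6 of 255), 8-bit output.
* **Ganglion fields**: 3 substacks of 10 µm at 1 µm spacing,
  512×512×(0.5 µm)² pixels, round cells (radius 5 µm) placed without
  in-plane overlap; per-channel normalized intensities drawn from the
  two-component mixture; rendered at gain 200 over background 20 with
  light blur and Gaussian noise, 16-bit.
* **Traces**: first-order rise/decay kinetics toward `baseline +
  amplitude` during the stimulus (τ = 0 gives steps and exact plateaus),
  linear drift, white Gaussian noise; integrated nerve traces at 10 Hz,
  ratio traces at 1 Hz, clipped at zero.
* **Plates**: linear RLU with Gaussian noise; standards at
  0–400 nM.

Not modeled: optical sectioning artifacts beyond the Gaussian PSF,
scattering/depth attenuation, fiber branching statistics, cell-shape
irregularity, photobleaching, amplifier/integration dynamics of the nerve
signal, luciferase kinetics. Passing recovery tests therefore demonstrates
correctness of the measurement chain under a realistic forward model, not
robustness to every artifact of real tissue.

## Problem sizes and determinism

Tests and the acceptance script use single-bud 16×96×96 stacks (the
smallest geometry at which bud, fibers and the 50 px rolling ball are all
meaningfully exercised), 10-bud batches for profile-count recovery, 20
seeds × 500 cells for ganglion scoring, 100-replicate Monte-Carlo runs for
traces, and 1,000-replicate null calibrations — sizes chosen so the whole
suite completes in minutes on one CPU while keeping every binomial/SE
bound meaningful. All randomness flows from explicit seeds
(`numpy.random.default_rng`); the demo pipeline writes a manifest with
SHA-256 checksums, and two runs with the same configuration are
byte-identical.

## Known limitations

* Otsu on a channel whose histogram is genuinely unimodal (no signal)
  splits noise; the pipeline guards the constant case and the simulator
  avoids the empty-channel case, but real blank channels should be
  excluded upstream.
* The repeated-measures ANOVA assumes sphericity (no Greenhouse–Geisser
  correction) and complete balanced within-subject data.
* The calcium peak estimator's positive bias (see above) is inherent to
  max-based peak reading; heavier smoothing trades it against peak
  attenuation.
* Mixture-based thresholding needs both components populated (≥20 values,
  reasonably separated peaks); for unimodal channels the mean + 2 SD
  fallback is a flagged extrapolation, not a validated rule.
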