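# Methods

`hdspace` analyzes head-direction (HD) cell recordings from a rodent
foraging in a rectangular walled arena, asking whether a neuron's apparent
spatial firing is an artifact of behaviorally biased heading or genuine
spatial coding. This note documents the models, estimators, numerical
choices and their limitations.

## The scientific problem

An HD cell fires as a unimodal function of head azimuth. Because a walled
environment constrains which headings can be displayed where — an animal
running along the east wall mostly faces north or south — even a *pure* HD
cell produces a spatially structured rate map and therefore positive
spatial information from the viewpoint of a naive downstream reader. The
package separates this behaviorally induced (spurious) component from true
spatial coding, and quantifies two candidate sources of true coding:
modulation by the identity of a specific nearby wall (allocentric border
signal) and by the side of the body on which the nearest wall lies
(egocentric signal).

## Estimators

### HD tuning and classification (`tuning`)

Tuning curves: spike counts per 6 degree HD bin divided by occupancy in
seconds, over movement samples only (speed > 2.5 cm/s; speed is the central
difference of 3-sample-smoothed positions — the tracking pipeline upstream
is not modeled, so the smoother is a package choice). A cell is an HD cell
when all three hold:

1. circular-shift shuffle test on the tuning-curve resultant length,
   p <= 0.001 at 1000 shuffles. Shuffles shift the whole spike train by a
   uniform offset in [20 s, T - 20 s] (mod T), preserving inter-spike
   structure; p uses the +1 correction, so the minimum attainable p with
   1000 shuffles is 1/1001 <= 0.001.
2. split-half stability: Pearson r > 0.75 between tuning curves of the two
   session halves over >= 10 commonly visited bins.
3. von Mises concentration of the tuning curve > 1, with kappa obtained by
   the standard piecewise inversion of A(kappa) = I1(kappa)/I0(kappa)
   (Fisher 1993) applied to the rate-weighted resultant length. The
   alternative — estimating kappa from individual spike phases — gives the
   same answer for unimodal curves on near-uniform occupancy; the
   curve-based version is robust to occupancy bias because occupancy is
   divided out first.

### Information and bias correction (`information`)

Skaggs-style information of a binned rate function lambda(x) with occupancy
probability p(x):

    I = sum_x lambda(x) log2(lambda(x)/lambda_bar) p(x)   [bits/s],

bits/spike = I / lambda_bar, with 0 log 0 := 0 and unvisited bins excluded.
Spatial maps use 0.5 cm bins; spike-count and occupancy maps are smoothed
(Gaussian, sigma = 2.5 cm by default) *before* division, which avoids
edge-rate inflation; the 2.5 cm default sits inside the 2-4 cm scale that
cross-validation selects for spatially tuned spike trains.

Unbiased spatial information: 500 control spike trains (100 in the reduced
desk-scale runs) are generated per neuron as inhomogeneous Poisson
processes whose only drive is the neuron's own HD tuning curve evaluated at
the animal's instantaneous heading. Control rate maps are built with the
*identical* estimator (same bins, same smoothing, same occupancy), and

    unbiased = observed bits/spike - mean(control bits/spike)

exactly. The subtraction removes the information attributable to HD tuning
combined with heading bias *and* the finite-sampling bias the two share.
For generated pure-HD cells the unbiased values are centered on zero; for
cells with genuine border or egocentric gain they are positive at several
control standard deviations.

Cross-validated information: contiguous 10-block partition (blocks respect
temporal autocorrelation; random frames would leak training data into the
test set). Per fold and smoothing scale sigma in {0.5 ... 25} cm, the
training rate map predicts test-frame rates; the score is the Poisson
log-likelihood gain over the homogeneous mean-rate model in bits per test
spike. This is a proper scoring rule consistent with the Poisson GLM; the
prediction is floored at 1e-3 of the training mean rate so that empty map
regions cannot produce infinite penalties. Folds without test spikes are
skipped and logged.

### Border / egocentric GLM (`glm`)

Spike trains are binned at 5 ms and smoothed with a Gaussian kernel of sd
25.6 ms (one video frame), truncated at +-4 sd and normalized to unit sum
(symmetric boundary handling conserves the total count exactly). Two
log-link Poisson regressions are fitted per cell, never jointly, each with
the HD-expected-rate covariate:

- border: four binary wall variables (within 15 cm of exactly one wall;
  in corners all four are zero — corner exclusion removes wall *attribution*
  rather than dropping bins, which would distort the HD covariate).
  Border modulation = max wall coefficient; border-modulated iff > 0.1.
- egocentric: wall_left / wall_right flags set when the bearing of the
  nearest wall's perpendicular foot point (nearest wall <= 15 cm; corner
  ties break E < N < W < S) falls within +-60 degrees of the left / right
  body axis. Egocentric modulation = |beta_left - beta_right|.

All regressors, binary ones included, are z-scored over the analyzed
(speed-masked wake) bins; constant columns are zeroed and reported. The
fit maximizes the continuous-response Poisson quasi-likelihood (smoothed
counts are non-integer) by iteratively reweighted least squares on the
normal equations; convergence at relative deviance change < 1e-8 or 100
iterations; singular systems retry once with ridge 1e-6 and are flagged.
The fit is verified in tests against direct likelihood maximization
(scipy) and against statsmodels GLM.

### Behavioral orientation bias (`behavior`)

Headings are doubled (mod 360 degrees) so opposite directions collapse
onto one orientation (90 and 270 both become 180). Per 2 cm spatial bin
(coarser than rate maps, for stable circular statistics) the resultant of
the doubled angles gives the mean orientation (direction / 2) and a von
Mises kappa, capped at 50 because the A(kappa) inversion diverges at
resultant length 1; bins with fewer than 10 samples are flagged undefined.
Caveat: a bin crossed in a single pass contains essentially one heading and
shows high kappa without any systematic bias — region-level comparisons
should require several passes per bin (the tests use >= 30 samples).

### Cross-state correlations (`statecorr`)

Rates are binned at 1 s (the source analyses do not state their bin;
configurable) inside wake / REM / non-REM epochs, on a global grid with
straddling bins dropped; wake bins are restricted to movement. Pearson
correlations of z-scored series give one r per pair per state. Pairs are
ranked by the mean unbiased information of their two cells and split at the
33rd percentiles. Preservation per group = Pearson correlation across
pairs between r_wake and r_sleep; groups are compared by the
independent-samples Fisher z test on the two coefficients (the classical
"comparison of two correlations"; its p-values are uniform under the null
and agree with a permutation oracle in tests).

### Cell types (`celltype`)

Putative interneurons: waveform duration < 0.9 ms and trough-to-peak
< 0.42 ms; putative pyramidal cells: duration > 0.95 ms and trough-to-peak
> 0.42 ms; anything else (including the boundaries) unclassified. Feature
extraction from raw waveforms is upstream of this package; features arrive
in waveforms.csv.

## The synthetic world (`synthetic`)

The generator exists so that every estimator can be validated by parameter
recovery. It emulates, mechanistically, the features the analyses depend
on — not rodent biomechanics.

- **Trajectory**: a random walk at 39 Hz in the 53 x 46 cm arena.
  Per-step speed ~ N(8, 4) cm/s truncated at 0 (typical foraging speeds;
  nearly all samples pass the 2.5 cm/s movement filter), heading noise
  sd 0.25 rad/step, reflective walls with a 1 cm margin. Within 15 cm of a
  wall the heading relaxes toward the nearer wall tangent at rate
  4 x wall_bias (1 - d/15) per second; wall_bias defaults to 2, which
  yields the strong thigmotaxis of rodents in open arenas (~90% of time in
  the 15 cm wall band) and, crucially, the heading-position correlation
  that creates spurious spatial information. Head direction = movement
  heading + von Mises jitter (kappa 20); coupling HD to locomotion is what
  makes the behavioral bias propagate into HD-cell rate maps.
- **Cells**: von Mises HD tuning (shape normalized to 1 at the preferred
  direction, so peak_rate is attained exactly), optionally gated
  multiplicatively by nearest-wall identity (hd_border), by the egocentric
  side of the nearest wall within the same 15 cm / +-60 degree geometry
  the analyzer uses (hd_egocentric), plus Gaussian place fields and
  homogeneous cells. Defaults: peak 10 Hz, baseline 1 Hz, kappa 4 —
  ordinary numbers for thalamic/post-subicular HD cells. The egocentric
  default gains (1.5, 0.5) are fixture choices, not empirical claims.
- **Spiking**: inhomogeneous Poisson; per-frame counts at rate x dt with
  uniform jitter within the frame. No refractoriness, bursting or theta
  rhythmicity — so green tests certify estimator correctness under Poisson
  assumptions, not robustness to non-Poisson spike-train structure.
- **Sleep**: a latent heading performs a wrapped Gaussian random walk
  (drift 0.5 rad/sqrt(s): full-circle mixing within minutes, second-scale
  autocorrelation) and drives all HD-kind cells through their pure-HD
  reduction; spatial and egocentric gains are inactive (spatial_decouple),
  place cells fall to baseline. This realizes the attractor-like property
  that pure-HD co-firing is preserved across brain states while spatially
  driven wake correlations are not, and is the ground truth behind the
  preservation-contrast tests. Sessions take one non-REM and one REM
  segment with independent latent walks.
- **Seeding**: one session seed expands through `numpy` SeedSequence spawn
  into independent streams per stage and per cell; identical seeds give
  byte-identical pipeline outputs.

What the generator does *not* emulate: lighting cues, tracking noise and
LED geometry, non-Poisson firing statistics, theta/ripple dynamics,
sleep-stage microstructure, and arena geometries other than a rectangle.

## Design choices made where the design was open

- Shuffle null = circular time shift (ISI-preserving) with a 20 s guard;
  stricter nulls (jittering individual spikes) would be anticonservative
  for bursty trains.
- The two GLMs are fitted separately (border; egocentric), matching the
  two-regression design; a joint fit would split shared variance between
  collinear wall and side regressors.
- The egocentric window is defined on the angle between the body axis and
  the bearing of the nearest wall's perpendicular foot; an alternative
  (wall-normal rather than foot-point bearing) is equivalent for
  rectangular arenas.
- Occupancy probability is normalized over visited bins only; unvisited
  bins are flagged and excluded from information sums and correlations.
- Session interchange is plain CSV/JSON: lowest-friction, lossless at
  double precision (round-trip verified to 1e-9).

## Known limitations

- The surrogate correction assumes the HD tuning curve itself is estimated
  from the same session; at very low spike counts the shared estimation
  noise grows and per-cell unbiased values become noisy (population means
  remain centered).
- The cross-validated score divides by the test spike count; cells with
  near-zero rates give volatile fold scores (folds without test spikes are
  skipped).
- Fisher's z comparison assumes approximately bivariate-normal pair
  correlation scatter and independent pairs; pairs sharing a cell are not
  independent, so borderline p-values near the 0.01 criterion should be
  read cautiously.
- All epoch labels (wake/REM/non-REM) are taken as input; no sleep scoring
  is performed.
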