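# Methods

This note records the models, parameter choices and numerical conventions
behind `edgesite`, and what the synthetic validation does and does not
establish about real recordings.

## Probe geometries and site grouping

Coordinates are continuous micrometers with `x` lateral from the left
shank edge and `y` longitudinal from the tip. The five built-in layouts
encode the published geometries of the probes they model: a 32-site
polytrode (three columns of 10/12/10 at 50 um pitch, 125 um shank), a
128-site array (four columns of 32, 22.5 um pitch, 100 um shank), a
255-site dense grid (17 rows x 15 columns at 6 um pitch), and two
Neuropixels-style checkerboards (384 sites, four staggered column
positions, 20 um row pitch, 70 and 50 um shanks). The 128-site probe's
oversized internal-reference pad sits above the recorded array and is not
one of the 128 channels, so it is not modeled.

A column counts as *edge* when the boundary of its sites lies within
10 um of a lateral shank edge; this covers the built-in probes' 5–6.25 um
margins without per-probe hardcoding and applies unchanged to user JSON
layouts. *Center* is the middle column for an odd column count and the
middle two columns for an even one — for the 15-column grid this selects
the 8th column, the natural single-column counterpart of a 17-channel
edge column. Sites in neither role (the other twelve columns of the
grid) are recorded as excluded, so every grouping partitions the layout.

For Neuropixels-style layouts, internal reference sites are excluded
together with the sites in their own and the adjacent row — the minimal
symmetric reading of "neighbors" for a checkerboard. Which sites were
out of tissue in a given experiment cannot be inferred from geometry, so
out-of-cortex exclusions are an explicit per-recording list, never
guessed.

Equalized splitting trims larger groups to the smallest group's channel
count by removing sites alternately from the top and bottom of the shank
(top first when the excess is odd), reproducing e.g. a 10-channel file
from a 12-site center column. Longitudinal grouping divides site rows
into bands from the tip upward, dropping remainder rows from the top.

## Synthetic recordings

The generator emulates acute cortical recordings under slow-wave
anesthesia at 20 kHz and 16-bit quantization (0.195 uV/bit for the
passive-probe front end, 2.34 uV/bit for Neuropixels variants):

* **States.** Up and down states alternate with gamma-distributed
  durations (shape 4; means 0.5 s up, 0.4 s down by default). The gamma
  shape is a modeling choice — slow-wave duration statistics are broadly
  unimodal with a refractory-like minimum, which a shape-4 gamma captures;
  no quantitative distribution is claimed.
* **Spikes.** Each neuron fires as a state-modulated Poisson process with
  a 2 ms enforced refractory period, default silence in down states. The
  extracellular waveform is a biphasic template (1.2 ms support, trough
  then smaller after-peak, trough depth normalized to 1) whose amplitude
  decays exponentially with the neuron-to-site Euclidean distance,
  `A(d) = A0 * exp(-d / lambda)` with `lambda = 28 um` by default —
  the simplest monotone decay consistent with rapid extracellular
  attenuation; the constant is configurable.
* **Noise.** White Gaussian noise per channel (2–10 uV RMS is the
  realistic range; defaults use 4–5 uV).
* **Edge asymmetry.** A multiplicative `edge_gain` on edge-column sites.
  Gain 1.0 is the null hypothesis; modeling the effect as a per-site gain
  (rather than displacing neurons) gives a directly controllable effect
  size for power and type-I studies.

Signal assembly places spike deltas on a channel-major grid and convolves
once per template (FFT), in float32 — the rounding is orders of magnitude
below the quantization step applied afterwards. Identical configurations
give bit-identical outputs.

Two population presets fix the study conditions:

* `cortical_population` — ~30 sortable single units (120–400 uV at the
  soma, 2–10 Hz in up states) plus a distant multiunit background
  (default 400 neurons, 20–90 uV, 20–60 Hz). The background matters: real
  up states carry vigorous population firing, and the summed-MUA envelope
  that slow-wave state detection relies on has no contrast without it.
* `amplitude_population` — ~1200 sparsely firing neurons (0.05–0.5 Hz,
  80–350 uV) plus the same background, used for amplitude-distribution
  experiments. Sparse firing is the realistic regime (cortical rates are
  lognormal with most cells well below 1 Hz) and it is also what makes
  `edge_gain = 1` a *true* null for the binomial scan: when a few
  high-rate cells dominate a channel, their spike trains form persistent
  correlated clusters of beyond-threshold samples, and the scan then
  correctly reports the geometric asymmetry of any single neuron
  placement rather than the gain under test.

What the generator does **not** emulate: biophysical LFPs, the shank's
electrical shielding field, electrode impedance noise spectra, drift,
bursting, spike-waveform variability within a neuron, and spatially
correlated noise. Passing the synthetic validation therefore shows the
*estimators and tests* behave correctly under known ground truth; it does
not by itself establish effect sizes in tissue.

## Preprocessing and the amplitude scan

The spike band is 500–5000 Hz, extracted with a 3rd-order Butterworth
band-pass applied forward and backward (`sosfiltfilt`, reflective edge
padding), giving zero phase and an effective magnitude response
`|H(f)|^2`. Amplitude pools take every 50th sample per channel starting
at index 0, and drop samples strictly beyond ±1000 uV (values exactly at
the limit are kept).

The threshold scan tests, at each of 100 uniform thresholds per side
(10 uV spacing over (0, ±1000]), whether edge samples are
over-represented among beyond-threshold samples, one-sidedly against
`Binomial(k_e + k_c, N_e / (N_e + N_c))`, and symmetrically for the
center direction; both directions at both sides give the Bonferroni
denominator of 200. Conventions:

* strict inequalities (`a < x`, `a > x`) — a sample at the threshold is
  not beyond it;
* p-values via the regularized incomplete beta (`scipy`'s binomial
  survival function), numerically exact at pool sizes of 10^7 and
  beyond — no normal approximation;
* the selected threshold is the *least extreme* significant one in the
  edge direction, regardless of non-contiguity deeper in the tail; the
  full significance masks for both directions are returned;
* the same subsampled pools feed the PDFs, the RMS, the Brown–Forsythe
  test and the scan. Pooled-sample testing (rather than per-recording)
  is the default, with per-recording use possible by calling the same
  functions per file.

Tail percentages (`pct_edge`, `pct_center`) are fractions of each group's
own same-sign samples beyond the selected threshold.

The Brown–Forsythe test is the median-centered Levene one-way F test.

## Down-state noise estimation

Rectified MUA is summed across channels and smoothed with a zero-phase
50 Hz Butterworth low-pass (order 3). The up/down threshold sits at 20%
of the way from the envelope's 10th to its 90th percentile, capped at
1.5x the 10th percentile:

* the down-state baseline is narrow while up-state activity is strongly
  right-skewed, so a near-baseline split classifies weakly active up
  periods correctly — a midpoint split absorbs them into down states and
  inflates the noise estimate by tens of percent at low noise levels;
* the multiplicative cap anchors the threshold to the baseline when
  spikes are very large, making detection invariant to the overall
  spike-amplitude scale.

Both constants are exposed as parameters. Sub-threshold runs of at least
200 ms are down states, supra-threshold runs of at least 100 ms are up
states; shorter runs are merged into the enclosing state, shortest first.
A zero-dynamic-range envelope raises an error rather than returning a
meaningless segmentation.

The estimate is the RMS of one 50 ms window centered in each qualifying
(≥ 200 ms) down state, averaged per channel across windows and then
across channels — the orders commute here since every channel shares the
same windows. RMS is invariant to rectification, so rectified and raw
band-passed input agree identically. On synthetic input the estimator is
compared against the band-limited truth
`sigma * sqrt(mean(|H(f)|^4))`, the injected white-noise RMS attenuated by
the forward–backward filter's power response integrated numerically over
the Nyquist band. On real recordings this estimator is known to read
above a saline measurement of the same hardware — residual distant
activity survives in down states — so it is used comparatively between
site groups, not as an absolute hardware figure, and no correction is
applied.

## Unit quality

Refractory violations are counted as inter-spike intervals below 2 ms
(each violating ISI counts one spike); units with fewer than two spikes
get 0 by convention. Peak-to-peak amplitude is the largest positive value
minus the trough of the mean waveform per channel, with a zero baseline
substituting for a missing positive peak or (flagged as atypical) a
missing trough; the best channel maximizes this quantity. The
well-isolation screen uses strict inequalities exactly as stated:
violations < 2%, rate > 0.05 Hz *or* ≥ 100 spikes, peak-to-peak > 60 uV.

Isolation distance is computed in a 12-dimensional feature space: spike
waveforms on the unit's best channel and its three nearest channels,
projected per channel onto the first three principal components fit over
all spikes in the recording. A singular cluster covariance is diagonally
loaded by `1e-6 * trace / d`. The distance is undefined when the
non-cluster spike count is below the cluster size. The choice of feature
space follows common sorting-quality practice; any consistent feature
space yields an affine-invariant statistic, which the tests verify.

Unit yield counts well-isolated units per recording and site group, and
groups sharing a recording are counted independently — adjacent edge and
center files sorted separately contain partly redundant units by design,
because each group stands in for a probe that has only that site
position.

## Group statistics

All tests are two-sided at alpha = 0.05. Mann–Whitney U uses exact
enumeration for tie-free samples up to n = 20 per group and the
tie-corrected normal approximation otherwise; Z is signed so positive
means the first group is stochastically larger, and `r = Z / sqrt(N)`
with N the pooled size. Kruskal–Wallis applies the tie correction and
requires three or more groups (two groups are redirected to
Mann–Whitney). Dunn's post hoc compares mean ranks with the tie-corrected
variance and multiplies each p by the number of pairs, capped at 1;
calling it without a significant omnibus result warns but proceeds.
Left/right side groups are pooled before edge-vs-center tests, with
per-side analysis available for laterality.

## Study conditions and problem sizes

The canonical experiments (in `edgesite.experiments`, shared by the test
suite and the examples) use the 32-site layout: effect recovery runs 60 s
recordings at 5 uV noise with `edge_gain` 1.3 versus 1.0 across 20 seeds;
type-I control draws 200 replicate pools of 10^5 samples per side from
one distribution; noise recovery runs 40 s recordings at 2, 4 and 8 uV
with a 10x spike-amplitude robustness pair. These sizes give each check
clear statistical resolution while keeping a full validation run in the
minutes range on a single core.

## Known limitations

* The state-detection threshold rule, though validated against ground
  truth here, is one of several defensible choices; recordings whose
  up-state envelope barely clears the baseline (very low multiunit
  activity) will fragment the segmentation regardless of rule.
* The binomial scan treats subsampled amplitudes as exchangeable between
  groups; on real recordings with few dominant nearby neurons the
  per-recording null is geometrically violated (see the population notes
  above), which is an inherent property of the published test, not of
  this implementation — pooling across recordings mitigates it.
* The generator's noise is white and uncorrelated across channels;
  estimator behavior under correlated noise is untested.
* Spike sorting itself is out of scope: unit metrics assume the provided
  labels are correct, and ground-truth labels are used for synthetic
  data.
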