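# Methods

## The measurement model

A block-design task run is a sequence of trials, each a short task period
followed by rest (here 6 s + 24 s, i.e. 12 volumes at TR 2.5 s). Neural
events reach the BOLD signal through the hemodynamic response function
(HRF); the expected time course of a task-driven voxel is therefore the
task boxcar convolved with the HRF — the *ideal response*. `trialfc.hrf`
implements the canonical two-gamma HRF: a positive lobe peaking at 6 s and
a negative undershoot peaking at 16 s with relative depth 1/6, each gamma
parameterized so its mode falls exactly at the stated delay
(shape = 1 + delay/dispersion, scale = dispersion) and rescaled to unit
peak before mixing. A single regressor is used throughout: the method
correlates data against one template, so temporal/dispersion derivative
bases would change the definition of the measure, not refine it.
Convolution runs on a 0.1 s grid before decimation to the TR, because the
6 s block is not an integer multiple of the 2.5 s TR; the sampled
regressor is peak-normalized, which is inconsequential for correlation but
fixes a canonical representation for serialization and tests.

Per trial, the *FC map* assigns every brain-mask voxel the Pearson
correlation r between its 12-volume windowed time course and the trial's
segment of the full-run ideal response. Windows start at the task-onset
volume: the hemodynamic lag is inside the 30 s window, so no extra shift
is applied. The per-trial template is cut from the full-run regressor
rather than re-convolved in isolation, so any residual carryover from the
preceding trial is represented; under this design the two choices agree to
correlation > 0.99 (tested), and same-task trials with identical
predecessors agree exactly.

Similarity between two trials is the Pearson spatial correlation R of
their FC maps over the mask, always computed on unthresholded signed maps
(display thresholds — |r| > 0.58 for trial maps, |r| > 0.3 for task-mean
maps — are cosmetic only). Marker-based identification is
nearest-prototype classification under R, exhaustively over all 512 ways
of choosing one marker per category; correct rates are micro-averaged
over all 10,752 tests, which coincides with the macro average here because
every combination tests exactly 7 trials of each category. Rates are
compared to the 33.3 % chance level with a one-sample t test (pairing
with a constant degenerates to the one-sample case), one-sided because
the claim is directional. The association between mean within-category R
and correct rate is a two-sided Pearson test over subjects × categories.

## Significance threshold

`critical_r(n, alpha)` inverts the exact t distribution:
r* = t*/sqrt(t*² + n − 2) with t* the (1 − alpha/2) quantile on n − 2
degrees of freedom; for n = 12, alpha = 0.05 this is 0.576 (0.58 at two
decimals). The inversion assumes temporally independent samples. Data
bandpassed to 0.009–0.08 Hz at TR 2.5 s violate that badly — the
brick-wall filter keeps roughly 11 of 144 positive-frequency bins, so
12-sample windows of filtered noise have far fewer than 10 effective
degrees of freedom and the nominal threshold is anticonservative on
filtered data. The null-calibration tests therefore run on temporally
white zero-signal data (`preprocess_run(band=None)`), where the empirical
exceedance matches the nominal 5 % level; on bandpassed data the
threshold should be read as a display convention, not an error rate.

## Preprocessing

In scope: isotropic Gaussian smoothing specified as FWHM in mm (converted
per axis by voxel size; nearest-edge replication avoids dark borders on
small grids), a brick-wall Fourier bandpass (exact idempotent projection;
the 0 Hz bin is always removed; the band must end below Nyquist), and
percent signal change, 100·x/baseline with the per-voxel mean of the
smoothed, pre-bandpass series as baseline — i.e. the mean volume image's
value at that voxel. Despiking, slice-timing and motion correction are
deliberately out of scope; real data are expected to arrive with those
applied. The mask builder thresholds the mean volume at a fraction
(default 0.3) of its 98th-percentile intensity and keeps the largest
connected component; it is a documented stand-in for anatomically derived
masks. Voxels with non-positive baseline or zero windowed variance in any
trial are removed from the subject mask up front, so all of a subject's
maps — and hence all spatial correlations — use one identical voxel set.

## The synthetic generator

`trialfc.simulate` emulates the target study's acquisition: a 12-minute
run of 288 volumes at TR 2.5 s, 24 interleaved trials (WR/PV/FT analogs,
8 each), on a 24 × 24 × 18 grid of 3.5 mm voxels whose ellipsoidal
"brain" holds ≈ 2,800 voxels — small enough for desk-scale runs, large
enough that the null spatial-correlation sd (~1/√n_vox) is small.

Signal model, per subject:

* Each task has a unit-variance smooth core pattern (Gaussian random
  field, sigma 1.5 voxels). A task-nonspecific shared pattern is blended
  into every core with weight w = 0.55, because real tasks share
  activation (visual input, arousal, task-general control); this gives
  between-category map correlations of the magnitude the method is
  designed to contend with rather than an orthogonal toy.
* The pattern realized on trial t of task T is
  c_T · core_T + (1 − c_T) · jitter_t, where the consistency c_T is the
  fraction of the pattern that is stable across trials (defaults
  FT 0.9, PV 0.6, WR 0.4 — the finger-tapping analog most reliable, the
  word-reading analog least). Jitter is not voxelwise white: it is a
  random mixture of 6 shared co-activity modes, reflecting that
  trial-to-trial variation runs along a low-dimensional set of brain
  networks. This matters quantitatively: with high-dimensional jitter,
  pairwise map correlations are precise to ~1/√n_vox and the decoder
  saturates at 100 %.
* Trial amplitudes are N(1.0, 0.25) percent signal (clipped at 0),
  multiplying the whole pattern.
* Noise is voxelwise AR(1) (sd 1.0 %, lag-1 coefficient 0.3) plus
  spatially structured noise — 8 smooth spatial modes with AR(1) time
  courses, sd 0.9 % — standing in for physiological fluctuations and
  residual motion, plus a global cosine drift (0.5 % at 0.005 Hz, below
  the passband so the bandpass provably removes it). All of this rides on
  a baseline of 1000 with magnitude-only air noise outside the brain.
* Cohorts share common core patterns; each subject adds an independent
  smooth deviation field (sd 0.7, re-standardized, so cross-subject core
  correlation is 1/(1 + 0.7²) ≈ 0.67) and jitters its consistencies
  (sd 0.08, clipped to [0.05, 1]), which is what spreads subjects along
  the similarity-vs-correct-rate association line. Per-subject seeds are
  spawned from the master seed; identical spec + seed gives bit-identical
  output.

The free parameters above (w, mode counts, noise levels) were fixed once
so the default cohort lands in the empirically reported regimes for this
paradigm — within-category mean R around 0.1–0.4 ordered FT > PV > WR,
between-category means below them, per-category correct rates roughly
45–90 % ordered FT > PV > WR — and are not adjusted per analysis.

What the generator does **not** model: biophysical BOLD nonlinearity,
cardiac/respiratory quasi-periodicity, motion, susceptibility dropout,
anatomical structure, or between-subject differences in brain geometry
(all subjects share one grid, so template-space registration is out of
scope by construction). Passing tests on synthetic cohorts therefore
demonstrate the correctness and internal consistency of the measurement
chain under a plausible signal model, not performance on real scanners.

## Numerical choices and degenerate inputs

* Correlations are computed by centered dot products (voxels flattened in
  fixed C order), clipped to [−1, 1]; SC matrices are symmetrized and
  given an exact unit diagonal.
* Classification ties (measure-zero in floating point) break to the first
  label in the canonical WR < PV < FT order and are flagged.
* Constant templates, constant maps, zero-variance rate vectors and empty
  masks raise errors rather than propagate NaN.
* Block sd uses the sample (n − 1) denominator; single-value blocks
  report sd 0 with a `degenerate` flag.
* Group analyses use the intersection of subject masks.
* Between-category group blocks pair every subject's map for task A with
  every subject's map for task B (S × S pairs), the cross-subject analog
  of the 8 × 8 within-subject between-category blocks; cross-subject
  decoding classifies task-mean maps (24 test maps per reference subject
  in a 9-subject cohort).
* The ideal response can optionally be bandpassed like the data before
  correlation (`filter_template`); default off, since correlating a
  smooth template against filtered data already captures the intended
  co-fluctuation and filtering the template changes the measure's
  definition.

## Problem sizes in tests

Unit tests run on 14³-scale grids and short series; the acceptance checks
use full 288-volume runs on grids between 14 × 14 × 10 and the default
24 × 24 × 18 — small enough for a laptop-class single core while keeping
every design count (trials, pairs, combinations) at full size. The
complete suite runs in under a minute.

## Known limitations

* Pearson R between maps ignores spatial autocorrelation, so its null
  distribution on smooth maps is wider than the independent-voxel one;
  no autocorrelation-corrected null is provided (noted as future work).
* The critical-r threshold ignores temporal autocorrelation (see above).
* The trial window has no hemodynamic-lag offset option beyond choosing
  onsets; onset-aligned windows are the documented default.
* Real-data use assumes upstream registration and motion correction;
  the package performs none.
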