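# Methods

This note records the models, parameter choices and numerical conventions
behind `restid`, and what the synthetic-data tests do and do not establish.

## Signal model and preprocessing

Instances are consecutive, non-overlapping windows of `window_seconds`
(default 1 s) cut from the start of each recording; a trailing remainder is
dropped, so a 60-s run at 160 Hz yields exactly 60 instances.  The common
average reference (CAR) subtracts the instantaneous across-channel mean from
every channel.  CAR is applied **per instance over the full montage**, after
segmentation: this keeps instances self-contained, and computing the average
over all recorded channels (not just the channels a chromosome later
selects) is what makes per-channel feature caching valid — the reference,
and hence every channel's feature block, is independent of the channel
subset under evaluation.  No filtering, resampling or artifact rejection is
applied; EDF physical units (microvolts) are taken at face value.

## Decomposition

**EMD.**  Sifting uses cubic-spline envelopes through the local maxima and
minima with natural boundary conditions and mirrored-extrema end extension
(up to two extrema reflected about each window edge).  An IMF is accepted
when the Cauchy-type criterion Σ(h_prev − h)² / Σh_prev² falls below 0.2 or
after 100 sifting iterations; decomposition stops at a monotone residual or
10 IMFs.  These internals (spline type, end handling, stopping constants)
are standard defaults of the EMD literature, exposed in
`DecompositionConfig`; they are choices, not uniquely determined by the
method's definition.  Because each IMF is subtracted from the running
residual, `Σ IMFs + residual` rebuilds the input to machine precision by
construction.  The two IMFs closest to the raw window under the Minkowski
distance (order p = 2 by default; p is not dictated by the method and is
configurable) become the feature bands, in ascending-distance order; if
sifting yields fewer than two IMFs the residual is appended so the feature
vector keeps fixed width.

**DWT.**  `bior2.2`, three levels, symmetric extension, via PyWavelets; the
bands are ordered `[D1, D2, D3, A3]`.  At 160 Hz these span roughly 40–80,
20–40, 10–20 and 0–10 Hz, so the four bands tile the physiological EEG
range.

## Features

Per band: log₁₀ mean squared amplitude (instantaneous energy), log₁₀ mean
absolute Teager–Kaiser operator |xₙ² − xₙ₋₁xₙ₊₁|, the Higuchi fractal
dimension, and the Petrosian fractal dimension.  Conventions worth stating:

* Energies are log₁₀-scaled so sub-bands of very different power live on
  comparable scales, with an epsilon floor (1e-12) preventing −∞ on silent
  bands.
* Higuchi uses k_max = 10 (capped at band length − 1 for the shortest DWT
  bands); a constant signal has zero curve length and returns 1.0 by
  convention.
* Petrosian counts strict sign changes of the first difference; zero
  differences break no run, so monotone and constant signals score exactly 1.
* No feature standardization is applied by default (`FeatureConfig.standardize`
  exists but is off); LOF is locally density-based and tolerates the mixed
  scales in practice.

Feature vectors concatenate the four features per band, bands within a
channel, then channels in mask order: 8 values/channel for EMD, 16 for DWT.

## One-class models and metrics

LOF is used in novelty mode: a query's local reachability density is
compared with that of its k training neighbors (scikit-learn backend,
cross-checked in the tests against a quadratic-time implementation of the
k-distance/reachability/lrd definitions).  The neighbor-search structure
(ball tree, k-d tree, brute force) cannot change the scores — the tests
assert backend agreement to 1e-9 — yet it is kept as an optimizer gene
because the encoding treats it as a first-class hyper-parameter.  **The
accept threshold is the one consequential convention the method definition
leaves open**: a score is accepted iff LOF ≤ 1.5, a widely used novelty
offset, configurable per `ModelSpec`; ties accept.  OC-SVM accepts iff the
RBF decision function is ≥ 0; ν and γ come from the chromosome's two decimal
genes, repaired away from zero by 1e-6.

TAR/TRR are unweighted means over subjects of per-subject acceptance /
rejection fractions (subject-weighted, not instance-weighted); each
subject's impostor pool is the union of all other subjects' *test* rows,
keeping train/test hygiene symmetric between genuine and impostor scoring.

## NSGA-III

Reference points: Das–Dennis lattice with p = 5 divisions for 3 objectives
(21 points against a population of 20).  Normalization translates by the
ideal point and scales by intercepts of the hyperplane through
achievement-scalarizing-function extremes, falling back to per-axis spread
(then unit scale) when the system is singular — degenerate fronts must not
crash the niching step.  Variation: binary tournament on (rank,
perpendicular distance); uniform crossover (0.9) and per-bit flips (1/66)
on the channel bits; SBX (η = 30) and polynomial mutation (η = 20, rate 0.1)
on real genes; integer genes are inherited parent-wise and mutated by
uniform resampling (rate 0.1).  All tie-breaks (argmin collisions,
tournament ties, niche choice) use the run's seeded generator, so a seed
fixes the entire trajectory.  Offspring with empty channel masks are
repaired by setting one random bit.  Fitness values are memoized on the
genotype, which matters because the population revisits good chromosomes
often.

Termination follows an objective-space tolerance of 1e-4 evaluated every
10th generation — the run stops when the first front's ideal and nadir
points both move at most that much between checks — with a hard cap of 300
generations.

One property deliberately *not* asserted strictly: the hypervolume of the
population's first front is not guaranteed monotone under niching, because
when the combined front exceeds the population size the niche-count rule may
trade a boundary member for diversity (observed dips ≈ 0.02% relative on
DTLZ1).  The tests therefore assert exact monotonicity for the archive of
all evaluated points and near-monotonicity (0.1% slack, with strict overall
improvement) for the population front.

## Channel-selection experiments

"Ten-fold cross-validation" is implemented as its operational meaning here:
10 independent runs, each with a fresh uniform 80/20 per-subject split (60
instances → 48 train / 12 test).  The split is frozen for all generations of
a run so the objectives are stationary during evolution.  Reported tables
take, per run and channel count, the Pareto record maximizing TAR + TRR
(the "best trade-off" reading of a front), then mean ± SD over runs.
Channel-occurrence maps count channel appearances in Pareto records,
stratified by montage size, as tables; no topographic plotting.

## Synthetic cohort

The generator emulates what the pipeline needs from resting-state EEG and
nothing more: per-subject **stationary** signals in which a designated
channel subset carries a subject-specific signature (two sinusoidal tones;
the dominant tone is unique per subject, drawn from a shuffled 5–38 Hz grid;
amplitudes U(6, 10) µV), all channels carry 1/f-shaped noise (σ = 2 µV), and
a 15 µV, 50 Hz common-mode sinusoid rides on every channel so CAR is
exercised (the tests verify ≥ 20 dB attenuation).  The default test cohort —
12 subjects × 8 channels × 60 s at 160 Hz with channels {2, 5} informative —
was calibrated once, via `cohort_separability_check`, into the "separable"
regime (full-channel LOF TAR/TRR ≥ 0.95; measured 1.000/0.979): large enough
to exercise niching, small enough to keep the suite in minutes on one CPU.
The end-to-end tests and the acceptance script run 3 optimization runs of
≤ 30 generations with population 20 at this size.

What passing does and does not show: the synthetic signatures are stationary
narrowband processes, so recovery of the planted channels demonstrates that
the feature chain, one-class models and optimizer interact correctly — it
does not demonstrate robustness to non-stationarity, artifacts,
session-to-session variability or volume-conduction correlations of real
EEG, which only real recordings can test.  CAR also leaks an attenuated copy
of the signatures into noise channels (−1/n of each channel's signal enters
the average); at the default sizes this leakage sits ≈ 10 dB below the noise
and does not make noise channels competitive.

## Degenerate inputs and edge rules

Single-channel CAR yields zeros (valid).  Constant bands: energies floor at
log₁₀(1e-12), both fractal dimensions return 1.  LOF with duplicated
training rows fits and scores via the same reachability conventions as
scikit-learn.  A chromosome whose model cannot be fitted (e.g. a neighbor
count reaching the training-set size on an unusually small split) is scored
worst-case (n_channels, 1, 1) and logged rather than aborting the run.

## Known limitations

EMD end effects and mode mixing are handled only by the standard mirror
extension — ensemble variants are out of scope.  The LOF threshold (1.5) and
Minkowski order (2) are conventions, not fitted; results at other values are
a configuration flag away.  OC-SVM with default ν, γ is known to reject
roughly half the genuine instances unless the optimizer tunes the genes;
that behavior is reproduced, not "fixed".  The EDF writer is minimal
(16-bit, 1-s records, integer sampling rates) and intended for fixtures and
synthetic export, not clinical interchange.
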