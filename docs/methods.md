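# Methods

`leverhold` analyzes extracellular single-unit activity recorded while
mice perform a self-paced lever hold-down ("action differentiation")
task, and ships a generative model of the same task so every stage of the
analysis can be validated end-to-end against known ground truth.

## The task and its data model

A press is the half-open interval `[onset, offset)`; a spike exactly at
the offset belongs to the post-press epoch. A press *succeeds* when its
duration strictly exceeds the session's hold criterion (800 or 1600 ms);
reward is delivered at the offset of successful presses, and the reward
timestamp is identified with that offset (delivery latency 0 in the data
model — any hardware latency is absorbed into the outcome epoch).
Sessions end at 60 rewards or 90 min. Behavioral timestamps live on a
10-ms grid; spike times are unconstrained. Zero-duration presses are
forbidden; nothing shorter than the 10-ms grid can be represented.

## Event-aligned firing-rate analysis

For each unit and task event (press onset, press offset, reward
delivery):

1. **PETH.** Spikes are counted in 20-ms bins over ±10 s around each
   event and averaged across events (Hz). The task is self-paced, so
   event windows may overlap and a spike may count toward several events;
   no events are excluded for proximity.
2. **Smoothing.** A 3-tap Gaussian-weighted moving average,
   `[w, 1, w] / (1 + 2w)` with `w = exp(-1/(2σ²))`, σ = 0.4 bins
   (configurable). At the array edges the kernel is truncated and
   renormalized, so constants are preserved everywhere.
3. **Baseline.** The 400 smoothed bins from −10 s to −2 s before *press
   onset* form the baseline distribution: mean, sample SD, and an
   empirical 2.5/97.5-percentile interval. The same press-onset baseline
   serves all three alignments of a unit (one baseline period per unit).
   The "95% confidence interval" is percentile-based by default; a
   parametric mean ± 1.96·SD variant is available in the configuration.
4. **Modulation detection.** Within −2 s to +3 s of the event, a unit is
   *up-modulated* if ≥ 4 consecutive bins exceed the upper baseline
   bound, *down-modulated* if ≥ 4 consecutive bins fall below the lower
   bound (both rules consecutive, symmetric). If both patterns occur the
   earlier qualifying run decides the headline direction (tie → up) and
   both flags are retained. Onset latency is the left edge of the first
   bin of the first qualifying run. Comparisons are strict, so a
   degenerate (zero-SD) interval classifies any deviation.
5. **z-scoring and summaries.** PETHs are z-scored against the baseline
   mean/SD. With SD = 0, on-mean bins get z = 0 and any off-mean bin
   flags the trace undefined; undefined traces are excluded from
   population averages with a logged warning. Epoch summaries average z
   in four consecutive 250-ms bins of the pre-onset (−1000, 0), post-
   offset (0, 1000) or post-reward (0, 1000) epoch; because 250/20 =
   12.5, each 250-ms bin holds the 12 or 13 twenty-ms bins whose left
   edge it contains. Group traces are unweighted means ± SEM across
   units, with up- and down-modulated units combined.

## Within-press dynamics

Presses are split into within-session duration quartiles by rank
(ties broken by press order, remainder to the earliest quartiles), which
guarantees counts balanced within one and is unambiguous under ties;
reported boundaries are the maximum duration in Q1–Q3. Each press is cut
into four equal-duration segments. Two summaries:

* **segment spike proportions** — segment count over total in-press
  count; presses without in-press spikes are excluded from per-unit means
  (0/0) but kept in the spike-presence denominator;
* **quartile segment profiles** — segment *rates* (count ÷ quarter
  length, so quartiles of different durations are comparable) z-scored
  against a baseline window of length equal to the quartile's mean press
  duration immediately before onset, binned at ~20 ms and pooled across
  the quartile's presses for SD stability. Quartiles with zero pooled
  baseline SD are flagged and excluded from group means.

## Pseudo-population decoding

Sessions with fewer than 10 successful presses are excluded. For each
resampling run every eligible unit independently draws `n_per_class`
success and failure events without replacement (default: the minimum
per-class count across units, optionally capped); the k-th drawn event of
each unit forms pseudo-trial k. Rasters are binned at 1 ms over −2 s to
+10 s around the aligned event. At 100-ms steps, 200-ms-window rates are
fed to a linear maximum-margin classifier (SVM, C = 1 by default) with
10-fold stratified cross-validation; features are z-scored per unit by
training-fold statistics so no test information leaks. Accuracy is the
mean over folds and runs (500 runs by default). Null distributions repeat
the procedure with labels permuted once per run (5 nulls × 500 runs by
default). Significance per time point is the empirical one-sided
`p = (1 + #{null ≥ observed}) / (1 + N_null)` over the pooled null runs,
reported raw and Benjamini–Hochberg-corrected across time points.

Notes. (1) Units pooled across sessions and animals form the
pseudo-population; within-session noise correlations are not preserved —
an inherent limitation of the approach. (2) The pooled-null p compares a
run-averaged accuracy with run-level null accuracies; under the null this
p concentrates near 0.5, so the raw mask is conservative at chance.
(3) BH significance is attainable only when the pooled null count N
satisfies `1/(N+1) ≤ α/m` for m time points; configurations should size
their null runs accordingly.

## The generative model

**Behavior.** Alternating exponential inter-press intervals (mean 9 s)
and log-normal hold durations (median 1100 ms, σ = 0.55 in log-space),
snapped to the 10-ms grid; strict-exceedance reward; termination at 60
rewards or 90 min. With the default 1600-ms criterion the log-normal tail
gives P(success) ≈ 0.25, matching the ~25% rewarded presses typical of
late training; sessions reach 60 rewards in roughly 40–50 min.

**Spiking.** Inhomogeneous Poisson by thinning: candidates are drawn at a
dominating rate above the scanned maximum of the rate profile and
accepted with probability rate/bound. The instantaneous rate is the
baseline rate multiplied by

* Gaussian gain kernels anchored to press onset, press offset, or reward
  (peak gain > 1 up, < 1 down; multiplicative across overlapping events so
  down-modulation can never produce negative rates);
* a hold-suppression profile during the press: constant depth with a
  linear pre-release ramp over the final quarter of the hold (the
  U-shaped within-press profile), and optionally deepening with duration
  (`depth · exp(−k · duration)`), so longer holds are more suppressed;
* an outcome gain over the first second after release, allowed to differ
  between successful and failed presses.

Firing-rate magnitudes are free parameters, not measurements: the default
prior draws log-normal baseline rates (median 8 Hz), gives each anchor a
kernel with probability 0.6 (up with probability 0.65; up gains 1.8–3.0,
down 0.2–0.6; widths 100–250 ms; latencies −400 to +200 ms, allowing
preparatory pre-onset activity), hold depths 0.4–0.9 with deepening
0.2–0.6 /s, and success outcome gains 1.4–2.2 against failure gains
0.9–1.2. A configurable ceiling (500 Hz) rejects parameter sets implying
implausible peak rates.

**Group effects.** Air is the reference; CIE scales the *excess* gain of
press-anchored kernels by 1.5 and of reward-anchored kernels and outcome
gains by 0.5 (`g' = 1 + (g − 1)·m`, direction-preserving), encoding
stronger action-related but weaker outcome-related modulation after
chronic ethanol exposure.

**RNG design.** All randomness flows through named `SeedSequence`
substreams. Behavior and unit-parameter streams are keyed by (mouse,
unit) but not group; spike-noise streams are keyed by (group, mouse,
unit). The groups are therefore yoked (common random numbers): every CIE
unit has an air twin with identical parameters before the group effect,
which makes group contrasts low-variance and their signs stable at
desk-scale cohort sizes without altering marginal statistics. Adding
mice or units never changes earlier draws.

**What the generator does not emulate.** Learning across days, bursting
and refractory structure, non-Poisson count dispersion, within-session
noise correlations between units, licking/consumption micro-behavior,
and electrode drift. Passing tests therefore demonstrate that the
analysis recovers what this model injects — not that it is robust to
every property of real recordings.

## Problem sizes and numerical choices

The validation suite runs everything at desk scale, chosen to keep
Monte-Carlo error well below each tested margin: cohorts of 5 mice ×
10 units per group; detector calibration on 500 homogeneous 5-Hz units
against a 10,000-replicate independent oracle; detector power on 50
units with a 2.5× onset kernel; decoder chance calibration with 500
observed runs and 5 × 150 null runs at 1-s steps; decoder recovery with
30 units, 40 events per class, 30 observed and 5 × 60 null runs at
500-ms steps over −1.9 s to +2.1 s. `scripts/acceptance.py` uses the
same cohort scale with 12 decoding runs per group and alignment. The
full-protocol settings (500 runs, 5 × 500 nulls, 100-ms steps over the
whole window) remain the configuration defaults.

Other numerical choices: onset-latency ground truth for power tests is
the analytic first crossing of the injected rate profile above the
unit's baseline bound (a Gaussian bump's detectable onset precedes its
peak); percentiles use linear interpolation (NumPy default); CSV writers
print doubles with `%.17g` and readers parse with round-trip precision so
dataset round-trips are bit-exact; degenerate CV folds (one class) are
skipped and logged; zero-SD feature dimensions are left unscaled.

## Known limitations

* The pseudo-population discards noise correlations; reported accuracies
  are not estimates of simultaneous-population decodability.
* The percentile baseline interval is computed from 400 trial-averaged
  bins; with very few events it is noisy and detection power drops.
* One session per simulated mouse; multi-session pooling is supported by
  repeated generator calls with linked seeds but not exercised by default.
* The devaluation machinery computes normalized response rates and
  exclusions only; omnibus repeated-measures statistics are exported as
  tidy tables for external tools.
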