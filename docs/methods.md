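# Methods

## The problem and the data model

A nanopore sequencer (MinION class) was run during a parabolic flight
while a triaxial accelerometer recorded the gravito-inertial environment.
The analysis asks three questions: does g level affect read quality, does
vibration affect per-base ionic-current noise, and does flight affect
per-base translocation time? Answering them requires merging two streams:

* **Acceleration**: `gx, gy, gz` at a fixed sample rate (5 kHz by
  default), in Earth-g units, starting at the accelerometer's elapsed
  time t = 0.
* **Event-aligned reads**: for each read, a channel, start time on the
  instrument clock, a mux flag, and per-base records — genomic position,
  event length in raw-signal samples, normalised signal mean/SD, and a
  Phred quality. The normalised signal SD (`norm_std`) is the per-base
  ionic-current noise measure; this package treats it as an opaque
  nonnegative value produced by a signal-to-reference aligner and does
  not re-derive signal normalisation.

## Vibration processing

The magnitude `g = sqrt(gx² + gy² + gz²)` is orientation-independent
(rotations preserve norms), so sensor mounting does not matter. Vibration
is isolated with a high-pass whose design targets are: stopband edge 5 Hz
at 60 dB attenuation, passband edge 10 Hz, unity ripple (read as 1 dB),
sample rate 5 kHz. The filter family is the minimum-order elliptic IIR
meeting those targets — the family a specs-driven design tool returns —
realised as second-order sections for numerical stability; the design
lands at order 5 with 60.003 dB at the stopband edge. It is applied
forward and backward, so the effective response is |H|² (stopband
attenuations double in dB) with exactly zero phase delay; edge transients
are handled with odd-reflective padding of 3× the filter order. Because
the cutoff is near DC the edge transient of a broadband signal decays
over a few seconds, so time-reversal symmetry of the filtered output
holds in the interior of a recording but not at its edges — binned
statistics are unaffected, since the first and last bins of a session are
never analysed in isolation here.

RMS vibration is computed over consecutive 1-s bins aligned to t = 0,
dropping a trailing partial bin. PSDs use Welch's method with
pwelch-style defaults: 8 segments, 50 % overlap, Hamming window,
one-sided density (the original tool's "default parameters" leave the
exact segment count unrecoverable; ours is documented and configurable).

## Flight-phase segmentation

The segmentation procedure itself comes from a prior campaign and is not
fully specified in the present study, so the defaults here are this
package's design: the magnitude is block-averaged to a 20 Hz profile
(vibration averages out; the subsequent moving median becomes cheap),
smoothed with a centred 1-s moving median, and thresholded:

* hypergravity: smoothed g ≥ 1.2 sustained ≥ 2 s;
* parabola: smoothed g < 0.5 and within ±0.07 of the nearest configured
  target in {0, 0.166, 0.378}, sustained ≥ 5 s; the period's target is
  the nearest configured target of its median smoothed g, ties broken
  toward the lower g;
* transition: any gap between a hypergravity period and an adjacent
  parabola period;
* other: the remainder. All thresholds are configurable
  (`SegmentationParams`).

Periods are half-open, non-overlapping, and tile the analysed interval;
a quiet trace yields a single "other" period. The `periods.txt` dialect
is a TSV with `start_s, end_s, label, target_g` (target empty outside
parabolas).

## Sequencing metrics

* `q_p̄ = −10 log₁₀(mean(10^(−q/10)))` over a read's per-base Phreds.
  Averaging on the probability scale makes the statistic sensitive to the
  worst bases: by Jensen's inequality q_p̄ ≤ mean(q), with equality only
  for constant quality.
* Translocation time per base is `1000 · event_len / f_signal` ms. The
  raw-signal rate is not stated alongside the event data; the package
  defaults to 4 kHz (the standard MinION digitisation rate), under which
  a 7-sample event is 1.75 ms — consistent with the reported ~1.8 ms
  median at its printed rounding. The rate is configurable everywhere.
* Per-base timestamps are the read start plus cumulative preceding event
  samples over the signal rate; genome coordinates are 0-based half-open
  throughout.
* Coverage of a flight phase is the number of aligned bases whose
  timestamps fall in the period, divided by the genome length (48,502
  for phage lambda).

## Timeline integration

Read/base clocks are shifted onto the accelerometer clock by a configured
offset (generator-known in synthetic runs). A read belongs to a phase
only if its whole interval lies inside one period (closed containment);
otherwise it is "spanning". Boundary ties go to the earlier interval.
Joint 1-s bins carry the median q_p̄ over reads overlapping the bin, the
median `norm_std` over bases inside the bin, the RMS vibration, the mean
magnitude (g level), and the phase at the bin midpoint (bins can straddle
period boundaries; midpoint is a deterministic, documented choice).
Regressions run on bins truncated to elapsed time ≤ 4000 s inclusive, to
avoid the descent/landing tail; empty bins carry NaN medians and are
dropped listwise per regression.

## Statistics

* **Stepwise regression**: intercept-only start; candidates are the named
  main effects plus all pairwise interaction products. At each step the
  candidate with the smallest partial-F p-value below 0.05 enters; adding
  an interaction pulls in any missing parent main effects (the model
  stays hierarchical, and the entry test is then a multi-column partial
  F); afterwards any term with partial-F p above 0.10 leaves, except
  mains locked by an included interaction. The search stops when no move
  is possible or a model state repeats. Under a global null each
  candidate's entry p-value is uniform, so the probability of an
  intercept-only outcome is about (1 − 0.05)^k for k effective
  candidates — with three mutually correlated flight covariates this sits
  near 0.9, which the test suite checks as a rate, not per run.
* **ANOVA / Tukey**: classic between/within decomposition; Tukey–Kramer
  intervals use the studentized-range distribution (scipy's numerical
  implementation) with the ANOVA residual df, valid and conservative for
  unequal group sizes. For two groups the statistic reduces to √2·|t|,
  giving back the pooled t-test p — used as a closed-form cross-check.
* **Kolmogorov–Smirnov**: two-sided, asymptotic p (the dwell samples are
  in the 10⁵–10⁷ range; exact small-sample p is out of scope).
* **MAD outliers**: flag when |x − median| / (1.4826 · MAD) > k
  (default 3); when MAD = 0 any value differing from the median is
  flagged.
* Degenerate inputs (single group, zero within-group variance, constant
  regressors, empty samples) raise typed errors or return the documented
  infinite-F guard.

## Synthetic generators

**Flight.** The low-frequency profile is built from plateaus joined by
3-s cosine ramps: cruise at 1 g, pull-up/pull-out arcs at 1.8 g, and
parabola plateaus at the target g. The flown schedule is the default:
four sets of 5, 6, 4, 5 parabolas, the first set targeting Mars, Mars,
Lunar, 0, 0 g and all others 0 g. Zero-g plateaus sit at a residual
0.041 ± 0.005 g, as real parabolas do. Parabola plateau durations are
target-dependent (22 / 26 / 33 s for 0 g / Lunar / Mars) with a ±10 s
uniform jitter per parabola; the spread is chosen so that duration
variance dominates read-sampling variance in the per-parabola coverage
regression, which is the regime the coverage–duration analysis probes
(expected adj. R² ≈ 0.85 at the default read model). Vibration is a sum
of narrowband sinusoids (default peaks near 120, 260, 495, 620, 876 Hz,
jittered ±2 Hz per seed to avoid bin-exact artefacts) plus broadband
Gaussian noise, scaled to half RMS during parabolas (freefall is the
quietest phase). The vibration vector is distributed over the three axes
with most weight on the profile axis, so the filtered magnitude carries
the planted RMS to within a few percent. Ground truth is the exact
construction intervals, with hypergravity defined as where the ideal
profile is ≥ 1.2 g (ramp tails above threshold belong to the arc) so
that threshold-based segmentation and truth agree to well under a
second.

**Reads.** Read starts form a Poisson process (default 3 reads/s, the
order of the flight session's ~18k reads over ~100 min); lengths are
lognormal (mean 6 kb, matching the library's fragmentation target). Per
base: dwell from a lognormal parameterised by (median, mean) —
σ² = 2 ln(mean/median), μ = ln(median) — giving the long right tail seen
in dwell distributions, with an inverse-Gaussian alternative; defaults
median 1.8 ms with mean 2.2786 ms (ground) or 2.4035 ms (flight). Dwells
are discretised to integer signal samples (`max(1, round(·))`), which
reproduces the 7-sample granularity and biases the realised mean by well
under 0.005 ms. Phred qualities are rounded clipped normals
(mean 9.5, sd 3), which puts q_p̄ near 8.5 — inside the study's 8.3–8.7
phase range; `norm_std` is lognormal with mean 0.28. Optional linear
effects couple dwell/quality/noise to phase, elapsed time, and binned
RMS vibration; they are applied at provisional timestamps computed from
the uncoupled dwells, an approximation that is excellent for the small
planted shifts used. Reads starting in the first 90 s are flagged mux.

**What the generators do not emulate.** Pore-state dynamics, channel
blocking and recovery, basecalling errors correlated along a read,
k-mer-dependent current levels, clock drift between instruments, and any
mechanistic coupling of vibration to the pore. Passing tests therefore
show that the pipeline recovers what the generative model plants under
realistic magnitudes and schedules — not that real sequencing hardware
behaves this way.

## Problem sizes and numerical choices

The default test and analysis runs are scaled to desk size as the
package's own choice of problem size: segmentation-recovery flights are
generated at 2 kHz (all default vibration peaks stay below Nyquist); the
end-to-end session uses 500 Hz with peaks moved to 60/120/200 Hz and
2-kb reads (~10⁷ bases); KS recovery uses 10⁵ bases per arm; the
stepwise null calibration uses a one-set flight with 500-base reads over
50 seeds. Full 5 kHz defaults are exercised in targeted unit tests.
Other numerics: filters run as SOS cascades; OLS fits use `lstsq` with a
rank check (collinear candidates are skipped during stepwise search and
a singular final design raises, naming the constant term where it can);
studentized-range accuracy follows scipy (well below 1e-6 in p); ties in
stepwise entry resolve by candidate order; the periods reader/writer
round-trips at millisecond precision.

## Known limitations

* The segmentation thresholds are this package's defaults, not the prior
  campaign's exact values; they reproduce the four-phase vocabulary and
  named g levels but are not claimed to match the original boundaries.
* The event table carries no raw current; resquiggling, basecalling, and
  alignment are upstream and out of scope.
* The asymptotic KS p-value is inaccurate for very small samples.
* Offsets between instrument and accelerometer clocks must be supplied;
  there is no drift estimation.
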