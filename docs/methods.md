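# Methods

This note documents the models, algorithmic conventions, and numerical
choices behind `caldrift`, and what the synthetic benchmarks do and do not
establish about real data.

## Study design emulated

Eight recording days on calendar days 1, 3, …, 15; two linear-track
environments (A, B) per day; five 3-minute trials per session; 20 Hz
imaging; a 96 cm track analyzed in 24 bins of 4 cm with the two bins at
each end (reward zones) excluded. All defaults live in `SimConfig` and are
plain constructor arguments.

## Synthetic generator

The generator is a minimal mechanistic stand-in for the drift
phenomenology the analysis assumes: decaying ensemble correlations within
and across environments, stable place fields for recurring cells, and
distinct spatial maps per environment.

**Behavior.** Constant-speed laps (`run_speed`, 20 cm/s) with
exponentially distributed dwell epochs at both track ends (`pause_mean`,
2 s) — the dwells exercise the > 1 cm/s speed filter and the end-bin
exclusion downstream. Behavior is identical in distribution across days by
design; the drift analyses assume stable behavior.

**Recruitment.** Each cell carries an independent two-state Markov chain
per environment over recording days: persistence
`recruitment_persistence` (P(active → active per 2-day step), default
0.8) and stationary occupancy `active_fraction` (default 0.6), from which
the recruitment probability of inactive cells follows as
`π(1−p11)/(1−π)`. The k-step closed form
`P(active at d+k | active at d) = π + (1−π)(p11−p01)^k` is tested by
Monte-Carlo.

**Rates.** Cell n's log event rate in environment E on day d is

    log λ = base_n + g_{n,E} + η_{n,d} + ζ_{n,d,E}

with `base_n` log-normal around `base_rate` (0.05 events/s while active,
spread 0.4), a **static environment gain** `g` (`env_gain_sigma`, 0.4) —
persistent rate remapping, giving within-environment session pairs a
lag-independent correlation advantage over across-environment pairs — a
**shared random walk** `η` (`shared_drift_sigma`, 0.25 per calendar day)
common to both environments, and an **environment-specific walk** `ζ`
(`env_drift_sigma`, 0.12). Walk increments scale with the square root of
the calendar gap. The shared walk is the only cross-environment
time-varying component: switching it off removes across-environment day
decoding entirely (the falsification control), while each environment's
own drift remains decodable.

**Tuning.** A configurable fraction of cells (0.5) are place-tuned with
Gaussian fields (`field_width` = 10 cm FWHM), centers uniform outside the
excluded end bins, drawn independently per environment when `remap_mode`
is set (global remapping) and identical otherwise. Tuning curves are
normalized to unit track-average gain so `λ` is the mean running rate.
Field centers never move across days — the generator's stable-field
assumption.

**Events, traces, footprints.** Events are an inhomogeneous Poisson
process (per-frame thinning) with log-normal amplitudes (`amp_median`
0.3 ΔF/F, `amp_sigma` 0.35). Traces are amplitude-weighted impulses
convolved with a unit-peak double-exponential kernel (rise 0.2 s, decay
0.75 s) plus white noise (`noise_sigma` 0.02 ΔF/F); event times are
recorded at impulse onset while detection reports the fluorescence peak,
which lags onset by `τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r)` ≈ 0.36 s at the
defaults. Footprints are Gaussian blobs whose 50%-of-max contour sits at
`footprint_radius` (8 µm), placed by dart-throwing with ≥ 20 µm centroid
separation in a 400 µm field of view and jittered per session
(`footprint_jitter`, 2 µm/axis). Only cells active in a session get a
footprint there, as with real extraction.

All randomness derives from one root seed through named substreams
(`substream(seed, name)`), so stages are reproducible independently; a
fixed seed yields bit-identical datasets.

**What the generator does not emulate.** Behavioral variability and
direction-dependent tuning asymmetries; bursty within-field spiking beyond
Poisson; correlated noise and neuropil contamination in traces; non-rigid
tissue deformation; experience-dependent (as opposed to time-dependent)
drift. Passing tests therefore demonstrate correctness of the analysis
under the stated model, not decoder performance on any real recording;
accuracies measured on real data depend on that data's cell counts, rates,
and drift magnitude and are not reproduction targets here.

## Event detection

1. **Preprocessing** — subtract a 20 s sliding-median baseline
   (reflect-padded; nearest-padding biases the baseline one-sidedly near
   the trace ends and inflates edge false positives), then a zero-phase
   2nd-order Butterworth low-pass at 2 Hz.
2. **Thresholding** — candidate peaks must exceed `mad_threshold` (4 slow
   indicator / 5 fast) times the raw median absolute deviation of the
   preprocessed trace. MAD carries no 1.4826 normal-consistency factor:
   the integer multipliers absorb it. A flat trace (MAD = 0) yields no
   events rather than a division error.
3. **One event per transient** — a peak following an accepted event must
   rise `peak_over_prev` MADs above the intervening trough (otherwise it
   is a shoulder on the decay); a peak closer than `peak_over_next` MADs
   to a higher upcoming peak with a shallow trough between is a shoulder
   on the rise and yields to that peak.
4. **Kinetics** — rise and decay times are measured at 20%-amplitude
   crossings (half-amplitude times are biased toward symmetry by the
   zero-phase low-pass; 20% crossings recover the true decay-to-rise ratio
   of the kernel, ≈ 3.5 measured vs 3.75 nominal). The implied decay
   constant must fall within `decay_bounds` (0.2–5×) of the indicator
   decay and the decay-to-rise ratio must reach `decay_rise_ratio_min`
   (2). Transients truncated by the trace end pass (no decay evidence
   against them).
5. **Crosstalk** — cells with centroids < 18 µm apart are neighbors.
   Neighbor pairs whose 100 ms-binned event trains correlate above 0.9
   lose the lower-mean-amplitude member entirely (computed on the
   pre-pruning trains, so a fully shadowed duplicate is still detected as
   such). Among remaining neighbor events within |Δt| ≤ 200 ms (closed
   interval), only the highest peak survives, resolved greedily by
   descending amplitude.

With defaults and well-separated planted transients at ≥ 8× the noise MAD,
detection achieves precision and recall ≥ 0.9; bursts of same-cell events
closer than the transient width merge into one detection by construction.

## Registration

Footprints are thresholded at 50% of max (sub-threshold pixels exactly
zero, largest connected component kept); filters with equivalent radius
outside 5–14 µm or circularity `4πA/P²` below 0.8 are discarded.
Sessions are aligned to the first session by a rotation scan (coarse 0.5°,
refined 0.05°) with subpixel phase-correlation translation on blurred
centroid-projection images. Matching uses either footprint Pearson
correlation in the common frame (> 0.7) or centroid distance (< 5 µm),
with *global greedy* assignment by score when candidates compete — the
source is silent on tie handling; greedy-by-score is deterministic and
order-independent after sorting. Unmatched cells found in any session open
singleton master ids, which the per-session activity accounting requires.
Diagnostics reproduce the expected regime on synthetic data:
within-session nearest neighbors always correlate < 0.6 and lie > 6 µm
apart, and the candidates-per-cell curve is flat (≈ 1) across correlation
thresholds 0.5–0.85 at low jitter. Downstream decoder accuracy agrees
within 5 percentage points between the two methods on a fixed dataset.

## Place analysis

Occupancy and event-count maps (running epochs only, per direction) are
smoothed with a truncated Gaussian (σ = 1.5 bins, 5 bins) before division;
spatial information uses the *unsmoothed* rate map over the 20 valid bins,
with 0·log 0 ≡ 0. Field position is the smoothed map's peak (ties → lowest
bin). The shuffle test redraws each event's position from the session- and
direction-specific occupancy distribution (an occupancy-weighted
independent redraw; a circular-shift variant would preserve event
autocorrelation but the event-count maps the statistic uses carry none)
and uses the `(1+k)/(1+N)` p-value estimator so p never reaches 0; cells
with ≤ 5 events are ineligible. The test is calibrated: occupancy-null
cells are rejected at ≈ 5% at p ≤ 0.05.

Field-shift nulls shuffle cell identities independently on each day,
pooling displacements over shuffle pairs. Population-vector correlation
averages per-bin Pearson correlations over valid bins, skipping bins with
a zero-variance vector (Pearson undefined; skipping matches averaging over
positions with defined values). Because two linear tracks admit two
end-to-end correspondences, cross-environment comparisons evaluate both
and keep the higher global mean; that chosen alignment also feeds peak
displacement.

## Drift statistics

Rates are per minute of session; divergence and CV are unit-free. "Active
in a session" means ≥ 1 detected event. Zero differences (ties) break
monotonic runs and count for neither side of the monotonicity score —
consistent treatment of ties in both statistics. The recurrence curve
conditions on activity in one environment on the earlier day (a switch
selects the stricter both-environments conditioning). The Poisson CV null
matches each always-active cell's mean count; note the sample standard
deviation over 8 sessions carries the c₄(8) ≈ 0.965 small-sample factor,
so the null mean CV is c₄(8)/√λ, not 1/√λ. The population-monotonicity
curve aligns each cell to its peak day (ties → earliest) after
max-normalization; at |lag| ≥ 5 only cells peaking on edge days
contribute, a selection effect that makes the extreme tail non-monotone
even at large n — decay is therefore asserted strictly over |lag| ≤ 4 and
as a near-vs-far trend beyond.

## Time decoders

Correlations are Pearson over the full master cell list, zeros included;
a zero-variance test vector skips that item with a log entry. Argmax ties
break toward the earlier day. The normalization expectation `E_{d'}` runs
over all eight days including the test day, exactly as defined. The
across-environment trial form subtracts the *same* trial index from each
training session, mirroring the within-environment exclusion. Day errors
are counted in recording-day steps (one step = 2 calendar days). Segment
decoding restricts the *test* vector to a contiguous window with a seeded
random offset; training patterns stay whole-trial.

**Chance control.** `shuffle_day_labels` permutes each cell's across-day
sequence independently (trial columns move with their day), preserving
each cell's multiset of per-day patterns. Decoding a shuffled tensor
against itself is *not* a chance control: each cell's test trial moves
together with its own session, leave-trial-out stays self-consistent, and
accuracy remains perfect (verified). The control therefore decodes the
original test trials against shuffled training patterns, which converges
to the 1/8 chance level. Per-shuffle accuracies are over-dispersed
relative to independent trials (trials within a shuffle share its
permutations), so calibration is asserted at the empirical standard error
over ≥ 20 shuffles.

## Problem sizes

Synthetic benchmarks default to 150–200 cells — enough that the default
drift regime saturates within-environment decoding and keeps
across-environment decoding clearly above chance — with 8 days × 2
environments × 5 trials throughout; Monte-Carlo properties average 6–10
generator seeds, closed-form checks use up to 2,000–10,000 simulated
cells, and shuffle tests use 400–1,000 shuffles. The acceptance script
runs the full chain at these sizes in well under a minute.

## Known limitations

- The generator's drift is purely time-dependent; it cannot dissociate
  time from accumulated experience.
- Event detection assumes a single kernel shape per indicator; mixed
  populations need per-cell kinetic bounds.
- Registration assumes rigid inter-session motion; non-rigid deformation
  is out of scope.
- The dedup rule operates on binned event trains (100 ms bins), a
  configurable interpretation (raw-trace correlation is an alternative).
- Inter-trial-interval activity is not modeled; all data lie within
  trials.
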