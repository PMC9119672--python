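# Methods

`pstnkit` quantifies three kinds of measurements made in appetite-circuit
experiments: bulk calcium signals recorded by fiber photometry,
feeding microstructure inferred from continuous bottle-weight traces,
and marker co-expression in sectioned tissue. This note documents the
models, the parameters that matter, and the choices made where the
underlying protocols leave room.

## Fiber-photometry dF/F

A trial consists of two demodulated fluorescence channels sampled on a
common clock: a 465 nm calcium-dependent GCaMP signal F and a 405 nm
calcium-independent control C, with the stimulus event at t = 0 and
negative times forming the baseline. Processing follows the order
*downsample, normalize, screen, measure*:

1. **Downsampling to 1 Hz.** Both channels are averaged independently
   over the non-overlapping bins [k, k+1) s, so one bin edge always
   coincides with the event and no bin mixes pre- and post-event
   samples. The output sample for bin k carries the label k. Averaging
   (rather than decimation) is used because it suppresses white noise
   by the square root of the bin occupancy.
2. **Normalization.** dF/F(t) = (F(t) − F_b) / F_b with F_b the median
   of the 465 nm samples in [−30, 0) s. The median makes F_b robust to
   brief baseline transients; because the dF/F map is affine, the
   median of dF/F over the baseline window is exactly zero, and the
   trace is invariant to rescaling the raw fluorescence (gain changes).
   No isosbestic regression is applied — the control channel is used
   only for screening.
3. **Artifact screen.** A trial is excluded when the 405 nm channel
   deviates from its own baseline-window median by strictly more than
   20% (peak fractional deviation, evaluated over the whole trace).
   Calcium-independent excursions of that size indicate motion or
   severe bleaching. The comparison is strict, so a deviation of
   exactly the threshold is retained; raising the threshold can only
   retain more trials.
4. **Metrics.** The peak response is the maximum dF/F over the closed
   window [0, 75] s (configurable; infusion experiments use longer
   windows). The area under the curve is the trapezoidal integral of
   dF/F from t = 0 to the first sample at which the trace returns to
   zero — the first sample strictly after the event with dF/F ≤ 0 for
   a positive-onset response, symmetrically ≥ 0 for a negative one.
   The crossing is not interpolated; integration ends at that sample,
   which keeps the metric deterministic on the 1 Hz grid. If the trace
   never returns, the integral runs to the end of the recording and
   the return time is reported as "never".

Group summaries average non-excluded trials on their common 1 Hz grid
and report mean ± SEM (sample SD over trials divided by √n; with a
single trial the SEM is reported as 0 and flagged undefined), plus the
trials × time matrix used for heat maps.

**A note on bin means and the AUC.** Downsampling produces bin means,
not point samples. For an exponential decay with time constant τ the
1 Hz trace therefore holds τ·A·(e^{−k/τ} − e^{−(k+1)/τ}) at label k,
and its trapezoid underestimates the continuous integral A·τ by about
half the first bin (≈ 2.7% for τ = 20 s), independent of the original
sampling rate. On un-downsampled traces the trapezoid converges to the
closed form as density grows, which is what the convergence tests
assert; the validation suite's noiseless 1 Hz trial is generated at
1 Hz, where bin means and point samples coincide.

## Meal microstructure

A scale under the liquid-diet bottle is sampled continuously (1 Hz by
default in simulation). The defining rules are: a meal is a net weight
decrease strictly greater than **0.02 g**, and bouts separated by less
than **15 s** count as one meal (a separation of exactly 15 s counts
as two). Detection proceeds in three stages:

1. **Bout finding with a dead band.** The trace is read through a dead
   band of half-width `noise_tol_g` (default **0.005 g**): the weight
   registers a movement only when it leaves the band around the last
   committed level. Jitter inside the band therefore neither starts,
   extends, nor ends a bout — which is what makes detection robust at
   realistic scale noise, where any amplitude-only tolerance lets
   noise-generated micro-bouts bridge the merge gap and fuse distinct
   meals. A bout begins at the sample preceding a committed downward
   movement, chains further downward movements, and ends when the
   weight commits an upward movement or stays inside the band for a
   full merge gap after the last downward movement (feeding stopped).
   With `noise_tol_g = 0` the dead band degenerates to exact
   strict-decrease semantics. Start/end weights of a bout bracket the
   true levels within one band half-width each, which bounds the size
   error of a recovered meal by 2·`noise_tol_g`.
2. **Merging.** Bouts whose gap (end of one to start of the next) is
   strictly less than the merge gap become one meal whose size is the
   total drop from the merged start to the merged end and whose
   duration spans the merge.
3. **Size filter.** Meals not strictly exceeding `min_meal_g` are
   discarded *after* merging, so nearby sub-threshold sips can jointly
   form a meal.

An enumeration-based re-derivation of the same semantics
(`pstnkit.reference`) exists purely for validation; the scanner and the
enumerator are checked for exact agreement on thousands of randomized
traces. One consequence of merge-before-filter worth knowing: shrinking
the merge gap can *reduce* the meal count, because two sub-threshold
drops that merged into one valid meal may fall below threshold
separately. Increasing `min_meal_g` only ever removes meals.

Downstream statistics: meals are assigned to an analysis window by
their start time (default: the first 3 h of a session); frequency is
meals per hour of window. Cumulative-intake curves and per-epoch totals
(e.g. 1 h pre-stimulation / stimulation / post-stimulation) attribute
each meal's mass uniformly in time across its duration, so a meal
straddling a boundary is split in proportion to time spent on each
side and totals are conserved. When an animal runs several sessions,
the per-animal mean of session totals is the unit of analysis. An
optional conversion reports kcal at 450 kcal/L and an assumed density
of 1 g/mL; grams are the default unit.

Evaporation and drift are handled only through the dead band; no drift
model is fitted. No slope-linearity criterion is applied within bouts
— the recordings' within-meal decreases are close to linear and the
defining rules above do not require a fit.

## Cell-count quantification

Counts arrive as a long-format table (`animal_id, section_id,
bregma_mm, class, count`) of exclusive marker classes per section —
for the two-marker design: `tac1_only`, `crh_only`, `both`. The
expected protocol is 18 sections per animal spanning roughly −2.3 to
−2.84 mm from bregma; deviations warn but do not fail.

- **Pooling.** Sections are summed within an animal before any ratio
  is formed (ratio of sums, not mean of ratios), which is robust to
  sparse sections. Group dispersion is always across animals: SD for
  co-expression panels, SEM for Fos co-activation panels.
- **Conventions.** Exclusive percentages (`pct_tac1_only`,
  `pct_crh_only`, `pct_both`) sum to 100 of labeled cells; inclusive
  marker totals (`pct_tac1`, `pct_crh`) count co-expressing cells
  toward each marker. Both are always reported because published
  overlap panels mix the two readings (a marker total alongside an
  exclusive complement); the defaults assert neither as canonical.
- **Abercrombie correction.** Profile counts over-count cells whose
  nuclei appear in two adjacent sections; the corrected count is
  N = n · T / (T + h) with T the section thickness (default 30 µm) and
  h the mean particle (nuclear) height along the cutting axis. h is
  preparation-specific and must be supplied by the user; h = 0 means
  no correction. The factor lies in (0, 1], is strictly decreasing in
  h, preserves count ordering, and — being class-independent —
  cancels out of every percentage, so correction matters only for
  absolute counts.
- Animals with a zero denominator for a requested ratio are excluded
  with a warning rather than poisoning the group mean.

## Synthetic data

The generators exist so every stage can be validated against known
ground truth without any recordings; each is fully deterministic given
its seed and emits the truth alongside the data.

- **Photometry** (`PhotometrySimConfig`): 465 = F0·bleach·(1 +
  transient)·artifact + noise and 405 = F0′·bleach·artifact + noise.
  The transient is a double-exponential kernel A·(1 −
  e^{−Δ/τ_r})·e^{−Δ/τ_d} (instantaneous rise when τ_r = 0) — a
  standard phenomenological shape for bulk GCaMP signals, chosen as a
  validation surface, not as a kinetic model of GCaMP6s. Defaults:
  20 Hz sampling, 60 s baseline, 120 s post-event, A = 0.3 dF/F,
  τ_r = 0, τ_d = 20 s (bulk signals decay over tens of seconds),
  photobleaching 5·10⁻⁵ s⁻¹, white noise 1% of each channel's
  baseline. Motion artifacts multiply *both* channels by the same
  fractional excursion (default 25% for 3 s), exactly the geometry the
  405 nm screen is designed to catch.
- **Feeding** (`FeedingSimConfig`): weight = start − linearly consumed
  meal mass − evaporation drift + jitter + optional transient positive
  bumps (animal contacting the bottle). Defaults: 3 h session at 1 Hz,
  5 meals of 0.05–0.5 g lasting 10–60 s with gaps ≥ 30 s, 1 mg
  jitter — a meal count, size range, and noise scale typical of
  liquid-diet sessions in feeding chambers.
- **Cells** (`CellSimConfig`): per-section multinomial draws at fixed
  class probabilities, default 4 animals × 18 sections ×
  ~Poisson(100) cells at p = (0.832, 0.149, 0.019), the nearly
  distinct two-population mix reported for this region under the
  inclusive reading.

What the generators do *not* emulate: hemodynamic or pH artifacts and
wavelength-dependent motion in photometry (artifacts here are
perfectly shared between channels, so the screen's false-negative
behaviour under channel-specific motion is untested); licking
microstructure, spout leaks, or scale quantization in feeding traces;
segmentation error, section loss, or spatial gradients in cell counts.
Passing recovery tests therefore demonstrate correctness of the
quantification rules, not robustness to every failure mode of real
rigs.

## Orchestration and reproducibility

The pipeline runner validates its configuration against the full
default tree (unknown keys are rejected with their paths), executes
simulate → analyze per modality, isolates per-unit failures (a broken
trial or session is logged and skipped), and emits a JSON run report
with package versions, a configuration hash, the complete file
inventory, QC exclusions, and warnings. A run is considered failed
only when a stage retains zero analyzable units — e.g. a screening
threshold of 0 excludes every trial and exits nonzero. All writers use
a fixed float format, so identical configuration and seed reproduce
byte-identical analytic outputs; this is asserted by test and
recomputed by `scripts/acceptance.py`.

Validation problem sizes (100 photometry trials, 50 feeding sessions,
1000 oracle traces, 200 count-table replicates) were chosen so the
whole suite completes in seconds while keeping Monte-Carlo noise well
inside the asserted tolerances.

## Known limitations

- The 405 nm channel is used only to reject trials; no isosbestic
  regression or motion correction is offered by design.
- "Return to zero" at 1 Hz without interpolation makes the AUC grid-
  dependent near the crossing; the bin-mean attenuation of the first
  post-event second is described above.
- The meal detector assumes a non-increasing true bottle weight apart
  from bounded jitter and transient bumps; refills mid-session must be
  split into separate recordings.
- Abercrombie's correction assumes a single mean particle height per
  preparation; class-specific heights would require per-class factors
  (supported by calling the correction per class), and percentages
  would then no longer be correction-invariant.
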