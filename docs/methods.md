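# Methods

## The paradigm and the inference problem

Human MTL "concept cells" respond selectively to a specific person or place
(the *identity*). The paradigm analyzed here embeds each of two identities in
two short narrative episodes (*stories* — the contexts), learned over 10–15
encoding/recall repetitions, with a passive visual-presentation (VP) task
before and after. The scientific question is whether an identity-selective
response is modulated by which story the identity appears in. Because the
headline claim is a *negative* (no context modulation), the package pairs
standard difference tests with equivalence testing and decoding, so that
"no significant difference" can be separated from "statistically equivalent".

## Synthetic sessions

`synthetic.generate_session` draws spike trains from an inhomogeneous Poisson
process over one continuous session timeline containing the three task
blocks. The per-unit rate model is deliberately minimal:

* baseline `baseline_rate` (default 5 Hz) everywhere;
* a rectangular step to `evoked_rate` (default 30 Hz, times `context_gain`
  in story 2) from `latency_true` (0.3 s) after stimulus onset for
  `response_duration` (0.5 s), on VP and encoding trials of the tuned
  identity — the evoked rate replaces, not adds to, the baseline;
* during correct recalls of tuned-identity stories, a linear ramp from
  baseline beginning `recall_ramp_start` (2.5 s) before the labeled
  vocalization onset up to `recall_rate`, held for 0.5 s after onset.
  `recall_rate` defaults to 0.6 × the evoked rate; recall responses are
  known to be weaker than encoding responses but the factor is not
  quantitatively constrained, so it is exposed as a parameter.

Sampling is exact per rate segment (Poisson counts + uniform positions for
constant segments, thinning for ramps), so generated counts have the
textbook Poisson statistics the tests rely on. Event onsets for encoding
are the identity-picture times inside each story sequence; the surrounding
"when/where/what" pictures are absorbed into inter-trial spacing rather
than modeled individually. Inter-picture intervals are uniform on
[2.65, 2.9] s and inter-story blanks on [5, 5.1] s. Incorrect recalls fire
at baseline only and are flagged; their probability decays linearly from
`incorrect_recall_frac` (default 10%) on the first repetition to zero on
the last, a coarse stand-in for the observed learning curve.

Waveforms are a fixed 64-sample extracellular template (negative trough,
small positive after-potential, peak magnitude 1) scaled by
`waveform_amplitude` plus i.i.d. Gaussian noise per sample.

What the generator does **not** emulate: refractory periods (a Poisson train
at 5 Hz has ~1.5% inter-spike intervals below 3 ms, so synthetic units
typically classify as multi-units — by design the classifier is honest
about that), bursting, rate drift, waveform drift or sorting confusability,
overdispersion of real spike counts, and correlated noise across units.
Passing tests therefore demonstrate correctness of the *procedures* under
the stated model, not robustness to every property of patient data.

## Unit quality

* `SNR_peak = |W̄(peak)| / σ_W`, with the peak at the sample where the mean
  waveform has maximal absolute value (sign-agnostic, since extracellular
  spikes are negative-going) and `σ_W` the across-spike SD at the *first*
  epoched sample — a pre-spike sample that carries noise only. A config
  switch (`snr_sigma_sample="peak"`) uses the SD at the peak sample instead.
* `SNR_whole` is the RMS over all 64 samples of `W̄(i)/σ_W(i)`.
* `CV2` is the mean over consecutive ISI pairs of `|ΔISI| / pair mean`;
  it lies in [0, 2], is 0 for perfectly regular trains and ≈1 for Poisson
  trains (for independent exponentials, `|X−Y|/(X+Y)` is distributed as
  `|2U−1|` with `U` uniform, whose mean is 1/2).
* Standard deviations use the n−1 convention; at realistic spike counts the
  difference from the population convention is negligible.
* Classification: excluded below 0.1 Hz session-wide; *single* requires
  `SNR_peak > 5` **and** under 1% of ISIs below 3 ms; otherwise *multi*.
  An undefined SNR (zero noise SD) is reported as NaN and cannot support a
  single-unit call. The spike-shape and ISI-distribution criteria that a
  human sorter would also weigh are treated as advisory diagnostics, not
  gates, because no combination rule is defined for them.

## Rates, thresholds, latencies, windows

The instantaneous rate convolves the spike train with a Gaussian kernel
(σ = 10 ms, truncated where amplitude falls below 1% of the peak, i.e. at
±3.03 σ), normalized to unit area so the trace integrates to the mean spike
count per trial, then averages across trials on a 1 ms grid. Kernel mass
falling outside the epoch is lost at the edges; epochs are padded so this
never touches analysis windows.

The detection threshold pools the trial-averaged baseline samples (900 to
100 ms before onset) across all stimuli and takes mean + 4 SD, floored at
5 Hz. The SD is the timepoint-to-timepoint variability of the pooled
trial-averaged traces; pooling per-trial rates instead is configurable
(the averaging level is ambiguous in the source procedure).

A latency onset is the earliest upward threshold crossing whose
supra-threshold state persists ≥ 90 ms, with sub-threshold dips shorter
than 20 ms bridged. Two conventions matter and are fixed as follows: run
persistence counts bridged samples; and a run already in progress at the
start of the search window (default [0, 1] s) is not an onset — the
crossing itself must occur inside the window. Consequence: strict
monotonicity of the latency in the threshold holds when the trace starts
at the search origin, but a run straddling the window edge can gain a
valid (later) crossing as the threshold rises. The brute-force run-length
scanner in the test suite mirrors these conventions independently.

The encoding/VP response window is the 500 ms after the latency onset, or
the fixed 200–700 ms window when no latency is found; response *strength*
is the median spike count across trials in the window. Recall uses a fixed
[−1.5, +0.5] s window around vocalization onset and a gate: the median
in-window rate must exceed baseline mean + 1 SD, floored at 3 Hz, for at
least one story. Recall analyses use correct trials only by default
(configurable), and a session needs ≥ 10 correct recalls per identity to be
analyzed at all. Because the pre-cue period is not represented in the
synthetic timeline, the pipeline estimates recall baseline statistics from
the encoding pre-onset windows.

## Statistics

* **ANOVA.** Two-way fixed-effects ANOVA of per-trial counts with factors
  identity and context plus interaction, via statsmodels OLS. Type II sums
  of squares by default — identical to Type I on balanced designs, and the
  standard choice when discarding incorrect recalls unbalances cells.
  A unit is *responsive* (encoding) when the identity factor is significant
  at 0.01 and a latency exists for ≥ 1 story; *story-modulated* when the
  context factor or the interaction is significant (strict inequality at
  the boundary). Zero-variance data report p = 1 with F undefined.
  Total df is always n − 1 (59 for 15 trials × 4 stories).
* **Permutation tests.** Statistic |median(A) − median(B)| for strength and
  |latency(A) − latency(B)| for latency (each latency recomputed from the
  permuted trial sets' trial-averaged rate); 1000 surrogates;
  p = (k+1)/(N+1), so zero exceedances report 1/1001 < 0.001. Surrogates
  with undefined latency contribute +∞ — conservative, counting against
  significance; discarding them is available via a flag. The median-based
  strength statistic is conservative on discrete counts (its null
  distribution is lumpy), which shows up as sub-nominal type-I rates.
* **TOST equivalence.** Welch t statistics against symmetric bounds
  ±d₀·σ_pooled with d₀ = √(2 (z_α + z_{β/2})² / min(n₁, n₂)); both
  one-sided nulls must be rejected at level α with Welch–Satterthwaite df.
  Defaults (α, β) = (0.05, 0.05). The d₀ formula is the normal-approximation
  bound at which the TOST attains power 1 − β against a true zero
  difference — and because d₀ shrinks exactly as fast as the standard
  error, the probability of declaring truly identical conditions equivalent
  is ≈ 1 − β at *every* sample size (≈95% with the defaults, a point or two
  lower in finite samples with the t correction), not approaching 1.
  Identical constant samples are degenerate-equivalent.

## Decoding

Each trial is represented by every recorded unit's spike count in that
unit's own response window (latency-anchored for its strongest story, fixed
fallback otherwise; the fixed recall window for recall decoding). All units
enter regardless of responsiveness. `PoissonNBDecoder` is a scikit-learn
estimator (fit/predict/predict_proba, `get_params`/`set_params`) with a
per-unit Poisson likelihood on counts and additive rate smoothing: the
class rate estimate is the training mean plus 0.5 spikes per window, so
empty cells never zero out a posterior. Class priors are uniform by default
(the designs are balanced; empirical fold priors are available). Ties break
to the lowest class index. A Gaussian variant exists behind a config flag.
Leave-one-out cross-validation is computed by a fully vectorized path that
provably (tested) equals refitting the estimator per fold; overall
significance uses 10,000 label shuffles with the (k+1)/(N+1) convention.

**A property worth knowing:** leave-one-out with class-conditional means has
a below-chance tilt for labels that are exchangeable *given* a strong
nuisance dimension. Decoding story from identity-tuned sessions, the
held-out trial's own story class is the one training class depleted of that
trial's identity signature, so every tuned unit votes slightly against the
true story; with the realistic sparse composition (2 tuned units among 35)
the story decoder averages ≈ 43% rather than 50%, and with many tuned units
it collapses far below chance. This is a property of LOOCV itself, not a
bug — the full paradigm's reported story decoding (46%/45%) sits below
chance for the same reason. Shuffle p-values are unaffected (the surrogate
distribution has the same tilt), which is why significance, not raw
accuracy, carries the inference.

Time-resolved decoding slides a window (25 ms steps; 250 ms wide,
trailing-aligned, for encoding so no future spikes are used; 1 s wide,
centered, for recall). Significance across sessions: per-bin one-sided sign
tests of accuracy vs chance (and a paired sign test for the
identity-minus-story difference); bins significant at 0.01 for ≥ 100 ms
form clusters; the cluster statistic is the within-cluster sum of the sign
statistic (n_above − n_below); its null distribution is the maximum cluster
sum over 1000 within-session label permutations (family-wise control).
With S sessions the smallest attainable sign-test p is 2⁻ˢ, so at least 7–8
sessions are needed for any bin to clear 0.01 — cluster analyses here use 8
synthetic sessions.

## Population summaries

Traces are normalized by subtracting the unit's baseline mean and dividing
by its responsive-story encoding peak; the default divisor is
(peak − baseline mean) so the responsive encoding trace peaks at exactly 1
(the literal raw-peak divisor, which tops out below 1, is available). The
encoding factor is reused for VP traces — which may therefore exceed 1 —
and recall traces use the recall peak. The per-unit activity measure is the
mean rate difference between responsive and non-responsive stimuli in
0.1–0.8 s (encoding/VP) or −2.5 to 0.75 s (recall); story-1 vs story-2 and
task-vs-task Pearson correlations of these activities across units
quantify context invariance at the population level (both the per-story
and the story-mean variants are reported, since either reading is
defensible for the between-task comparisons). Unit ordering for population
displays sorts ascending by mean latency over responsive stories, stable,
undefined last.

## Problem sizes and determinism

Simulation-based tests use the study's stated conditions: 30-vs-5 Hz
exemplar tuning, 15 trials per story, 35-unit sessions for decoding
calibration (with 2 tuned units — one per identity, matching the screening
procedure that selects two response-eliciting stimuli per session), 2000
neurons for type-I calibration, 50 sessions for chance-level checks, and
1000–10,000 surrogates as per the respective procedure. The calibration
script finishes in well under a minute and the full test suite in a couple
of minutes on one CPU. All randomness flows through explicit
`numpy.random.Generator` seeds; rerunning a session analysis with the same
seed reproduces every table bit for bit.

## Known limitations

* The generator's Poisson model has no refractory period, so synthetic
  units rarely classify as single units; quality-metric logic is instead
  validated on constructed trains and waveforms.
* The TOST (α, β) defaults are a package choice; the source procedure's
  exact grids are not public, so equivalence *rates* (not verdict logic)
  depend on them.
* Latency estimates inherit a small early bias (≈ −10 to −15 ms for strong
  steps) from kernel smoothing at response edges; recovery is validated to
  within ±30 ms (≈ 3 kernel σ).
* The across-session sign test is underpowered below ~8 sessions; cohorts
  smaller than that cannot produce significant clusters at 0.01.
* Recall baseline statistics are proxied by encoding pre-onset activity
  because the pre-cue period is not modeled.
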