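# Methods

## Scope

`respco` implements a complete respiration–behaviour coupling analysis:
respiratory cycle detection and phase assignment from a single-channel
trace, event-locked phase-consistency (phase-locking) testing against
time-shift surrogates, and circular-predictor mixed-model comparison
quantifying how the respiratory phase at lagged time points predicts
reaction times and response accuracy.  Because the package ships no
recordings, a synthetic-session generator with known ground truth defines
the test surface; its defaults encode the study conditions the analysis is
designed for.

## Respiratory preprocessing

Raw traces (any rate ≥ 50 Hz) are filtered with third-order Butterworth
filters, 0.03 Hz high-pass and 6 Hz low-pass, both applied
forward–backward (zero phase: cycle *timing* is the measured quantity, so
the filters must not delay it), resampled to 100 Hz and z-scored.

Cycle peaks come from the analytic (Hilbert) signal: each upward zero
crossing of the analytic phase marks a local maximum and is snapped to the
local signal maximum within ±0.4 s — for asymmetric cycles the analytic
phase crosses zero a few tens of milliseconds away from the actual
maximum.  Peaks with z ≤ 0.5 are discarded; each retained peak is
delineated within a 7 s window.  The inhalation is the maximal continuous
positive-slope run ending at the peak, the exhalation the maximal
negative-slope run following it, bridging interruptions shorter than
500 ms.  Slope classification is two-tier: the raw central-difference
sign decides rising/falling (sample-accurate boundaries), while "flat"
requires the slope magnitude averaged over 110 ms to stay below 0.05 z/s.
The 0.05 z/s bound is deliberate: typical mid-inhale slopes are 1.5–3 z/s,
whereas residual baseline drift inside a genuine breathing pause after the
0.03 Hz high-pass is of order 0.01–0.1 z/s, so a much smaller bound would
never classify anything as flat.  Boundaries not adjacent to a flat pause
are refined to the zero crossing of a 150 ms-averaged slope (a symmetric
average leaves the crossing of a locally linear slope unbiased while
suppressing low-pass ripple).  Flat pauses ≥ 500 ms terminate the
exhalation and stay unclassified.

Atypical cycles are rejected by shape: every cycle resampled to 100
points, distance = mean squared deviation from the pointwise-mean
centroid, and cycles beyond mean + 3 SD of the distance distribution are
marked invalid ("3 SD from the centroid" is read as a cut on the distance
distribution, the only SD available).  Phase is then linear in time, 0→π
over each inhalation and π→2π over each exhalation; samples in pauses,
invalid cycles or between cycles are undefined (NaN).

Timing accuracy: on noise-free synthetic traces the median landmark error
(inhale onset, peak, exhale end) is 6–12 ms.  The tail is wider (95th
percentile ~25 ms, worst ~0.1 s): pseudo-periodic breathing with
cycle-duration SD 0.7 s is an FM process whose phase-diffusion sidebands
extend below 0.1 Hz, and the 0.03 Hz third-order high-pass removes part of
them, leaving a wandering baseline whose local tilt displaces trough-type
landmarks by tilt/curvature.  This is a property of the prescribed
filtering, not of the detector; any detector seeing only the filtered
trace inherits it.

## Event-relative phase and exclusions

Phase at (event + lag) uses nearest-sample lookup at 100 Hz (≤ 5 ms, about
half a degree for a 3.6 s cycle); lags run 0 to −4.5 s in 0.3 s steps for
both stimulus- and response-alignment.  Trials are excluded for wrong
button, RT < 200 ms, RT > 3 s, or undefined phase at the time point of
interest — in that precedence order, so per-reason counts partition the
exclusions.  Participants with ≥ 30% excluded trials (strict rule) are
dropped after trial-level exclusions at the primary lag (−2.1 s,
response-aligned).

## Phase locking and surrogates

The phase-locking value (PLV) is the length of the mean unit phase vector;
the group statistic is the median over participants with a
1000-resample participant bootstrap CI.  Significance uses time-shift
surrogates: each participant's phase series is circularly shifted by an
independent uniform offset (independent shifts, drawn per participant),
the group-median curve recomputed, and its maximum over the time axis
collected; pointwise p-values against the max distribution are therefore
family-wise corrected.  Permutation p-values throughout use the add-one
estimator, so p = 0 never occurs.  Split analyses (fast/slow RT by median,
correct/wrong with the majority class subsampled to the minority count —
20 seeded draws averaged, participants with < 40 trials per class
excluded — and first/second experiment half) compare participant-wise PLV
at the event by Wilcoxon signed-rank.

## Behaviour models and model comparison

√RT is modelled with a Gaussian linear mixed model, accuracy with a
Laplace-approximate logistic mixed model: fixed effects intercept,
stimulus level, and optionally the sin φ/cos φ pair; random intercept and
random (scaled) trial-number slope per participant with an unstructured
2×2 covariance.  Both are fitted by maximum likelihood with the in-package
solver: the Gaussian deviance is profiled so each evaluation touches only
per-participant cross-product matrices (fits are microseconds-to-
milliseconds regardless of trial count — the lag and permutation scans
refit thousands of times), and the logistic model uses penalised IRLS
inside a Nelder–Mead search over the covariance factor.  Both are verified
against statsmodels `MixedLM` (ML) and lme4 `glmer` in the test suite.  If
the random-slope fit fails to converge, both members of a comparison pair
are refitted with a random intercept only, keeping AICs comparable.

ΔAIC = AIC(reduced) − AIC(full); positive favours the respiration model;
the Akaike weight of the full model is exp(ΔAIC/2)/(1 + exp(ΔAIC/2)), and
ΔAIC = 9.2 corresponds to a weight of 0.990.  The lag scan fits the pair
at every lag on the grid, by default on the common trial set whose phase
is defined at *every* scanned lag: AIC values are only comparable across
lags on identical data, so the curve's peak is then a valid cross-lag
comparison (per-lag exclusion mode is available for single-lag evidence).
Vector strength is V = √(β_sin² + β_cos²) — the phrase "geometric average
of the sine and cosine terms" is ambiguous for opposite-signed
coefficients, and the resultant amplitude is the standard rotation-
invariant circular-linear effect size, so it is adopted.  Its null
distribution comes from refitting after permuting phase values within
participant (preserving both marginals); dataset-level p-values combine by
Fisher's method (−2Σ ln p against χ² with 2k df; p = 0 is rejected —
upstream estimators are add-one).

## Synthetic sessions

Trial timing: fixation onset, stimulus after a uniform 0.4–1.0 s fixation,
response, next fixation after a uniform 1.2–1.5 s inter-trial interval —
stimulus onsets recur every ~3 s.  Respiration: raised-cosine half-cycles
(−cos φ with φ advancing at π/T_inhale then π/T_exhale), per-cycle
durations Normal(participant mean, within SD), participant means
Normal(3.6, 0.45²) s with within-participant SD √(0.7² − 0.45²) so pooled
durations are 3.6 ± 0.7 s; inhale fraction 0.46 (inhalation 1.6-ish of a
3.5 s cycle); end-expiratory pauses with probability 0.10 per cycle,
uniform 0.2–0.8 s; additive white measurement noise (0.05 z) at 200 Hz.
Entrainment: at every fixation onset the phase is partially reset,
φ ← arg((1−λ) e^{iφ} + λ e^{iφ_target}), λ = 0.4 and target π/2 by
default; this produces event-locked PLV ≈ 0.27, in the empirically
reported range.  Behaviour: √RT = 1.0 + 0.03·(level−3) + participant
offset (SD 0.08) + participant trial slope (SD 0.04) + 0.12·noise +
β_s sin φ + β_c cos φ with β = (0.02, 0) √s at lag −2.1 s before the
response; accuracy is Bernoulli with logit = 1.6 + 0.35·(level−3) +
0.1 sin φ (≈ 84% correct).  Because response-referenced coupling is
self-referential, φ is evaluated at (stimulus + provisional RT + lag) and
refined by one fixed-point iteration; the RT shift per iteration
(≪ 0.05 s) is far below one phase bin.  Subsequent fixation onsets are
laid down from the provisional RTs, so realized inter-trial intervals can
deviate from the nominal range by up to the coupling amplitude.  All
randomness derives from one master seed via per-participant,
per-stage seed sequences; identical spec + seed is bit-identical.

What the generator does *not* emulate: respiratory depth/volume, oral vs
nasal routes, amplitude drift, autocorrelated cycle durations, cardiac
coupling, non-stationary behaviour (fatigue beyond a linear trial slope).
Passing tests therefore show the statistical machinery is calibrated and
recovers known coupling under idealised but realistically parameterised
signals — not that real recordings meet these assumptions.

## Response-aligned identifiability (an important caveat)

With any trial-locked entrainment, the phase sampled at
(response + lag) depends mechanically on the reaction time: RT shifts the
sample time along a partially predictable phase trajectory, so sin/cos of
the sampled phase correlates with RT even when the generative coupling is
zero.  At the default conditions this mechanical association alone yields
ΔAIC of several hundred across the whole response-aligned lag grid,
peaking around −1 to −1.5 s.  Consequences, demonstrated by the validation
runs: (i) the *peak* of the response-aligned evidence curve does not
estimate the coupling lag when entrainment is present; (ii) evidence bars
are only null-calibrated in the no-entrainment configuration (λ = 0),
which is what the null-calibration runs use; (iii) stimulus-aligned scans
do not have this problem.  Even without entrainment, localising the
coupling lag to one 0.3 s step is information-limited: the phase
decorrelates by only ~0.5% per step (cycle-duration CV ≈ 0.19), so at
cohort scale (6,000 trials, amplitude 0.02 √s) the evidence curve is a
plateau whose argmax wanders ±2–3 steps; the scan reliably *detects* the
coupling (ΔAIC 50–110 ≫ 9.2) and the median recovered peak sits at the
generative lag, but single-cohort ±1-step recovery holds in only ~60% of
cohorts.

## Validation run sizes

`scripts/acceptance.py` (a few minutes, one CPU): lag recovery — 20
cohorts of 20 participants × 300 trials, coupling 0.02 √s at −2.1 s,
cycle durations N(3.6, 0.7²), run once with λ = 0.4 and once with λ = 0;
null calibration — 20 cohorts, λ = 0, β = 0; shuffle calibration — 100
replicates of 5 × 60 null trials with 200 shuffles each, KS-tested against
U(0,1); surrogate family-wise error — 200 null sessions of 6 × 60 trials
with 200 surrogates each; timing oracle — 5 noise-free single-participant
traces (~200 cycles); plus closed-form PLV, Akaike-weight and Fisher
checks.  The demonstration analyses use 8 × 150 trials.

## Numerical choices

Filtering uses second-order sections throughout.  The Gaussian LMM
optimises the relative Cholesky factor by Nelder–Mead from two starts
(warm-started inside permutation loops); k counts fixed effects +
covariance parameters + residual variance, so AIC = 2k − 2ℓ holds as an
identity.  Degenerate inputs are flagged rather than silently handled:
constant traces warn on z-scoring, all-identical outcomes raise, p = 0
in Fisher's method raises, cohorts with < 5 valid cycles skip the
atypical-cycle rule with a warning, odd breather cohorts send the median
participant to the slow group, and ties in the rate–PLV correlation use
average ranks.
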