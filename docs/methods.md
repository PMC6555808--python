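# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic validation does and
does not establish about real data.

## Data model

An `EpochSeries` holds one subject's aligned per-epoch channels on a fixed
grid (30-s epochs by default): nonnegative activity counts (NaN =
off-wrist), PSG stage codes 0–5 (0 wake, 1–4 NREM, 5 REM; NaN outside the
PSG recording), and an optional expert sleep/wake annotation. Indexing is
0-based and the PSG window is a closed interval `[first, last]`, inferred
as the span of scored stages when not given. Binary hypnograms collapse
stages with sleep = 1 as the positive class. Missing counts are never
imputed at the I/O layer; each consumer decides (scorers emit a missing
prediction for an epoch whose own count is missing, features and window
datasets read missing as zero movement).

Cohort filters mirror standard PSG-actigraphy quality rules: drop records
with no synchronized epoch, records with under 3 h of usable data, and
records whose PSG span exceeds 16 h. "Usable" is read strictly as epochs
carrying both a count and a stage; the looser readings (actigraphy hours
or PSG hours alone) would only keep more records. The subject split is
uniform random without stratification, with half-up rounding of
`fraction · n` (so 80% of 1817 ids is exactly 1454).

## Traditional scorers

The registry transcribes the canonical published coefficient sets and
records a source note per entry:

| scorer | form | decision |
|---|---|---|
| Webster | 0.025·Σ w·c, offsets −4..+2, w = (.15,.15,.15,.08,.21,.12,.13) | sleep iff < 1 |
| Cole–Kripke | 0.001·Σ w·c, offsets −4..+2, w = (106,54,58,76,230,74,67) | sleep iff < 1 |
| Oakley | symmetric ±2-min window: 1/25 at ±2 min, 1/5 at ±1 min, 1 at center | wake iff > θ (θ = 40 is the device value) |
| Scripps Clinic | 0.204·Σ w·c, offsets −10..+10, zero weight beyond +2 | sleep iff < 1 |
| Sadeh | PS = 7.601 − 0.065·AVG − 1.08·NAT − 0.056·SD − 0.703·LG | sleep iff PS ≥ 0 |
| Sazonov | 1.727 − Σₖ coefₖ·max(c over [t−k, t]), k = 0..4 | sleep iff ≥ 0.5 |

Conventions that needed fixing and are tested: coefficients are applied on
the native epoch grid without resampling the 1-min-native algorithms;
out-of-range window positions contribute zero; missing counts contribute
zero to weighted sums and are excluded from Sadeh's mean/SD/NAT
denominators; Sadeh's SD uses the population formula (divisor n) over the
trailing six epochs; NAT counts epochs with 50 ≤ c < 100 in the centered
11-epoch window; threshold ties follow each rule's stated inequality
(Oakley scores equal to θ are sleep). Sazonov is the only causal scorer —
its prediction at *t* never depends on later epochs, which is enforced as
a property test.

## Rescoring rules

The five wake-rescoring rules run sequentially, one full left-to-right
pass each, with run lengths measured on the pass's input: a flip cannot
re-trigger the same rule within its own pass, but later passes see it
(so 10 wake + 6 sleep cascades to all wake across R1, R2 and R4). Only
sleep→wake changes occur, hence specificity can only rise and sensitivity
only fall — also property-tested. Missing labels break runs and are never
rescored; runs touching a boundary count at their actual length. The
island rules read "surrounded (before or after)" disjunctively by
default; `flank_mode="and"` restores the stricter both-flanks variant of
the original formulation. The implementation is verified exhaustively
against an independent index-walking interpreter on all 4096 binary
strings of length 12 (both flank modes).

## Features and classifiers

The feature schema emits, per epoch, the raw count and log1p, plus
summary statistics of centered (`[t−N, t+N]`) and trailing (`[t−N, t]`,
strictly causal) windows for N = 1..19, zero-filled at boundaries. The
default composition totals exactly 370 columns: nine core statistics
(mean, median, SD, variance, min, max, sum, count-in-[50,100),
count-positive) on every window/type pair, plus skewness and kurtosis on
centered windows with N ≥ 7 only, where the ≥ 15 samples make the higher
moments estimable; no uniform statistics-per-window design can reach that
total, so the non-uniformity is deliberate and the composition is
serialized with the schema. Small-sample-undefined statistics return 0.

Classifiers grid-search hyperparameters with k-fold cross-validation
maximizing accuracy and refit the winner on all data. Folds are cut by
subject when group labels are supplied (the default protocol — epoch-level
folds leak within-subject autocorrelation and inflate CV scores);
contiguous-block folds are the fallback. Sequence inputs are fixed-width
centered windows of raw counts (20/50/100 are the customary widths); the
shipped window model is a small multilayer perceptron, chosen because the
pipeline contract — not leaderboard parity of deep architectures — is
what the package exercises and tests.

## Metrics

Confusion metrics are computed over jointly non-missing epochs with
zero-denominator metrics defined as 0 (so an always-wake predictor has
precision 0, as the baseline rows of published tables print). WASO counts
predicted-wake epochs strictly after the first ground-truth sleep epoch,
times epoch length; sleep efficiency is predicted-sleep percent over the
whole record. Every cohort-level number is computed per subject first and
then summarized — mean with a normal-approximation 95% half-width
(1.96·SEM; published tables do not state their CI formula, and at the
cohort sizes involved the t-quantile correction is negligible) — because
per-subject-then-average is what published benchmark tables do (their
printed F1 is not the harmonic mean of printed precision and sensitivity).
Paired two-tailed t-tests compare methods by subject; identical samples
give p = 1 by convention. The packaged 41-row table of published
per-method results supports the metric–metric correlation analysis
(F1 is the strongest correlate of WASO error, r = −0.98; accuracy of
sleep-efficiency error, r = −0.93).

## Synthetic cohorts

The simulator emulates a sleep-study wear pattern: a PSG night drawn
uniformly from 9–12 h (capped at 16 h so generated cohorts always pass
the filters) flanked by up to 8 h of day wear each side. The hidden
sleep/wake path is a two-state alternating-renewal (semi-Markov) process
with geometric-mixture dwell times — chosen over a plain Markov chain so
consolidated sleep bouts and brief awakenings coexist, which is what
gives the rescoring rules realistic firing opportunities. Night defaults:
sleep bouts mix 30% short (mean 8 epochs) with 70% long (mean ≈ 97),
wake bouts 80% brief (mean 4) with 20% long (mean 234), giving a
stationary sleep fraction of 58.4%, the sleep prevalence of a large
overnight PSG cohort. The night segment starts in equilibrium (stationary
state plus residual dwell, exact for geometric dwells by memorylessness)
so the expected in-window sleep fraction equals the configured fraction
with no edge bias; all-wake nights — degenerate draws under which
sleep-onset-anchored metrics are undefined — are redrawn. Day segments
start awake, with long wake bouts set by the nap rate (default 0.15
naps/h) and naps averaging 24 min, so day segments are always more
wakeful than nights.

Counts are zero-inflated gamma per state, rounded to integers: sleep
epochs are 80% motionless with small residual counts (gamma mean 5),
wake epochs rarely still (12% zeros) with gamma mean 180 — scales on
which the published `< 1`-threshold formulas operate. The expert channel
is the hidden truth with a 3% per-epoch flip. Per-subject generators
derive from `(master seed, subject index)`, so cohorts share prefixes
across size changes.

What the synthetic validation shows — and does not. The emission states
are well separated, so absolute agreement scores on synthetic cohorts run
higher than on real wrists; these cohorts validate *contracts and
orderings* (oracle rows, baseline identities, the device ≡ Oakley-θ40
equality, rescoring's specificity/sensitivity trade, classifiers beating
the majority floor, parameter recovery), not absolute accuracy levels.
Real-data phenomena not emulated: circadian structure beyond the
night/day switch, count autocorrelation within bouts, device-specific
count generation, off-wrist gaps (missing counts are representable in the
data model but not simulated), and disordered-sleep phenotypes. Reproducing
published per-method accuracy tables additionally requires the restricted
source accession and full-scale training, which is outside desk scale;
the published-table fixture carries those numbers instead.

## Tasks and harness

Task Night restricts to the PSG window with PSG-derived truth only. Task
Night&Day extends by up to 8 h of available data per side; truth stays
PSG inside the window (annotation never overrides it) and comes from the
expert channel outside, with annotated rest — naps included — scored
sleep (`rest_is_sleep=False` scores all unannotated-rest day epochs
wake). WASO/efficiency MAE columns and the oracle row are night-only,
since sleep onset anchors on PSG. Benchmark problem sizes in the examples
and acceptance script (tens of subjects, single nights) are chosen to
keep any run interactive while leaving every cohort statistic
well-determined.
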