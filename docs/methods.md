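# Methods

This note records the models, parameter choices and numerical decisions
behind the toolkit, in the order of the processing pipeline.

## Battery and stimulus assembly

The battery is a fixed catalogue of 25 environmental sounds, each with
a nominal duration and a (sequence, position) assignment in both the
coherent and the incoherent sequence set.  Validation enforces: unique
labels; positions in 1–5 (1-based throughout); exactly five members per
sequence covering positions 1–5; and each label appearing exactly once
per sequence set.  Violations are collected and reported together, not
one at a time.

**RMS normalisation with silent-pause correction.**  Clip levels are
equalised on the RMS of their *non-silent* portion so that leading,
trailing or internal pauses do not bias the level estimate.  The rule:
frame the clip into 10 ms windows; windows whose RMS falls more than
60 dB below the loudest window are excluded; a single gain then scales
the whole clip so the active-frame RMS hits the target.  Window length
and threshold are configurable — the exact correction used for the
original recordings is not documented anywhere, so this rule is this
package's own, chosen to be insensitive to digital silence (appending
silence leaves the gain unchanged, which is the tested invariant).
An all-silent clip is an error rather than a no-op.

**Assembly.**  Sequences are concatenations of the five member clips in
order with 250 ms of digital silence between consecutive sounds and no
leading/trailing gap; mixed sample rates are polyphase-resampled to a
single working rate (default 44.1 kHz) first.  Nominal sequence
duration is the sum of member durations plus 4×gap; with the catalogue
durations all ten sequences fall in the 12–17 s window the protocol
targets.

**Synthetic fixture audio.**  The original recordings are not bundled;
`make_fixture_audio` synthesizes one clip per label (two-partial
amplitude-modulated tone plus coloured noise, per-label parameters from
a seeded generator) at the catalogued duration.  These clips exercise
every signal-path property (durations, level, band energies,
determinism) but carry no perceptual content, so nothing downstream
should be interpreted as evidence about the recognisability of real
sounds.

## Vocoder

Four-step noise vocoder: band-filter → envelope → noise modulation →
re-filter and sum.  Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `n_bands` | 4 | analysis channels, log-spaced edges f_lo·(f_hi/f_lo)^(k/n) |
| `f_lo`, `f_hi` | 300, 5500 Hz | analysis range; `f_hi` must lie below Nyquist |
| `filter_order` | 6 | bandpass transfer-function order (3rd-order lowpass prototype), −3 dB at both edges, so adjacent bands overlap at −3 dB |
| `env_cutoff` | 160 Hz | envelope lowpass after half-wave rectification |
| `env_filter_order` | 4 | Butterworth order of that lowpass |
| `carrier` | white noise | seeded Gaussian, unit variance, independent substream per band |
| `level_match` | on | output RMS rescaled to input RMS (silence maps to silence) |
| `zero_phase` | on | forward–backward filtering (see below) |

Numerical decisions:

- **Filter application is zero-phase by default.**  A single causal
  pass of a 6th-order bandpass leaves ~14% of re-filtered carrier
  energy outside the nominal band edges (the skirt integral), which
  blurs channel separation; forward–backward application squares the
  magnitude response and keeps ≥95% of a channel's output energy inside
  its edges while leaving the −3 dB *design* overlap untouched.  A
  causal single-pass mode (`zero_phase=False`) is available for
  real-time-equivalent processing.
- Envelope samples are clamped at zero after the lowpass (an amplitude
  envelope is non-negative; the filter can undershoot).
- The envelope lowpass order and the carrier distribution are not
  pinned down by any published description of this processing chain;
  4th-order Butterworth and Gaussian white noise are this package's
  documented choices.
- Envelope fidelity is verified on amplitude-modulated noise by
  correlating input and output band envelopes smoothed at 20 Hz: the
  imposed modulation (4 Hz in the test) lives well below that, while
  the carrier's intrinsic Rayleigh envelope fluctuations — which are
  *supposed* to differ between input and output — are averaged out.

## Scoring

The three metrics are computed from one response: LC by set membership
of each chosen label in the sequence, OC by positional equality, SC as
the indicator of OC = 5.  Per condition the LC/OC denominator is 25
(five sequences × five positions) and the SC denominator is 5.

- **Arcsine transform:** arcsin(√p) in radians (a 2·arcsin(√p) variant
  is available; only the monotone transform matters for the F-tests).
- **Duplicate labels** in a response are rejected by default — the
  response interface forces an arrangement of distinct names — with a
  lenient mode that scores duplicates slot-by-slot.
- **Missing trials** are an error unless partial scoring is requested,
  in which case absent sequences score zero in all slots.
- Serial-position profiles use the OC basis (canonical); an LC basis
  exists but is marked non-canonical.
- Reports print percentages to one decimal and arcsine values to four.

## Statistics

- **Mixed ANOVA** (k groups between × 2-level coherence within) is the
  classical sums-of-squares decomposition, delegated to
  `pingouin.mixed_anova`; the test suite re-derives every F and
  partial eta-squared from explicit sums of squares and requires
  agreement to 1e-8.  Degenerate data with zero within-effect *and*
  zero within-error SS (0/0) are reported as F = 0, p = 1.
- **Regression** is OLS with intercept (`statsmodels`); squared
  semi-partials are computed as R²(full) − R²(full minus predictor);
  standardised betas come from refitting on z-scored data.  Missing
  covariates trigger listwise deletion with a warning and a reported
  effective n.  Adjusted R² uses the Wherry formula
  1−(1−R²)(n−1)/(n−k−1).
- **Commonality analysis** computes R² for all 2^k subsets (k ≤ 12) by
  least squares and assembles components by inclusion–exclusion.
  Components are reported unclipped — negative shared components are
  meaningful (suppression).  Two exact identities are enforced in
  tests at 1e-10: components sum to R²(full), and for every subset A
  the components touching A sum to R²(A).
- **Post-hoc t-tests** are pooled-variance by default (Welch behind a
  flag) at the Bonferroni-adjusted threshold α/m.
- Correlation tables flag p < .05 and, as an exploratory tier, p < .1.

## Synthetic listeners

The generative model is this package's own construction — no raw
single-subject data exist to fit — and its contract is *qualitative*
fidelity to the phenomena the test measures: a context benefit that
grows with serial position, U-shaped order memory, condition-separated
plausibility ratings, and slower incoherent-sequence responses.

Per position i (1-based), a label is identified with probability
σ(base_logit + coherent·context_gain·(1 + position_slope·(i−1))) and,
if identified, placed correctly with probability retention[i]
(`incoherent_recency_scale` < 1 additionally scales retention[5] on
incoherent trials, reproducing the absent-recency pattern of implant
users).  Misplaced identified labels are shuffled into the remaining
slots and unidentified slots are filled with foils, in both cases never
landing on their own correct slot, so per-position OC accuracy equals
the closed form σ(·)·retention[i] exactly — this is what makes
parameter-recovery tests sharp.  In the rare forced case (one remaining
slot whose only candidate is its own label) the identified label is
dropped for a foil, trading a little LC for exactness of OC.  Draws are
branch-free (one uniform per stage and position), so runs sharing a
seed are coupled across parameter settings and monotonicity properties
can be tested without Monte-Carlo slack.  Ratings are truncated normal
on [0,1]; times are log-normal with a multiplicative incoherence
penalty ≥ 1.

Cohorts draw listener profiles around a group mean via two latent
standard-normal traits — general ability (loads on base_logit and
context_gain) and order memory (loads on retention) — plus independent
jitter; the same latents generate covariate columns (MoCA, LNS,
QuickSIN, SPIN, RS, BKB-SIN) so regression and commonality stages have
true signal.  Group presets take their rating means and response-time
scales from the published group summaries; accuracy parameters are
qualitative choices fixed once (e.g. YNH base_logit 1.1, MON/MOI ≈ 0.4
with flatter retention, CIV base_logit 0 with a rising position slope,
CI with `incoherent_recency_scale` 0.55).  What passing tests show is
that the *pipeline* measures what the generator injects — not that the
generator reproduces human group means, which is out of scope.

## Problem sizes and tolerances in the test suite

Audio tests run at 16 kHz (above twice the 5.5 kHz band edge).
Monte-Carlo suites use: 3,000 trials for per-position accuracy (3-SE
binomial bound), 1,000 listeners (10,000 trials) for injected-gap
recovery within ±3 points, and 200 replicates for null-cohort checks,
where nominal 95% rates are asserted at ≥89–90% to allow 3-SE binomial
slack at 200 replicates.  Exact algebraic identities (commonality,
ANOVA oracle, normal equations) use absolute tolerances 1e-8–1e-12;
filter-magnitude checks use ±0.1 dB.

## Known limitations

- Synthetic audio is spectrally arbitrary; nothing here validates the
  perceptual identifiability of real recordings.
- The simulator's confusion structure is uniform over foils; a
  confusion-weight matrix is accepted in principle but not exercised.
- Ratings are analysed untransformed.
- The mixed ANOVA assumes the classical univariate decomposition; with
  a 2-level within factor sphericity is not at issue, and multilevel
  alternatives are out of scope.
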