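# Methods

This note documents the models behind `audiosim`, the parameters that
matter, the numerical choices, and what the simulator does and does not
capture about real clinical speech audiometry.

## Speech materials

Real clinical materials (phonetically balanced monosyllabic word lists in
quiet, logatom lists in noise) are copyrighted recordings; every procedure
and analysis in this package depends only on their *structure*. Generated
materials therefore reproduce exactly that structure: `n_lists` lists of
`words_per_list` words of `phonemes_per_word` phonemes (clinical defaults
20×17×3 in quiet, 5×17×3 in noise), words shaped consonant–vowel–consonant
by default (the shape of short French test words; any length ≥ 1 works,
with vowels at odd positions and a bare vowel for length-1 words).

Phonetic balance is enforced across the whole material rather than per
list: for each class (vowels, consonants) the symbol multiset filling that
class's slots is allocated by largest-remainder quota from the inventory's
target frequencies and shuffled by the seed. This is deterministic,
requires no rejection loop, and keeps the realized-vs-target
total-variation divergence (`balance_divergence`) at the rounding floor —
well under the 0.05 the test suite demands for ≥ 500-phoneme materials.
The default inventory has 6 vowels and 12 consonants with uniform target
frequencies, so the CVC slot share (one third vowels) matches the uniform
target exactly; other vowel/consonant ratios bias the divergence by the
mismatch between slot shares and class target mass, which is the main
reason to override `target_freq` when changing the inventory shape.

Generation is bit-reproducible for a fixed seed. `UNKNOWN` and `BLANK`
are reserved scorer tokens and are rejected as inventory symbols.

## Virtual listener

A listener maps the test axis x (presentation level in dB HL in quiet;
SNR in dB in noise — in both cases larger x means easier listening) to a
per-phoneme correctness probability via a four-parameter logistic

    p(x) = [floor + (ceiling − floor) / (1 + exp(−k (x − x₀)))] / 100.

The curve is specified clinically by `srt` (x at 50% intelligibility) and
`slope50` (derivative of the percent curve at that point, %/dB); `k` and
`x₀` are derived so the curve passes 50% at `srt` with that derivative.
This requires floor < 50 < ceiling, and the steepness is capped at
k ≤ 10/dB, bounding attainable slopes by (ceiling − floor)·10/4. The
logistic is a modelling choice: clinical studies *measure* the curve
without assuming a form, but the logistic is the standard psychoacoustic
model and makes SRT/slope recovery exactly testable.

Responses are per-phoneme independent Bernoulli draws with probability
p(x). Incorrect phonemes are replaced by a confusion policy: a uniformly
random different inventory phoneme (default), a draw from an explicit
confusion matrix, or omission. Per-phoneme independence mirrors clinical
phoneme-level scoring, which records correctness only; correlated errors
within a word are not modelled.

Defaults for cohort simulation (all package choices, not clinical
estimates):

| parameter | quiet | noise | rationale |
|---|---|---|---|
| PTA range (dB HL) | U(0, 80) | U(0, 70) | spans NH through severe (quiet) / moderate (noise) losses |
| slope50 (%/dB) | U(3, 8) | U(3, 8) | typical monosyllabic-material slopes |
| SRT link a·PTA + b ± σ | 1·PTA + 5 ± 5 dB | 0.15·PTA − 9 ± 2 dB SNR | strong PTA–SRT correlation in quiet; weaker, compressed link in noise |
| ceiling | 100 − 0.4·max(0, PTA − 40), floored at 55% | same | rollover grows with cochlear loss |
| audiogram | flat at PTA ± N(0,5) per frequency, recentred | same | keeps PTA exact while varying shape |

## Scoring

Two scorers transcribe the *same* utterances, so manual-vs-automated
comparisons are paired by construction.

**Oracle scorer** — the manual-equivalent expert: transcribes the uttered
phonemes verbatim (the expert hears the patient perfectly).

**ASR-emulating scorer** — each uttered phoneme is transcribed faithfully
except with probability `p_err_given_correct` (when the phoneme was a
correct repetition) or `p_err_given_incorrect` (when it was not), in which
case it becomes `UNKNOWN` (default), a random different phoneme, or a
mixture. The two rates are calibrated from the pre-validation of a
clinical phoneme-level recognizer: quiet material — phoneme accuracy
0.979 on correctly repeated samples (so `p_err_given_correct` = 0.021)
and phoneme error rate 0.174 on incorrectly repeated ones; noise
material — 0.964 and 0.161. Conditioning on repetition correctness
captures the empirical fact that recognizers transcribe clean, correct
repetitions far more reliably than distorted wrong ones.

**Alignment** — target and transcription are aligned by global
minimum-edit-distance (Needleman–Wunsch, unit costs). `BLANK` ("no
phoneme detected") is stripped before alignment; `UNKNOWN` participates
but can never match a target phoneme. Traceback ties are broken in the
fixed order match > substitution > deletion > insertion, so alignments
(not just distances) are reproducible. The phoneme score of a word is
100·(matches)/(target length); a word is "correct" when every target
phoneme matched and nothing was inserted.

**Corpus metrics** — over correct repetitions: word accuracy and pooled
phoneme accuracy. Over incorrect repetitions, errors are defined against
the *uttered* ground truth: the phoneme error rate is the pooled fraction
of uttered phonemes transcribed wrongly, and the word error rate is the
fraction of wrongly repeated words the scorer nevertheless transcribes as
a fully correct repetition of the target — i.e. the rate at which the
automated scorer wrongly credits the patient. (The alternative reading of
"word error rate" — infidelity to the utterance — is recoverable from the
same samples; the wrong-credit reading is the clinically consequential
one and matches the near-zero rates reported for clinical recognizers.)
Metrics on an empty stratum raise an explicit error by default
(`strict=False` returns `None` instead).

## Adaptive procedures

**Speech in quiet.** Levels are confined to 0–90 dB HL. The first level
is PTA + 20 (PTA < 60), PTA + 10 (60 ≤ PTA ≤ 80) or PTA + 5 (PTA > 80),
clamped. One fresh list (sampled without replacement, rotating when
exhausted) is presented per level. Early-stop rule: if the cumulative
phoneme score after the first 7 words is below 15%, the list stops, the
partial score is kept (`early_stopped`), and the next-lower level is
imputed 0% (`imputed_zero`) without testing. The procedure descends in
10 dB steps until a 0% point exists (measured or imputed, or the 0 dB HL
floor is reached), then ascends from the first level in 10 dB steps —
5 dB once the level exceeds 80 dB HL — until 100% is reached or the
newest score falls strictly below the running maximum (derivative
reversal, i.e. a speech maximum; tolerance configurable, default 0).
Finally, grid midpoints (5 dB grid, widest gap first) are added until at
least 3 measured levels lie strictly between the extremes, capped at 5
additions. The early-stop decision is driven by the procedure's reference
scorer — the oracle by default, since in the clinic the live score drives
the rule; it is configurable to the ASR scorer.

**Speech in noise.** Speech is fixed at 60 dB SPL and the masking noise
level is 60 − SNR dB SPL. One familiarization list is played in quiet
first; it is scored and recorded but excluded from the psychometric
points. Normal-hearing listeners (PTA ≤ 20) are tested at 0, −5, −10,
−15, −20, +5, +10 dB SNR in that order; all others at 0, −5, −10, +5,
+10. The same 7-word/15% early-stop rule applies; it imputes the next
5-dB-worse SNR as 0% (even when that SNR is not a scheduled condition)
and skips any remaining scheduled conditions worse than the imputed one,
while conditions later in the order that are *better* are still tested.
An imputation is suppressed when a point already exists at that SNR.

Sessions record every trial (list, word, level, target, utterance, every
scorer's transcription and correct count) and per-scorer point sets, and
are byte-reproducible from (material, profile, seed): the seed is split
into named child streams (listener, list order, one per scorer) via
SHA-256, so adding a scorer never perturbs the listener's draws.

## Psychometric metrics

`max_intelligibility` is the maximum percent score over the points.

`srt50` (default `interpolation`): points are monotonized by isotonic
regression (PAVA, via scipy) — measured curves can be locally
non-monotone through rollover while the SRT lives on the rising limb —
and the first 50% crossing of the piecewise-linear curve is read off,
scanning in the direction of improving intelligibility. Duplicated x
values are collapsed to their mean first, making the estimate invariant
to point duplication. If 50% is never bracketed (all points above, or
all below), the SRT is undefined and `None` is returned — never an
extrapolation. `slope_at_50` is the slope of the bracketing linear
segment (for an exact 50% point, the segment to the next strictly higher
point).

`logistic_fit`: a four-parameter logistic is least-squares fitted
(scipy `curve_fit`, bounds floor ∈ [0, 50), ceiling ∈ (50, 100],
k ∈ (0, 20]); the SRT is the fitted curve's 50% crossing (rejected as
undefined if it falls outside the tested range) and the slope is the
analytic derivative there. On noiseless logistic points the two methods
agree to a fraction of a dB; the fit gives smoother slope estimates,
interpolation makes fewer assumptions and matches clinical practice.

## Analyses

Raw difference = automated − manual; absolute difference = |raw|. Cohort
tables report mean ± sd of both, per list, per hearing status (NH ≤ 20 <
mild ≤ 40 < moderate ≤ 70 < severe ≤ 90 dB HL, from the four-frequency
PTA), and for per-session SRT/maximum-intelligibility; sample sd
(ddof = 1, 0 for n = 1).

Convergence: for each fully presented list occurrence the cumulative
phoneme-weighted score after k words, S_k, is compared to the final
S_17; |S_k − S_17| is averaged per subject or per list and reported as
mean ± sd by word index. Early-stopped lists are excluded — S_17 does
not exist for them. With equal phoneme counts per word the
phoneme-weighted and word-mean definitions of S_k coincide.

Test–retest: for session pairs sharing listener and mode, the metric
difference is oriented retest − test; pairs with an undefined metric in
either session are dropped and counted. As measurement noise shrinks
(more phonemes per point), absolute retest differences collapse toward
zero — a consistency property the test suite checks.

## Problem sizes and numerical choices

The test suite exercises desk-scale versions of each analysis: cohorts of
3–10 listeners, 200 replicates for SRT recovery (11 points × ~500
phonemes each), and 10,000+ phonemes for scorer-calibration checks —
sizes chosen so each property is measured with comfortable statistical
margin while the whole suite runs in well under a minute. Stochastic
assertions use 3-binomial-SE bands. All randomness flows from explicit
seeds; hypothesis-based property tests run derandomized.

## Limitations

- The virtual listener is a parametric stand-in for human patients: no
  lexical/contextual effects, no fatigue or learning across lists, no
  reaction-time window, no binaural advantage model (the noise-mode SRT
  link simply lives on the SNR axis).
- The ASR emulator is a per-phoneme error channel calibrated to two
  marginal rates; it does not model acoustic similarity structure,
  insertions/deletions by the recognizer, or confidence.
- Contralateral masking is deliberately not computed (a no-op hook marks
  where it would apply); its rules live in external audiometric
  guidelines.
- Group-level inferential statistics (ANOVAs, non-parametric tests,
  corrections) are out of scope; the analysis module stops at the
  descriptive mean ± sd tables those tests would consume.
- Passing tests therefore validate the *procedures, scoring rules and
  estimators* under a controlled generative model — not the clinical
  performance of any real recognizer on real patients.
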