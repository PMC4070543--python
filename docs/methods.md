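# Methods

## The estimation problem

The target is a six-way classification of a child speaker into calendar-age
groups 7–12 from sustained vowel phonations. The acoustic correlates of age
in this range — fundamental frequency (f0) declining on the order of 10 Hz
per year and formant frequencies shrinking roughly 1% per year as the vocal
tract grows — are small compared with between-speaker spread, so the classes
overlap heavily by construction. The system attacks the problem by
conditioning on the vowel (six specialist classifiers instead of one
generalist) and then fusing the specialists' decisions per speaker.

## Front end

Each utterance is reduced to one 120-dimensional vector:

* 55 ms frames, 27.5 ms hop (50% overlap), per-frame pre-emphasis
  (coefficient 0.97) and Hamming window;
* power spectrum → 40 triangular mel filters (HTK-style scale
  `2595·log10(1+f/700)`, equally spaced in mel between 0 Hz and Nyquist) →
  floored log (floor 1e-10) → orthonormal DCT-II, keeping all 40
  coefficients including the 0th;
* delta and delta-delta by ±2-frame linear regression with edge replication,
  computed over the whole frame sequence;
* the central frame's [static, delta, delta-delta] triplet is the
  utterance's vector.

Forty filters with a full-rank DCT is the minimal configuration consistent
with 40 static coefficients from "narrow" filters; the filter count, window
type, hop and the identity of the single analysis frame are this package's
choices — standard ASR front-end defaults. Sustained vowels are
near-stationary, so which frame is kept matters little, and the deltas of a
clean sustained vowel are near zero; they mainly capture phonation
instability. The front end reads mono PCM WAV at any rate (the corpus
convention is 20 kHz / 16-bit) and writes feature tables as CSV
(`speaker_id, age, gender, vowel, f001..f120`).

## Classifiers

**ELM.** Input weights and biases are drawn uniformly from [−1,1]; features
are affinely scaled per dimension to [−1,1] using training min/max (stored
on the model and re-applied at prediction); output weights are the
minimum-norm least-squares solution `β = H⁺T` against one-hot targets;
decoding is argmax with lowest-index tie-break. Activations: sigmoid, sin,
hardlim (z ≥ 0 → 1), plus an identity hook for testing.

**SaELM.** Differential evolution over the concatenated input-weight/bias
vector, with the analytic `β` solve inside the fitness function. Settings:
DE/rand-to-best/2 mutation (`v = x_r1 + F(x_best−x_r1) + F(x_r2−x_r3) +
F(x_r4−x_r5)`, five distinct partners), F = 1, binomial crossover with
CR = 0.5 and a guaranteed mutant gene, greedy selection, 40 individuals, 15
generations, 60 hidden neurons. Fitness is RMSE of the one-hot targets on a
held-out validation split (20%, stratified by class; when the split cannot
hold every class — fewer validation slots than classes, or singleton
classes — it falls back to a plain shuffled split). Equal-fitness selection
ties break toward the smaller output-weight norm. Trial vectors are clipped
to [−1,1], the conventional ELM weight range. The returned model re-solves
`β` on the full training set with the winning input layer, which makes
`generations=0` exactly the best-of-initial-population ELM. Greedy selection
makes the best-fitness trajectory non-increasing; this is asserted in the
tests rather than assumed.

**Vowel gate.** A one-vs-one linear maximum-margin classifier (sklearn's
SVC with linear kernel, C = 1, majority vote over the 15 class pairs) routes
test utterances to per-vowel models. It is trained on the same training
folds as the age classifiers, only with vowel labels.

## Fusion

Raw classifier score vectors (unbounded reals — these networks do not emit
probabilities) are used twice:

* min-max normalized per sample into memberships μᵢʲ ∈ [0,1]; an all-equal
  vector maps to the uniform 1/n (maximal ambiguity);
* the **local confidence** wᵢ = exp(−½(|1 − (S_max1−S_max2)/(S_max1−S_min)|/σ)²)
  is computed from the *raw* scores — after min-max normalization S_min is
  pinned to 0 and the ratio would lose its meaning. σ = 0.05 by default, so
  w is effectively binary: ≈1 when the runner-up sits near the score
  minimum, ≈0 otherwise. An all-equal vector gets the total-unreliability
  limit w = exp(−½/σ²).

The **global confidence** δᵢʲ is a binary matrix estimated from training
data only: per vowel-classifier, leave-one-out recall per age class; each
class's best classifier (ties to the lowest index) gets δ = 1, all others 0.
Inside the evaluation pipeline the LOO refits use a plain ELM with the same
hidden-layer size as the age classifiers — refitting the full DE loop once
per held-out sample would multiply the cost by the population×generations
budget while the winner-take-all structure of δ depends only on recall
rankings. `global_confidence_loo` accepts any classifier factory, so callers
who want the exact SaELM LOO can pay for it.

The fuzzy-or operator blends an optimistic max-term with a δ-gated weighted
mean, with compensation degree γ = 0.6 (γ = 1 is pure max, γ = 0 the
weighted average). The fusion unit is the speaker: every routed utterance of
a speaker contributes one (μ, w, δ-row) triple, duplicates included if the
gate routes two utterances to the same vowel model. Winner ties break to the
lowest class index. The operator's output is bounded in [0,1] whenever all
inputs are; it is *not* guaranteed to lie strictly between the member sets'
min and max for arbitrary w and δ (the gating can push it below the min), so
the tests assert boundedness and the two γ limits, not a strict compromise
property.

## Evaluation protocol

Cross-validation is 3-fold, **speaker-disjoint** and age-stratified: all six
vowels of a child share speaker identity, so splitting at the utterance
level would leak test voices into training. Three experiment modes:
vowel-independent (one pooled classifier, each utterance a sample),
vowel-based (six specialists with gate routing; per-vowel accuracies are
reported over utterances grouped by their true vowel, so routing errors
count against the vowel they belong to), and fusion (one decision per test
speaker). Confusion matrices are reported per fold and pooled; accuracies
are computed unrounded and rounded to 2 decimals only for display. The
6-class matrix can be collapsed onto the coarser 7–8 / 9–10 / 11–12 bands by
summing row- and column-groups, which preserves the total count.

## Synthetic data

The corpus generator emulates the layout the method assumes — six vowels per
speaker, 60 speakers per age by default (2160 utterances of 5 s at 20 kHz) —
and the statistical structure the method exploits:

* **waveform level**: glottal impulse train at the speaker's f0 (0.5% cycle
  jitter, 2% aspiration noise) through cascaded two-pole resonators at the
  speaker's scaled formants; formant tables use child-typical patterning
  (/a/ open, /i/ close front, /u/ close back, schwa central); age model:
  f0 falling linearly 280 → 230 Hz over ages 7 → 12, formant scale falling
  1%/year, per-speaker relative SDs of 5% (f0) and 2% (scale). These are
  plausible developmental magnitudes chosen once to make age classes
  learnable but overlapping; they are generator constants, not measurements
  of any real corpus.
* **feature level**: unit-variance Gaussian clusters with between-class mean
  distance `separation` (in within-class SD units). The complementary map
  assigns each stream the subset of classes it can separate (others collapse
  onto a common mean), creating the regime where fusion has information to
  gain; `stream_offset` displaces each stream along its own direction so the
  vowel gate has something to learn.

What the generator does **not** model: gender differences, recording-channel
and room variability, vowel-dependent f0, non-stationarity of real
phonations, or Malay phonetics specifically. Passing tests therefore
demonstrate the pipeline's correctness and the fusion mechanism's behavior
under its stated assumptions, not field performance on real children's
speech.

## Problem sizes and observed behavior

The test suite and the acceptance script run scaled-down designs chosen so
that each experiment completes in seconds while keeping its qualitative
regime: the complementary experiment uses 3 streams × 6 classes × 24
speakers/class (separation 5 SD) with plain-ELM specialists (40 hidden
neurons), where fused accuracy reliably exceeds the best single stream by
~3–7 points (medians over 10 draws). The waveform-level end-to-end run uses
12 speakers/age × 0.5 s utterances with a reduced DE budget (10 individuals,
5 generations, 20 hidden neurons). At that corpus size the six-way problem
sits close to its Bayes limit — adjacent ages differ by ~10 Hz in mean f0
against a ~13 Hz speaker SD — so six-class accuracies land modestly above
chance and fusion does not always beat the best specialist; the collapsed
three-band accuracy is the more stable summary. Scaling any of this up is a
matter of the generator's counts and the DE budget.

## Numerical choices and degenerate inputs

* `log_floor = 1e-10` guards log(0) on silence; a silent utterance yields
  the floor's DC cepstrum and exactly zero deltas.
* The filterbank constructor rejects configurations whose adjacent mel
  centers collide on the same FFT bin.
* `lstsq`'s minimum-norm solution covers the rank-deficient case (more
  hidden neurons than training samples) without regularization.
* Constant feature dimensions scale to 0 rather than dividing by zero.
* All tie-breaks (argmax decoding, δ winners, fused winners) resolve to the
  lowest index and are documented contracts, not incidental behavior.
* Model serialization stores float64 arrays as base64 inside JSON;
  round-trips reproduce predictions bit-exactly.

## Known limitations

* The DE stage implements the single stated mutation strategy with fixed
  F and CR; no strategy-pool self-adaptation.
* Global confidence assumes every vowel group contains every age class;
  corpora violating this are rejected rather than imputed.
* The per-speaker fusion unit presumes the gate routes all of a speaker's
  utterances somewhere; there is no abstention mechanism.
* Real-corpus accuracy claims are out of reach by construction — the
  package evaluates on synthetic data only.
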