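# Methods

## Problem setting

Sleep staging assigns one of five stages (Wake, N1, N2, N3, REM) to every
30-second epoch of an overnight recording. Two sources of per-epoch
probability distributions over stages ("hypnodensities") are treated
uniformly: the softmax output of an automatic classifier (averaged over an
ensemble of channels) and the vote fractions of a panel of S human scorers.
Epochs without scoreable content are coded UNSCORED and excluded from every
metric, ranking and mask; misaligned epoch grids always raise rather than
truncate.

The canonical stage order W=0, N1=1, N2=2, N3=3, REM=4 fixes the column
order of every probability matrix and doubles as the tie-break priority:
wherever votes or probabilities tie exactly (consensus, argmax hypnogram),
the lowest code — the more wake-like stage — wins. Using one convention
everywhere makes `majority_score` provably equal to
argmax ∘ `panel_to_hypnodensity`, which the tests verify by exhaustive
enumeration of all 5³ three-scorer patterns.

## Uncertainty metrics

For a row p with largest entries p⁽¹⁾ ≥ p⁽²⁾ (p⁽²⁾ taken over stage
indices excluding one argmax index, so a k-way tie at the top yields
p⁽²⁾ = p⁽¹⁾ and maximal margin/ratio uncertainty):

- least confidence U_L = (1 − p⁽¹⁾)·n/(n−1)
- margin of confidence U_M = 1 − (p⁽¹⁾ − p⁽²⁾)
- ratio of confidence U_R = p⁽²⁾/p⁽¹⁾ (0 when p⁽²⁾ = 0)
- coefficient of unalikeability U_U = 1 − Σ pᵢ² (the Gini impurity;
  maximum 1 − 1/n = 0.8 at the uniform row)
- classification entropy U_E = −Σ pᵢ log₂ pᵢ / log₂ n with 0·log 0 = 0

All five are 0 exactly at one-hot rows, permutation-invariant, and
orientated so larger = more uncertain. The confidence ratio is commonly
quoted as p⁽¹⁾/p⁽²⁾, which is unbounded and decreases with uncertainty; we
store its reciprocal so the five metrics share a [0, 1] range and one
orientation. The transform is strictly order-reversing, so rank-based
grey-area selection is unaffected. On rows supported on two stages,
p = (q, 1−q, 0, 0, 0), all five metrics are strictly increasing in
q ∈ (0, 0.5] and therefore induce the same epoch ranking; they differ only
on rows with three or more supported stages, which is why entropy-family
and max-family metrics produce slightly different exclusion curves.

## Grey areas

Two flagging strategies, with different budget semantics:

- **threshold**: flag u > t, strictly — an epoch exactly at the threshold
  is not a grey area. The default t = 0.6 on unalikeability corresponds,
  for a 10-scorer panel, to flagging splits at least as dispersed as 4/3/3
  (U_U = 0.66) while keeping 5/5 splits (U_U = 0.5) and 6/4 splits
  (U_U = 0.48) unflagged. The flagged count then varies per recording with
  scoring difficulty and model calibration.
- **percentile**: flag exactly ⌊f·N_scored⌋ epochs, the most uncertain by
  rank pooled across the dataset. Ties at the cut break by
  (recording index, epoch index) ascending, making masks deterministic and
  nested in f. A per-recording mode budgets each recording separately —
  the trade-off between the two is genuinely open (pooled ranking spends
  the review budget where it is most needed; per-recording keeps the
  workload per night constant), so both are exposed and pooled is the
  default.

## Evaluation

Accuracy, Cohen's κ (chance-corrected via marginal products), per-stage
precision/recall/F1, macro (unweighted) and support-weighted averages are
computed epoch-wise through scikit-learn behind the module surface. Stages
with zero reference support are reported absent and excluded from the macro
averages with a warning rather than imputed as zero. Both macro and
weighted F1 are always reported; exclusion curves conventionally use the
weighted form. When a scorer panel is the reference, epochs any scorer
marked uncertain are excluded from headline metrics by default (they have
no trustworthy ground truth) but retained for the stratified grey-area
agreement analysis, which reports a 2×2 manual-vs-model grey confusion
matrix and the manual-grey capture separately within the marked and
unmarked strata.

The exclusion and capture curves satisfy, and the tests assert, the exact
identity: retained-set error count = total errors × (1 − capture(f)).

## Signal preprocessing

Channels pass through zero-phase bandpass → polyphase resample → robust
normalization, in that order. The bandpass is an 8th-order Butterworth
(0.3–32 Hz) applied forward–backward (`sosfiltfilt`), chosen because zero
phase preserves epoch alignment; the effective magnitude response is the
squared design response. Resampling to 64 Hz uses band-limited polyphase
interpolation (no aliasing above 32 Hz). Normalization subtracts the
per-recording median and divides by the interquartile range; whether the
centering step belongs in the convention is ambiguous, so it is a flag
(`center=`, default on — the robust analogue of z-scoring). Division by
IQR makes the whole pipeline exactly invariant to affine rescaling of the
raw input, the property that lets one model serve montages whose amplitudes
differ by orders of magnitude; a constant signal (IQR = 0) is rejected by
name. Epoch slicing requires fs·30 to be an integer and drops a trailing
partial epoch with a warning.

## Reference classifier

The pluggable classifier contract is "per-epoch block in, valid 5-vector
out (tolerance 1e-6)". The bundled reference model is log₁₀ band power in
the five classic EEG bands (delta 0.5–4, theta 4–8, alpha 8–12, sigma
12–16, beta 16–32 Hz, from the per-epoch periodogram) standardized and fed
to a multinomial logistic regression (L-BFGS, C = 1). It is deterministic
given seed and data, trains in seconds on a CPU, and exists to exercise the
pipeline end-to-end — it is not a clinical-grade stager and deliberately
does not attempt the deep segmentation architectures used in production
systems, which need large clinical corpora and accelerators to train.

## Synthetic study generator

The generator emulates the data properties the framework needs, not the
physiology:

- **Hypnogram**: first-order Markov chain. The shipped transition matrix
  was built by detailed balance to have stationary distribution exactly
  (W, N1, N2, N3, REM) = (0.15, 0.10, 0.45, 0.15, 0.15) — a plausible
  whole-night stage mix — with every self-transition ≥ 0.85 for realistic
  stage persistence (≈7% of epochs are transitions; ≈14% are adjacent to
  one).
- **Scorer panel** (defaults: S = 10, reliability 0.85, ambiguity boost 3):
  each scorer reproduces the true stage with probability r, otherwise
  draws from a confusion kernel favouring adjacent-depth stages; next to a
  true transition the error probability triples (capped at 1). Per-scorer
  "uncertain" marks fire at 0.004 per epoch, ×14 next to transitions;
  with ten scorers this yields ≈9–10% of epochs marked by at least one
  scorer and ≈1% exactly-tied majority votes, and per-scorer accuracy
  against truth of 0.80–0.82 — chosen once as a realistic multi-scorer
  panel and frozen.
- **Model hypnodensity**: row i is a Dirichlet draw with concentration
  a·onehot(truthᵢ) + c·kernel_row + b, a = a0/(temp·difficulty),
  difficulty 1 at stable epochs and 3 next to transitions
  (a0 = 5, c = 1.8·difficulty, b = 0.3). Temperature → 0 recovers one-hot
  truth; the defaults give ≈83% argmax accuracy, κ ≈ 0.77 and a
  Spearman correlation ≈ 0.4 between unalikeability and the error
  indicator — i.e. confidence is calibrated to correctness, which is the
  property the grey-area analyses are designed to detect.
- **PSG signals**: white noise filtered into the five bands and re-weighted
  per epoch by the stage's shipped band-power profile (alpha-dominant
  Wake, theta-heavy N1, sigma-weighted N2, delta-dominant N3, mixed
  low-amplitude REM), a log-normal per-epoch spectral jitter (σ = 0.5)
  shared across channels, independent channel noise and per-channel gains.
  The jitter makes individual epochs spectrally ambiguous, so the
  reference classifier lands at ≈85–90% held-out accuracy with its errors
  concentrated on ambiguous epochs, rather than saturating. No spindle or
  K-complex morphology is attempted: spectral separability is the design
  goal, so passing tests demonstrate the framework's logic, not
  clinical-EEG performance.

All randomness flows from one integer seed through
`numpy.random.SeedSequence([seed, stream])` with fixed stream ids
(hypnogram 0, panel 1, model 2, psg 3); artifacts are bit-reproducible,
and the default matrix/kernel/profiles ship as JSON data files for test
transparency.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: 5000-epoch studies for metric/curve properties, a 10-recording
× 960-epoch × 10-scorer panel study, and an 8-recording × 8 h × 4-channel
signal pipeline (signals synthesized at 128 Hz and resampled to 64 Hz by
the preprocessing chain, since the 32 Hz band edge must lie strictly below
Nyquist). These sizes give stable statistics at interactive runtimes.

## Known limitations

- The bundled classifier is a linear model on band powers; it ignores
  epoch context and waveform morphology entirely.
- Simulated scorers are exchangeable: no per-scorer bias, experience
  effect, or centre effect.
- The synthetic model's miscalibration is purely transition-driven; real
  stagers also show dataset-shift miscalibration that the generator does
  not emulate (the threshold-based grey fraction on real cross-domain data
  can therefore behave differently).
- Exact probability ties (and hence the priority tie-break in argmax) are
  measure-zero for model hypnodensities; the convention matters mainly for
  vote fractions, where ties are common.
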