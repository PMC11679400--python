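# Methods

## Problem

Wrist-worn actigraphs summarise movement as *activity counts*, one scalar
per 30-s epoch, and sleep studies score each epoch as sleep or wake
against polysomnography (PSG).  Count algorithms are device-specific, so
a classifier trained on one device's counts degrades on another's — the
two count types are related by a monotone but nonlinear map.  `dasleep`
implements an epoch-level sleep/wake classifier that is trained on a
labeled *source* device and adapted, without target labels, to a *target*
device, together with the classic count-based scorers used as
comparators and the endpoint statistics used to judge them.

## Model

The classifier is a 1-D convolutional network over a fixed-length count
window centred on the epoch being scored.  Two window schemes are
canonical: 25 min of context on each side of the current epoch
(50 + 1 + 50 = 101 samples at 30-s epochs) and 25 min of past context
with 1 min of future context (50 + 1 + 2 = 53 samples).

The feature extractor is three blocks of (same-padded conv, batch
normalisation, ReLU, max-pool of size 2); each pool halves the temporal
length (101 → 50 → 25 → 12; 53 → 26 → 13 → 6).  The flattened features
feed two heads:

* **label head** — dense layer, dropout, 2-way softmax over sleep/wake;
  trained with cross-entropy on labeled source windows only;
* **domain head** — gradient-reversal operator, dense layer, 2-way
  softmax over source/target; trained with cross-entropy on source and
  target windows alike.

The gradient-reversal operator is the identity in the forward pass and
multiplies the backward gradient by −λ.  The domain head therefore
learns to *recognise* the domain while the extractor is pushed to
*hide* it, so at equilibrium the shared features are domain-invariant
but still sleep-informative.  Turning the domain head off gives the
plain source-only CNN used as the non-adapted reference.  At inference
only the label head is used and batch-norm statistics are frozen.

Counts are fed raw (no rescaling); batch normalisation inside the
network is relied on to absorb magnitude differences.

### Domain-specific batch normalisation

Batch-norm statistics are kept **per domain** (shared affine
parameters, separate batch and running moments — the AdaBN/DSBN
construction).  This is essential, not cosmetic: activity counts differ
across devices by an order of magnitude at high activity, so with a
single set of statistics the target rows of a mixed batch dominate the
shared moments, the source rows' normalised activations collapse
toward zero, and label learning fails — adversarial training then
reliably *underperforms* the source-only baseline.  With per-domain
moments, each domain is standardised into a common range before the
adversary aligns the remaining distributional differences.  At
inference the frozen statistics of the domain being scored are used:
the adapted model owns target statistics (estimated from unlabeled
target windows during training, no labels involved), while the
source-only baseline has only source statistics — which is precisely
the informational difference between the two methods.

### Training

Optimisation is Adam on mini-batches.  Adversarial batches are half
source, half target; only the source half contributes to the label
loss.  Two details matter for stability of the min–max game on small
problems and are exposed in `TrainConfig`:

* **λ schedule** (`lambda_schedule`, default `ramp`): λ follows the
  sigmoid ramp 2/(1+e^{−10p}) − 1 in training progress p, so label
  features can form before alignment pressure peaks.  A constant
  schedule is available.
* **domain-head learning rate** (`domain_head_lr_multiplier`): the
  reversed gradient is only informative if the domain head tracks the
  current best discriminator, so the head trains with a multiple of the
  base learning rate.

Early stopping monitors validation label loss on held-out source
subjects.  Among epochs whose validation loss is within 5% of the best,
the *latest* snapshot is restored, because later epochs embody more
domain alignment at equal source fit.

Target-domain labels are never read during training: they are stripped
from the target window set on model construction.

## Classic comparators

*Cole–Kripke* scores minute t from the weighted sum
0.001·(106 A_{t−4} + 54 A_{t−3} + 58 A_{t−2} + 76 A_{t−1} + 230 A_t +
74 A_{t+1} + 67 A_{t+2}) with sleep when the sum is < 1, using the
published one-minute coefficient set.  *Sadeh* scores minute t with
PS = 7.601 − 0.065·AVG − 1.08·NATS − 0.056·SD − 0.703·LOCACT (counts
capped at 300; AVG the ±5-min window mean, NATS the number of window
minutes with counts in [50, 100), SD the population standard deviation
of the current and five preceding minutes, LOCACT = ln(count+1)), sleep
when PS ≥ 0.  30-s counts are aggregated to minutes by summing pairs and
minute labels duplicated back to 30-s epochs; out-of-record context is
zero.

The five rescoring rules are applied sequentially, each in one
left-to-right pass over the previous rule's output, with triggers judged
against that pass's input: (1) after ≥4 wake epochs the next sleep epoch
becomes wake; (2) after ≥10, the next 3; (3) after ≥15, the next 4;
(4) sleep runs of ≤6 epochs flanked by ≥10 wake epochs on both sides
become wake; (5) sleep runs of ≤10 epochs flanked by ≥20.  Rule 5's
island size follows the original rule set; a single-epoch literal
variant is selectable (`literal_rule5`).  The flanking requirement is
both-sided.  Rescoring only ever converts sleep to wake.

## Endpoints and evaluation

Sleep is the positive class throughout: sensitivity = % of true sleep
epochs detected, specificity = % of true wake epochs detected, precision
= % of predicted sleep that is correct, F1 = harmonic mean of
sensitivity and precision.  ROC-AUC uses the trapezoidal convention.

Sleep onset is the first run of ≥10 consecutive sleep epochs (5 min,
configurable).  WASO is the wake time in minutes from onset to the end
of the record; a record with no onset is flagged and its full wake time
reported.  Sleep efficiency is the percentage of the record asleep; with
no diary information the whole record is the in-bed interval.  Per
subject, endpoint errors are predicted − true; cohorts are summarised by
MAE, RMSE, and a 95% limits-of-agreement width 2·1.96·SD of the
differences (Bland–Altman convention), with classification metrics
averaged across subjects unweighted.  Pooled-epoch confusion matrices
are also available.

## Synthetic cohorts

The generator emulates the structure that matters for this problem, not
any particular clinical population:

* **Hypnogram**: an alternating two-state semi-Markov process.  Records
  are 8 h at 30-s epochs, opening with 30 min of wake; bout lengths are
  lognormal (dispersion σ = 0.6) with mean sleep bouts of 45 min and
  wake bouts of 20 min, giving a long-run sleep fraction of ≈0.69 —
  typical of in-bed PSG cohorts that include sleep-disordered subjects.
* **Counts**: state-conditioned zero-inflated lognormals.  Sleep epochs
  are zero with probability 0.6, wake epochs with probability 0.1;
  nonzero counts have median 15 (sleep) and 300 (wake) with log-scale
  σ = 1.  A fraction of epochs is deliberately ambiguous — motionless
  wake (15% of wake epochs emit sleep-law counts) and restless sleep
  (10% of sleep epochs emit wake-law counts) — which bounds the accuracy
  any count-only classifier can reach.
* **Domain shift**: target-domain subjects are generated under the
  source count law and passed through the monotone map c ↦ c for
  c ≤ 20, c ↦ 20 + s·(c − 20)^e for c > 20 (defaults s = 1, e = 1.5), so
  the domains differ only by the count-scale warp.  The breakpoint 20 is
  small relative to wake-level counts, placing the sleep/wake overlap
  region inside the warped zone; this is what makes the shift
  consequential — a source-optimal decision boundary above the
  breakpoint lands in the wrong place on the target scale.  Counts are
  real-valued; integer quantisation is available (`round_counts`).

What the simulator does **not** model: raw tri-axial acceleration (hence
no z-angle comparator), sleep stages beyond binary sleep/wake, circadian
or multi-night structure, inter-subject heterogeneity of count laws, and
device noise such as off-wrist periods.  Passing tests on this simulator
demonstrate that the mechanisms work — windows, adversarial adaptation,
rescoring, endpoints — not that any particular accuracy will be attained
on a real cohort.

## Numerical choices

* Split sizes: validation and test are `round(n·fraction)` of subjects,
  remainder to train; splitting is always by subject to preclude
  leakage.  Default fractions 65-20-15.
* Window edges: zero-padded with an explicit pad mask, so every epoch of
  a record receives a prediction (WASO/SE need whole records).
* Precision with no predicted sleep epochs is reported as 0 with an
  explicit flag; ROC-AUC with single-class truth raises.
* Network engine: float64 numpy; conv as im2col matmul; He
  initialisation; Adam (β₁ = 0.9, β₂ = 0.999); batch-norm ε = 1e−5,
  momentum 0.1.  All layer gradients are verified against central finite
  differences in the test suite.
* Determinism: every stochastic component (bouts, counts, splits,
  initialisation, batch order, dropout) is a pure function of its seed;
  repeated runs are bitwise identical.

## Problem sizes

Development-scale experiments in the documentation and the reproduction
script use cohorts of 20–40 subjects per domain (≈1000 epochs each) and
a narrow network (8/16/32 channels, 32 dense units), which train in
minutes on one CPU core.  These sizes are the package's chosen
desk-scale defaults for demonstrating the mechanism; nothing in the
implementation is specific to them.

## Known limitations

* Adversarial adaptation is a saddle-point problem; on small cohorts
  its benefit varies across seeds, which is why the documented
  comparisons use several seeds and report medians.
* The classic-scorer coefficient sets are the published one-minute
  versions, calibrated to their original devices' count scales.  On the
  simulator's device-like count magnitudes (and a fortiori on the warped
  target domain) they label most epochs wake — itself a faithful
  illustration of why count-scale transfer breaks fixed-coefficient
  algorithms, but not a statement about their performance on the devices
  they were fitted for.
* The endpoint conventions (onset rule, in-bed interval = record) are
  reasonable defaults, not clinical prescriptions; both are
  configurable.
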