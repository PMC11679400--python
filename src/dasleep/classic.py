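"""Classic count-based sleep-scoring algorithms and rescoring rules.

Two generations of actigraphy scorers predate the neural approach and
serve as comparators:

* **Cole–Kripke** — a weighted moving sum of minute-level activity
  counts (four minutes back, the current minute, two minutes forward);
  the epoch is sleep when the scaled sum falls below 1.
* **Sadeh** — four hand-crafted features of an 11-minute window combined
  by a published linear discriminant; nonnegative score means sleep.

Both operate on 1-minute epochs: 30-s counts are aggregated by summing
pairs, and minute labels are duplicated back to 30-s epochs.

The **Webster rescoring rules** are a deterministic post-pass that
relabels sleep epochs near long wake runs as wake, trading sensitivity
for wake specificity.  Rules are applied sequentially, each in a single
left-to-right pass over the previous rule's output, and only ever
convert sleep to wake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .series import SLEEP, WAKE, EpochSeries, as_hypnogram

# Cole-Kripke 1992 one-minute weights for counts at minutes t-4 .. t+2,
# applied as sleep iff 0.001 * sum(w_i * A_i) < 1.
COLE_WEIGHTS = np.array([106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0])
COLE_SCALE = 0.001

# Sadeh 1994 discriminant: PS = 7.601 - 0.065*AVG - 1.08*NATS
#                               - 0.056*SD - 0.703*LOCACT ; PS >= 0 -> sleep
SADEH_INTERCEPT = 7.601
SADEH_COEF_AVG = 0.065
SADEH_COEF_NATS = 1.08
SADEH_COEF_SD = 0.056
SADEH_COEF_LOG = 0.703
SADEH_CAP = 300.0


@dataclass
class RescoreRule:
    """One Webster rule.

    ``kind='run'``: after a run of at least ``trigger_wake_run``
    consecutive wake epochs, the next ``relabel_next`` consecutive sleep
    epochs are relabeled wake.  ``kind='island'``: a maximal sleep run of
    at most ``max_sleep_island`` epochs flanked by wake runs of at least
    ``surround_wake`` epochs is relabeled wake entirely.
    """

    kind: str
    trigger_wake_run: int = 0
    relabel_next: int = 0
    max_sleep_island: int = 0
    surround_wake: int = 0

    def __post_init__(self):
        if self.kind not in ("run", "island"):
            raise ValueError("rule kind must be 'run' or 'island'")
        ints = (
            (self.trigger_wake_run, self.relabel_next)
            if self.kind == "run"
            else (self.max_sleep_island, self.surround_wake)
        )
        if any(v < 1 for v in ints):
            raise ValueError("rule parameters must be >= 1")


def default_rules(literal_rule5: bool = False) -> List[RescoreRule]:
    """The five published rescoring rules, in application order.

    The fifth rule's island size is 10 epochs per the original rule set;
    ``literal_rule5=True`` selects the single-epoch variant instead.
    """
    return [
        RescoreRule("run", trigger_wake_run=4, relabel_next=1),
        RescoreRule("run", trigger_wake_run=10, relabel_next=3),
        RescoreRule("run", trigger_wake_run=15, relabel_next=4),
        RescoreRule("island", max_sleep_island=6, surround_wake=10),
        RescoreRule(
            "island",
            max_sleep_island=1 if literal_rule5 else 10,
            surround_wake=20,
        ),
    ]


def _minute_counts(series: EpochSeries) -> np.ndarray:
    """Aggregate counts to 1-minute epochs (sum; 1-min input passes through)."""
    c = series.counts
    per_min = int(round(60.0 / series.epoch_len))
    if per_min <= 1:
        return c.astype(float)
    n_full = len(c) // per_min
    mins = c[: n_full * per_min].reshape(n_full, per_min).sum(axis=1)
    if len(c) % per_min:  # partial trailing minute
        mins = np.append(mins, c[n_full * per_min :].sum())
    return mins


def _upsample(minute_labels: np.ndarray, series: EpochSeries) -> np.ndarray:
    per_min = int(round(60.0 / series.epoch_len))
    if per_min <= 1:
        return minute_labels.astype(np.int8)
    return np.repeat(minute_labels, per_min)[: len(series)].astype(np.int8)


def cole_kripke_scores(minute_counts: np.ndarray) -> np.ndarray:
    """Scaled Cole weighted sums per minute, zero-padded at the edges."""
    n = len(minute_counts)
    padded = np.zeros(n + 6)
    padded[4 : 4 + n] = minute_counts
    win = np.lib.stride_tricks.sliding_window_view(padded, 7)
    return COLE_SCALE * (win @ COLE_WEIGHTS)


def cole_kripke(series: EpochSeries) -> np.ndarray:
    """Cole–Kripke sleep/wake hypnogram at the series' epoch resolution.

    Rescoring is *not* applied here; see :func:`apply_rescored_algorithm`.
    """
    mins = _minute_counts(series)
    labels = (cole_kripke_scores(mins) < 1.0).astype(np.int8)
    return _upsample(labels, series)


def sadeh_scores(minute_counts: np.ndarray) -> np.ndarray:
    """Sadeh discriminant scores per minute (counts capped at 300).

    Features over the 11-minute window centred on each minute (zero
    context beyond the record): window mean (AVG); number of window
    epochs with counts in [50, 100) (NATS); population standard
    deviation of the current and five preceding minutes (SD); and
    ln(current count + 1) (LOCACT).
    """
    c = np.minimum(np.asarray(minute_counts, float), SADEH_CAP)
    n = len(c)
    pad11 = np.zeros(n + 10)
    pad11[5 : 5 + n] = c
    win11 = np.lib.stride_tricks.sliding_window_view(pad11, 11)
    avg = win11.mean(axis=1)
    nats = ((win11 >= 50) & (win11 < 100)).sum(axis=1)
    pad6 = np.zeros(n + 5)
    pad6[5 : 5 + n] = c
    win6 = np.lib.stride_tricks.sliding_window_view(pad6, 6)
    sd = win6.std(axis=1)
    locact = np.log(c + 1.0)
    return (
        SADEH_INTERCEPT
        - SADEH_COEF_AVG * avg
        - SADEH_COEF_NATS * nats
        - SADEH_COEF_SD * sd
        - SADEH_COEF_LOG * locact
    )


def sadeh(series: EpochSeries) -> np.ndarray:
    """Sadeh sleep/wake hypnogram at the series' epoch resolution."""
    mins = _minute_counts(series)
    labels = (sadeh_scores(mins) >= 0.0).astype(np.int8)
    return _upsample(labels, series)


def _apply_run_rule(hyp: np.ndarray, rule: RescoreRule) -> np.ndarray:
    # wake runs are judged on the pass input, so a fired rule does not
    # immediately re-trigger on the wake epochs it just created
    out = hyp.copy()
    n = len(hyp)
    i = 0
    while i < n:
        if hyp[i] != WAKE:
            i += 1
            continue
        j = i
        while j < n and hyp[j] == WAKE:
            j += 1
        if j - i >= rule.trigger_wake_run:
            k = j
            while k < n and k - j < rule.relabel_next and hyp[k] == SLEEP:
                out[k] = WAKE
                k += 1
        i = j
    return out


def _apply_island_rule(hyp: np.ndarray, rule: RescoreRule) -> np.ndarray:
    # islands are judged against the pass input; relabels written to a copy
    out = hyp.copy()
    n = len(hyp)
    i = 0
    while i < n:
        if hyp[i] != SLEEP:
            i += 1
            continue
        j = i
        while j < n and hyp[j] == SLEEP:
            j += 1
        # sleep run [i, j); measure flanking wake runs in the pass input
        if j - i <= rule.max_sleep_island:
            k = i
            while k > 0 and hyp[k - 1] == WAKE:
                k -= 1
            before = i - k
            m = j
            while m < n and hyp[m] == WAKE:
                m += 1
            after = m - j
            if before >= rule.surround_wake and after >= rule.surround_wake:
                out[i:j] = WAKE
        i = j
    return out


def webster_rescore(
    hyp: np.ndarray, rules: Sequence[RescoreRule] = None
) -> np.ndarray:
    """Apply the rescoring rules sequentially to a binary hypnogram.

    Each rule makes one left-to-right pass over the previous rule's
    output.  Within a run-rule pass, relabeled epochs extend the current
    wake run; island rules judge sleep runs and their wake flanks against
    the pass input.  Rescoring only converts sleep to wake, so the wake
    count never decreases.
    """
    hyp = as_hypnogram(hyp)
    if rules is None:
        rules = default_rules()
    out = hyp.copy()
    for rule in rules:
        if rule.kind == "run":
            out = _apply_run_rule(out, rule)
        else:
            out = _apply_island_rule(out, rule)
    return out


ALGORITHMS = {"cole": cole_kripke, "sadeh": sadeh}


def apply_rescored_algorithm(
    name: str, series: EpochSeries, rules: Sequence[RescoreRule] = None
) -> np.ndarray:
    """Score with a classic algorithm then apply the rescoring rules."""
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; choose from {sorted(ALGORITHMS)}")
    return webster_rescore(ALGORITHMS[name](series), rules)
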