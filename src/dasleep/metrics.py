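"""Epoch-level agreement metrics, sleep endpoints, and cohort reports.

Conventions follow the actigraphy-validation literature: **sleep is the
positive class**, so sensitivity is the percentage of true sleep epochs
detected and specificity the percentage of true wake epochs detected.
Endpoints are wake after sleep onset (WASO, minutes of wake between
sleep onset and the end of the record) and sleep efficiency (SE, percent
of in-bed time asleep); with no sleep-diary information the whole record
is treated as the in-bed interval.  Per-subject endpoint errors are
aggregated as MAE, RMSE and a 95% limits-of-agreement width
(Bland–Altman convention, 2 * 1.96 * SD of the differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .series import SLEEP, WAKE, EpochSeries, as_hypnogram

#: default sleep-onset rule: first run of >= 10 consecutive sleep epochs (5 min)
ONSET_RUN_EPOCHS = 10

REPORT_COLUMNS = [
    "model", "acc", "sens", "spec", "prec", "F1",
    "WASO", "WASO_RMSE", "WASO_MAE", "WASO_CI_width",
    "SE", "SE_RMSE", "SE_MAE", "SE_CI_width",
]


@dataclass
class ConfusionMatrix:
    true_sleep_pred_sleep: int
    true_sleep_pred_wake: int
    true_wake_pred_wake: int
    true_wake_pred_sleep: int

    @classmethod
    def from_hypnograms(cls, pred, truth) -> "ConfusionMatrix":
        pred, truth = as_hypnogram(pred), as_hypnogram(truth)
        if len(pred) != len(truth):
            raise ValueError("prediction and truth lengths differ")
        return cls(
            true_sleep_pred_sleep=int(((truth == SLEEP) & (pred == SLEEP)).sum()),
            true_sleep_pred_wake=int(((truth == SLEEP) & (pred == WAKE)).sum()),
            true_wake_pred_wake=int(((truth == WAKE) & (pred == WAKE)).sum()),
            true_wake_pred_sleep=int(((truth == WAKE) & (pred == SLEEP)).sum()),
        )

    @property
    def total(self) -> int:
        return (
            self.true_sleep_pred_sleep
            + self.true_sleep_pred_wake
            + self.true_wake_pred_wake
            + self.true_wake_pred_sleep
        )


def classification_metrics(pred, truth) -> Dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1, in percent.

    Sensitivity and precision treat sleep as positive; F1 is the harmonic
    mean of sensitivity and precision.  When no sleep is predicted,
    precision (and hence F1) is reported as 0 with
    ``precision_defined=False``.
    """
    cm = ConfusionMatrix.from_hypnograms(pred, truth)
    n_sleep = cm.true_sleep_pred_sleep + cm.true_sleep_pred_wake
    n_wake = cm.true_wake_pred_wake + cm.true_wake_pred_sleep
    pred_sleep = cm.true_sleep_pred_sleep + cm.true_wake_pred_sleep
    sens = 100.0 * cm.true_sleep_pred_sleep / n_sleep if n_sleep else 0.0
    spec = 100.0 * cm.true_wake_pred_wake / n_wake if n_wake else 0.0
    prec_defined = pred_sleep > 0
    prec = 100.0 * cm.true_sleep_pred_sleep / pred_sleep if prec_defined else 0.0
    f1 = 2 * sens * prec / (sens + prec) if (sens + prec) > 0 else 0.0
    acc = 100.0 * (cm.true_sleep_pred_sleep + cm.true_wake_pred_wake) / cm.total
    return {
        "acc": acc,
        "sens": sens,
        "spec": spec,
        "prec": prec,
        "F1": f1,
        "precision_defined": prec_defined,
        "confusion": cm,
    }


def roc_auc(probabilities, truth) -> float:
    """Area under the ROC curve of sleep probability vs ground truth."""
    truth = as_hypnogram(truth)
    probabilities = np.asarray(probabilities, float)
    if not np.isfinite(probabilities).all():
        raise ValueError("probabilities must be finite")
    if len(set(truth.tolist())) < 2:
        raise ValueError("ROC-AUC undefined: truth contains a single class")
    return float(roc_auc_score(truth, probabilities))


@dataclass
class WasoResult:
    minutes: float
    onset_epoch: Optional[int]

    @property
    def onset_found(self) -> bool:
        return self.onset_epoch is not None


def sleep_onset(hyp: np.ndarray, onset_run_epochs: int = ONSET_RUN_EPOCHS) -> Optional[int]:
    """First epoch of the first run of >= ``onset_run_epochs`` sleep epochs."""
    hyp = as_hypnogram(hyp)
    run = 0
    for i, v in enumerate(hyp):
        run = run + 1 if v == SLEEP else 0
        if run >= onset_run_epochs:
            return i - onset_run_epochs + 1
    return None


def waso(
    hyp,
    epoch_len: float = 30.0,
    onset_run_epochs: int = ONSET_RUN_EPOCHS,
) -> WasoResult:
    """Wake after sleep onset, in minutes.

    Counts wake epochs from sleep onset to the end of the record.  If no
    onset is found the full record's wake time is returned with
    ``onset_epoch=None`` so callers can flag the subject.
    """
    hyp = as_hypnogram(hyp)
    onset = sleep_onset(hyp, onset_run_epochs)
    segment = hyp if onset is None else hyp[onset:]
    minutes = float((segment == WAKE).sum()) * epoch_len / 60.0
    return WasoResult(minutes=minutes, onset_epoch=onset)


def sleep_efficiency(hyp) -> float:
    """Percent of the record scored as sleep (record = time in bed)."""
    hyp = as_hypnogram(hyp)
    if hyp.size == 0:
        raise ValueError("empty hypnogram")
    return 100.0 * float((hyp == SLEEP).mean())


def endpoint_errors(
    true_values: Sequence[float], predicted_values: Sequence[float]
) -> Dict[str, float]:
    """MAE, RMSE and 95% limits-of-agreement width of per-subject errors."""
    t = np.asarray(true_values, float)
    p = np.asarray(predicted_values, float)
    if t.shape != p.shape:
        raise ValueError("paired value arrays must have equal length")
    d = p - t
    mae = float(np.abs(d).mean())
    rmse = float(np.sqrt((d**2).mean()))
    ci = float(2 * 1.96 * d.std(ddof=1)) if len(d) >= 2 else np.nan
    return {"MAE": mae, "RMSE": rmse, "CI_width": ci}


Predictor = Callable[[EpochSeries], Tuple[Optional[np.ndarray], np.ndarray]]


def constant_predictor(label: int) -> Predictor:
    """All-sleep (label=1) or all-wake (label=0) baseline predictor."""

    def _predict(series: EpochSeries):
        hyp = np.full(len(series), label, dtype=np.int8)
        return np.full(len(series), float(label)), hyp

    return _predict


def evaluate_cohort(
    predictor: Predictor,
    cohort: Sequence[EpochSeries],
    name: str = "model",
    onset_run_epochs: int = ONSET_RUN_EPOCHS,
) -> pd.DataFrame:
    """Per-subject evaluation of one predictor over a labeled cohort.

    Returns a long-format table with one row per subject: classification
    metrics, true and predicted WASO/SE, and (when probabilities are
    available) ROC-AUC.  Aggregation to a report row is done by
    :func:`cohort_report`.
    """
    rows = []
    for s in cohort:
        if s.labels is None:
            raise ValueError(f"subject {s.subject_id!r} has no ground-truth labels")
        probs, hyp = predictor(s)
        m = classification_metrics(hyp, s.labels)
        w_true = waso(s.labels, s.epoch_len, onset_run_epochs)
        w_pred = waso(hyp, s.epoch_len, onset_run_epochs)
        row = {
            "model": name,
            "subject_id": s.subject_id,
            "domain": s.domain,
            "acc": m["acc"],
            "sens": m["sens"],
            "spec": m["spec"],
            "prec": m["prec"],
            "F1": m["F1"],
            "WASO_true": w_true.minutes,
            "WASO_pred": w_pred.minutes,
            "WASO_onset_found": w_pred.onset_found,
            "SE_true": sleep_efficiency(s.labels),
            "SE_pred": sleep_efficiency(hyp),
        }
        if probs is not None and len(set(s.labels.tolist())) == 2:
            row["auc"] = roc_auc(probs, s.labels)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_report(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-subject tables into one comparison row per model.

    Metrics are averaged across subjects (unweighted); endpoint columns
    report the subject-mean predicted endpoint next to the MAE, RMSE and
    limits-of-agreement width of the per-subject prediction errors —
    the standard layout for algorithm-comparison tables in this field.
    """
    out = []
    for name, grp in per_subject.groupby("model", sort=False):
        we = endpoint_errors(grp["WASO_true"], grp["WASO_pred"])
        se = endpoint_errors(grp["SE_true"], grp["SE_pred"])
        out.append(
            {
                "model": name,
                "acc": grp["acc"].mean(),
                "sens": grp["sens"].mean(),
                "spec": grp["spec"].mean(),
                "prec": grp["prec"].mean(),
                "F1": grp["F1"].mean(),
                "WASO": grp["WASO_pred"].mean(),
                "WASO_RMSE": we["RMSE"],
                "WASO_MAE": we["MAE"],
                "WASO_CI_width": we["CI_width"],
                "SE": grp["SE_pred"].mean(),
                "SE_RMSE": se["RMSE"],
                "SE_MAE": se["MAE"],
                "SE_CI_width": se["CI_width"],
            }
        )
    return pd.DataFrame(out, columns=REPORT_COLUMNS)


def pooled_confusion(
    predictor: Predictor, cohort: Sequence[EpochSeries]
) -> ConfusionMatrix:
    """Confusion matrix pooled over all epochs of a cohort."""
    preds, truths = [], []
    for s in cohort:
        if s.labels is None:
            raise ValueError(f"subject {s.subject_id!r} has no ground-truth labels")
        _, hyp = predictor(s)
        preds.append(hyp)
        truths.append(s.labels)
    return ConfusionMatrix.from_hypnograms(
        np.concatenate(preds), np.concatenate(truths)
    )


def baseline_rows(
    cohort: Sequence[EpochSeries], onset_run_epochs: int = ONSET_RUN_EPOCHS
) -> pd.DataFrame:
    """Per-subject rows for the all-sleep and all-wake baselines."""
    frames = [
        evaluate_cohort(constant_predictor(SLEEP), cohort, "All sleep", onset_run_epochs),
        evaluate_cohort(constant_predictor(WAKE), cohort, "All wake", onset_run_epochs),
    ]
    return pd.concat(frames, ignore_index=True)
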