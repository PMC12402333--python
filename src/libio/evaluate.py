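"""Response-prediction performance: AUC, odds ratio, fixed thresholds.

The AUC is computed as the Mann-Whitney pair statistic over all
responder x non-responder pairs (concordant pairs plus half ties),
which equals the trapezoidal area under the ROC curve.  A sample is
predicted a responder iff its score >= threshold (inclusive).  The
odds ratio at a threshold is TP*TN / (FP*FN); when any cell is zero
the Haldane-Anscombe +0.5 correction is applied to all four cells and
the result is flagged.  Threshold calibration searches the midpoints
of consecutive distinct sorted scores for the maximum odds ratio
(ties: higher balanced accuracy, then lower threshold) and the chosen
threshold is then applied unchanged to validation cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, InputError

__all__ = [
    "ConfusionCounts",
    "ThresholdCalibration",
    "roc_auc",
    "confusion_at",
    "odds_ratio",
    "calibrate_threshold",
    "cross_cohort_eval",
    "OddsRatioThresholdClassifier",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int


@dataclass
class ThresholdCalibration:
    threshold: float
    or_at_threshold: float
    or_corrected: bool
    balanced_accuracy: float
    confusion: ConfusionCounts
    training_cohorts: tuple = ()
    modality_or_cancer: str = ""
    tie_break_note: str = ""


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise InputError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """AUC by pair counting: P(score_+ > score_-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with predicted-positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    return ConfusionCounts(
        TP=int((pred & labels).sum()),
        FP=int((pred & ~labels).sum()),
        FN=int((~pred & labels).sum()),
        TN=int((~pred & ~labels).sum()),
    )


def odds_ratio(c: ConfusionCounts) -> tuple[float, bool]:
    """(TP*TN)/(FP*FN); Haldane-Anscombe corrected when any cell is 0."""
    cells = (c.TP, c.FP, c.FN, c.TN)
    if 0 in cells:
        tp, fp, fn, tn = (x + 0.5 for x in cells)
        return (tp * tn) / (fp * fn), True
    return (c.TP * c.TN) / (c.FP * c.FN), False


def _balanced_accuracy(c: ConfusionCounts) -> float:
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    return (sens + spec) / 2.0


def calibrate_threshold(scores, labels, **info) -> ThresholdCalibration:
    """Pick the score threshold maximizing the odds ratio.

    Candidate grid: midpoints of consecutive distinct sorted scores
    (every achievable confusion table).  Thresholds predicting a single
    class are inadmissible.  Ties on the (corrected) odds ratio go to
    the higher balanced accuracy, then the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    if scores.size < 4:
        raise InputError("calibration needs at least 4 samples")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise CalibrationError("all scores identical; no admissible threshold")
    grid = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    note = ""
    for th in grid:
        c = confusion_at(scores, labels, th)
        if (c.TP + c.FP) == 0 or (c.FN + c.TN) == 0:
            continue  # empty predicted class
        o, corr = odds_ratio(c)
        key = (o, _balanced_accuracy(c), -th)
        if best is None or key > best[0]:
            if best is not None and np.isclose(o, best[1].or_at_threshold):
                note = "tie on OR broken by balanced accuracy / lower threshold"
            best = (key, ThresholdCalibration(
                threshold=float(th), or_at_threshold=float(o), or_corrected=corr,
                balanced_accuracy=_balanced_accuracy(c), confusion=c,
                training_cohorts=tuple(info.get("training_cohorts", ())),
                modality_or_cancer=str(info.get("modality_or_cancer", "")),
            ))
    if best is None:
        raise CalibrationError("no admissible threshold found")
    best[1].tie_break_note = note
    return best[1]


def cross_cohort_eval(calib: ThresholdCalibration, cohorts) -> pd.DataFrame:
    """Apply a fixed threshold to each (score table, manifest) cohort.

    Returns per-cohort AUC, confusion counts and odds ratio; cohorts
    with a single response class get ``or_defined = False``.
    """
    rows = []
    for name, score_table, manifest in cohorts:
        merged = score_table.merge(
            manifest[["sample_id", "response_label"]], on="sample_id"
        )
        merged = merged[merged["response_label"] != "unknown"]
        labels = (merged["response_label"] == "responder").to_numpy()
        scores = merged["libio"].to_numpy(dtype=float)
        row = {"cohort": name, "n": len(merged), "threshold": calib.threshold}
        if labels.all() or not labels.any():
            row.update({"auc": np.nan, "odds_ratio": np.nan, "or_defined": False})
        else:
            c = confusion_at(scores, labels, calib.threshold)
            o, corr = odds_ratio(c)
            row.update(
                {
                    "auc": roc_auc(scores, labels),
                    "TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN,
                    "odds_ratio": o, "or_corrected": corr, "or_defined": True,
                }
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if out["or_defined"].any():
        defined = out.loc[out["or_defined"], "odds_ratio"]
        out.attrs["or_mean"] = float(defined.mean())
        out.attrs["or_sd"] = float(defined.std(ddof=1)) if len(defined) > 1 else 0.0
    return out


class OddsRatioThresholdClassifier:
    """Fixed-threshold responder classifier, sklearn-style.

    ``fit`` runs :func:`calibrate_threshold` on training scores;
    ``predict`` applies the frozen threshold (score >= threshold).
    """

    def __init__(self):
        pass

    def fit(self, scores, labels) -> "OddsRatioThresholdClassifier":
        self.calibration_ = calibrate_threshold(scores, labels)
        self.threshold_ = self.calibration_.threshold
        return self

    def predict(self, scores) -> np.ndarray:
        return np.asarray(scores, dtype=float) >= self.threshold_

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "OddsRatioThresholdClassifier":
        return self
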