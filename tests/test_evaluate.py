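"""AUC, odds ratio, and threshold calibration against brute force."""

import numpy as np
import pandas as pd
import pytest

from libio.errors import CalibrationError, InputError
from libio.evaluate import (
    ConfusionCounts,
    OddsRatioThresholdClassifier,
    calibrate_threshold,
    confusion_at,
    cross_cohort_eval,
    odds_ratio,
    roc_auc,
)


def _auc_pairs_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _calibrate_oracle(scores, labels):
    """Exhaustive search over all real thresholds (only midpoints matter)."""
    import itertools

    distinct = sorted(set(scores))
    cands = [(a + b) / 2 for a, b in itertools.pairwise(distinct)]
    best = None
    for th in cands:
        tp = sum(1 for s, l in zip(scores, labels) if s >= th and l)
        fp = sum(1 for s, l in zip(scores, labels) if s >= th and not l)
        fn = sum(1 for s, l in zip(scores, labels) if s < th and l)
        tn = sum(1 for s, l in zip(scores, labels) if s < th and not l)
        if tp + fp == 0 or fn + tn == 0:
            continue
        if 0 in (tp, fp, fn, tn):
            o = (tp + 0.5) * (tn + 0.5) / ((fp + 0.5) * (fn + 0.5))
        else:
            o = tp * tn / (fp * fn)
        bacc = (tp / (tp + fn) + tn / (tn + fp)) / 2
        key = (o, bacc, -th)
        if best is None or key > best[0]:
            best = (key, th, o)
    return best


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 4, [1, 1, 0, 0]) == 0.5

    def test_one_discordant_pair(self):
        assert roc_auc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_pair_counting_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(30):
            n = int(rng.integers(4, 21))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            mine = roc_auc(scores, labels)
            assert mine == pytest.approx(_auc_pairs_oracle(scores, labels))
            assert mine == pytest.approx(roc_auc_score(labels, scores))

    def test_complement_symmetry_without_ties(self, rng):
        scores = rng.permutation(10).astype(float)
        labels = np.array([True] * 5 + [False] * 5)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([1.0, 2.0], [1, 1])


class TestConfusion:
    def test_threshold_extremes(self):
        scores = [0.9, 0.8, 0.3, 0.2]
        labels = [1, 1, 0, 0]
        low = confusion_at(scores, labels, 0.0)
        assert (low.FN, low.TN) == (0, 0)
        high = confusion_at(scores, labels, 2.0)
        assert (high.TP, high.FP) == (0, 0)
        mid = confusion_at(scores, labels, 0.5)
        assert (mid.TP, mid.FP, mid.FN, mid.TN) == (2, 0, 0, 2)

    def test_threshold_inclusive(self):
        c = confusion_at([0.5], [1], 0.5)
        assert c.TP == 1


class TestOddsRatio:
    def test_direct_arithmetic(self):
        assert odds_ratio(ConfusionCounts(8, 2, 1, 9)) == (36.0, False)

    def test_null_table(self):
        assert odds_ratio(ConfusionCounts(5, 5, 5, 5))[0] == 1.0

    def test_haldane_correction(self):
        o, corrected = odds_ratio(ConfusionCounts(2, 0, 0, 2))
        assert corrected
        assert o == pytest.approx(25.0)


class TestCalibration:
    def test_perfect_separation_threshold_between_classes(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        calib = calibrate_threshold(scores, labels)
        assert 0.2 < calib.threshold < 0.8
        assert calib.or_corrected

    def test_matches_exhaustive_midpoint_search(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 51))
            scores = np.round(rng.normal(size=n), 2)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            try:
                calib = calibrate_threshold(scores, labels)
            except CalibrationError:
                assert len(set(scores)) < 2
                continue
            _, th, o = _calibrate_oracle(list(scores), list(labels))
            assert calib.threshold == pytest.approx(th)
            assert calib.or_at_threshold == pytest.approx(o)

    def test_monotone_transform_maps_threshold_consistently(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0] = True
        labels[1] = False
        c1 = calibrate_threshold(scores, labels)
        transformed = np.exp(scores)  # strictly monotone
        c2 = calibrate_threshold(transformed, labels)
        # same confusion table at the chosen thresholds
        assert confusion_at(scores, labels, c1.threshold) == confusion_at(
            transformed, labels, c2.threshold
        )
        assert roc_auc(scores, labels) == pytest.approx(roc_auc(transformed, labels))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            calibrate_threshold([0.1, 0.9], [0, 1])

    def test_classifier_wrapper_fit_predict(self):
        clf = OddsRatioThresholdClassifier().fit([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert clf.predict([0.85, 0.15]).tolist() == [True, False]


class TestCrossCohort:
    def _cohort(self, name, scores, labels):
        ids = [f"{name}_{i}" for i in range(len(scores))]
        st = pd.DataFrame({"sample_id": ids, "libio": scores, "modality": "bulk"})
        mf = pd.DataFrame(
            {
                "sample_id": ids,
                "response_label": ["responder" if l else "non_responder" for l in labels],
            }
        )
        return name, st, mf

    def test_identity_validation_reproduces_training_or(self):
        scores = [0.9, 0.8, 0.3, 0.2, 0.7, 0.1]
        labels = [1, 1, 0, 0, 1, 0]
        calib = calibrate_threshold(scores, labels)
        out = cross_cohort_eval(calib, [self._cohort("train", scores, labels)])
        assert out["odds_ratio"].iloc[0] == pytest.approx(calib.or_at_threshold)

    def test_single_class_cohort_marked_undefined(self):
        calib = calibrate_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        out = cross_cohort_eval(calib, [self._cohort("v", [0.5, 0.6], [1, 1])])
        assert not out["or_defined"].iloc[0]
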