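import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trapeval as te
from trapeval.metrics import (
    DP_COEF_EXACT,
    ConfusionCounts,
    UndefinedMetricWarning,
    compute_metrics,
)

counts_strategy = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
)


def oracle_metrics(tp, tn, fp, fn):
    """Independently coded reference formulas (kappa via the p_o/p_e form,
    mcc/f1 cross-checked against scikit-learn in the test below)."""
    n = tp + tn + fp + fn
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    ppv = tp / (tp + fp)
    p_o = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((fn + tn) / n) * ((fp + tn) / n)
    p_e = p_yes + p_no
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else math.nan
    return {
        "tpr": tpr,
        "tnr": tnr,
        "ppv": ppv,
        "acc": p_o,
        "err": 1 - p_o,
        "bac": 0.5 * tpr + 0.5 * tnr,
        "gm": (tpr * tnr) ** 0.5,
        "yi": tpr - (1 - tnr),
        "f1": tp / (tp + 0.5 * (fp + fn)),
        "mcc": (tp * tn - fp * fn)
        / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)),
        "kappa": kappa,
    }


class TestComputeMetrics:
    def test_best_standalone_model_counts(self):
        mv = compute_metrics(ConfusionCounts(tp=767, tn=290417, fp=1557, fn=863))
        assert round(mv.tpr, 5) == 0.47055
        assert round(mv.tnr, 5) == 0.99467
        assert round(mv.ppv, 5) == 0.33003
        assert round(mv.acc, 5) == 0.99176
        assert round(mv.bac, 5) == 0.73261
        assert round(mv.gm, 6) == 0.684137
        assert round(mv.yi, 6) == 0.465219
        assert round(mv.dp, 6) == 1.224305
        assert round(mv.f1, 5) == 0.38796
        assert round(mv.mcc, 5) == 0.39008
        assert round(mv.kappa, 5) == 0.38394

    def test_chance_level_symmetry(self):
        mv = compute_metrics(ConfusionCounts(50, 50, 50, 50))
        assert mv.tpr == mv.tnr == mv.bac == mv.gm == 0.5
        assert mv.yi == 0 and mv.mcc == 0 and mv.kappa == 0 and mv.dp == 0

    @given(counts_strategy)
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_independent_oracle(self, counts):
        tp, tn, fp, fn = counts
        mv = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        expected = oracle_metrics(tp, tn, fp, fn)
        for name, value in expected.items():
            assert getattr(mv, name) == pytest.approx(value, abs=1e-12), name

    def test_thousand_random_vectors_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score, f1_score, matthews_corrcoef

        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 60, size=4)
            mv = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            y_true = np.repeat([1, 1, 0, 0], [tp, fn, tn, fp])
            y_pred = np.repeat([1, 0, 0, 1], [tp, fn, tn, fp])
            assert mv.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
            assert mv.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)
            assert mv.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)

    @given(counts_strategy)
    @settings(max_examples=200, deadline=None)
    def test_identity_chain(self, counts):
        mv = compute_metrics(ConfusionCounts(*counts))
        assert mv.err == pytest.approx(1 - mv.acc, abs=1e-12)
        assert mv.yi == pytest.approx(2 * mv.bac - 1, abs=1e-12)
        assert mv.gm ** 2 == pytest.approx(mv.tpr * mv.tnr, abs=1e-12)
        assert mv.gm <= mv.bac + 1e-12  # AM-GM

    def test_undefined_ppv_flagged_not_zero(self):
        with pytest.warns(UndefinedMetricWarning):
            mv = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert math.isnan(mv.ppv)
        assert math.isnan(mv.dp)  # tpr == 0
        assert not math.isnan(mv.acc)

    def test_all_negative_detector_on_study_shape(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedMetricWarning)
            mv = compute_metrics(ConfusionCounts(tp=0, tn=291_974, fp=0, fn=1630))
        assert mv.tnr == 1.0
        assert mv.tpr == 0.0
        assert math.isnan(mv.ppv) and math.isnan(mv.dp)

    def test_dp_requires_published_coefficient(self):
        c = ConfusionCounts(tp=767, tn=290417, fp=1557, fn=863)
        published = compute_metrics(c).dp
        exact = compute_metrics(c, dp_coef=DP_COEF_EXACT).dp
        assert round(published, 6) == 1.224305
        assert round(exact, 6) != 1.224305
        assert published / exact == pytest.approx(math.pi / 3.14, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)


class TestConfusionCountsFromMatrix:
    def test_enumerable_case(self):
        import pandas as pd

        idx = pd.Index(["a", "b", "c", "d"], name="image_id")
        matrix = te.DetectionMatrix(
            detections=pd.DataFrame({"m": [True, False, True, False]}, index=idx),
            truth=pd.Series([True, True, False, False], index=idx),
        )
        c = te.confusion_counts(matrix, "m")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_unknown_model(self, tiny_records, tiny_truths):
        matrix = te.build_detection_matrix(tiny_records, tiny_truths)
        with pytest.raises(KeyError):
            te.confusion_counts(matrix, "nope")

    def test_against_per_image_tally_oracle(self, small_sim):
        _, records, truths = small_sim
        matrix = te.build_detection_matrix(records, truths)
        truth_by_img = {t.image_id: t.is_positive for t in truths}
        for model in matrix.models:
            tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
            for img in matrix.detections.index:
                det = bool(matrix.detections.loc[img, model])
                pos = truth_by_img[img]
                key = ("tp" if det else "fn") if pos else ("fp" if det else "tn")
                tally[key] += 1
            c = te.confusion_counts(matrix, model)
            assert (c.tp, c.tn, c.fp, c.fn) == (
                tally["tp"], tally["tn"], tally["fp"], tally["fn"],
            )


class TestMetricTable:
    def test_single_model_matrix(self, tiny_records, tiny_truths):
        matrix = te.build_detection_matrix(
            [r for r in tiny_records if r.model_id == "A"], tiny_truths
        )
        table = te.metric_table(matrix)
        assert len(table) == 1 and table.index[0] == "A"

    def test_rows_match_compute_metrics(self, small_sim):
        _, records, truths = small_sim
        matrix = te.build_detection_matrix(records, truths)
        table = te.metric_table(matrix)
        for model in matrix.models:
            c = te.confusion_counts(matrix, model)
            mv = compute_metrics(c)
            row = table.loc[model]
            assert (row.TP, row.TN, row.FP, row.FN) == (c.tp, c.tn, c.fp, c.fn)
            for name in te.metrics.METRIC_NAMES:
                assert row[name.upper()] == pytest.approx(getattr(mv, name), nan_ok=True)

    def test_study_counts_give_36_rows(self, study_table):
        assert len(study_table) == 36
        assert list(study_table.columns) == list(te.metrics.TABLE_COLUMNS)


class TestRankModels:
    def test_top5_by_kappa(self, study_table):
        top, _ = te.rank_models(study_table, "kappa", 5)
        assert top == ["Inc_Res_v2", "Pns_lrg", "Inc_v4", "Ns_lrg", "Inc_v3"]

    def test_top_model_by_accuracy(self, study_table):
        top, _ = te.rank_models(study_table, "ACC", 1)
        assert top == ["Inc_v1"]

    def test_bottom_by_kappa(self, study_table):
        _, bottom = te.rank_models(study_table, "kappa", 2)
        assert bottom[0] == "AlxNet"  # worst model first in bottom list

    def test_k_zero(self, study_table):
        top, bottom = te.rank_models(study_table, "MCC", 0)
        assert top == [] and bottom == []

    def test_k_too_large(self, study_table):
        with pytest.raises(ValueError):
            te.rank_models(study_table, "MCC", 37)

    def test_unknown_metric(self, study_table):
        with pytest.raises(KeyError):
            te.rank_models(study_table, "AUC", 5)
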