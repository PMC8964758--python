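"""Stage distances, single-marker ROC, cutoff metrics and the treatment
response analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathvoc.classify import fit_classifier
from breathvoc.stage import (
    evaluate_cutoff,
    paired_deltas,
    response_analysis,
    roc_curve,
    stage_distances,
    youden_optimal_cutoff,
)


class TestRoc:
    def test_perfect_separation_auc_one_and_antisymmetry(self):
        roc = roc_curve([3, 4, 1, 2], [True, True, False, False])
        assert roc.auc == 1.0
        flipped = roc_curve([3, 4, 1, 2], [False, False, True, True])
        assert flipped.auc == 0.0

    def test_interleaved_auc_quarter(self):
        # cases {1,3}, controls {2,4}: one concordant pair of four
        roc = roc_curve([1, 3, 2, 4], [True, True, False, False])
        assert roc.auc == 0.25

    def test_ties_count_half(self):
        roc = roc_curve([1, 2, 1, 2], [True, True, False, False])
        assert roc.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True])

    def test_cutoffs_strictly_increasing_and_metric_monotonicity(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[0], labels[1] = True, False
        roc = roc_curve(v, labels)
        assert (np.diff(roc.cutoffs) > 0).all()
        assert (np.diff(roc.sensitivity) <= 1e-12).all()   # nonincreasing
        assert (np.diff(roc.specificity) >= -1e-12).all()  # nondecreasing

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 1000))
    def test_auc_invariant_under_monotone_transform(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=n_pos + n_neg)
        labels = np.array([True] * n_pos + [False] * n_neg)
        a = roc_curve(v, labels).auc
        b = roc_curve(np.exp(v / 3) + 5, labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestCutoff:
    def test_cutoff_below_all_values(self):
        m = evaluate_cutoff([1, 2, 3, 4], [True, False, True, False], -10)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_boundary_value_counts_positive(self):
        m = evaluate_cutoff([5.0, 3.0], [True, False], 5.0)
        assert m.tp == 1 and m.tn == 1

    def test_acetone_reduction_separation_at_study_cutoff(self):
        # responder reduced 40e6 AU, non-responder 30e6 AU, cutoff 35.9e6
        m = evaluate_cutoff([40e6, 30e6], [True, False], 35.9e6, "higher")
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_lower_direction(self):
        m = evaluate_cutoff([1.0, 4.0], [True, False], 2.0, "lower")
        assert m.tp == 1 and m.tn == 1

    def test_agrees_with_roc_grid_entry(self):
        rng = np.random.default_rng(7)
        v = np.round(rng.normal(size=30), 2)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        roc = roc_curve(v, labels)
        for i in [0, len(roc.cutoffs) // 2, -1]:
            m = evaluate_cutoff(v, labels, roc.cutoffs[i])
            assert m.sensitivity == roc.sensitivity[i]
            assert m.specificity == roc.specificity[i]


class TestYouden:
    def test_perfect_separation_achieves_j_one(self):
        roc = roc_curve([10, 11, 0, 1], [True, True, False, False])
        c = youden_optimal_cutoff(roc)
        m = evaluate_cutoff([10, 11, 0, 1], [True, True, False, False], c)
        assert m.sensitivity + m.specificity - 1 == pytest.approx(1.0)

    def test_degenerate_identical_values(self):
        roc = roc_curve([2.0, 2.0, 2.0], [True, False, True])
        c = youden_optimal_cutoff(roc)
        m = evaluate_cutoff([2.0, 2.0, 2.0], [True, False, True], c)
        assert m.sensitivity + m.specificity - 1 == pytest.approx(0.0)

    def test_full_scan_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=25) + np.where(rng.random(25) < 0.5, 1.0, 0.0)
        labels = v > np.median(v)
        labels[3] = ~labels[3]
        roc = roc_curve(v, labels)
        c = youden_optimal_cutoff(roc)
        m = evaluate_cutoff(v, labels, c)
        j_best = m.sensitivity + m.specificity - 1
        for cand in roc.cutoffs:
            mc = evaluate_cutoff(v, labels, cand)
            assert j_best >= mc.sensitivity + mc.specificity - 1 - 1e-12


class TestStageDistances:
    def test_degenerate_stages(self, separable_xy):
        X, y = separable_xy
        model = fit_classifier(X, y, positive_label="hcc")
        hcc = X[y == "hcc"]
        stages = np.array(["A"] * 10 + ["B"] * 9 + ["C"])
        summ = stage_distances(model, hcc, stages)
        assert list(summ.table.index) == ["A", "B", "C"]
        assert summ.table.loc["C", "sd"] == 0.0
        assert any("single sample" in n for n in summ.notes)
        assert any("stage 0" in n for n in summ.notes)  # empty stage omitted

    def test_distances_match_classifier_exactly(self, separable_xy):
        X, y = separable_xy
        model = fit_classifier(X, y, positive_label="hcc")
        hcc = X[y == "hcc"]
        summ = stage_distances(model, hcc, ["A"] * len(hcc))
        direct = model.signed_distance(hcc)
        assert summ.table.loc["A", "mean"] == pytest.approx(direct.mean(), abs=1e-12)


def _delta_frame():
    rows = []
    # 6 responders with large acetone reductions, 4 non-responders with small
    for i in range(6):
        rows.append({"patient": f"R{i}", "compound": "Acetone", "pre": 100e6,
                     "post": 100e6 - (60e6 + i * 1e6), "delta": -(60e6 + i * 1e6),
                     "modality": "TACE" if i % 2 else "PLAT", "responder": True})
    for i in range(4):
        rows.append({"patient": f"N{i}", "compound": "Acetone", "pre": 90e6,
                     "post": 90e6 - (10e6 + i * 1e6), "delta": -(10e6 + i * 1e6),
                     "modality": "TACE", "responder": False})
    return pd.DataFrame(rows)


class TestResponse:
    def test_no_change_gives_null_results(self):
        df = _delta_frame()
        df["post"] = df["pre"]
        df["delta"] = 0.0
        rep = response_analysis(df, by_modality=False)
        acetone = rep["overall"]["Acetone"]
        assert acetone["paired_t"]["pvalue"] == 1.0
        assert acetone["delta_mw"]["pvalue"] == 1.0
        assert acetone["roc_auc"] == 0.5

    def test_separated_deltas_detected_and_classified(self):
        rep = response_analysis(_delta_frame(), by_modality=False)
        acetone = rep["overall"]["Acetone"]
        assert acetone["delta_mw"]["pvalue"] < 0.05
        assert acetone["roc_auc"] == 1.0
        assert acetone["cutoff_metrics"]["sensitivity"] == 1.0
        assert acetone["cutoff_metrics"]["specificity"] == 1.0
        assert acetone["marker"].startswith("reduction")

    def test_responder_share_percentage(self):
        df = _delta_frame()
        rep = response_analysis(df, by_modality=False)
        assert rep["responder_share_pct"] == pytest.approx(60.0)

    def test_single_class_modality_skipped_with_warning(self):
        rep = response_analysis(_delta_frame(), by_modality=True)
        assert "TACE" in rep["by_modality"]
        assert "PLAT" not in rep["by_modality"]  # all PLAT patients responded
        assert any("PLAT" in w for w in rep["warnings"])

    def test_all_one_class_rejected(self):
        df = _delta_frame()
        df["responder"] = True
        with pytest.raises(ValueError):
            response_analysis(df)


def test_paired_deltas_from_cohort_tables(small_cohort):
    coh = small_cohort
    deltas = paired_deltas(coh.voc_table, coh.meta, compounds=["Acetone"])
    n_pairs = (coh.meta["timepoint"] == "post").sum()
    assert len(deltas) == n_pairs
    assert (deltas["delta"] == deltas["post"] - deltas["pre"]).all()
    assert set(deltas["modality"]) <= {"TACE", "PLAT"}
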