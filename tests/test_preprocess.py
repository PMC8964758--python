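"""Blank subtraction, identification acceptance, prevalence filter, log2
transform, day alignment and train/test splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathvoc import preprocess as pp
from breathvoc.preprocess import (
    CompoundID,
    VOCTable,
    accept_identification,
    align_days,
    log2_normalize,
    prevalence_filter,
    split_train_test,
    subtract_blank,
)


@pytest.mark.parametrize(
    "score,ri_diff,expected",
    [
        (0.85, 10.0, True),   # comfortably inside both thresholds
        (0.80, 20.0, True),   # both boundaries inclusive
        (0.79, 0.0, False),   # below the spectral-match threshold
        (0.95, 20.5, False),  # RI difference too large
    ],
)
def test_identification_acceptance_rule(score, ri_diff, expected):
    assert accept_identification(CompoundID("x", score, ri_diff)) is expected


def test_compound_id_validation():
    with pytest.raises(ValueError):
        CompoundID("x", 1.2, 0.0)
    with pytest.raises(ValueError):
        CompoundID("x", 0.9, -1.0)


class TestBlankSubtraction:
    def test_arithmetic_floor_and_identity(self, blank_fixture):
        raw, blanks, days = blank_fixture
        out = subtract_blank(raw, blanks, days)
        assert out.loc["s1", "Acetone"] == 8e6          # 10e6 − 2e6
        assert out.loc["s2", "Acetone"] == 0.0          # 1e6 − 3e6 floored
        assert (out["Benzene"] == raw["Benzene"]).all()  # zero blank: identity

    def test_missing_day_and_compound_mismatch(self, blank_fixture):
        raw, blanks, days = blank_fixture
        with pytest.raises(KeyError, match="day"):
            subtract_blank(raw, blanks, pd.Series([0, 7], index=raw.index))
        with pytest.raises(ValueError, match="Toluene"):
            subtract_blank(raw, blanks.rename(columns={"Benzene": "Toluene"}), days)

    def test_never_negative_and_idempotent_on_zero_blanks(self, blank_fixture):
        raw, blanks, days = blank_fixture
        zero = blanks * 0.0
        once = subtract_blank(raw, zero, days)
        pd.testing.assert_frame_equal(once, subtract_blank(once, zero, days))
        assert (subtract_blank(raw, blanks * 10, days).to_numpy() >= 0).all()


class TestPrevalenceFilter:
    @staticmethod
    def _table(detected_counts, n=20):
        data = {
            f"c{j}": [1.0] * k + [0.0] * (n - k) for j, k in enumerate(detected_counts)
        }
        raw = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
        return VOCTable(raw, raw.copy())

    def test_strict_boundary(self):
        table = self._table([1, 2, 20])  # 5%, 10%, 100% of 20 samples
        kept = prevalence_filter(table, 0.05)
        assert list(kept.compounds) == ["c1", "c2"]  # exactly-5% compound removed

    def test_idempotent_and_never_grows(self):
        table = self._table([0, 1, 3, 20])
        once = prevalence_filter(table)
        twice = prevalence_filter(once)
        assert list(once.compounds) == list(twice.compounds)
        assert len(once.compounds) <= len(table.compounds)

    def test_64_of_89_compounds_survive_on_constructed_table(self):
        # 64 compounds present in 50% of samples, 25 in exactly 5% (removed)
        counts = [100] * 64 + [10] * 25
        table = self._table(counts, n=200)
        assert prevalence_filter(table, 0.05).raw.shape[1] == 64


class TestLog2:
    def test_values(self):
        assert log2_normalize(np.array([0.0]))[0] == 0.0
        assert log2_normalize(np.array([7.0]))[0] == pytest.approx(3.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_normalize(np.array([-1.0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 10**12), min_size=2, max_size=20, unique=True))
    def test_strictly_monotone(self, values):
        v = np.sort(np.asarray(values, dtype=float))
        out = log2_normalize(v)
        assert (np.diff(out) > 0).all()

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 1e12))
    def test_invertible(self, au):
        assert 2 ** log2_normalize(np.array([au]))[0] - 1 == pytest.approx(au, rel=1e-9)


class TestAlignDays:
    def _day(self, ids, cols):
        return pd.DataFrame(1.0, index=ids, columns=cols)

    def test_identical_compound_sets_concatenate(self):
        merged = align_days([self._day(["a"], ["x", "y"]), self._day(["b"], ["x", "y"])])
        assert merged.shape == (2, 2)

    def test_extra_compound_backfilled_with_zero(self):
        merged = align_days([self._day(["a"], ["x"]), self._day(["b"], ["x", "y"])])
        assert merged.loc["a", "y"] == 0.0
        assert list(merged.columns) == ["x", "y"]  # first-appearance order

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            align_days([self._day(["a"], ["x"]), self._day(["a"], ["x"])])

    def test_alignment_commutes_with_prevalence_filter(self):
        """Merging three day tables then filtering equals filtering the
        pre-merged table (3-day fixture with uneven compound sets)."""
        rng = np.random.default_rng(2)
        cols = [f"c{i}" for i in range(6)]
        tables = []
        for d in range(3):
            ids = [f"d{d}s{i}" for i in range(7)]
            sub = cols[: 4 + d]
            tables.append(pd.DataFrame(
                rng.integers(0, 2, size=(7, len(sub))).astype(float), index=ids,
                columns=sub))
        merged = align_days(tables)
        via_merge = prevalence_filter(VOCTable(merged, merged.copy()))
        pre_merged = pd.concat(
            [t.reindex(columns=cols, fill_value=0.0) for t in tables])
        direct = prevalence_filter(VOCTable(pre_merged, pre_merged.copy()))
        assert list(via_merge.compounds) == list(direct.compounds)


class TestSplit:
    @staticmethod
    def _cohort_table(n=208, n_hcc=97, n_cirr=78):
        raw = pd.DataFrame(
            np.ones((n, 3)), index=[f"s{i}" for i in range(n)], columns=list("abc"))
        groups = ["hcc"] * n_hcc + ["cirrhosis"] * n_cirr + ["healthy"] * (n - n_hcc - n_cirr)
        meta = pd.DataFrame({"sample_id": raw.index, "group": groups})
        return VOCTable(raw, raw.copy()), meta

    def test_study_fractions_give_152_56(self):
        table, meta = self._cohort_table()
        (tr, _), (te, _), comp = split_train_test(
            table, meta, train_frac=152 / 208, seed=1)
        assert (len(tr.raw), len(te.raw)) == (152, 56)
        assert comp["train"]["n"] == 152

    def test_full_train_fraction_empty_test(self):
        table, meta = self._cohort_table(20, 10, 5)
        (_, _), (te, _), _ = split_train_test(table, meta, train_frac=1.0, seed=0)
        assert len(te.raw) == 0

    def test_same_seed_identical_split(self):
        table, meta = self._cohort_table(40, 20, 10)
        a = split_train_test(table, meta, train_frac=0.7, seed=3)
        b = split_train_test(table, meta, train_frac=0.7, seed=3)
        assert list(a[0][0].sample_ids) == list(b[0][0].sample_ids)

    def test_explicit_ids_and_overlap_rejected(self):
        table, meta = self._cohort_table(10, 5, 3)
        (tr, _), (te, _), _ = split_train_test(table, meta, train_ids=["s0", "s1"])
        assert len(tr.raw) == 2 and len(te.raw) == 8
        with pytest.raises(ValueError):
            split_train_test(table, meta, train_ids=["s0", "s0"])
        with pytest.raises(ValueError):
            split_train_test(table, meta, train_ids=["nope"])


def test_transformer_facades_match_functions(blank_fixture):
    raw, blanks, days = blank_fixture
    sub = pp.BlankSubtractor(blanks, days).fit(raw).transform(raw)
    pd.testing.assert_frame_equal(sub, subtract_blank(raw, blanks, days))
    log2 = pp.Log2Transformer().fit(sub).transform(sub)
    pd.testing.assert_frame_equal(log2, log2_normalize(sub))
    filt = pp.PrevalenceFilter(0.4).fit(sub)
    assert filt.transform(sub).shape[1] == int((sub > 0).mean().gt(0.4).sum())
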