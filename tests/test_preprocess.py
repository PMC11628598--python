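"""Preprocessing chain: QC filter, IS normalization, scaling, splits."""

import numpy as np
import pandas as pd
import pytest

from lipidsig.datatypes import IntensityTable, ProcessedMatrix
from lipidsig.preprocess import (
    autoscale,
    merge_modes,
    normalize_log,
    rsd_qc_filter,
    split_cohort,
)


def _table(qc_values: dict[str, list[float]]) -> IntensityTable:
    n = len(next(iter(qc_values.values())))
    idx = [f"q{i}" for i in range(n)]
    intens = pd.DataFrame(qc_values, index=idx, dtype=float)
    return IntensityTable(
        intens,
        pd.Series("pos", index=intens.columns),
        pd.DataFrame({"pos": [1.0] * n}, index=idx),
        pd.Series(True, index=idx),
    )


class TestRsdFilter:
    def test_hand_computed_rsd(self):
        # (50,100,150): sd=50, mean=100 -> RSD 0.50, removed at 0.30;
        # (100,100,100): RSD 0 kept
        t = _table({"stable": [100, 100, 100], "noisy": [50, 100, 150]})
        kept, removed = rsd_qc_filter(t, threshold=0.30)
        assert list(kept.feature_ids) == ["stable"]
        assert removed == ["noisy"]

    def test_vacuous_threshold_keeps_all_nondegenerate(self):
        t = _table({"a": [1, 2, 3], "b": [5, 6, 7], "zero": [0, 0, 0]})
        kept, removed = rsd_qc_filter(t, threshold=1.0)
        assert list(kept.feature_ids) == ["a", "b"]
        assert removed == ["zero"]

    def test_requires_two_qc_rows(self):
        t = _table({"a": [1.0]})
        with pytest.raises(ValueError, match="QC rows"):
            rsd_qc_filter(t)

    def test_row_order_invariance(self, tiny_table):
        shuffled = tiny_table.subset_samples(
            ["q2", "c", "a", "q3", "d", "b", "q1"]
        )
        kept1, _ = rsd_qc_filter(tiny_table, 0.8)
        kept2, _ = rsd_qc_filter(shuffled, 0.8)
        assert list(kept1.feature_ids) == list(kept2.feature_ids)


class TestNormalizeLog:
    def test_closed_form_values(self, tiny_table):
        pm = normalize_log(tiny_table.study_samples())
        # f1: raw=100, IS=100 -> log2(1)+5 = 5; raw=400 -> log2(4)+5 = 7
        assert pm.values.at["a", "f1"] == pytest.approx(5.0)
        assert pm.values.at["c", "f1"] == pytest.approx(7.0)
        # neg-mode feature uses the neg IS (=10): raw 5 -> log2(0.5)+5 = 4
        assert pm.values.at["a", "f3"] == pytest.approx(4.0)

    def test_direct_evaluation(self):
        t = _table({"x": [3.0, 3.0]})
        pm = normalize_log(t)
        assert pm.values.iloc[0, 0] == pytest.approx(5 + np.log2(3))

    def test_monotone_per_feature(self, tiny_table):
        pm = normalize_log(tiny_table.study_samples())
        raw = tiny_table.study_samples().intensities
        for f in raw.columns:
            assert (
                raw[f].rank().to_numpy() == pm.values[f].rank().to_numpy()
            ).all()

    def test_zero_policy(self):
        idx = ["s1", "s2", "s3"]
        intens = pd.DataFrame({"x": [0.0, 4.0, 8.0]}, index=idx)
        t = IntensityTable(
            intens,
            pd.Series({"x": "pos"}),
            pd.DataFrame({"pos": [1.0] * 3}, index=idx),
            pd.Series(False, index=idx),
        )
        with pytest.raises(ValueError):
            normalize_log(t, zero_policy="reject")
        pm = normalize_log(t, zero_policy="impute")
        # half-minimum positive = 2 -> log2(2)+5 = 6
        assert pm.values.at["s1", "x"] == pytest.approx(6.0)


class TestMergeAndScale:
    def test_merge_shapes_and_namespacing(self, rng):
        idx = ["s1", "s2", "s3"]
        pos = ProcessedMatrix(pd.DataFrame(
            rng.normal(size=(3, 2)), index=idx, columns=["shared", "p2"]))
        neg = ProcessedMatrix(pd.DataFrame(
            rng.normal(size=(3, 1)), index=idx, columns=["shared"]))
        merged = merge_modes(pos, neg)
        assert merged.values.shape == (3, 3)
        assert list(merged.feature_ids) == ["pos:shared", "pos:p2", "neg:shared"]

    def test_merge_empty_neg_is_identity(self, rng):
        pos = ProcessedMatrix(pd.DataFrame(rng.normal(size=(3, 2)),
                                           columns=["a", "b"]))
        neg = ProcessedMatrix(pd.DataFrame(index=pos.values.index))
        assert merge_modes(pos, neg).values.equals(pos.values)

    def test_merge_sample_mismatch(self, rng):
        pos = ProcessedMatrix(pd.DataFrame(rng.normal(size=(2, 1)),
                                           index=["s1", "s2"], columns=["a"]))
        neg = ProcessedMatrix(pd.DataFrame(rng.normal(size=(2, 1)),
                                           index=["s1", "s9"], columns=["b"]))
        with pytest.raises(ValueError, match="mismatch"):
            merge_modes(pos, neg)

    def test_autoscale_self_and_inverse(self, rng):
        X = ProcessedMatrix(pd.DataFrame(rng.normal(5, 3, size=(40, 4)),
                                         columns=list("abcd")))
        scaled = autoscale(X)[0]
        assert np.allclose(scaled.values.mean(), 0, atol=1e-9)
        assert np.allclose(scaled.values.std(ddof=1), 1, atol=1e-9)
        back = scaled.values * scaled.scaling.sd + scaled.scaling.mean
        assert np.allclose(back.to_numpy(), X.values.to_numpy(), atol=1e-9)

    def test_autoscale_frozen_parameters_propagate_shift(self, rng):
        X = ProcessedMatrix(pd.DataFrame(rng.normal(size=(30, 3)),
                                         columns=list("abc")))
        c = 2.5
        shifted = ProcessedMatrix(X.values + c)
        fit, applied = autoscale(X, [X, shifted])
        delta = applied.values - fit.values
        expected = c / fit.scaling.sd
        assert np.allclose(delta.mean(axis=0), expected, atol=1e-9)

    def test_constant_column_dropped(self, rng):
        X = ProcessedMatrix(pd.DataFrame(
            {"a": rng.normal(size=10), "const": np.ones(10)}))
        scaled = autoscale(X)[0]
        assert list(scaled.feature_ids) == ["a"]
        assert scaled.scaling.dropped_constant == ["const"]

    def test_unknown_feature_rejected(self, rng):
        X = ProcessedMatrix(pd.DataFrame({"a": rng.normal(size=10)}))
        other = ProcessedMatrix(pd.DataFrame(
            {"a": rng.normal(size=5), "b": rng.normal(size=5)}))
        with pytest.raises(ValueError, match="absent"):
            autoscale(X, [other])


class TestSplitCohort:
    @staticmethod
    def _ann(n_gc, n_hd):
        return pd.DataFrame(
            {"group": ["GC"] * n_gc + ["HD"] * n_hd},
            index=[f"s{i}" for i in range(n_gc + n_hd)],
        )

    def test_published_cohort_sizes(self):
        # 266 GC + 266 HD at 85/15 must give 227/227 train and 39/39 test
        ann = self._ann(266, 266)
        train, test = split_cohort(ann, 0.85, seed=0)
        tr = ann.loc[train, "group"].value_counts()
        te = ann.loc[test, "group"].value_counts()
        assert tr["GC"] == tr["HD"] == 227
        assert te["GC"] == te["HD"] == 39

    def test_partition_is_disjoint_and_exhaustive(self):
        ann = self._ann(30, 25)
        train, test = split_cohort(ann, 0.8, seed=3)
        assert set(train) | set(test) == set(ann.index)
        assert not set(train) & set(test)

    def test_deterministic(self):
        ann = self._ann(50, 50)
        assert split_cohort(ann, 0.85, seed=9) == split_cohort(ann, 0.85, seed=9)
        assert split_cohort(ann, 0.85, seed=9) != split_cohort(ann, 0.85, seed=10)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            split_cohort(self._ann(5, 5), fraction=1.0, seed=0)

    def test_tiny_stratum_goes_to_train(self):
        ann = pd.DataFrame({"group": ["GC"] * 10 + ["PL"]},
                           index=[f"s{i}" for i in range(11)])
        train, test = split_cohort(ann, 0.8, seed=0)
        assert "s10" in train
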