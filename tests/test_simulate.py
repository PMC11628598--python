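"""Synthetic cohort generator: bookkeeping, correlation and survival laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidsig.prognosis import cox_univariate_batch
from lipidsig.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_qc_replicates,
    simulate_survival,
)


class TestConfigValidation:
    def test_invalid_rho(self):
        with pytest.raises(ValueError, match="block_rho"):
            SimulationConfig(block_rho=1.0)

    def test_negative_counts(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SimulationConfig(n_gc=-1)

    def test_blocks_exceeding_features(self):
        with pytest.raises(ValueError, match="block_sizes"):
            SimulationConfig(n_features=10, block_sizes=[8, 8])


class TestGenerateCohort:
    def test_truth_bookkeeping(self, small_cohort):
        table, ann, truth = small_cohort
        assert len(truth.informative_feature_ids) == 16
        assert set(truth.informative_feature_ids) <= set(table.feature_ids)
        assert set(truth.subtype) == set(ann.index[ann["group"] == "GC"])
        assert set(truth.trend_labels.values()) <= {
            "up", "down", "biphasic", "flat"
        }

    def test_intensities_strictly_positive(self, small_cohort):
        table, _, _ = small_cohort
        assert (table.intensities.to_numpy() > 0).all()
        assert (table.internal_standards.to_numpy() > 0).all()

    def test_deterministic_for_fixed_seed(self):
        cfg = dict(n_gc=20, n_hd=20, n_features=30, n_informative=4,
                   block_sizes=[4], n_prognostic=4, n_unstable_qc=0)
        t1, a1, _ = generate_cohort(SimulationConfig(seed=5, **cfg))
        t2, a2, _ = generate_cohort(SimulationConfig(seed=5, **cfg))
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
        pd.testing.assert_frame_equal(a1, a2)
        t3, _, _ = generate_cohort(SimulationConfig(seed=6, **cfg))
        assert not t1.intensities.equals(t3.intensities)

    def test_within_block_spearman_realized(self):
        # one block of 10 at rho 0.9, n=500: median pairwise Spearman >= 0.5
        cfg = SimulationConfig(
            n_gc=0, n_hd=500, n_features=20, n_informative=0,
            block_sizes=[10], block_rho=0.9, n_prognostic=0,
            n_unstable_qc=0, seed=11,
        )
        table, _, _ = generate_cohort(cfg)
        block = table.study_samples().intensities.iloc[:, :10]
        rho = stats.spearmanr(block).statistic
        tri = rho[np.triu_indices(10, k=1)]
        assert np.median(tri) >= 0.5

    def test_cross_block_spearman_near_zero(self):
        cfg = SimulationConfig(
            n_gc=0, n_hd=500, n_features=30, n_informative=0,
            block_sizes=[10, 10], block_rho=0.7, n_prognostic=0,
            n_unstable_qc=0, seed=12,
        )
        table, _, _ = generate_cohort(cfg)
        X = table.study_samples().intensities
        rho = stats.spearmanr(X).statistic
        cross = rho[:10, 10:20]
        assert abs(np.median(cross)) < 0.1

    def test_informative_shift_on_log2_scale(self):
        cfg = SimulationConfig(
            n_gc=400, n_hd=400, n_features=40, n_informative=4,
            block_sizes=[4], block_rho=0.0, effect_size=1.0,
            trend_profiles=["flat"] * 4, n_prognostic=0,
            n_unstable_qc=0, seed=13,
        )
        table, ann, truth = generate_cohort(cfg)
        logx = np.log2(table.study_samples().intensities)
        gc = ann.index[ann["group"] == "GC"]
        hd = ann.index[ann["group"] == "HD"]
        f = truth.informative_feature_ids[0]
        shift = logx.loc[gc, f].mean() - logx.loc[hd, f].mean()
        assert shift == pytest.approx(1.0, abs=0.2)

    def test_null_effect_gives_chance_level_classifier(self):
        # with effect 0 a held-out LDA panel cannot beat chance
        from lipidsig.classify import fit_lda, predict_score
        from lipidsig.metrics import roc_auc

        aucs = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_gc=200, n_hd=200, n_features=40, n_informative=8,
                block_sizes=[4, 4], effect_size=0.0, n_prognostic=0,
                n_unstable_qc=0, seed=100 + seed,
            )
            table, ann, truth = generate_cohort(cfg)
            X = np.log2(table.study_samples().intensities[
                truth.informative_feature_ids])
            y = (ann["group"] == "GC").to_numpy()
            tr = np.arange(len(y)) % 2 == 0
            lda = fit_lda(X[tr], y[tr], positive=True)
            s, _ = predict_score(lda, X[~tr])
            aucs.append(roc_auc(s, y[~tr]).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestQcReplicates:
    def test_one_qc_row_per_twenty_samples(self):
        cfg = SimulationConfig(n_gc=50, n_hd=50, n_features=10,
                               n_informative=0, block_sizes=[],
                               n_prognostic=0, n_unstable_qc=0, seed=1)
        table, _, _ = generate_cohort(cfg)
        assert int(table.qc_flags.sum()) == 5  # ceil(100/20)

    def test_zero_cv_gives_identical_rows(self, tiny_table):
        out = generate_qc_replicates(tiny_table.study_samples(), 0.0, seed=0)
        qc = out.qc_samples().to_numpy()
        assert np.allclose(qc, qc[0])

    def test_realized_rsd_matches_target(self):
        idx = [f"s{i}" for i in range(600)]
        rng = np.random.default_rng(0)
        intens = pd.DataFrame(
            rng.lognormal(10, 0.3, size=(600, 50)),
            index=idx,
            columns=[f"f{j}" for j in range(50)],
        )
        t = pd.Series("pos", index=intens.columns)
        table = generate_qc_replicates(
            __import__("lipidsig").IntensityTable(
                intens, t,
                pd.DataFrame({"pos": np.ones(600)}, index=idx),
                pd.Series(False, index=idx),
            ),
            qc_cv=0.10,
            seed=3,
        )
        qc = table.qc_samples()  # 30 rows
        assert len(qc) == 30
        rsd = qc.std(ddof=1) / qc.mean()
        frac_in_band = ((rsd >= 0.06) & (rsd <= 0.14)).mean()
        assert frac_in_band >= 0.95


class TestSimulateSurvival:
    def test_exponential_median_closed_form(self):
        lam = 0.02
        df = simulate_survival([0] * 20000, 1.0, lam, censor_horizon=1e9,
                               seed=4, dropout_scale=1e12)
        assert df["event"].all()
        assert df["time_months"].median() == pytest.approx(
            np.log(2) / lam, rel=0.05)

    def test_invalid_hr(self):
        with pytest.raises(ValueError):
            simulate_survival([0, 1], 0.0, 0.01, 60, seed=0)

    def test_records_valid(self):
        df = simulate_survival([0, 1] * 50, 3.34, 0.005, 60, seed=5)
        assert (df["time_months"] > 0).all()
        assert set(df["event"].unique()) <= {0, 1}
        assert df["time_months"].max() <= 60

    def test_null_hr_logrank_rejection_rate(self):
        # with no subtype effect the log-rank test rejects at ~alpha
        from lifelines.statistics import multivariate_logrank_test

        labels = np.array([0] * 50 + [1] * 50)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            df = simulate_survival(labels, 1.0, 0.01, 60, seed=1000 + i)
            res = multivariate_logrank_test(
                df["time_months"], labels, df["event"])
            rejections += res.p_value < 0.05
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.10

    def test_cox_ci_covers_configured_hr(self):
        # planted HR 3.34, n=266: Wald CI covers truth in >= 90% of runs
        rng = np.random.default_rng(0)
        cover = 0
        n_rep = 100
        for i in range(n_rep):
            labels = rng.integers(0, 2, size=266)
            df = simulate_survival(labels, 3.34, 0.005, 60, seed=2000 + i)
            fit = cox_univariate_batch(
                labels[:, None].astype(float),
                df["time_months"].to_numpy(),
                df["event"].to_numpy(),
            )
            lo = np.exp(fit["coef"][0] - 1.959964 * fit["se"][0])
            hi = np.exp(fit["coef"][0] + 1.959964 * fit["se"][0])
            cover += lo <= 3.34 <= hi
        assert cover / n_rep >= 0.90

    def test_proportional_hazards_realized(self):
        labels = np.array([0, 1] * 3000)
        df = simulate_survival(labels, 3.34, 0.005, censor_horizon=120,
                               seed=6, dropout_scale=1e9)
        fit = cox_univariate_batch(
            labels[:, None].astype(float),
            df["time_months"].to_numpy(),
            df["event"].to_numpy(),
        )
        assert fit["hr"][0] == pytest.approx(3.34, rel=0.10)
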