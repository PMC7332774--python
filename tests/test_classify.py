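"""Classifier stage: scores, filters, ensemble, LOPO protocol."""

import numpy as np
import pandas as pd
import pytest
from helpers import trapezoid_auc

import neostress as ns
from neostress.classify import _prepare_fold, feature_columns, is_power_feature


def _table(n_subjects=8, events_per_subject=6, n_features=5, informative=0.0,
           seed=0, group="5days"):
    """Synthetic feature table: Gaussian features, optional class shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        label = s < n_subjects // 2
        pma = rng.uniform(30, 36)
        for e in range(events_per_subject):
            row = {"subject_id": f"s{s}", "group": group, "event_id": f"s{s}_{e}",
                   "label": label, "pma_weeks": pma, "desat_threshold_pct": 10.0}
            for f in range(n_features):
                row[f"feat_{f}"] = rng.standard_normal() + informative * label * (f == 0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestFScore:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(400)
        y = np.arange(400) % 2 == 0
        assert ns.f_score(x, y) < 0.05

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(1)
        y = np.arange(1000) >= 500
        scores = []
        for mu in (0.5, 1.0, 2.0):
            x = rng.standard_normal(1000) + mu * y
            scores.append(ns.f_score(x, y))
        assert scores[0] < scores[1] < scores[2]

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = rng.random(200) < 0.4
        xp, xn = x[y], x[~y]
        expected = ((xp.mean() - x.mean()) ** 2 + (xn.mean() - x.mean()) ** 2) \
            / (xp.var(ddof=1) + xn.var(ddof=1))
        assert ns.f_score(x, y) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ns.ValidationError):
            ns.f_score(np.arange(10.0), np.ones(10, dtype=bool))


class TestKappaAndAUC:
    def test_perfect_agreement(self):
        y = np.array([True, False, True, False])
        assert ns.cohens_kappa(y, y) == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        y = np.array([True, False, True, False])
        assert ns.cohens_kappa(~y, y) == pytest.approx(-1.0)

    def test_confusion_table_example(self):
        # TP=40 TN=40 FP=10 FN=10 -> po=0.8, pe=0.5, kappa=0.6
        pred = np.array([True] * 40 + [False] * 40 + [True] * 10 + [False] * 10)
        true = np.array([True] * 40 + [False] * 40 + [False] * 10 + [True] * 10)
        assert ns.cohens_kappa(pred, true) == pytest.approx(0.6)

    def test_rank_auc_equals_trapezoid(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            s = rng.standard_normal(200)
            y = rng.random(200) < 0.5
            assert ns.rank_auc(s, y) == pytest.approx(trapezoid_auc(s, y),
                                                      abs=1e-12)


class TestPreprocessing:
    def test_power_features_log_transformed(self):
        rows = [{"subject_id": "a", "group": "5days", "event_id": "a0",
                 "label": True, "pma_weeks": 32.0, "desat_threshold_pct": 10.0,
                 "rr__mu_hf__pre": float(np.exp(2.0)), "rr__mu__pre": 0.4}]
        df = ns.assemble_features(rows)
        assert df["rr__mu_hf__pre"].iloc[0] == pytest.approx(2.0)
        assert df["rr__mu__pre"].iloc[0] == pytest.approx(0.4)
        assert is_power_feature("eeg_C3__mu_pdelta__pre")
        assert not is_power_feature("rr__mu_hfnu__pre")

    def test_age_correction_removes_pma_trend(self):
        table = _table(n_subjects=10, seed=4)
        rng = np.random.default_rng(5)
        table["feat_0"] = 2.0 * table["pma_weeks"] + 1e-6 * rng.standard_normal(len(table))
        out = ns.age_correct(table, train_ids=table["subject_id"].unique())
        from scipy import stats
        r, _ = stats.pearsonr(out["pma_weeks"], out["feat_0"])
        assert abs(r) < 0.05
        assert np.abs(out["feat_0"]).max() < 1e-3

    def test_age_correction_uses_train_coefficients_only(self):
        table = _table(n_subjects=10, seed=6)
        table["feat_0"] = 3.0 * table["pma_weeks"]
        held_out = "s9"
        table.loc[table.subject_id == held_out, "pma_weeks"] = 44.0
        table.loc[table.subject_id == held_out, "feat_0"] = 0.0   # breaks the trend
        train_ids = [s for s in table["subject_id"].unique() if s != held_out]
        out = ns.age_correct(table, train_ids)
        # test rows are residualized with the train fit: 0 - (3*44) = -132
        got = out.loc[out.subject_id == held_out, "feat_0"].iloc[0]
        assert got == pytest.approx(-132.0, abs=1e-6)

    def test_uncorrelated_feature_untouched(self):
        table = _table(n_subjects=10, seed=7)
        before = table["feat_1"].copy()
        out = ns.age_correct(table, table["subject_id"].unique())
        np.testing.assert_allclose(out["feat_1"], before)

    def test_correlation_filter_drops_duplicates(self):
        table = _table(n_subjects=6, seed=8)
        table["feat_dup"] = table["feat_0"]
        scores = {"feat_0": 2.0, "feat_dup": 1.0, "feat_1": 0.5}
        kept = ns.correlation_filter(table, scores, cap=0.9)
        assert "feat_0" in kept and "feat_dup" not in kept and "feat_1" in kept

    def test_higher_f_of_correlated_pair_retained(self):
        rng = np.random.default_rng(9)
        table = _table(n_subjects=6, seed=9)
        table["feat_corr"] = table["feat_0"] * 0.98 + 0.02 * rng.standard_normal(len(table))
        kept = ns.correlation_filter(table, {"feat_0": 1.0, "feat_corr": 3.0})
        assert kept[0] == "feat_corr" and "feat_0" not in kept


class TestSubspaceLDA:
    def test_separable_data_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((120, 6))
        y = X[:, 0] > 0
        X[:, 0] += 6 * y
        model = ns.SubspaceLDA(n_learners=20, subspace_dim=3, seed=1).fit(X, y)
        auc = ns.rank_auc(model.predict_scores(X), y)
        assert auc >= 0.99

    def test_same_seed_same_model_scores(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 5))
        y = rng.random(80) < 0.5
        a = ns.SubspaceLDA(10, 2, seed=3).fit(X, y).predict_scores(X)
        b = ns.SubspaceLDA(10, 2, seed=3).fit(X, y).predict_scores(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ns.ValidationError):
            ns.SubspaceLDA(5, 2).fit(np.zeros((10, 3)), np.ones(10, dtype=bool))


class TestLOPO:
    def test_informative_feature_high_auc(self):
        table = _table(n_subjects=8, informative=5.0, seed=11)
        cfg = ns.PipelineConfig(tune_ensemble=False, ensemble_size=15)
        report = ns.lopo_evaluate(table, cfg, seed=0)
        res = report.results[("5days", 10.0)]
        assert res.auc >= 0.99
        assert res.kappa >= 0.9

    def test_null_table_chance_level(self):
        table = _table(n_subjects=10, events_per_subject=10, informative=0.0,
                       seed=12)
        cfg = ns.PipelineConfig(tune_ensemble=False, ensemble_size=15)
        report = ns.lopo_evaluate(table, cfg, seed=1)
        res = report.results[("5days", 10.0)]
        assert 0.3 <= res.auc <= 0.7

    def test_no_subject_in_its_own_training_fold(self):
        table = _table(n_subjects=6, informative=2.0, seed=13)
        cfg = ns.PipelineConfig(tune_ensemble=False, ensemble_size=10)
        report = ns.lopo_evaluate(table, cfg, seed=2)
        pooled = report.results[("5days", 10.0)].scores
        # every subject with events appears exactly once per its event count
        counts = pooled.groupby("subject_id").size()
        expected = table.groupby("subject_id").size()
        assert counts.to_dict() == expected.to_dict()

    def test_single_class_group_flagged(self):
        table = _table(n_subjects=6, seed=14)
        table["label"] = True
        report = ns.lopo_evaluate(table, ns.PipelineConfig(tune_ensemble=False),
                                  seed=0)
        res = report.results[("5days", 10.0)]
        assert np.isnan(res.auc) and res.flags

    def test_fold_statistics_ignore_heldout_values(self):
        """Leakage canary: corrupting the held-out subject's feature values
        must not change any train-fold statistic or feature selection."""
        table = _table(n_subjects=8, informative=1.0, seed=15)
        held_out = "s7"
        train_ids = [s for s in table["subject_id"].unique() if s != held_out]
        cfg = ns.PipelineConfig(tune_ensemble=False)
        corrupted = table.copy()
        mask = corrupted["subject_id"] == held_out
        for c in feature_columns(table):
            corrupted.loc[mask, c] = 1e6
        kept_a, med_a, corr_a = _prepare_fold(table, train_ids, cfg)
        kept_b, med_b, corr_b = _prepare_fold(corrupted, train_ids, cfg)
        assert kept_a == kept_b
        pd.testing.assert_series_equal(med_a, med_b)
        tr = ~mask
        for c in kept_a:
            np.testing.assert_allclose(corr_a.loc[tr, c], corr_b.loc[tr, c])
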