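"""Tests of z-scoring, rankers, subset evaluation and stability selection."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from hdpanel import (
    COMBOS,
    GENOTYPE_TASK,
    TREATMENT_TASK,
    BiomarkerTable,
    ClassificationTask,
    CohortConfig,
    ModelCombo,
    StabilitySelection,
    compare_models,
    default_panel,
    evaluate_subsets,
    generate_cohort,
    logistic_rank,
    rank_features,
    zscore_features,
)

SVM_KNN = ModelCombo("svm_linear", "knn3_distance")


def _single_signal_cohort(seed, d=3.0, n=13):
    """27-feature cohort where only striatal volume separates the classes."""
    feats = []
    for f in default_panel():
        dg = d if f.name == "vol_striatum" else 0.0
        feats.append(
            dataclasses.replace(f, d_genotype=dg, d_treatment=0.0, d_wt_treatment=0.0)
        )
    cfg = CohortConfig(
        group_sizes={"WT-Veh": n, "R6/2-Veh": n}, features=feats,
        correlation_rho=0.0, seed=seed,
    )
    return generate_cohort(cfg)


class TestZScore:
    def test_standardizes_columns(self, default_cohort):
        X = default_cohort.data[default_cohort.features]
        Z = zscore_features(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0, ddof=0) - 1).max() < 1e-10

    def test_affine_invariance(self, default_cohort):
        X = default_cohort.data[default_cohort.features]
        X2 = X.copy()
        X2["vol_striatum"] = 5.0 * X2["vol_striatum"] - 3.0
        pd.testing.assert_series_equal(
            zscore_features(X)["vol_striatum"], zscore_features(X2)["vol_striatum"]
        )

    def test_train_only_scope_leaves_test_offset(self, default_cohort):
        X = default_cohort.data[default_cohort.features]
        train = X.index[:20]
        Z = zscore_features(X, subjects=train)
        assert np.abs(Z.loc[train].mean(axis=0)).max() < 1e-10
        assert np.abs(Z.drop(index=train).mean(axis=0)).max() > 1e-3

    def test_zero_sd_named(self, default_cohort):
        X = default_cohort.data[default_cohort.features].copy()
        X["il_2"] = 1.0
        with pytest.raises(ValueError, match="il_2"):
            zscore_features(X)


class TestLogisticRank:
    def test_sign_equivariance(self, default_cohort):
        base = logistic_rank(default_cohort, GENOTYPE_TASK).set_index("feature")
        flipped = default_cohort.copy()
        flipped.data["tnf_alpha"] = -flipped.data["tnf_alpha"]
        alt = logistic_rank(flipped, GENOTYPE_TASK).set_index("feature")
        assert alt.loc["tnf_alpha", "coefficient"] == pytest.approx(
            -base.loc["tnf_alpha", "coefficient"], abs=1e-6
        )
        others = [f for f in base.index if f != "tnf_alpha"]
        assert np.allclose(
            alt.loc[others, "coefficient"], base.loc[others, "coefficient"], atol=1e-6
        )

    def test_label_swap_flips_all_signs(self, default_cohort):
        fwd = logistic_rank(default_cohort, GENOTYPE_TASK).set_index("feature")
        rev_task = ClassificationTask("genotype_rev", "R6/2-Veh", "WT-Veh")
        rev = logistic_rank(default_cohort, rev_task).set_index("feature")
        assert np.allclose(
            rev.loc[fwd.index, "coefficient"], -fwd["coefficient"], atol=1e-6
        )

    def test_single_informative_feature_dominates(self):
        wins = 0
        for i in range(100):
            table = _single_signal_cohort(seed=3000 + i)
            ranking = logistic_rank(table, GENOTYPE_TASK)
            top = ranking.loc[ranking["coefficient"].abs().idxmax(), "feature"]
            wins += top == "vol_striatum"
        assert wins >= 95

    def test_disease_direction_signs(self, default_cohort):
        """With R6/2-Veh coded 1, markers raised in disease get positive
        coefficients and atrophied volumes negative ones."""
        coef = logistic_rank(default_cohort, GENOTYPE_TASK).set_index("feature")
        assert coef.loc["p75_urinary", "coefficient"] > 0
        assert coef.loc["vol_striatum", "coefficient"] < 0


class TestRankFeatures:
    @pytest.mark.parametrize("ranker", ["svm_linear", "xgb"])
    def test_single_informative_ranked_first(self, ranker):
        wins = 0
        for i in range(40):
            table = _single_signal_cohort(seed=4000 + i)
            X = zscore_features(table.data[table.features])
            y = (table.data["genotype"] == "R6/2").to_numpy().astype(int)
            ranking = rank_features(X, y, ranker, seed=i)
            wins += ranking[0] == "vol_striatum"
        assert wins >= 38  # >= 95%

    def test_column_permutation_changes_only_tie_breaks(self, default_cohort):
        X = zscore_features(default_cohort.data[default_cohort.features])
        y = (default_cohort.data["genotype"] == "R6/2").to_numpy().astype(int)
        base = rank_features(X, y, "svm_linear")
        shuffled = X[list(X.columns[::-1])]
        alt = rank_features(shuffled, y, "svm_linear")
        assert set(base) == set(alt)
        # SVM weights are continuous: no exact ties, so the order agrees
        assert base == alt

    def test_pure_noise_has_no_stable_winner(self):
        tops = set()
        for i in range(20):
            table = _single_signal_cohort(seed=5000 + i, d=0.0)
            X = zscore_features(table.data[table.features])
            y = (table.data["genotype"] == "R6/2").to_numpy().astype(int)
            tops.add(rank_features(X, y, "svm_linear", seed=i)[0])
        assert len(tops) > 3

    def test_one_class_train_rejected(self, default_cohort):
        X = zscore_features(default_cohort.data[default_cohort.features])
        with pytest.raises(ValueError, match="both classes"):
            rank_features(X.iloc[:10], np.zeros(10), "svm_linear")


class TestEvaluateSubsets:
    def test_separable_feature_gives_perfect_accuracy(self):
        # Small k only: KNN distances over many pure-noise z-scored
        # dimensions would swamp the single informative coordinate.
        table = _single_signal_cohort(seed=1, d=12.0)
        X = zscore_features(table.data[table.features])
        y = (table.data["genotype"] == "R6/2").to_numpy().astype(int)
        tr = np.r_[0:7, 13:20]
        te = np.r_[7:13, 20:26]
        ranking = rank_features(X.iloc[tr], y[tr], "svm_linear")
        assert ranking[0] == "vol_striatum"
        res = evaluate_subsets(
            ranking, X.iloc[tr], y[tr], X.iloc[te], y[te], "knn3_distance",
            k_range=[2, 5],
        )
        assert all(m[0] == 1.0 for m in res.values())

    def test_metrics_on_constructed_confusions(self):
        """Balanced classes with symmetric errors: acc = prec = recall."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12)})
        y = np.array([0, 1] * 6)
        res = evaluate_subsets(["a", "b"], X, y, X, y, "knn3_distance", k_range=[2])
        acc, prec, rec = res[2]
        assert acc == prec == rec == 1.0  # train = test, distance weighting

    def test_missing_test_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(8.0)})
        with pytest.raises(ValueError, match="missing a class"):
            evaluate_subsets(["a"], X, np.r_[np.zeros(4), np.ones(4)],
                             X, np.zeros(8), "knn3_distance", k_range=[1])


class TestStabilitySelection:
    def test_single_permutation_occurrence_counting(self, default_cohort):
        res = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, n_permutations=1, seed=0,
            k_range=[2],
        ).fit()
        assert (res.occurrence == 100).sum() == 15
        assert (res.occurrence == 0).sum() == 12

    def test_occurrence_conservation(self, default_cohort):
        res = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, n_permutations=13, seed=3,
            k_range=[2],
        ).fit()
        assert res.occurrence.sum() == pytest.approx(100 * 15)
        assert res.occurrence.between(0, 100).all()

    def test_bit_identical_reproducibility(self, default_cohort):
        kw = dict(n_permutations=8, seed=11, k_range=range(2, 6))
        a = StabilitySelection(default_cohort, GENOTYPE_TASK, SVM_KNN, **kw).fit()
        b = StabilitySelection(default_cohort, GENOTYPE_TASK, SVM_KNN, **kw).fit()
        pd.testing.assert_frame_equal(a.curves, b.curves)
        pd.testing.assert_series_equal(a.occurrence, b.occurrence)
        assert [p.test_ids for p in a.permutations] == [p.test_ids for p in b.permutations]
        c = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, n_permutations=8, seed=12,
            k_range=range(2, 6),
        ).fit()
        assert not a.curves.equals(c.curves) or a.occurrence.equals(c.occurrence) is False

    def test_split_sizes_match_design(self, default_cohort):
        """6 test subjects per class; at most 7 training per class."""
        res = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, n_permutations=5, seed=0,
            k_range=[2],
        ).fit()
        for p in res.permutations:
            assert len(p.test_ids) == 12
            assert len(p.train_ids) == 13  # 6 WT-Veh (of 12) + 7 R6/2-Veh (of 14)
            assert set(p.test_ids).isdisjoint(p.train_ids)

    def test_insufficient_subjects_cited(self):
        cfg = CohortConfig(group_sizes={"WT-Veh": 8, "R6/2-Veh": 14}, seed=0)
        table = generate_cohort(cfg)
        with pytest.raises(ValueError, match="6 test"):
            StabilitySelection(table, GENOTYPE_TASK, SVM_KNN, n_permutations=1).fit()

    def test_dominant_features_always_in_top15(self):
        """With 15 huge-effect and 12 null features, occurrence is 0 or 100."""
        feats = []
        for j, f in enumerate(default_panel()):
            feats.append(
                dataclasses.replace(
                    f, d_genotype=8.0 if j < 15 else 0.0,
                    d_treatment=0.0, d_wt_treatment=0.0,
                )
            )
        cfg = CohortConfig(
            group_sizes={"WT-Veh": 13, "R6/2-Veh": 13}, features=feats,
            correlation_rho=0.0, seed=77,
        )
        table = generate_cohort(cfg)
        res = StabilitySelection(
            table, GENOTYPE_TASK, SVM_KNN, n_permutations=10, seed=1, k_range=[2],
        ).fit()
        strong = {f.name for f in feats[:15]}
        assert set(res.occurrence[res.occurrence == 100].index) == strong
        assert (res.occurrence[~res.occurrence.index.isin(strong)] == 0).all()

    def test_signal_monotonicity(self):
        """Scaling every effect size up never hurts mean accuracy (MC slack)."""
        accs = []
        for lam in (0.0, 0.5, 1.0):
            feats = [
                dataclasses.replace(
                    f, d_genotype=f.d_genotype * lam,
                    d_treatment=f.d_treatment * lam,
                    d_wt_treatment=f.d_wt_treatment * lam,
                )
                for f in default_panel()
            ]
            cfg = CohortConfig(
                group_sizes={"WT-Veh": 13, "R6/2-Veh": 13}, features=feats, seed=8,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = generate_cohort(cfg)
            res = StabilitySelection(
                table, GENOTYPE_TASK, SVM_KNN, n_permutations=40, seed=2,
                k_range=[10, 20],
            ).fit()
            accs.append(res.curves["accuracy_mean"].mean())
        mc_slack = 3 * np.sqrt(0.25 / (40 * 12))
        assert accs[0] <= accs[1] + mc_slack <= accs[2] + 2 * mc_slack

    def test_refit_per_step_mode_runs(self, default_cohort):
        res = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, n_permutations=2, seed=0,
            k_range=[2, 10], refit_per_step=True,
        ).fit()
        assert len(res.permutations[0].ranking) == 27
        assert set(res.permutations[0].ranking) == set(default_cohort.features)

    def test_train_scope_zscoring_differs_from_full(self, default_cohort):
        kw = dict(n_permutations=4, seed=5, k_range=range(2, 8))
        full = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, zscore_scope="full", **kw
        ).fit()
        train = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, zscore_scope="train", **kw
        ).fit()
        assert not np.allclose(
            full.curves["accuracy_mean"], train.curves["accuracy_mean"]
        ) or not full.occurrence.equals(train.occurrence)


class TestCompareModels:
    def test_ordering_deterministic_and_dominance(self, default_cohort):
        strong = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, n_permutations=10, seed=1,
            k_range=[5, 10],
        ).fit()
        noise_table = _single_signal_cohort(seed=9, d=0.0)
        weak_model = StabilitySelection(
            noise_table, GENOTYPE_TASK, SVM_KNN, n_permutations=10, seed=1,
            k_range=[5, 10],
        ).fit()
        cmp1 = compare_models([strong, weak_model])
        cmp2 = compare_models([strong, weak_model])
        pd.testing.assert_frame_equal(cmp1, cmp2)
        assert cmp1.iloc[0]["accuracy"] >= cmp1.iloc[1]["accuracy"]

    def test_mismatched_tasks_rejected(self, default_cohort):
        g = StabilitySelection(
            default_cohort, GENOTYPE_TASK, SVM_KNN, n_permutations=2, seed=0, k_range=[2]
        ).fit()
        t = StabilitySelection(
            default_cohort, TREATMENT_TASK, SVM_KNN, n_permutations=2, seed=0, k_range=[2]
        ).fit()
        with pytest.raises(ValueError, match="mismatch"):
            compare_models([g, t])

    def test_four_combo_labels(self):
        assert {c.label for c in COMBOS} == {"SVM-KNN", "SVM-RFC", "XGB-KNN", "XGB-RFC"}
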