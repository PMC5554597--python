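"""Pair feature tables, confusion metrics and the random-forest baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecoknn as ek
from ecoknn.baseline import ConfusionCounts

counts_st = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 1000),
    tn=st.integers(0, 1000),
    fp=st.integers(0, 1000),
    fn=st.integers(0, 1000),
)


class TestMetrics:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(tp=1, tn=0, fp=0, fn=0), 1.0),
            (ConfusionCounts(tp=0, tn=0, fp=5, fn=0), 0.0),
            (ConfusionCounts(tp=3, tn=0, fp=1, fn=0), 0.75),
        ],
    )
    def test_interaction_precision(self, c, expected):
        assert ek.score_y(c) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(tp=0, tn=1, fp=0, fn=0), 1.0),
            (ConfusionCounts(tp=0, tn=0, fp=0, fn=2), 0.0),
            (ConfusionCounts(tp=0, tn=9, fp=0, fn=1), 0.9),
        ],
    )
    def test_non_interaction_precision(self, c, expected):
        assert ek.score_not_y(c) == pytest.approx(expected)

    def test_precision_undefined_without_predictions_of_that_class(self):
        with pytest.raises(ZeroDivisionError):
            ek.score_y(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        with pytest.raises(ZeroDivisionError):
            ek.score_not_y(ConfusionCounts(tp=5, tn=0, fp=5, fn=0))

    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(tp=1, tn=1, fp=0, fn=0), 1.0),
            (ConfusionCounts(tp=0, tn=0, fp=1, fn=1), -1.0),
            (ConfusionCounts(tp=96, tn=995, fp=5, fn=4), 0.955),
        ],
    )
    def test_true_skill_statistic(self, c, expected):
        assert ek.tss(c) == pytest.approx(expected)

    @given(counts_st)
    @settings(max_examples=200, derandomize=True)
    def test_tss_bounded_and_antisymmetric(self, c):
        try:
            value = ek.tss(c)
        except ZeroDivisionError:
            return
        assert -1.0 <= value <= 1.0
        swapped = ConfusionCounts(tp=c.fn, tn=c.fp, fp=c.tn, fn=c.tp)
        assert ek.tss(swapped) == pytest.approx(-value)

    def test_weighted_accuracy_of_perfect_classifier_is_one(self):
        c = ConfusionCounts(tp=10, tn=90, fp=0, fn=0)
        assert ek.weighted_accuracy(c, 20, 80, 10) == pytest.approx(1.0)

    def test_weighted_accuracy_balances_classes(self):
        c = ConfusionCounts(tp=10, tn=0, fp=0, fn=90)  # score_y=1, score_not_y=0
        assert ek.weighted_accuracy(c, 50, 50, 10) == pytest.approx(0.5)

    def test_weighted_accuracy_with_soil_web_constants_is_identity_on_equal_scores(self):
        # 34,193 interactions + 741,968 non-interactions = 881^2: when both
        # precisions equal s the weighted accuracy collapses to s
        c = ConfusionCounts(tp=3, tn=3, fp=1, fn=1)  # both scores 0.75
        acc = ek.weighted_accuracy(c, 34193, 741968, 881)
        assert acc == pytest.approx(0.75)

    def test_weighted_accuracy_count_mismatch_raises(self):
        c = ConfusionCounts(tp=1, tn=1, fp=1, fn=1)
        with pytest.raises(ValueError, match="mismatch"):
            ek.weighted_accuracy(c, 10, 10, 10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestPairTable:
    def test_three_species_web_has_six_off_diagonal_rows(self):
        web = ek.FoodWeb()
        for sid in ("a", "b", "c"):
            web.add_species(ek.SpeciesRecord(sid, body_mass_log=1.0, ph0=0.1, ph1=0.2))
        web.add_interaction("a", "b")
        table = ek.build_pair_table(web)
        assert len(table) == 6
        assert table["label"].sum() == 1

    def test_diagonal_toggle_gives_n_squared_rows(self):
        web = ek.FoodWeb()
        for sid in range(4):
            web.add_species(ek.SpeciesRecord(sid, body_mass_log=0.0, ph0=0.0, ph1=0.0))
        assert len(ek.build_pair_table(web, include_self=True)) == 16

    def test_label_column_sums_to_interaction_count(self):
        web = ek.make_mass_window_web(40, window=0.2, seed=1)
        table = ek.build_pair_table(web)
        assert table["label"].sum() == len(web.interactions)

    def test_feature_order_is_predator_then_prey(self):
        web = ek.FoodWeb(vocabulary=ek.TraitVocabulary(["T1", "T2"]))
        web.add_species(
            ek.SpeciesRecord("x", binary_traits={"T1"}, body_mass_log=1.0, ph0=0.2, ph1=0.3)
        )
        web.add_species(
            ek.SpeciesRecord("y", binary_traits={"T2"}, body_mass_log=2.0, ph0=0.4, ph1=0.5)
        )
        table = ek.build_pair_table(web)
        from ecoknn.baseline import feature_columns

        cols = feature_columns(table)
        assert cols == [
            "pred_T1", "pred_T2", "pred_body_mass_log", "pred_ph0", "pred_ph1",
            "prey_T1", "prey_T2", "prey_body_mass_log", "prey_ph0", "prey_ph1",
        ]
        row = table[(table.predator_id == "x") & (table.prey_id == "y")].iloc[0]
        assert row["pred_T1"] == 1 and row["pred_T2"] == 0
        assert row["prey_body_mass_log"] == pytest.approx(2.0)

    def test_feature_subset_restriction(self):
        web = ek.make_mass_window_web(20, window=0.2, seed=0)
        from ecoknn.baseline import feature_columns

        table = ek.build_pair_table(web, features=["body_mass_log", "ph0", "ph1"])
        assert len(feature_columns(table)) == 6
        with pytest.raises(ValueError, match="unknown"):
            ek.build_pair_table(web, features=["nope"])

    def test_missing_continuous_values_raise_listing_species(self):
        web = ek.FoodWeb()
        web.add_species(ek.SpeciesRecord("a", body_mass_log=1.0, ph0=0.1, ph1=0.1))
        web.add_species(ek.SpeciesRecord("b"))
        with pytest.raises(ValueError, match="b"):
            ek.build_pair_table(web)


@pytest.fixture(scope="module")
def rule_table():
    web = ek.make_mass_window_web(n_species=80, window=0.2, seed=5)
    return ek.build_pair_table(web, features=["body_mass_log"])


class TestTrainAndScore:
    def test_threshold_rule_web_is_learnable(self, rule_table):
        result = ek.train_and_score(rule_table, test_fraction=0.1, seed=0)
        assert result.tss > 0.8
        assert result.counts.total == result.n_test

    def test_shuffled_labels_give_no_skill(self, rule_table):
        rng = np.random.default_rng(0)
        null = rule_table.copy()
        null["label"] = rng.permutation(null["label"].to_numpy())
        result = ek.train_and_score(
            null, test_fraction=0.1, seed=0, grid={"n_estimators": [50]}
        )
        assert abs(result.tss) < 0.25  # single small split; tighter bound needs replication

    def test_deterministic_under_seed(self, rule_table):
        a = ek.train_and_score(rule_table, test_fraction=0.1, seed=3, grid={"n_estimators": [50]})
        b = ek.train_and_score(rule_table, test_fraction=0.1, seed=3, grid={"n_estimators": [50]})
        assert a.counts == b.counts and a.tss == b.tss

    def test_grid_search_reports_chosen_parameters(self, rule_table):
        result = ek.train_and_score(
            rule_table,
            test_fraction=0.1,
            seed=0,
            grid={"n_estimators": [20, 50], "max_depth": [4]},
        )
        assert result.best_params["n_estimators"] in (20, 50)
        assert result.best_params["max_depth"] == 4

    def test_continuous_only_features_run_end_to_end(self):
        web = ek.make_mass_window_web(n_species=60, window=0.2, seed=2)
        table = ek.build_pair_table(web, features=["body_mass_log", "ph0", "ph1"])
        result = ek.train_and_score(table, test_fraction=0.1, seed=0, grid={"n_estimators": [50]})
        assert -1.0 <= result.tss <= 1.0

    def test_single_class_training_set_raises(self):
        web = ek.FoodWeb()
        for sid in range(6):
            web.add_species(ek.SpeciesRecord(sid, body_mass_log=float(sid), ph0=0.0, ph1=0.0))
        table = ek.build_pair_table(web)  # no interactions at all
        with pytest.raises(ValueError, match="single class"):
            ek.train_and_score(table, test_fraction=0.1, seed=0)

    def test_invalid_test_fraction_raises(self, rule_table):
        with pytest.raises(ValueError):
            ek.train_and_score(rule_table, test_fraction=0.0)
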