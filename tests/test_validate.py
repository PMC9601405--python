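import numpy as np
import pytest

from stopflow import data, simulate
from stopflow.errors import LeakageError, NoSignalError
from stopflow.features import FeatureSetSpec
from stopflow.model import MetricReport, ModelConfig
from stopflow.validate import (
    LedgerEntry,
    ModelLedger,
    evaluate_temporal,
    make_loao_splits,
    make_random_splits,
    prioritization_analysis,
    run_cv_protocol,
    select_best_model,
    train_final_model,
)

COND_SPEC = FeatureSetSpec("cond_only", ("conditions",))


class TestRandomSplits:
    def test_sixty_forty_sizes(self, campaign):
        labelled, _ = campaign
        plan = make_random_splits(labelled, seed=0)
        n = len([r for r in labelled.records if r.label != "missing"])
        assert len(plan.splits) == 3
        for train, test in plan.splits:
            assert abs(len(train) - round(0.6 * n)) <= 1
            assert len(train) + len(test) == n
            assert not set(train) & set(test)

    def test_stratified_by_label(self, campaign):
        labelled, _ = campaign
        plan = make_random_splits(labelled, seed=0)
        y = {
            i: labelled.records[i].label == "successful"
            for i, r in enumerate(labelled.records)
            if r.label != "missing"
        }
        overall = np.mean(list(y.values()))
        for train, _ in plan.splits:
            frac = np.mean([y[i] for i in train])
            assert abs(frac - overall) < 0.02

    def test_deterministic_per_seed(self, campaign):
        labelled, _ = campaign
        assert make_random_splits(labelled, seed=5) == make_random_splits(labelled, seed=5)
        assert make_random_splits(labelled, seed=5) != make_random_splits(labelled, seed=6)

    def test_degenerate_train_fraction_rejected(self, campaign):
        labelled, _ = campaign
        with pytest.raises(ValueError):
            make_random_splits(labelled, train_frac=1.0)


class TestLoaoSplits:
    def test_one_split_per_amine(self, campaign):
        labelled, _ = campaign
        plan = make_loao_splits(labelled)
        assert len(plan.splits) == 5
        assert len(plan.held_out_amines) == 5
        for (train, test), amine in zip(plan.splits, plan.held_out_amines):
            assert {labelled.records[i].amine_id for i in test} == {amine}
            assert amine not in {labelled.records[i].amine_id for i in train}

    def test_test_sets_partition_the_usable_records(self, campaign):
        labelled, _ = campaign
        plan = make_loao_splits(labelled)
        all_test = [i for _, test in plan.splits for i in test]
        usable = [i for i, r in enumerate(labelled.records) if r.label != "missing"]
        assert sorted(all_test) == sorted(usable)

    def test_two_amines_give_two_complementary_splits(self):
        config = simulate.SyntheticConfig(n_acids=2, n_amines=2, seed=0, dropout_rate=0.0)
        ds, _ = simulate.generate_library(config)
        labelled = data.label_outcomes(ds)
        plan = make_loao_splits(labelled)
        assert len(plan.splits) == 2
        (tr1, te1), (tr2, te2) = plan.splits
        assert sorted(tr1) == sorted(te2)
        assert sorted(tr2) == sorted(te1)

    def test_single_amine_rejected(self):
        config = simulate.SyntheticConfig(n_acids=2, n_amines=1, seed=0)
        ds, _ = simulate.generate_library(config)
        with pytest.raises(ValueError):
            make_loao_splits(data.label_outcomes(ds))


@pytest.fixture(scope="module")
def protocol_ledger(campaign, tiny_space):
    labelled, _ = campaign
    return run_cv_protocol(labelled, [COND_SPEC], budget=1, seed=3, search_space=tiny_space)


class TestCvProtocol:
    def test_sixteen_models_per_feature_set(self, protocol_ledger):
        assert len(protocol_ledger) == 16
        by_mode = {"true": 0, "shuffled": 0}
        for e in protocol_ledger.entries:
            by_mode[e.label_mode] += 1
        assert by_mode == {"true": 8, "shuffled": 8}
        kinds = {(e.split_kind, e.split_index) for e in protocol_ledger.entries}
        assert sum(k == "random_60_40" for k, _ in kinds) == 3
        assert sum(k == "leave_one_amine_out" for k, _ in kinds) == 5

    def test_true_models_beat_their_shuffled_twins(self, protocol_ledger):
        frame = protocol_ledger.to_frame()
        means = frame.groupby("label_mode")["auc"].mean()
        assert means["true"] > 0.7
        assert 0.3 < means["shuffled"] < 0.7

    def test_temporal_guard_blocks_overlapping_campaigns(self, campaign, tiny_space):
        labelled, _ = campaign
        with pytest.raises(LeakageError):
            run_cv_protocol(
                labelled,
                [COND_SPEC],
                budget=1,
                seed=0,
                search_space=tiny_space,
                temporal_guard=labelled,
            )


def _entry(feature_set, label_mode, precision, auc, width=10, split=0):
    return LedgerEntry(
        feature_set=feature_set,
        split_kind="random_60_40",
        split_index=split,
        label_mode=label_mode,
        config=ModelConfig(),
        metrics=MetricReport(
            TP=1, FP=1, TN=1, FN=1,
            precision=precision, recall=0.5, accuracy=0.5,
            roc_auc=auc, cutoff=0.5,
        ),
        feature_width=width,
    )


class TestSelection:
    def test_dominating_feature_set_wins(self):
        ledger = ModelLedger(
            entries=[
                _entry("good", "true", 0.9, 0.9),
                _entry("good", "shuffled", 0.5, 0.5),
                _entry("bad", "true", 0.6, 0.6),
                _entry("bad", "shuffled", 0.5, 0.5),
            ]
        )
        name, config = select_best_model(ledger)
        assert name == "good"
        assert isinstance(config, ModelConfig)

    def test_precision_tie_broken_by_auc(self):
        ledger = ModelLedger(
            entries=[
                _entry("a", "true", 0.8, 0.7),
                _entry("a", "shuffled", 0.5, 0.5),
                _entry("b", "true", 0.8, 0.9),
                _entry("b", "shuffled", 0.5, 0.5),
            ]
        )
        assert select_best_model(ledger)[0] == "b"

    def test_winner_must_beat_its_shuffled_nulls(self):
        ledger = ModelLedger(
            entries=[
                _entry("a", "true", 0.5, 0.5),
                _entry("a", "shuffled", 0.7, 0.7),
            ]
        )
        with pytest.raises(NoSignalError):
            select_best_model(ledger)

    def test_condition_spec_wins_when_conditions_carry_all_signal(self, tiny_space):
        # generator with zero substrate structure: only agent + condition effects
        config = simulate.SyntheticConfig(
            n_acids=3, n_amines=3, seed=9, dropout_rate=0.0,
            acid_sd=0.0, amine_sd=0.0, pair_sd=0.0,
        )
        ds, _ = simulate.generate_library(config)
        labelled = data.label_outcomes(ds)
        fp_spec = FeatureSetSpec("rxnfp", ("reaction_fp",), fp_length=128)
        ledger = run_cv_protocol(
            labelled, [COND_SPEC, fp_spec], budget=1, seed=1, search_space=tiny_space
        )
        # 2 x (3 random + 3 LOAO) entries per feature set for a 3-amine library
        assert len(ledger) == 24
        assert select_best_model(ledger)[0] == "cond_only"


class TestTemporalEvaluation:
    @pytest.fixture(scope="class")
    def pair(self, tiny_space):
        config = simulate.SyntheticConfig(seed=21)
        train, truth, temporal, _ = simulate.generate_temporal_pair(config)
        labelled = data.label_outcomes(train)
        temporal_lab = data.label_outcomes(temporal)
        final = train_final_model(
            labelled, COND_SPEC, budget=1, seed=2, search_space=tiny_space
        )
        return labelled, temporal_lab, final

    def test_one_score_per_usable_temporal_record(self, pair):
        _, temporal_lab, final = pair
        report, scores, keys = evaluate_temporal(final, temporal_lab)
        n_usable = len(temporal_lab.usable_records())
        assert len(scores) == len(keys) == n_usable
        assert scores.min() >= 0 and scores.max() <= 1
        assert 0 <= report.accuracy <= 1

    def test_scoring_the_training_campaign_is_a_leakage_error(self, pair):
        labelled, _, final = pair
        with pytest.raises(LeakageError):
            evaluate_temporal(final, labelled)

    def test_temporal_accuracy_tracks_hold_out_accuracy_on_shared_surface(self, tiny_space):
        # both campaigns drawn from one latent surface are exchangeable up to
        # reagent novelty; accuracies should land in the same region
        gaps = []
        for seed in range(4):
            config = simulate.SyntheticConfig(seed=50 + seed)
            train, _, temporal, _ = simulate.generate_temporal_pair(config)
            labelled = data.label_outcomes(train)
            temporal_lab = data.label_outcomes(temporal)
            plan = make_random_splits(labelled, n_splits=1, seed=seed)
            final = train_final_model(
                labelled, COND_SPEC, budget=1, seed=seed, search_space=tiny_space
            )
            report, _, _ = evaluate_temporal(final, temporal_lab)
            # hold-out comparator trained on the same campaign
            from stopflow.features import assemble_features
            from stopflow.model import evaluate_metrics, predict_scores, train_classifier

            X, y, std, keys = assemble_features(labelled, COND_SPEC)
            idx = {k: i for i, k in enumerate(keys)}
            tr, te = plan.splits[0]
            tr = np.array([idx[labelled.records[i].key] for i in tr])
            te = np.array([idx[labelled.records[i].key] for i in te])
            std.fit(X, rows=tr)
            Xs = std.transform(X)
            m = train_classifier(Xs[tr], y[tr], final.config)
            hold_on = evaluate_metrics(y[te], predict_scores(m, Xs[te])).accuracy
            gaps.append(abs(report.accuracy - hold_on))
        assert np.mean(gaps) < 0.15


class TestPrioritization:
    # hand toy: 6 experiments over 3 products with fixed scores and outcomes
    SCORES = np.array([0.9, 0.2, 0.6, 0.4, 0.8, 0.1])
    LABELS = np.array([1, 0, 1, 1, 0, 0])
    PRODUCTS = [("A1", "B1"), ("A1", "B1"), ("A1", "B2"), ("A1", "B2"), ("A2", "B1"), ("A2", "B1")]

    def test_hand_enumerated_threshold_rows(self):
        rows = prioritization_analysis(
            self.SCORES, self.LABELS, self.PRODUCTS,
            thresholds=(0.0, 0.5), highest_per_product=False,
        )
        t0, t5 = rows
        assert (t0.n_experiments, t0.n_success, t0.n_fail) == (6, 3, 3)
        # (A2, B1) never succeeds, so it is the one failed product
        assert (t0.n_products_success, t0.n_products_fail) == (2, 1)
        # score >= 0.5 selects experiments 0, 2, 4: outcomes 1, 1, 0
        assert (t5.n_experiments, t5.n_success, t5.n_fail) == (3, 2, 1)
        assert (t5.n_products_success, t5.n_products_fail) == (2, 1)

    def test_highest_per_product_selects_one_experiment_per_product(self):
        rows = prioritization_analysis(
            self.SCORES, self.LABELS, self.PRODUCTS, thresholds=()
        )
        (hp,) = rows
        assert hp.selector == "highest_score_per_product"
        # picks experiments 0 (0.9, success), 2 (0.6, success), 4 (0.8, fail)
        assert hp.n_experiments == 3
        assert (hp.n_success, hp.n_fail) == (2, 1)
        assert (hp.n_products_success, hp.n_products_fail) == (2, 1)

    def test_threshold_zero_row_equals_dataset_totals(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        products = [(f"A{i % 5}", f"B{i % 3}") for i in range(50)]
        row = prioritization_analysis(
            scores, labels, products, thresholds=(0.0,), highest_per_product=False
        )[0]
        assert row.n_experiments == 50
        assert row.n_success == labels.sum()

    def test_counts_monotone_in_the_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = 60
            scores = rng.uniform(size=n)
            labels = rng.integers(0, 2, n)
            products = [(f"A{rng.integers(4)}", f"B{rng.integers(4)}") for _ in range(n)]
            rows = prioritization_analysis(
                scores, labels, products,
                thresholds=tuple(np.linspace(0, 1, 8)), highest_per_product=False,
            )
            for a, b in zip(rows, rows[1:]):
                assert b.n_experiments <= a.n_experiments
                assert b.n_products_success <= a.n_products_success

    def test_all_max_scores_make_high_threshold_equal_threshold_zero(self):
        scores = np.ones(6)
        rows = prioritization_analysis(
            scores, self.LABELS, self.PRODUCTS,
            thresholds=(0.0, 0.9), highest_per_product=False,
        )
        assert rows[0] == rows[1].__class__(
            selector=rows[0].selector, **{
                f: getattr(rows[1], f)
                for f in ("n_experiments", "n_success", "n_fail",
                          "n_products_success", "n_products_fail")
            }
        )

    def test_tie_broken_by_harsher_condition_then_agent(self):
        scores = np.array([0.7, 0.7, 0.7])
        labels = np.array([1, 0, 1])
        products = [("A1", "B1")] * 3
        ranks = np.array([1, 3, 3])
        agents = ["HATU", "T3P", "HATU"]
        rows = prioritization_analysis(
            scores, labels, products, thresholds=(),
            condition_ranks=ranks, agent_ids=agents,
        )
        # harshest rank wins; among rank-3 ties HATU < T3P lexicographically
        assert rows[0].n_experiments == 1
        assert rows[0].n_success == 1

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            prioritization_analysis(np.ones(3), np.ones(2, dtype=int), [("a", "b")] * 3)
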