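import numpy as np
import pandas as pd
import pytest

from genetrait.balancing import plan_bags
from genetrait.datatypes import (ContributionCube, CorrelationGroups,
                                 PipelineConfig, SelectionResult)
from genetrait.forest import casewise_cube, fit_forest_bag
from genetrait.selection import (aggregate_bags, class_accuracy, gate_classes,
                                 iterate_selection, rank_and_readd,
                                 stable_feature_set, strain_accuracy_report)
from genetrait.simulate import gen_panel

from conftest import imbalanced_labels


def _cube(scores: pd.DataFrame, labels: pd.Series,
          fractions: pd.DataFrame | None = None) -> ContributionCube:
    samples = list(scores.columns)
    if fractions is None:
        classes = sorted(labels.unique())
        fractions = pd.DataFrame(1.0 / len(classes), index=samples, columns=classes)
    tallies = pd.DataFrame(0, index=samples, columns=["n_correct", "n_incorrect"])
    errors = pd.Series(0.0, index=sorted(labels.unique()))
    return ContributionCube(scores=scores, class_errors=errors,
                            vote_fractions=fractions, vote_tallies=tallies,
                            labels=labels)


class TestAggregateBags:
    def test_single_bag_identity(self):
        labels = pd.Series(["a", "b"], index=["s1", "s2"])
        cube = _cube(pd.DataFrame([[0.1, 0.2]], index=["g1"], columns=["s1", "s2"]),
                     labels)
        assert aggregate_bags([cube]) is cube

    def test_mean_over_bags(self):
        labels = pd.Series(["a", "b"], index=["s1", "s2"])
        c1 = _cube(pd.DataFrame([[0.2, 0.0]], index=["g1"], columns=["s1", "s2"]), labels)
        c2 = _cube(pd.DataFrame([[0.4, 0.2]], index=["g1"], columns=["s1", "s2"]), labels)
        agg = aggregate_bags([c1, c2])
        assert agg.scores.loc["g1", "s1"] == pytest.approx(0.3)
        assert agg.scores.loc["g1", "s2"] == pytest.approx(0.1)

    def test_sample_absent_from_bag_excluded_from_its_mean(self):
        l1 = pd.Series(["a", "b"], index=["s1", "s2"])
        l2 = pd.Series(["a", "b"], index=["s1", "s3"])
        c1 = _cube(pd.DataFrame([[0.2, 0.6]], index=["g1"], columns=["s1", "s2"]), l1)
        c2 = _cube(pd.DataFrame([[0.4, 0.8]], index=["g1"], columns=["s1", "s3"]), l2)
        agg = aggregate_bags([c1, c2])
        assert agg.scores.loc["g1", "s2"] == pytest.approx(0.6)  # only bag 1
        assert agg.scores.loc["g1", "s3"] == pytest.approx(0.8)  # only bag 2
        assert agg.scores.loc["g1", "s1"] == pytest.approx(0.3)


class TestStability:
    def _run(self, pos_samples, labels):
        """Cube where g1 scores +0.5 on pos_samples and -0.1 elsewhere."""
        scores = pd.DataFrame(-0.1, index=["g1"], columns=labels.index)
        scores.loc["g1", pos_samples] = 0.5
        return _cube(scores, labels)

    def test_three_strain_support_in_all_runs_kept(self):
        labels = pd.Series(["Yes"] * 6 + ["No"] * 6,
                           index=[f"s{i}" for i in range(12)])
        runs = [self._run(["s0", "s1", "s2"], labels) for _ in range(3)]
        kept, discarded = stable_feature_set(runs, min_support_strains=3)
        assert kept == ["g1"] and discarded == []

    def test_support_in_two_of_three_runs_discarded(self):
        labels = pd.Series(["Yes"] * 6 + ["No"] * 6,
                           index=[f"s{i}" for i in range(12)])
        runs = [self._run(["s0", "s1", "s2"], labels),
                self._run(["s0", "s1", "s2"], labels),
                self._run(["s0", "s1"], labels)]
        kept, discarded = stable_feature_set(runs, min_support_strains=3)
        assert kept == [] and discarded == ["g1"]
        # the relaxed any-run rule keeps it
        kept_any, _ = stable_feature_set(runs, min_support_strains=3, rule="any-run")
        assert kept_any == ["g1"]

    def test_support_split_across_classes_does_not_count(self):
        """Positive scores must concentrate in one class: 2 strains of each
        of two classes is not 3 strains of the same phenotype."""
        labels = pd.Series(["Yes"] * 6 + ["No"] * 6,
                           index=[f"s{i}" for i in range(12)])
        runs = [self._run(["s0", "s1", "s6", "s7"], labels) for _ in range(3)]
        kept, _ = stable_feature_set(runs, min_support_strains=3)
        assert kept == []

    def test_all_zero_scores_discarded(self):
        labels = pd.Series(["Yes"] * 4 + ["No"] * 4,
                           index=[f"s{i}" for i in range(8)])
        cube = _cube(pd.DataFrame(0.0, index=["g1"], columns=labels.index), labels)
        kept, discarded = stable_feature_set([cube] * 3)
        assert discarded == ["g1"]

    def test_support_fraction_raises_bar_for_large_classes(self):
        labels = pd.Series(["Yes"] * 30 + ["No"] * 6,
                           index=[f"s{i}" for i in range(36)])
        runs = [self._run(["s0", "s1", "s2"], labels) for _ in range(3)]
        kept, _ = stable_feature_set(runs, min_support_strains=3, support_fraction=0.25)
        assert kept == []  # 3 of 30 < 25% of the Yes class


class TestIteration:
    def test_monotone_shrinkage_and_stop_rule(self):
        rng = np.random.default_rng(0)
        fm, pt, truth = gen_panel(n_samples=24, n_features=60, n_causal=3,
                                  operon_block=None, flip_noise=0.02,
                                  class_sizes=(8, 16), rng=rng)
        cfg = PipelineConfig(n_trees=40, cover_l=3).validate()
        res = iterate_selection(fm.values, pt.experiment("exp1"), cfg, rng)
        sizes = [t["n_features_in"] for t in res.trace]
        assert sizes == sorted(sizes, reverse=True)
        assert res.trace[-1]["n_removed"] < cfg.r_stop
        for t in res.trace[:-1]:
            assert t["n_removed"] >= cfg.r_stop

    def test_all_causal_features_stop_first_round(self):
        """When every feature is informative, round 1 removes (almost)
        nothing and iteration stops immediately."""
        rng = np.random.default_rng(1)
        fm, pt, _ = gen_panel(n_samples=24, n_features=4, n_causal=4,
                              operon_block=None, flip_noise=0.0,
                              class_sizes=(8, 16), rng=rng)
        cfg = PipelineConfig(n_trees=40, cover_l=3).validate()
        res = iterate_selection(fm.values, pt.experiment("exp1"), cfg, rng)
        assert len(res.trace) == 1
        assert res.trace[0]["n_removed"] < cfg.r_stop

    def test_r_stop_one_runs_until_no_removals(self):
        rng = np.random.default_rng(2)
        fm, pt, _ = gen_panel(n_samples=24, n_features=30, n_causal=2,
                              operon_block=None, flip_noise=0.02,
                              class_sizes=(8, 16), rng=rng)
        cfg = PipelineConfig(n_trees=40, cover_l=3, r_stop=1).validate()
        res = iterate_selection(fm.values, pt.experiment("exp1"), cfg, rng)
        assert res.trace[-1]["n_removed"] == 0


class TestGating:
    def _result(self, accuracy: dict) -> SelectionResult:
        return SelectionResult(experiment="e", gated_classes=[],
                               ranking=pd.DataFrame(), trace=[], cube=None,
                               class_accuracy=pd.Series(accuracy),
                               bag_mode="none")

    def test_two_thirds_retained(self):
        res = self._result({"Yes": 4 / 6, "No": 1.0})
        assert gate_classes(res, 0.60) == ["Yes", "No"]

    def test_zero_accuracy_dropped(self):
        res = self._result({"Yes": 0.0, "No": 0.9})
        assert gate_classes(res, 0.60) == ["No"]

    def test_boundary_exactly_sixty_percent_retained(self):
        res = self._result({"Yes": 0.6})
        assert gate_classes(res, 0.60) == ["Yes"]
        # the exclusive convention would drop it
        assert [c for c, a in res.class_accuracy.items() if a > 0.60] == []

    def test_class_accuracy_majority_of_averaged_votes(self):
        labels = pd.Series(["a", "a", "b"], index=["s1", "s2", "s3"])
        frac = pd.DataFrame([[0.8, 0.2], [0.5, 0.5], [0.1, 0.9]],
                            index=["s1", "s2", "s3"], columns=["a", "b"])
        cube = _cube(pd.DataFrame(0.0, index=["g"], columns=labels.index),
                     labels, fractions=frac)
        acc = class_accuracy(cube)
        assert acc["a"] == pytest.approx(0.5)  # tie on s2 counts as wrong
        assert acc["b"] == pytest.approx(1.0)


class TestRankingAndReadd:
    def _result_with_cube(self, scores, labels) -> SelectionResult:
        cube = _cube(scores, labels)
        return SelectionResult(experiment="e", gated_classes=["Yes"],
                               ranking=pd.DataFrame(), trace=[], cube=cube,
                               class_accuracy=pd.Series({"Yes": 1.0}),
                               bag_mode="none")

    def test_phenotype_importance_is_class_sum(self):
        labels = pd.Series(["Yes", "Yes", "No"], index=["s1", "s2", "s3"])
        scores = pd.DataFrame([[0.1, 0.3, 0.9]], index=["g1"],
                              columns=["s1", "s2", "s3"])
        res = rank_and_readd(self._result_with_cube(scores, labels), None, top_t=5)
        imp = res.ranking.set_index("feature")["importance"]
        assert imp["g1"] == pytest.approx(0.4)  # s3 is not in class Yes

    def test_top_one_is_argmax_plus_group_members(self):
        labels = pd.Series(["Yes", "Yes"], index=["s1", "s2"])
        scores = pd.DataFrame([[0.1, 0.1], [0.4, 0.4]], index=["g1", "g2"],
                              columns=["s1", "s2"])
        groups = CorrelationGroups(groups={"g2": ["g7", "g8"], "g1": []},
                                   scores={})
        res = rank_and_readd(self._result_with_cube(scores, labels), groups, top_t=1)
        assert list(res.ranking["feature"]) == ["g2", "g7", "g8"]
        added = res.ranking[res.ranking["origin"] == "correlated-added"]
        assert added["importance"].tolist() == pytest.approx([0.8, 0.8])

    def test_empty_gated_set_gives_empty_ranking(self):
        labels = pd.Series(["Yes", "No"], index=["s1", "s2"])
        scores = pd.DataFrame([[0.1, 0.1]], index=["g1"], columns=["s1", "s2"])
        res = self._result_with_cube(scores, labels)
        res.gated_classes = []
        assert rank_and_readd(res, None).ranking.empty


class TestStrainAccuracyReport:
    def test_flipped_label_sample_ranks_last(self):
        rng = np.random.default_rng(4)
        fm, pt, _ = gen_panel(n_samples=20, n_features=10, n_causal=3,
                              operon_block=None, flip_noise=0.0,
                              class_sizes=(8, 12), rng=rng)
        labels = pt.experiment("exp1").copy()
        labels.iloc[0] = "No"  # planted outlier: Yes genotype, No label
        cfg = PipelineConfig(n_trees=60, cover_l=3, bag_mode="none").validate()
        res = iterate_selection(fm.values, labels, cfg, rng)
        report = strain_accuracy_report(res)
        assert report.iloc[-1]["sample"] == labels.index[0]
        assert report["accuracy"].is_monotonic_decreasing

    def test_empty_result_still_reports(self):
        res = SelectionResult(experiment="e", gated_classes=[],
                              ranking=pd.DataFrame(), trace=[], cube=None,
                              class_accuracy=pd.Series(dtype=float),
                              bag_mode="none")
        report = strain_accuracy_report(res)
        assert list(report.columns) == ["sample", "label", "n_correct",
                                        "n_incorrect", "accuracy"]
        assert report.empty


class TestImbalanceBenefit:
    def test_multiple_covering_helps_minority_class(self):
        """With 6-vs-36 classes and a noisy minority marker, the minority's
        OOB accuracy under multiple-covering bagging is at least as high as
        without bagging (mean over 20 seeds)."""
        bagged, plain = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = imbalanced_labels(6, 36)
            X = (rng.random((42, 40)) < 0.5).astype(float)
            marker = (labels == "Yes").astype(float).to_numpy()
            flip = rng.random(42) < 0.15
            marker[flip] = 1 - marker[flip]
            X[:, 0] = marker
            values = pd.DataFrame(X, index=labels.index,
                                  columns=[f"g{j}" for j in range(40)])

            plan = plan_bags(labels, cover_l=5, rng=rng)
            cubes = []
            for bag in plan.bags:
                sub = values.loc[bag]
                forest = fit_forest_bag(sub, labels, n_trees=40, rng=rng)
                cubes.append(casewise_cube(forest, sub, labels, rng))
            bagged.append(class_accuracy(aggregate_bags(cubes))["Yes"])

            forest = fit_forest_bag(values, labels, n_trees=40, rng=rng)
            cube = casewise_cube(forest, values, labels, rng)
            plain.append(class_accuracy(aggregate_bags([cube]))["Yes"])
        assert np.mean(bagged) >= np.mean(plain)
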