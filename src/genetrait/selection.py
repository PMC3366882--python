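"""Iterative Random-Forest feature selection.

One elimination round = m independent repeats of {bag plan -> per-bag forest
-> casewise scores -> bag averaging}; a feature survives the round only if in
every repeat it shows positive casewise scores for enough samples of a single
class.  Rounds repeat on the shrinking feature set until fewer than ``r_stop``
features are removed.  Classes classified below the accuracy gate are then
dropped, the remaining features are ranked per class by phenotype importance
(the sum of casewise scores over that class's samples), the top ``t`` are
reported, and members of collapsed correlation groups are re-added with their
representative's importance so that co-inherited genes are not lost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .balancing import plan_bags, plan_downsized_bags
from .datatypes import (ContributionCube, CorrelationGroups, PipelineConfig,
                        SelectionResult, ValidationError)
from .forest import casewise_cube, fit_forest_bag


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_bags(cubes: list[ContributionCube]) -> ContributionCube:
    """Average casewise scores and errors over bags.

    A sample's scores/votes are averaged only over the bags that contain it;
    vote tallies are summed.  A single bag aggregates to itself.
    """
    if not cubes:
        raise ValidationError("nothing to aggregate")
    if len(cubes) == 1:
        return cubes[0]
    features = cubes[0].feature_ids
    samples = list(dict.fromkeys(s for c in cubes for s in c.sample_ids))
    labels = pd.concat([c.labels for c in cubes]).groupby(level=0).first().reindex(samples)
    classes = sorted({cl for c in cubes for cl in c.vote_fractions.columns})

    score_sum = pd.DataFrame(0.0, index=features, columns=samples)
    score_n = pd.DataFrame(0, index=features, columns=samples)
    frac_sum = pd.DataFrame(0.0, index=samples, columns=classes)
    frac_n = pd.DataFrame(0, index=samples, columns=classes)
    tallies = pd.DataFrame(0, index=samples, columns=["n_correct", "n_incorrect"])
    for c in cubes:
        s = c.scores
        ok = s.notna()
        score_sum.loc[s.index, s.columns] += s.fillna(0.0)
        score_n.loc[s.index, s.columns] += ok.astype(int)
        f = c.vote_fractions
        okf = f.notna()
        frac_sum.loc[f.index, f.columns] += f.fillna(0.0)
        frac_n.loc[f.index, f.columns] += okf.astype(int)
        tallies.loc[c.vote_tallies.index] += c.vote_tallies
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = score_sum / score_n.replace(0, np.nan)
        fracs = frac_sum / frac_n.replace(0, np.nan)
    errors = pd.concat([c.class_errors for c in cubes], axis=1).mean(axis=1)
    return ContributionCube(scores=scores, class_errors=errors,
                            vote_fractions=fracs, vote_tallies=tallies,
                            labels=labels)


# ---------------------------------------------------------------------------
# Stability criterion
# ---------------------------------------------------------------------------

def _run_supported(cube: ContributionCube, min_support_strains: int,
                   support_fraction: float | None) -> pd.Series:
    """Boolean per feature: positive scores for enough samples of one class."""
    labels = cube.labels.loc[cube.sample_ids]
    pos = cube.scores.gt(0)
    supported = pd.Series(False, index=cube.feature_ids)
    for cls in labels.dropna().unique():
        cls_samples = labels.index[labels == cls]
        need = int(min_support_strains)
        if support_fraction is not None:
            need = max(need, int(np.ceil(support_fraction * len(cls_samples))))
        supported |= pos[cls_samples].sum(axis=1) >= need
    return supported


def stable_feature_set(cubes: list[ContributionCube],
                       min_support_strains: int = 3,
                       support_fraction: float | None = None,
                       rule: str = "all-runs") -> tuple[list[str], list[str]]:
    """Split features into (kept, discarded) across ``m`` repeated runs.

    A feature is kept iff it is supported (positive casewise scores for at
    least ``min_support_strains`` samples of some single class, optionally
    at least ``support_fraction`` of that class) consistently, i.e. in every
    run; rule "any-run" relaxes this to at least one run.
    """
    if not cubes:
        raise ValidationError("need at least one run")
    per_run = [_run_supported(c, min_support_strains, support_fraction) for c in cubes]
    table = pd.concat(per_run, axis=1)
    keep = table.all(axis=1) if rule == "all-runs" else table.any(axis=1)
    features = cubes[0].feature_ids
    return ([f for f in features if keep[f]], [f for f in features if not keep[f]])


# ---------------------------------------------------------------------------
# Iteration
# ---------------------------------------------------------------------------

def _one_run(values: pd.DataFrame, labels: pd.Series, config: PipelineConfig,
             rng) -> ContributionCube:
    if config.bag_mode == "multiple-downsizing":
        plan = plan_downsized_bags(labels, n_bags=config.cover_l,
                                   k_min_class=config.k_min_class, rng=rng)
    elif config.bag_mode == "none":
        from .datatypes import BagPlan
        plan = BagPlan(bags=[list(labels.index)], labels=labels, mode="none")
    else:
        plan = plan_bags(labels, cover_l=config.cover_l,
                         bag_multiplier=config.bag_multiplier,
                         k_min_class=config.k_min_class, rng=rng)
    bag_cubes = []
    for bag in plan.bags:
        sub = values.loc[bag]
        forest = fit_forest_bag(sub, labels, n_trees=config.n_trees, rng=rng)
        bag_cubes.append(casewise_cube(forest, sub, labels, rng))
    cube = aggregate_bags(bag_cubes)
    cube.bag_mode = plan.mode
    return cube


def iterate_selection(values: pd.DataFrame, labels: pd.Series,
                      config: PipelineConfig, rng,
                      experiment: str = "experiment") -> SelectionResult:
    """Run elimination rounds until fewer than r_stop features are removed.

    Returns a pre-gating SelectionResult whose cube averages the final
    round's m runs over the surviving features; ranking is filled in by
    :func:`rank_and_readd`.
    """
    current = list(values.columns)
    trace: list[dict] = []
    final_cubes: list[ContributionCube] | None = None
    bag_mode = "none"
    while current:
        sub = values[current]
        run_cubes = [_one_run(sub, labels, config, rng) for _ in range(config.m_runs)]
        bag_mode = getattr(run_cubes[0], "bag_mode", "none")
        kept, _ = stable_feature_set(run_cubes, config.min_support_strains,
                                     config.support_fraction)
        removed = len(current) - len(kept)
        trace.append({"round": len(trace) + 1, "n_features_in": len(current),
                      "n_removed": removed, "n_kept": len(kept)})
        final_cubes = run_cubes
        current = kept
        if removed < config.r_stop:
            break
    if not current or final_cubes is None:
        return SelectionResult(experiment=experiment, gated_classes=[],
                               ranking=_empty_ranking(), trace=trace, cube=None,
                               class_accuracy=pd.Series(dtype=float),
                               bag_mode=bag_mode)
    cube = aggregate_runs(final_cubes, features=current)
    accuracy = class_accuracy(cube)
    return SelectionResult(experiment=experiment, gated_classes=[],
                           ranking=_empty_ranking(), trace=trace, cube=cube,
                           class_accuracy=accuracy, bag_mode=bag_mode)


def aggregate_runs(cubes: list[ContributionCube],
                   features: list[str] | None = None) -> ContributionCube:
    """Average the m runs of one round (same samples, same features)."""
    agg = aggregate_bags(cubes) if len(cubes) > 1 else cubes[0]
    if features is not None:
        agg = ContributionCube(scores=agg.scores.loc[features],
                               class_errors=agg.class_errors,
                               vote_fractions=agg.vote_fractions,
                               vote_tallies=agg.vote_tallies,
                               labels=agg.labels)
    return agg


def _empty_ranking() -> pd.DataFrame:
    return pd.DataFrame(columns=["class", "feature", "importance", "origin"])


# ---------------------------------------------------------------------------
# Gating, ranking, re-adding
# ---------------------------------------------------------------------------

def class_accuracy(cube: ContributionCube) -> pd.Series:
    """Fraction of each class correctly classified by the majority of the
    bag-averaged out-of-bag vote fractions (ties -> misclassified)."""
    frac = cube.vote_fractions
    labels = cube.labels.loc[frac.index]
    out = {}
    for cls in sorted(labels.dropna().unique()):
        samples = labels.index[labels == cls]
        correct = 0
        for s in samples:
            row = frac.loc[s]
            if row.isna().all():
                continue
            top = row.index[row == row.max()]
            if len(top) == 1 and top[0] == cls:
                correct += 1
        out[cls] = correct / len(samples) if len(samples) else np.nan
    return pd.Series(out, dtype=float)


def gate_classes(result: SelectionResult, accuracy_gate: float = 0.60) -> list[str]:
    """Classes whose accuracy reaches the gate (boundary inclusive)."""
    acc = result.class_accuracy
    gated = [c for c in acc.index if acc[c] >= accuracy_gate]
    result.gated_classes = gated
    return gated


def rank_and_readd(result: SelectionResult, groups: CorrelationGroups | None,
                   top_t: int = 50) -> SelectionResult:
    """Per gated class: rank by phenotype importance, keep the top t, and
    append collapsed group members with their representative's importance."""
    if result.cube is None or not result.gated_classes:
        result.ranking = _empty_ranking()
        return result
    cube = result.cube
    labels = cube.labels
    rows = []
    for cls in result.gated_classes:
        samples = [s for s in cube.sample_ids if labels.get(s) == cls]
        imp = cube.scores[samples].sum(axis=1, skipna=True)
        top = imp.sort_values(ascending=False, kind="stable").head(int(top_t))
        for feat, value in top.items():
            rows.append({"class": cls, "feature": feat, "importance": float(value),
                         "origin": "selected"})
            if groups is not None:
                for member in groups.members_of(feat):
                    rows.append({"class": cls, "feature": member,
                                 "importance": float(value),
                                 "origin": "correlated-added"})
    result.ranking = pd.DataFrame(rows, columns=["class", "feature", "importance", "origin"])
    return result


def strain_accuracy_report(result: SelectionResult) -> pd.DataFrame:
    """Per-sample classification tallies across bags and runs, best first.

    Useful for spotting outliers: a consistently misclassified sample often
    has a wrong or ambiguous phenotype, or belongs to a minority class.
    """
    if result.cube is None:
        return pd.DataFrame(columns=["sample", "label", "n_correct",
                                     "n_incorrect", "accuracy"])
    t = result.cube.vote_tallies
    total = (t["n_correct"] + t["n_incorrect"]).replace(0, np.nan)
    report = pd.DataFrame({
        "sample": t.index,
        "label": result.cube.labels.loc[t.index].to_numpy(),
        "n_correct": t["n_correct"].to_numpy(),
        "n_incorrect": t["n_incorrect"].to_numpy(),
        "accuracy": (t["n_correct"] / total).to_numpy(),
    })
    return report.sort_values(["accuracy", "sample"], ascending=[False, True],
                              na_position="last").reset_index(drop=True)
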