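"""Core containers for gene-trait matching.

The two primary inputs are a feature matrix (samples x features, binary gene
presence/absence or continuous ~omics values) and a phenotype table (samples x
experiments, categorical labels such as "Yes"/"No"/"Maybe").  Both wrap a
:class:`pandas.DataFrame` and validate the invariants every downstream stage
relies on: unique ids, matching shapes, numeric values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureMatrix",
    "PhenotypeTable",
    "PipelineConfig",
    "CorrelationGroups",
    "BagPlan",
    "ContributionCube",
    "SelectionResult",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {', '.join(dups[:5])}")
    return ids


class FeatureMatrix:
    """Samples x features numeric matrix (the ~omics side of the association).

    Values may be binary {0,1} (gene presence/absence) or continuous; missing
    entries are held as NaN until imputation.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (samples x features)")
        _check_unique(values.index, "sample")
        _check_unique(values.columns, "feature")
        df = values.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric cell in feature matrix: {exc}") from exc
        self.values = df

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def is_binary(self) -> bool:
        v = self.values.to_numpy()
        v = v[~np.isnan(v)]
        return bool(np.isin(v, (0.0, 1.0)).all())

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy())

    def subset(self, samples=None, features=None) -> "FeatureMatrix":
        df = self.values
        if samples is not None:
            df = df.loc[list(samples)]
        if features is not None:
            df = df[list(features)]
        return FeatureMatrix(df.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "binary" if self.is_binary() else "continuous"
        return f"<FeatureMatrix {self.n_samples} samples x {self.n_features} features ({kind})>"


class PhenotypeTable:
    """Samples x experiments categorical labels, with declared ambiguous labels.

    Labels are kept verbatim; an "ambiguous" label (default ``{"Maybe"}``)
    marks phenotypes that were only weakly expressed or possibly mis-scored.
    Dropping those samples is a downstream, per-experiment choice, not a parse
    step.
    """

    def __init__(self, labels: pd.DataFrame, ambiguous_labels: Iterable[str] = ("Maybe",)):
        if not isinstance(labels, pd.DataFrame):
            raise TypeError("labels must be a pandas DataFrame (samples x experiments)")
        _check_unique(labels.index, "sample")
        _check_unique(labels.columns, "experiment")
        df = labels.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        # Missing stays NaN; everything else becomes str.
        df = df.where(df.isna(), df.astype(str))
        self.labels = df
        self.ambiguous_labels = frozenset(str(a) for a in ambiguous_labels)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.labels.columns)

    def experiment(self, name: str, drop_missing: bool = True,
                   drop_ambiguous: bool = False) -> pd.Series:
        """Per-sample labels for one experiment, optionally cleaned."""
        s = self.labels[name]
        if drop_missing:
            s = s.dropna()
        if drop_ambiguous:
            s = s[~s.isin(self.ambiguous_labels)]
        return s

    def class_counts(self, name: str, drop_ambiguous: bool = False) -> dict[str, int]:
        s = self.experiment(name, drop_ambiguous=drop_ambiguous)
        return s.value_counts().to_dict()

    def mismatched_samples(self, fm: FeatureMatrix) -> dict[str, set[str]]:
        """Sample ids present in exactly one of the two tables, by side."""
        mine, theirs = set(self.sample_ids), set(fm.sample_ids)
        return {"phenotype_only": mine - theirs, "features_only": theirs - mine}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<PhenotypeTable {len(self.sample_ids)} samples x "
                f"{len(self.experiment_ids)} experiments>")


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline, with shipped defaults.

    variance_min
        Minimum per-feature (population) variance; binary features with a
        minority pattern rarer than this are treated as homogeneous noise.
    pearson_cut / spearman_cut
        Absolute correlation above which two features are collapsed into one
        group (co-inherited, e.g. one operon).
    k_min_class
        Minimum samples per phenotype class for an experiment to be usable.
    cover_l
        Multiple-covering bagging: every dominant-class sample must appear in
        at least this many bags.
    bag_multiplier
        Per-bag cap on (other class size) / (smallest class size).
    m_runs
        Repeat classifications per elimination round; a feature must show
        support in every run to be kept.
    r_stop
        Stop iterating once a round removes fewer than this many features.
    min_support_strains
        Minimum samples of one class with positive casewise scores for a
        feature to count as supported.
    support_fraction
        Optional alternative to min_support_strains: a fraction of the class
        size (guards against chance support in large classes).
    accuracy_gate
        Minimum fraction of a class correctly classified (out-of-bag majority
        vote) for that class to be reported, boundary inclusive.
    top_t
        Number of top-ranked features reported per gated class (before
        correlated-group members are re-added).
    presence_cut
        "Sufficiently present/absent" threshold for the relation categories.
    n_bins
        Equal-width bins used to categorize continuous phenotype measurements.
    omics_cutoff
        Binarization cutoff for continuous ~omics values; "midrange" uses
        (max+min)/2 of the whole matrix.
    fdr_alpha
        Benjamini-Hochberg threshold for the correlation baseline.
    n_trees
        Trees per Random-Forest ensemble (per bag).
    """

    variance_min: float = 0.05
    pearson_cut: float = 0.98
    spearman_cut: float = 0.95
    k_min_class: int = 4
    cover_l: int = 10
    bag_multiplier: int = 2
    m_runs: int = 3
    r_stop: int = 5
    min_support_strains: int = 3
    support_fraction: float | None = None
    accuracy_gate: float = 0.60
    top_t: int = 50
    presence_cut: float = 0.75
    n_bins: int = 3
    omics_cutoff: object = "midrange"
    fdr_alpha: float = 0.05
    n_trees: int = 200
    rng_seed: int = 0
    drop_ambiguous: bool = True
    bag_mode: str = "multiple-covering"
    impute_method: str = "proximity"

    def validate(self) -> "PipelineConfig":
        fracs = {
            "variance_min": self.variance_min,
            "pearson_cut": self.pearson_cut,
            "spearman_cut": self.spearman_cut,
            "accuracy_gate": self.accuracy_gate,
            "presence_cut": self.presence_cut,
            "fdr_alpha": self.fdr_alpha,
        }
        for name, v in fracs.items():
            if not (0.0 <= float(v) <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        counts = {
            "k_min_class": self.k_min_class,
            "cover_l": self.cover_l,
            "bag_multiplier": self.bag_multiplier,
            "m_runs": self.m_runs,
            "r_stop": self.r_stop,
            "min_support_strains": self.min_support_strains,
            "top_t": self.top_t,
            "n_bins": self.n_bins,
            "n_trees": self.n_trees,
        }
        for name, v in counts.items():
            if int(v) != v or int(v) <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v}")
        if self.support_fraction is not None and not (0.0 < self.support_fraction <= 1.0):
            raise ValidationError("support_fraction must be in (0,1]")
        if self.bag_mode not in ("multiple-covering", "multiple-downsizing", "none"):
            raise ValidationError(f"unknown bag_mode {self.bag_mode!r}")
        if self.omics_cutoff != "midrange" and not isinstance(self.omics_cutoff, (int, float)):
            raise ValidationError("omics_cutoff must be 'midrange' or a number")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw).validate()


@dataclass
class CorrelationGroups:
    """Outcome of collapsing highly correlated features.

    ``groups`` maps each retained representative to the members collapsed
    under it; ``scores`` records (pearson, spearman) for each collapsed pair.
    Representatives and members are disjoint sets.
    """

    groups: dict[str, list[str]] = field(default_factory=dict)
    scores: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @property
    def representatives(self) -> list[str]:
        return list(self.groups)

    @property
    def members(self) -> list[str]:
        return [m for ms in self.groups.values() for m in ms]

    def members_of(self, rep: str) -> list[str]:
        return list(self.groups.get(rep, []))

    def all_features(self) -> list[str]:
        return self.representatives + self.members

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep, members in self.groups.items():
            for m in members:
                r, rho = self.scores.get((rep, m), (np.nan, np.nan))
                rows.append({"representative": rep, "member": m,
                             "pearson": r, "spearman": rho})
        return pd.DataFrame(rows, columns=["representative", "member", "pearson", "spearman"])


@dataclass
class BagPlan:
    """Sample bags produced by the imbalance correction.

    mode is one of "multiple-covering", "multiple-downsizing" or "none"
    (single bag of all samples when classes are already balanced).
    """

    bags: list[list[str]]
    labels: pd.Series  # sample id -> class label
    mode: str

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    @property
    def usage_count(self) -> pd.Series:
        counts = pd.Series(0, index=self.labels.index, dtype=int)
        for bag in self.bags:
            counts[bag] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [{"bag": i, "sample": s, "label": self.labels[s]}
                for i, bag in enumerate(self.bags) for s in bag]
        return pd.DataFrame(rows, columns=["bag", "sample", "label"])


@dataclass
class ContributionCube:
    """Casewise (local) importance scores and classification bookkeeping.

    scores: features x samples DataFrame; entry (f, s) is the mean, over trees
    for which s was out-of-bag, of [votes for s's true class with f intact] -
    [votes for the true class with f permuted among out-of-bag samples].  NaN
    marks samples never out-of-bag (undefined, not zero).
    """

    scores: pd.DataFrame                 # features x samples
    class_errors: pd.Series              # class -> error fraction in [0,1]
    vote_fractions: pd.DataFrame         # samples x classes (OOB vote shares)
    vote_tallies: pd.DataFrame           # samples x [n_correct, n_incorrect]
    labels: pd.Series                    # sample -> true class

    @property
    def feature_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class SelectionResult:
    """Per-experiment outcome of iterative Random-Forest feature selection."""

    experiment: str
    gated_classes: list[str]
    ranking: pd.DataFrame        # columns: class, feature, importance, origin
    trace: list[dict]            # one dict per elimination round
    cube: ContributionCube | None
    class_accuracy: pd.Series    # class -> fraction correctly classified
    bag_mode: str

    @property
    def kept_features(self) -> list[str]:
        if self.ranking.empty:
            return []
        return list(pd.unique(self.ranking["feature"]))
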