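"""Model/Results interface over the gene-trait matching pipeline.

:class:`GeneTraitModel` holds a feature matrix, a phenotype table and a
configuration; :meth:`GeneTraitModel.fit` runs preprocessing, per-experiment
imbalance-corrected Random-Forest selection and relation categorization, and
returns a :class:`GeneTraitResults` carrying the rankings, accuracies,
iteration traces and the relation matrix, with ``summary()`` and ``save()``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (FeatureMatrix, PhenotypeTable, PipelineConfig,
                        SelectionResult, ValidationError)
from .io import (read_feature_matrix, read_phenotype_table, write_tsv)
from .preprocess import (bin_phenotype, binarize_omics, collapse_correlated,
                         filter_experiments, impute_missing, remove_homogeneous)
from .relations import build_relation_matrix, render_outputs, strain_grid
from .selection import (gate_classes, iterate_selection, rank_and_readd,
                        strain_accuracy_report)


class GeneTraitModel:
    """Associates feature presence/absence patterns with phenotype classes.

    Parameters
    ----------
    features
        Samples x features matrix; binary panels are used as-is, continuous
        matrices are binarized at ``config.omics_cutoff`` for visualization
        and classification.
    phenotypes
        Samples x experiments categorical labels.
    config
        Pipeline settings; defaults are the shipped ones.
    """

    def __init__(self, features: FeatureMatrix, phenotypes: PhenotypeTable,
                 config: PipelineConfig | None = None):
        self.features = features
        self.phenotypes = phenotypes
        self.config = (config or PipelineConfig()).validate()
        common = [s for s in features.sample_ids if s in set(phenotypes.sample_ids)]
        if len(common) < 2 * self.config.k_min_class:
            raise ValidationError(
                f"only {len(common)} samples shared between feature matrix and "
                f"phenotype table; need at least {2 * self.config.k_min_class}")
        self._common_samples = common

    def _binned_phenotypes(self) -> PhenotypeTable:
        """Classification needs categories: a phenotype column whose labels
        are all numeric with more distinct values than n_bins is grouped
        into equal-width bins; everything else passes through verbatim."""
        cfg = self.config
        cols = {}
        for exp in self.phenotypes.experiment_ids:
            col = self.phenotypes.labels[exp]
            obs = col.dropna()
            numeric = pd.to_numeric(obs, errors="coerce")
            if len(obs) and numeric.notna().all() and numeric.nunique() > cfg.n_bins:
                binned = bin_phenotype(numeric, cfg.n_bins)
                col = col.copy()
                col.loc[binned.index] = binned
            cols[exp] = col
        return PhenotypeTable(pd.DataFrame(cols),
                              ambiguous_labels=self.phenotypes.ambiguous_labels)

    @classmethod
    def from_files(cls, feature_path, phenotype_path, config: PipelineConfig | None = None,
                   orientation: str = "samples_in_rows",
                   ambiguous_labels=("Maybe",)) -> "GeneTraitModel":
        fm = read_feature_matrix(feature_path, orientation=orientation)
        pt = read_phenotype_table(phenotype_path, ambiguous_labels=ambiguous_labels)
        return cls(fm, pt, config)

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "GeneTraitResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)

        fm = self.features.subset(samples=self._common_samples)
        if fm.has_missing():
            fm = impute_missing(fm, cfg, rng=rng)
        if not fm.is_binary():
            fm = binarize_omics(fm, cfg.omics_cutoff)
        fm_full = fm  # pre-collapse matrix: used for presence fractions
        fm, removed = remove_homogeneous(fm, cfg.variance_min)
        fm, groups = collapse_correlated(fm, cfg.pearson_cut, cfg.spearman_cut)

        phenotypes = self._binned_phenotypes()
        usability = filter_experiments(phenotypes, cfg.k_min_class,
                                       drop_ambiguous=cfg.drop_ambiguous)
        usable = list(usability.loc[usability["usable"], "experiment"])

        results: dict[str, SelectionResult] = {}
        labels_by_exp: dict[str, pd.Series] = {}
        for exp in usable:
            labels = phenotypes.experiment(exp, drop_ambiguous=cfg.drop_ambiguous)
            labels = labels[labels.index.isin(fm.values.index)]
            counts = labels.value_counts()
            labels = labels[labels.map(counts) >= cfg.k_min_class]
            res = iterate_selection(fm.values.loc[labels.index], labels, cfg,
                                    rng, experiment=exp)
            gate_classes(res, cfg.accuracy_gate)
            rank_and_readd(res, groups, cfg.top_t)
            results[exp] = res
            labels_by_exp[exp] = labels

        relations = build_relation_matrix(results, fm_full, labels_by_exp,
                                          cfg.presence_cut)
        return GeneTraitResults(model=self, preprocessed=fm, full_matrix=fm_full,
                                removed_features=removed, groups=groups,
                                usability=usability, experiments=results,
                                labels_by_experiment=labels_by_exp,
                                relations=relations,
                                seed=cfg.rng_seed if seed is None else seed)


class GeneTraitResults:
    """Fitted gene-trait associations with diagnostics and writers."""

    def __init__(self, model, preprocessed, full_matrix, removed_features,
                 groups, usability, experiments, labels_by_experiment,
                 relations, seed):
        self.model = model
        self.preprocessed = preprocessed
        self.full_matrix = full_matrix
        self.removed_features = removed_features
        self.groups = groups
        self.usability = usability
        self.experiments = experiments
        self.labels_by_experiment = labels_by_experiment
        self.relations = relations
        self.seed = seed

    # -- summaries -----------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        lines = []
        lines.append("Gene-trait matching results")
        lines.append("=" * 60)
        lines.append(f"samples: {self.full_matrix.n_samples}    "
                     f"features: {self.model.features.n_features} -> "
                     f"{self.full_matrix.n_features - len(self.removed_features)} "
                     f"(variance filter) -> {self.preprocessed.n_features} (collapsed)")
        n_us = int(self.usability["usable"].sum())
        lines.append(f"experiments: {len(self.usability)} total, {n_us} usable "
                     f"(k_min_class={cfg.k_min_class}, "
                     f"ambiguous {'dropped' if cfg.drop_ambiguous else 'kept'})")
        lines.append(f"seed: {self.seed}    trees/bag: {cfg.n_trees}    "
                     f"bagging: {cfg.bag_mode} (l={cfg.cover_l})")
        lines.append("-" * 60)
        header = f"{'experiment':<20}{'class':<10}{'accuracy':>9}{'gated':>7}{'features':>10}"
        lines.append(header)
        for exp, res in self.experiments.items():
            for cls in res.class_accuracy.index:
                acc = res.class_accuracy[cls]
                gated = cls in res.gated_classes
                nfeat = int((res.ranking["class"] == cls).sum()) if gated else 0
                lines.append(f"{exp:<20}{cls:<10}{acc:>9.2f}{str(gated):>7}{nfeat:>10}")
            if res.cube is None:
                lines.append(f"{exp:<20}{'-':<10}{'nan':>9}{'False':>7}{0:>10}")
        lines.append("-" * 60)
        counts = self.relations["category"].value_counts() if not self.relations.empty else {}
        lines.append("relation categories: " + (", ".join(
            f"{c}={int(n)}" for c, n in sorted(dict(counts).items())) or "none"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GeneTraitResults: {len(self.experiments)} experiments, seed={self.seed}>"

    # -- persistence ---------------------------------------------------
    def save(self, out_dir) -> list[Path]:
        """Write every report artifact (TSVs, heatmap, manifest)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _w(df, name, index=False):
            p = out / name
            write_tsv(df, p, index=index)
            written.append(p)

        _w(self.usability, "experiment_usability.tsv")
        _w(self.removed_features.rename("variance").rename_axis("feature").reset_index(),
           "removed_features.tsv")
        _w(self.groups.to_frame(), "correlation_groups.tsv")

        rankings, traces, accuracies = [], [], []
        for exp, res in self.experiments.items():
            r = res.ranking.copy()
            r.insert(0, "experiment", exp)
            rankings.append(r)
            for t in res.trace:
                traces.append({"experiment": exp, **t})
            acc = strain_accuracy_report(res)
            acc.insert(0, "experiment", exp)
            accuracies.append(acc)
        _w(pd.concat(rankings, ignore_index=True) if rankings else
           pd.DataFrame(columns=["experiment", "class", "feature", "importance", "origin"]),
           "selected_features.tsv")
        _w(pd.DataFrame(traces, columns=["experiment", "round", "n_features_in",
                                         "n_removed", "n_kept"]),
           "iteration_trace.tsv")
        _w(pd.concat(accuracies, ignore_index=True) if accuracies else
           pd.DataFrame(columns=["experiment", "sample", "label", "n_correct",
                                 "n_incorrect", "accuracy"]),
           "strain_accuracy.tsv")

        if not self.relations.empty:
            grids = {exp: strain_grid(res, self.full_matrix, self.labels_by_experiment[exp])
                     for exp, res in self.experiments.items() if not res.ranking.empty}
            written += render_outputs(self.relations, out, strain_grids=grids)
        else:
            _w(self.relations, "relations.tsv")

        manifest = {"package": "genetrait", "version": __version__,
                    "seed": int(self.seed), "config": asdict(self.model.config)}
        mp = out / "run_manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written.append(mp)
        return written

    def plot_relations(self, path):
        from .relations import _heatmap
        if self.relations.empty:
            raise ValidationError("no relations to plot")
        _heatmap(self.relations, path)
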