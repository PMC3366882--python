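"""Preprocessing: imputation, homogeneous-feature removal, correlated-feature
collapsing, and categorization of continuous values.

Binary gene panels are noisy: missing calls, near-constant genes, and
co-inherited (operon) genes with near-identical presence patterns all distort
tree-ensemble importances.  Each step here removes one of those distortions
while keeping enough bookkeeping (removed ids, correlation groups) to restore
collapsed features after selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CorrelationGroups, FeatureMatrix, PhenotypeTable, ValidationError


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _initial_fill(df: pd.DataFrame) -> pd.DataFrame:
    """Mode fill for binary columns, median for continuous ones."""
    out = df.copy()
    for col in out.columns[out.isna().any()]:
        s = out[col]
        obs = s.dropna()
        vals = obs.unique()
        if set(np.unique(vals)) <= {0.0, 1.0}:
            # Mode; ties break toward the majority, then 1.
            fill = 1.0 if (obs == 1.0).sum() >= (obs == 0.0).sum() else 0.0
        else:
            fill = float(obs.median())
        out[col] = s.fillna(fill)
    return out


def forest_proximity(X: np.ndarray, y: np.ndarray, n_trees: int, rng) -> np.ndarray:
    """Pairwise sample proximities: fraction of trees in which two samples
    land in the same leaf, from a small bootstrap ensemble."""
    from .forest import BaggedForest, _apply_idx  # local import to avoid a cycle

    forest = BaggedForest(n_trees=n_trees, rng=rng)
    forest.fit(X, y)
    n = X.shape[0]
    prox = np.zeros((n, n))
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for rec in forest.trees:
        leaves = _apply_idx(rec, X32)
        same = leaves[:, None] == leaves[None, :]
        prox += same
    prox /= len(forest.trees)
    return prox


def impute_missing(fm: FeatureMatrix, config=None, labels: pd.Series | None = None,
                   method: str | None = None, n_trees: int = 50, n_iter: int = 5,
                   rng=None) -> FeatureMatrix:
    """Fill missing cells; non-missing entries are never altered.

    method "proximity" (default when labels are given) grows a forest on the
    current fill, then replaces each missing cell with the proximity-weighted
    average (continuous) or proximity-weighted majority value (binary) of the
    observed entries of that feature, iterating a few times.  Without labels,
    or with method "simple", the mode/median fill is used directly.
    """
    df = fm.values
    if not fm.has_missing():
        return fm
    empty = [c for c in df.columns if df[c].isna().all()]
    if empty:
        raise ValidationError(f"feature(s) entirely missing: {', '.join(empty[:5])}")
    if method is None:
        method = getattr(config, "impute_method", "proximity") if config is not None else "proximity"
    filled = _initial_fill(df)
    if method == "simple" or labels is None:
        return FeatureMatrix(filled)

    if rng is None:
        rng = np.random.default_rng(getattr(config, "rng_seed", 0) if config is not None else 0)
    labels = labels.loc[df.index]
    y = pd.factorize(labels)[0]
    miss = df.isna()
    for _ in range(n_iter):
        prox = forest_proximity(filled.to_numpy(), y, n_trees=n_trees, rng=rng)
        np.fill_diagonal(prox, 0.0)
        new = filled.copy()
        for col in df.columns[miss.any()]:
            observed = ~miss[col].to_numpy()
            colvals = df[col].to_numpy()
            binary = set(np.unique(colvals[observed])) <= {0.0, 1.0}
            for i in np.flatnonzero(miss[col].to_numpy()):
                w = prox[i, observed]
                if w.sum() <= 0:
                    continue  # keep current fill
                if binary:
                    score = float(w @ colvals[observed]) / w.sum()
                    new.iloc[i, new.columns.get_loc(col)] = 1.0 if score >= 0.5 else 0.0
                else:
                    new.iloc[i, new.columns.get_loc(col)] = float(w @ colvals[observed]) / w.sum()
        if new.equals(filled):
            break
        filled = new
    return FeatureMatrix(filled)


# ---------------------------------------------------------------------------
# Homogeneous features
# ---------------------------------------------------------------------------

def feature_variances(fm: FeatureMatrix) -> pd.Series:
    """Population variance per feature (for binary features this is p(1-p))."""
    return fm.values.var(axis=0, ddof=0)


def remove_homogeneous(fm: FeatureMatrix, variance_min: float = 0.05
                       ) -> tuple[FeatureMatrix, pd.Series]:
    """Drop features whose population variance falls below ``variance_min``.

    With 42 samples this removes every binary feature whose minority value
    occurs in at most two samples.  Returns the filtered matrix and the
    variances of the removed features.
    """
    if fm.has_missing():
        raise ValidationError("impute missing values before the variance filter")
    var = feature_variances(fm)
    keep = var >= variance_min
    if not keep.any():
        raise ValidationError("no informative features: all fall below the variance cutoff")
    removed = var[~keep]
    return fm.subset(features=var.index[keep]), removed


# ---------------------------------------------------------------------------
# Correlated features
# ---------------------------------------------------------------------------

def _abs_corr_matrices(values: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.abs(np.corrcoef(X, rowvar=False))
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        spearman = np.abs(np.corrcoef(ranks, rowvar=False))
    return pearson, spearman


def collapse_correlated(fm: FeatureMatrix, pearson_cut: float = 0.98,
                        spearman_cut: float = 0.95
                        ) -> tuple[FeatureMatrix, CorrelationGroups]:
    """Keep one representative per group of (near-)identical features.

    Greedy in input feature order: the first unclaimed feature becomes a
    representative; every later feature whose |Pearson r| >= pearson_cut or
    |Spearman rho| >= spearman_cut with an existing representative joins the
    earliest such representative.  Anti-correlated duplicates are collapsed
    too (absolute values), since they induce the same tree splits.
    """
    if fm.has_missing():
        raise ValidationError("impute missing values before collapsing correlated features")
    feats = fm.feature_ids
    pearson, spearman = _abs_corr_matrices(fm.values)
    hit = (pearson >= pearson_cut) | (spearman >= spearman_cut)
    reps: list[int] = []
    groups: dict[str, list[str]] = {}
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for j in range(len(feats)):
        owner = next((r for r in reps if hit[r, j]), None)
        if owner is None:
            reps.append(j)
            groups[feats[j]] = []
        else:
            groups[feats[owner]].append(feats[j])
            scores[(feats[owner], feats[j])] = (float(pearson[owner, j]),
                                                float(spearman[owner, j]))
    cg = CorrelationGroups(groups=groups, scores=scores)
    return fm.subset(features=[feats[r] for r in reps]), cg


# ---------------------------------------------------------------------------
# Categorization of continuous values
# ---------------------------------------------------------------------------

def binarize_omics(fm: FeatureMatrix, cutoff="midrange") -> FeatureMatrix:
    """Map continuous ~omics values to presence/absence.

    Values >= cutoff become 1 (present), values below become 0.  cutoff
    "midrange" uses (max+min)/2 of the whole matrix.
    """
    vals = fm.values
    if cutoff == "midrange":
        lo, hi = float(vals.min().min()), float(vals.max().max())
        if lo == hi:
            raise ValidationError("constant matrix: midrange cutoff is undefined")
        cut = (hi + lo) / 2.0
    else:
        cut = float(cutoff)
    return FeatureMatrix((vals >= cut).astype(float))


def bin_phenotype(values: pd.Series, n_bins: int = 3) -> pd.Series:
    """Equal-width binning of a continuous phenotype into labels bin1..binK.

    Bin edges span [min, max]; the maximum is assigned to the top bin.
    Non-numeric input is assumed already categorical and passed through.
    """
    try:
        numeric = values.astype(float)
    except (TypeError, ValueError):
        return values.astype(str)
    n_bins = int(n_bins)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if numeric.nunique() < n_bins:
        raise ValidationError(
            f"only {numeric.nunique()} distinct values for {n_bins} bins; lower n_bins")
    lo, hi = float(numeric.min()), float(numeric.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(numeric.to_numpy(), edges[1:-1], right=False), 0, n_bins - 1)
    return pd.Series([f"bin{i + 1}" for i in idx], index=values.index)


# ---------------------------------------------------------------------------
# Experiment usability
# ---------------------------------------------------------------------------

def filter_experiments(pt: PhenotypeTable, k_min_class: int = 4,
                       drop_ambiguous: bool = True) -> pd.DataFrame:
    """Decide which experiments can support an association analysis.

    An experiment is usable iff, after optional removal of ambiguous-label
    samples, at least two classes each hold at least ``k_min_class`` samples.
    Returns one row per experiment with the class counts and, for unusable
    experiments, the reason.
    """
    rows = []
    for exp in pt.experiment_ids:
        counts = pt.class_counts(exp, drop_ambiguous=drop_ambiguous)
        big = {c: n for c, n in counts.items() if n >= k_min_class}
        if len(counts) == 0:
            usable, reason = False, "no labelled samples"
        elif len(counts) < 2:
            usable, reason = False, "all samples share one phenotype"
        elif len(big) < 2:
            usable, reason = False, (f"fewer than 2 classes with >= {k_min_class} samples")
        else:
            usable, reason = True, ""
        rows.append({
            "experiment": exp,
            "usable": usable,
            "reason": reason,
            "class_counts": ";".join(f"{c}:{n}" for c, n in sorted(counts.items())),
            "n_samples": int(sum(counts.values())),
        })
    return pd.DataFrame(rows, columns=["experiment", "usable", "reason",
                                       "class_counts", "n_samples"])


def usable_experiments(pt: PhenotypeTable, k_min_class: int = 4,
                       drop_ambiguous: bool = True) -> list[str]:
    report = filter_experiments(pt, k_min_class=k_min_class, drop_ambiguous=drop_ambiguous)
    return list(report.loc[report["usable"], "experiment"])
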