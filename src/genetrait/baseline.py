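"""Correlation-based feature screen (the conventional comparison method).

Per feature, Pearson and Spearman correlations against a numeric encoding of
the phenotype, two-sided p-values, Benjamini-Hochberg adjustment, and
selection at an FDR threshold.  Global correlation cannot see partial
relations (a gene that matters for only a subset of one phenotype's strains),
which is exactly where the casewise Random-Forest selection earns its keep.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureMatrix, ValidationError


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (the "fdr" method)."""
    pvals = np.asarray(pvals, dtype=float)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return p_adj


def encode_labels(labels: pd.Series) -> pd.Series:
    """Numeric encoding: 0/1 for two classes, rank codes (sorted label order)
    for more."""
    classes = sorted(labels.dropna().unique())
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes to correlate")
    mapping = {c: i for i, c in enumerate(classes)}
    return labels.map(mapping).astype(float)


def correlate_and_select(fm: FeatureMatrix, labels: pd.Series,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Feature-phenotype correlation screen with FDR control.

    Returns a long table (feature, metric, r, p, p_adj, selected, reason);
    zero-variance features are excluded from testing with a reason.  BH
    adjustment is applied per metric across the tested features; selection is
    p_adj <= alpha.
    """
    y = encode_labels(labels)
    samples = y.index.intersection(fm.values.index)
    if len(samples) < 3:
        raise ValidationError("need at least 3 samples")
    X = fm.values.loc[samples]
    y = y.loc[samples]
    rows = []
    tested: dict[str, list] = {"pearson": [], "spearman": []}
    for feat in X.columns:
        x = X[feat].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            for metric in ("pearson", "spearman"):
                rows.append({"feature": feat, "metric": metric, "r": np.nan,
                             "p": np.nan, "p_adj": np.nan, "selected": False,
                             "reason": "zero variance"})
            continue
        pr = stats.pearsonr(x, y.to_numpy())
        sr = stats.spearmanr(x, y.to_numpy())
        tested["pearson"].append((feat, float(pr.statistic), float(pr.pvalue)))
        tested["spearman"].append((feat, float(sr.statistic), float(sr.pvalue)))
    for metric, triples in tested.items():
        if not triples:
            continue
        p_adj = bh_adjust([t[2] for t in triples])
        for (feat, r, p), pa in zip(triples, p_adj):
            rows.append({"feature": feat, "metric": metric, "r": r, "p": p,
                         "p_adj": float(pa), "selected": bool(pa <= alpha),
                         "reason": ""})
    df = pd.DataFrame(rows, columns=["feature", "metric", "r", "p", "p_adj",
                                     "selected", "reason"])
    return df.sort_values(["metric", "p_adj", "feature"]).reset_index(drop=True)


def selected_features(table: pd.DataFrame, metric: str | None = None) -> set[str]:
    """Features selected by either metric (or one specific metric)."""
    sel = table[table["selected"]]
    if metric is not None:
        sel = sel[sel["metric"] == metric]
    return set(sel["feature"])
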