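"""Relation categories and their rendering.

A selected feature's presence pattern within one phenotype class is reduced
to three states -- sufficiently present (>= 75% of the class's strains),
sufficiently absent (absent in >= 75%), or partial (everything between) --
and crossed with a two-tier importance split (at the median phenotype
importance of the reported features) into six categories.  Partial relations
(black/grey) are the ones global correlation screens miss.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, SelectionResult, ValidationError
from .io import write_tsv

#: Fixed palette: bright/dark green = present, bright/dark red = absent,
#: black/grey = partial; "strong" is the bright/black tier.
PALETTE = {
    "present-strong": "#00cc00",
    "present-weak": "#006400",
    "absent-strong": "#ff0000",
    "absent-weak": "#8b0000",
    "partial-strong": "#000000",
    "partial-weak": "#808080",
}

CATEGORIES = list(PALETTE)


def categorize(presence_fraction: float, presence_cut: float = 0.75,
               importance_tier: str = "strong") -> str:
    """Total, deterministic map (presence_fraction, tier) -> category.

    Both comparisons are inclusive: fraction >= cut is present, fraction <=
    1 - cut is absent, otherwise partial.
    """
    if not (0.0 <= presence_fraction <= 1.0):
        raise ValidationError(f"presence fraction {presence_fraction} outside [0,1]")
    if importance_tier not in ("strong", "weak"):
        raise ValidationError(f"importance tier must be 'strong' or 'weak'")
    if presence_fraction >= presence_cut:
        state = "present"
    elif presence_fraction <= 1.0 - presence_cut:
        state = "absent"
    else:
        state = "partial"
    return f"{state}-{importance_tier}"


def build_relation_matrix(results: dict[str, SelectionResult], fm: FeatureMatrix,
                          labels_by_experiment: dict[str, pd.Series],
                          presence_cut: float = 0.75) -> pd.DataFrame:
    """Merge presence patterns with importances into the 6-category table.

    One row per (experiment, gated class, reported feature).  The importance
    tier splits at the median importance of the reported features within each
    experiment-class (>= median is "strong").
    """
    rows = []
    for exp, res in results.items():
        if res.ranking.empty:
            continue
        labels = labels_by_experiment[exp]
        for cls, sub in res.ranking.groupby("class", sort=True):
            class_samples = [s for s in labels.index if labels[s] == cls
                             and s in fm.values.index]
            if not class_samples:
                continue
            median_imp = float(sub["importance"].median())
            for _, row in sub.iterrows():
                feat = row["feature"]
                if feat not in fm.values.columns:
                    continue
                frac = float(fm.values.loc[class_samples, feat].mean())
                tier = "strong" if row["importance"] >= median_imp else "weak"
                rows.append({
                    "experiment": exp, "class": cls, "feature": feat,
                    "presence_fraction": frac,
                    "importance": float(row["importance"]),
                    "origin": row["origin"],
                    "category": categorize(frac, presence_cut, tier),
                })
    return pd.DataFrame(rows, columns=["experiment", "class", "feature",
                                       "presence_fraction", "importance",
                                       "origin", "category"])


def strain_grid(result: SelectionResult, fm: FeatureMatrix,
                labels: pd.Series) -> pd.DataFrame:
    """Feature x strain presence grid for one experiment, columns annotated
    with the strain's class (``sample|class``)."""
    feats = result.kept_features
    samples = [s for s in labels.index if s in fm.values.index]
    grid = fm.values.loc[samples, feats].T
    grid.columns = [f"{s}|{labels[s]}" for s in samples]
    return grid


def render_outputs(relmat: pd.DataFrame, out_dir,
                   strain_grids: dict[str, pd.DataFrame] | None = None,
                   fmt: str = "png") -> list[Path]:
    """Write the relation TSV, the 6-colour heatmap, and per-experiment
    strain grids; returns the written paths."""
    if relmat.empty:
        raise ValidationError("relation matrix is empty; nothing to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    tsv = out_dir / "relations.tsv"
    write_tsv(relmat.sort_values(["experiment", "class", "feature"]), tsv)
    written.append(tsv)

    img = out_dir / f"relations.{fmt}"
    _heatmap(relmat, img)
    written.append(img)

    for exp, grid in (strain_grids or {}).items():
        p = out_dir / f"strain_grid_{_safe(exp)}.tsv"
        write_tsv(grid, p, index=True)
        written.append(p)
    return written


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def _heatmap(relmat: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    cols = sorted({(e, c) for e, c in zip(relmat["experiment"], relmat["class"])})
    feats = sorted(relmat["feature"].unique())
    code = {cat: i for i, cat in enumerate(CATEGORIES)}
    mat = np.full((len(feats), len(cols)), np.nan)
    for _, row in relmat.iterrows():
        mat[feats.index(row["feature"]), cols.index((row["experiment"], row["class"]))] = \
            code[row["category"]]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(cols) + 2), max(3, 0.12 * len(feats) + 1)))
    cmap = ListedColormap([PALETTE[c] for c in CATEGORIES])
    masked = np.ma.masked_invalid(mat)
    cmap.set_bad("#ffffff")
    ax.imshow(masked, cmap=cmap, vmin=-0.5, vmax=len(CATEGORIES) - 0.5,
              aspect="auto", interpolation="nearest")
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels([f"{e}\n{c}" for e, c in cols], fontsize=7)
    ax.set_yticks(range(len(feats)))
    ax.set_yticklabels(feats, fontsize=5)
    ax.set_xlabel("experiment / phenotype class")
    ax.set_ylabel("feature")
    ax.legend(handles=[Patch(color=PALETTE[c], label=c) for c in CATEGORIES],
              bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=7)
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=150)
    except OSError as exc:
        raise ValidationError(f"could not write heatmap to {path}: {exc}") from exc
    finally:
        plt.close(fig)
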