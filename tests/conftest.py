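import numpy as np
import pandas as pd
import pytest

from genetrait.datatypes import FeatureMatrix, PhenotypeTable, PipelineConfig

# Class counts of the reconstructed strain-panel phenotype table (12
# experiments; "Maybe" is the ambiguous label).
PANEL_PHENOTYPE_COUNTS = {
    "D-arabitol": {"Yes": 7, "Maybe": 11, "No": 21},
    "D-melezitose": {"Yes": 34, "No": 5},
    "D-raffinose": {"Yes": 33, "Maybe": 1, "No": 5},
    "D-sorbitol": {"Yes": 35, "No": 4},
    "D-turanose": {"Yes": 32, "No": 7},
    "Glycerol": {"Maybe": 4, "No": 35},
    "K-gluconate": {"Yes": 26, "Maybe": 9, "No": 4},
    "L-Arabinose": {"Yes": 26, "Maybe": 3, "No": 10},
    "L-Rhamnose": {"Yes": 6, "Maybe": 8, "No": 25},
    "Methyl-d-glucopyranoside": {"Yes": 8, "Maybe": 1, "No": 30},
    "Methyl-d-mannopyranoside": {"Yes": 27, "Maybe": 1, "No": 12},
    "Nitrogen-dioxide": {"Yes": 6, "No": 36},
}


def phenotype_table_from_counts(counts: dict, n_samples: int = 42,
                                seed: int = 0) -> PhenotypeTable:
    """Build a samples x experiments label table realizing given class counts.

    Labels are assigned in a fixed shuffled order per experiment so columns
    are not mutually identical; samples beyond an experiment's total stay
    missing.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    data = {}
    for exp, cc in counts.items():
        labels = [lab for lab, n in cc.items() for _ in range(n)]
        order = rng.permutation(n_samples)[:len(labels)]
        col = pd.Series(np.nan, index=samples, dtype=object)
        col.iloc[np.sort(order)] = labels
        data[exp] = col
    return PhenotypeTable(pd.DataFrame(data, index=samples))


@pytest.fixture
def panel_phenotypes() -> PhenotypeTable:
    return phenotype_table_from_counts(PANEL_PHENOTYPE_COUNTS)


@pytest.fixture
def small_binary_fm() -> FeatureMatrix:
    rng = np.random.default_rng(5)
    df = pd.DataFrame((rng.random((10, 6)) < 0.5).astype(float),
                      index=[f"S{i}" for i in range(10)],
                      columns=[f"g{j}" for j in range(6)])
    return FeatureMatrix(df)


@pytest.fixture
def default_config() -> PipelineConfig:
    return PipelineConfig().validate()


def imbalanced_labels(n_yes: int = 6, n_no: int = 36) -> pd.Series:
    ids = [f"S{i + 1:02d}" for i in range(n_yes + n_no)]
    return pd.Series(["Yes"] * n_yes + ["No"] * n_no, index=ids)


# ---------------------------------------------------------------------------
# Independent oracles shared by unit and acceptance tests
# ---------------------------------------------------------------------------

def bh_stepup_bruteforce(pvals):
    """Independent BH: adj p_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (m * pvals[order] / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def casewise_bruteforce(forest, X, y, perm_seed: int):
    """Hand trace of casewise importance over a fitted ensemble.

    Walks every tree per sample with a plain recursive descent, counts
    correct votes with each used feature intact versus permuted among the
    tree's out-of-bag samples, replaying the documented permutation order
    (trees in index order, used features ascending, one permutation each).
    """
    def walk(rec, x):
        node = 0
        while rec.children_left[node] != -1:
            f, t = rec.feature[node], rec.threshold[node]
            node = rec.children_left[node] if x[f] <= t else rec.children_right[node]
        return rec.leaf_class[node]

    perm_rng = np.random.default_rng(perm_seed)
    n, p = X.shape
    delta = np.zeros((p, n))
    n_oob = np.zeros(n)
    X32 = X.astype(np.float32)
    for rec in forest.trees:
        oob = rec.oob_idx
        if oob.size == 0:
            continue
        n_oob[oob] += 1
        base_ok = {s: walk(rec, X32[s]) == y[s] for s in oob}
        for f in sorted(set(int(v) for v in rec.feature if v >= 0)):
            perm = perm_rng.permutation(len(oob))
            Xp = X32[oob].copy()
            Xp[:, f] = Xp[perm, f]
            for k, s in enumerate(oob):
                delta[f, s] += float(base_ok[s]) - float(walk(rec, Xp[k]) == y[s])
    return np.where(n_oob > 0, delta / np.where(n_oob == 0, 1, n_oob), np.nan)
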