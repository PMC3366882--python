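"""Synthetic data with the statistical structure the pipeline assumes.

Two generators: a binary gene panel with planted causal features (full and
partial penetrance), co-inherited "operon" blocks, flip noise and phenotype
imbalance; and a two-channel CGH array with a bimodal M distribution, planted
spatial gradient and dye-intensity bias.  Both are seed-deterministic and
emit a truth record so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgh import ArrayScan
from .datatypes import FeatureMatrix, PhenotypeTable, ValidationError


@dataclass
class PanelTruth:
    """Which planted features drive the phenotype, and how."""

    causal_full: list[str] = field(default_factory=list)
    causal_partial: list[str] = field(default_factory=list)
    operon_members: dict[str, list[str]] = field(default_factory=dict)
    neutral: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": f, "role": "causal_full", "group": ""} for f in self.causal_full]
        rows += [{"feature": f, "role": "causal_partial", "group": ""} for f in self.causal_partial]
        for rep, members in self.operon_members.items():
            rows += [{"feature": m, "role": "operon_member", "group": rep} for m in members]
        rows += [{"feature": f, "role": "neutral", "group": ""} for f in self.neutral]
        return pd.DataFrame(rows, columns=["feature", "role", "group"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PanelTruth":
        t = cls()
        for _, r in df.iterrows():
            if r["role"] == "causal_full":
                t.causal_full.append(r["feature"])
            elif r["role"] == "causal_partial":
                t.causal_partial.append(r["feature"])
            elif r["role"] == "operon_member":
                t.operon_members.setdefault(r["group"], []).append(r["feature"])
            else:
                t.neutral.append(r["feature"])
        return t


def gen_panel(n_samples: int = 40, n_features: int = 500, n_causal: int = 5,
              n_partial_pairs: int = 0, partial_fraction: float = 0.5,
              operon_block: tuple[int, int] | None = (0, 20),
              flip_noise: float = 0.02, class_sizes: tuple[int, int] = (6, 34),
              experiment: str = "exp1", rng=None
              ) -> tuple[FeatureMatrix, PhenotypeTable, PanelTruth]:
    """Binary gene panel with planted causal structure.

    Class "Yes" takes the first ``class_sizes[0]`` samples, "No" the rest.
    Fully causal features equal the Yes indicator (before flip noise).  Each
    partial pair (X, Y) covers the majority class: X is present in
    ``partial_fraction`` of its samples and Y in the remainder, both absent
    in the minority class, so either gene suffices for the trait and neither
    correlates strongly with it on its own.  ``operon_block=(i, k)`` clones
    causal feature i into k members that are co-inherited with it (flips hit
    the whole block together, as losing an operon loses every gene in it).
    Flip noise inverts each remaining cell independently.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if sum(class_sizes) != n_samples:
        raise ValidationError(f"class sizes {class_sizes} must sum to n_samples={n_samples}")
    n_yes, n_no = class_sizes
    if n_causal + 2 * n_partial_pairs > n_features:
        raise ValidationError("more planted features than n_features")
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    y = np.array([1] * n_yes + [0] * n_no)
    labels = pd.Series(np.where(y == 1, "Yes", "No"), index=samples)
    majority = np.flatnonzero(y == (0 if n_no >= n_yes else 1))

    truth = PanelTruth()
    cols: dict[str, np.ndarray] = {}
    flip_exempt: set[str] = set()

    for i in range(n_causal):
        name = f"causal{i + 1}"
        col = y.astype(float).copy()
        flips = rng.random(n_samples) < flip_noise
        col[flips] = 1.0 - col[flips]
        cols[name] = col
        flip_exempt.add(name)
        truth.causal_full.append(name)

    for i in range(n_partial_pairs):
        k = int(round(partial_fraction * len(majority)))
        cover = rng.permutation(majority)
        x = np.zeros(n_samples)
        x[cover[:k]] = 1.0
        z = np.zeros(n_samples)
        z[cover[k:]] = 1.0
        cols[f"partialX{i + 1}"] = x
        cols[f"partialY{i + 1}"] = z
        flip_exempt |= {f"partialX{i + 1}", f"partialY{i + 1}"}
        truth.causal_partial += [f"partialX{i + 1}", f"partialY{i + 1}"]

    if operon_block is not None:
        target_idx, block_size = operon_block
        rep = truth.causal_full[target_idx]
        members = []
        for j in range(block_size):
            name = f"operon{j + 1}"
            cols[name] = cols[rep].copy()  # co-inherited: identical pattern
            flip_exempt.add(name)
            members.append(name)
        truth.operon_members[rep] = members

    n_neutral = n_features - len(cols)
    base_p = rng.uniform(0.15, 0.85, size=n_neutral)
    for i in range(n_neutral):
        name = f"neutral{i + 1}"
        col = (rng.random(n_samples) < base_p[i]).astype(float)
        cols[name] = col
        truth.neutral.append(name)

    df = pd.DataFrame(cols, index=samples)
    noisy = [c for c in df.columns if c not in flip_exempt]
    if noisy and flip_noise > 0:
        flips = rng.random((n_samples, len(noisy))) < flip_noise
        block = df[noisy].to_numpy()
        block[flips] = 1.0 - block[flips]
        df[noisy] = block

    fm = FeatureMatrix(df)
    pt = PhenotypeTable(labels.to_frame(name=experiment))
    return fm, pt, truth


# ---------------------------------------------------------------------------
# CGH arrays
# ---------------------------------------------------------------------------

def gen_cgh(gene_truth: pd.Series | None = None, n_genes: int = 2800,
            absent_fraction: float = 0.15, probes_per_gene: int = 3,
            grid_shape: tuple[int, int] = (132, 132), gradient_amp: float = 0.6,
            dye_bias_amp: float = 0.4, noise_sd: float = 0.3,
            absent_mean: float = -3.0, rng=None
            ) -> tuple[ArrayScan, pd.Series]:
    """One synthetic two-channel CGH hybridization plus the gene truth.

    Defaults emulate a single-reference bacterial CGH platform: ~2800 genes,
    three probes per gene, every probe spotted in duplicate (~17k spots).
    Present genes draw probe M ~ N(0, noise_sd), absent genes
    M ~ N(absent_mean, noise_sd); each probe is spotted in duplicate.  A
    smooth planted spatial surface (amplitude ``gradient_amp``) is added to
    both M and A, and a smooth A-dependent dye trend (amplitude
    ``dye_bias_amp``) to M, before intensities are reconstructed from (M, A).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if gene_truth is None:
        present = rng.random(n_genes) >= absent_fraction
        gene_truth = pd.Series(present.astype(int),
                               index=[f"g{i + 1:04d}" for i in range(n_genes)])
    genes = list(gene_truth.index)
    n_spots = len(genes) * probes_per_gene * 2
    nr, nc = grid_shape
    if n_spots > nr * nc:
        raise ValidationError(f"grid {grid_shape} too small for {n_spots} spots")

    probe_ids, gene_ids, m_true, a_base = [], [], [], []
    for g in genes:
        present = bool(gene_truth[g])
        for p in range(probes_per_gene):
            pid = f"{g}_p{p + 1}"
            mu = 0.0 if present else absent_mean
            for _ in range(2):  # duplicate spots, independent noise
                probe_ids.append(pid)
                gene_ids.append(g)
                m_true.append(rng.normal(mu, noise_sd))
                a_base.append(rng.normal(11.0 if present else 9.0, 0.8))
    n = len(probe_ids)
    positions = rng.choice(nr * nc, size=n, replace=False)
    rows, cols = positions // nc, positions % nc

    # Planted biases: smooth spatial surface on M and A, dye trend on M.
    surface = gradient_amp * (np.sin(2 * np.pi * rows / nr)
                              + (cols / max(nc - 1, 1)) - 0.5)
    A = np.array(a_base) + 0.5 * surface
    dye = dye_bias_amp * np.sin(2 * np.pi * (A - A.min()) / np.ptp(A))
    M = np.array(m_true) + surface + dye

    data = pd.DataFrame({
        "probe_id": probe_ids, "gene_id": gene_ids,
        "row": rows, "col": cols,
        "i_sample": np.exp2((A + M) / 2.0),
        "i_reference": np.exp2((A - M) / 2.0),
    })
    return ArrayScan(data), gene_truth
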