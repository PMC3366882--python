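"""Two-channel CGH array normalization and gene presence/absence calling.

Per probe the array yields sample- and reference-channel intensities on a
spotted grid; M = log2(I_sample / I_reference) measures sequence presence
(M near 0) versus absence (strongly negative M), and A = log2(I_sample *
I_reference) serves as the dye-bias regressor.  Arrays carry spatial bias
(position-dependent drift of M and A) and dye-intensity bias (a smooth trend
of M with A).  Normalization removes both, after which the M histogram is
bimodal and a per-array threshold at the between-peak minimum separates
present from absent probes; genes are called by majority vote over their
probes, ties counting as absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import FeatureMatrix, ValidationError

REQUIRED_COLUMNS = ("probe_id", "gene_id", "row", "col", "i_sample", "i_reference")


@dataclass
class ArrayScan:
    """Per-spot records of one hybridization.

    One row per (probe, replicate spot): grid coordinates, two channel
    intensities, and the derived M and A values.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"array table lacks column(s): {', '.join(missing)}")
        d = self.data
        if (d["i_sample"] <= 0).any() or (d["i_reference"] <= 0).any():
            raise ValidationError("intensities must be positive to define M and A")
        d = d.copy()
        d["M"] = np.log2(d["i_sample"] / d["i_reference"])
        # A as the log product (the regressor only; the conventional 1/2
        # factor would merely rescale the x-axis of the dye-bias fit).
        d["A"] = np.log2(d["i_sample"] * d["i_reference"])
        self.data = d

    @classmethod
    def from_tsv(cls, path) -> "ArrayScan":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        return cls(df)

    def to_tsv(self, path) -> None:
        cols = [c for c in self.data.columns if c not in ("M", "A")]
        self.data[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class CallSet:
    """Per-array threshold plus probe- and gene-level calls."""

    threshold: float
    probe_calls: pd.Series   # probe id -> 1 present / 0 absent
    gene_calls: pd.Series    # gene id -> 1 present / 0 absent


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def spatial_correct(values: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                    kernel_bandwidth: float = 5.0) -> np.ndarray:
    """Remove a smooth spatial surface from per-spot values.

    The surface is the Gaussian-kernel weighted local mean of the values over
    grid coordinates (normal kernel, sd = ``kernel_bandwidth`` grid units);
    corrected = value - surface + global median, so the overall level is
    preserved.
    """
    values = np.asarray(values, dtype=float)
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if len(np.unique(np.stack([rows, cols], axis=1), axis=0)) < 2:
        raise ValidationError("degenerate grid: all spots share one position")
    r0, c0 = rows.min(), cols.min()
    nr, nc = rows.max() - r0 + 1, cols.max() - c0 + 1
    total = np.zeros((nr, nc))
    count = np.zeros((nr, nc))
    np.add.at(total, (rows - r0, cols - c0), values)
    np.add.at(count, (rows - r0, cols - c0), 1.0)
    # Ratio of two Gaussian-filtered grids = kernel-weighted local mean; a
    # generous truncation keeps the kernel effectively untruncated.
    sm_total = gaussian_filter(total, sigma=kernel_bandwidth, mode="constant",
                               cval=0.0, truncate=8.0)
    sm_count = gaussian_filter(count, sigma=kernel_bandwidth, mode="constant",
                               cval=0.0, truncate=8.0)
    surface = sm_total[rows - r0, cols - c0] / sm_count[rows - r0, cols - c0]
    return values - surface + float(np.median(values))


def loess_dye_correct(M: np.ndarray, A: np.ndarray, span: float = 0.5,
                      band: float = 1.0) -> np.ndarray:
    """Subtract the loess trend of M versus A from all probes.

    The trend is fitted only on probes with |M - median(M)| <= ``band`` --
    the bulk corresponding to present genes -- so the absent-probe cloud at
    strongly negative M cannot drag the fit; the fitted trend is then
    evaluated (by interpolation, constant beyond the fitted range) at every
    probe's A and subtracted.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    in_band = np.abs(M - np.median(M)) <= band
    if in_band.sum() < 10:
        raise ValidationError(
            f"only {int(in_band.sum())} probes within the dye-fit band; cannot fit")
    # delta spares refits at nearly identical A values (linear interpolation
    # within delta), keeping the fit near-linear-time on dense arrays.
    fit = lowess(M[in_band], A[in_band], frac=span, it=2, return_sorted=True,
                 delta=0.005 * float(np.ptp(A[in_band])))
    xs, ys = fit[:, 0], fit[:, 1]
    trend = np.interp(A, xs, ys, left=ys[0], right=ys[-1])
    return M - trend


# ---------------------------------------------------------------------------
# Threshold and calls
# ---------------------------------------------------------------------------

def lanczos_derivative(counts: np.ndarray, delta: float, half_window: int = 10
                       ) -> np.ndarray:
    """Lanczos low-noise differentiator over histogram counts.

    d_i = 3 * sum_{j=1..m} j * (h_{i+j} - h_{i-j}) / (m (m+1) (2m+1) delta)
    with m = ``half_window`` (window 2m+1 bins); edges where the window
    does not fit are NaN.
    """
    m = int(half_window)
    h = np.asarray(counts, dtype=float)
    d = np.full(h.shape, np.nan)
    norm = m * (m + 1) * (2 * m + 1) * delta
    j = np.arange(1, m + 1)
    for i in range(m, len(h) - m):
        d[i] = 3.0 * np.sum(j * (h[i + j] - h[i - j])) / norm
    return d


def find_threshold(M: np.ndarray, n_bins: int = 400, half_window: int = 10,
                   max_threshold: float = -0.5,
                   min_absent_fraction: float = 0.01) -> float:
    """Per-array presence threshold at the minimum between the two M peaks.

    The M histogram (``n_bins`` equal bins over the observed range) is
    differentiated with a 21-bin Lanczos window; the threshold is the
    position below ``max_threshold`` where the derivative traverses from
    negative to positive values.  With sparse counts the traversal can span
    a run of empty (zero-derivative) bins; the threshold is then the midpoint
    between the last strictly negative and the first strictly positive
    derivative, which tracks the density minimum between the peaks.

    Derivative values no larger in magnitude than what a single isolated
    count can produce are treated as zero (sparse-valley noise floor), so
    lone stray probes in the empty valley cannot move the traversal.

    Raises when no traversal exists below ``max_threshold`` or when fewer
    than ``min_absent_fraction`` of probes fall below the candidate
    threshold (a unimodal histogram: nothing to call absent).
    """
    M = np.asarray(M, dtype=float)
    counts, edges = np.histogram(M, bins=int(n_bins))
    centers = 0.5 * (edges[:-1] + edges[1:])
    delta = edges[1] - edges[0]
    d = lanczos_derivative(counts, delta, half_window=half_window)
    m = int(half_window)
    floor = 3.0 * m / (m * (m + 1) * (2 * m + 1) * delta)

    below = centers < max_threshold
    neg = np.flatnonzero(below & (d < -floor))
    if neg.size == 0:
        raise ValidationError("unimodal histogram; cannot call presence/absence")
    a = int(neg.max())
    pos_after = np.flatnonzero((np.arange(len(d)) > a) & (d > floor))
    if pos_after.size == 0:
        raise ValidationError("derivative never turns positive above the valley; cannot call")
    b = int(pos_after.min())
    # the upper end of the traversal never exceeds the cap
    threshold = float(0.5 * (centers[a] + min(centers[b], max_threshold)))
    if np.mean(M < threshold) < min_absent_fraction:
        raise ValidationError("unimodal histogram; cannot call presence/absence")
    return threshold


def call_probes(M: pd.Series, threshold: float) -> pd.Series:
    """Present (1) iff mean M over a probe's replicate spots >= threshold."""
    mean_m = M.groupby(level=0).mean()
    return (mean_m >= threshold).astype(int)


def call_genes(probe_calls: pd.Series, probe_gene: pd.Series) -> pd.Series:
    """Majority vote of a gene's probe calls; exact ties are absent."""
    probe_gene = probe_gene.loc[probe_calls.index]
    grouped = probe_calls.groupby(probe_gene)
    present = grouped.sum()
    total = grouped.count()
    if (total == 0).any():
        raise ValidationError("gene with zero probes cannot be called")
    return (present * 2 > total).astype(int)


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def normalize_scan(scan: ArrayScan, kernel_bandwidth: float = 5.0,
                   span: float = 0.5) -> pd.DataFrame:
    """Spatial correction of M and A separately, then dye-bias correction."""
    d = scan.data.copy()
    rows, cols = d["row"].to_numpy(), d["col"].to_numpy()
    M = spatial_correct(d["M"].to_numpy(), rows, cols, kernel_bandwidth)
    A = spatial_correct(d["A"].to_numpy(), rows, cols, kernel_bandwidth)
    d["M_norm"] = loess_dye_correct(M, A, span=span)
    d["A_norm"] = A
    return d


def call_array(scan: ArrayScan, kernel_bandwidth: float = 5.0, span: float = 0.5
               ) -> CallSet:
    """Normalize one array, find its threshold, and call probes and genes."""
    d = normalize_scan(scan, kernel_bandwidth=kernel_bandwidth, span=span)
    threshold = find_threshold(d["M_norm"].to_numpy())
    m_by_probe = pd.Series(d["M_norm"].to_numpy(), index=d["probe_id"].to_numpy())
    probe_calls = call_probes(m_by_probe, threshold)
    probe_gene = (d.drop_duplicates("probe_id").set_index("probe_id")["gene_id"]
                  .loc[probe_calls.index])
    gene_calls = call_genes(probe_calls, probe_gene)
    return CallSet(threshold=threshold, probe_calls=probe_calls, gene_calls=gene_calls)


def calls_to_feature_matrix(calls: dict[str, CallSet]) -> FeatureMatrix:
    """Stack per-array gene calls (one array per sample) into the samples x
    genes presence/absence matrix the association pipeline consumes."""
    mat = pd.DataFrame({sample: cs.gene_calls for sample, cs in calls.items()}).T
    return FeatureMatrix(mat.astype(float))
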