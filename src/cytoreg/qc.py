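"""Diagnostics: correlation heatmaps, QC log-ratio plots, relative RMSE,
and capture fraction.

These quantify variation between samples (and batches) before registration
and measure how much of it registration removed.  All statistics are computed
on per-cluster summaries of samples assigned to one shared cluster template.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .clusters import Assignment

__all__ = [
    "pearson",
    "correlation_heatmap",
    "cluster_mfi",
    "qc_log_ratios",
    "rmse_report",
    "capture_fraction",
    "plot_heatmap",
    "plot_qc",
    "group_comparison",
]


def pearson(a, b) -> float:
    """Pearson correlation ρ with the N−1 normalization:
    ρ = (1/(N−1)) Σ ((a_i−μ_a)/σ_a)((b_i−μ_b)/σ_b), σ the sample (ddof=1)
    standard deviation.  Inputs are vectors of single-channel cluster
    centroids or cluster sizes from two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least two observations")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0 or sb == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(((a - a.mean()) / sa * (b - b.mean()) / sb).sum() / (n - 1))


def correlation_heatmap(stats_by_sample: dict, mode, order: list | None = None) -> pd.DataFrame:
    """S × S matrix of pairwise Pearson correlations between samples.

    ``stats_by_sample`` maps sample id → (centroids K × C, sizes K); ``mode``
    is either a channel index (correlate that channel's cluster centroids) or
    the string ``"sizes"``.  Clusters undefined in either sample of a pair are
    excluded pairwise.  Row/column order follows ``order`` when given (sort
    keys such as assay day / cytometer / subject / batch).
    """
    ids = list(order) if order is not None else list(stats_by_sample)
    vecs = {}
    for sid in ids:
        centroids, sizes = stats_by_sample[sid]
        vecs[sid] = np.asarray(sizes, float) if mode == "sizes" else np.asarray(centroids, float)[:, mode]
    mat = np.eye(len(ids))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            va, vb = vecs[a], vecs[ids[j]]
            ok = np.isfinite(va) & np.isfinite(vb)
            mat[i, j] = mat[j, i] = pearson(va[ok], vb[ok])
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_mfi(events: np.ndarray, assignment: Assignment) -> np.ndarray:
    """Per-cluster median transformed intensity (MFI), K × C; NaN where the
    cluster caught no events (by hard label)."""
    K = assignment.k
    out = np.full((K, events.shape[1]), np.nan)
    for j in range(K):
        members = assignment.hard_labels == j
        if members.any():
            out[j] = np.median(events[members], axis=0)
    return out


def qc_log_ratios(mfi_by_sample: dict[str, np.ndarray], standard_mfi: np.ndarray,
                  channels: list[str]) -> pd.DataFrame:
    """QC table: log10 ratio of each sample's cluster MFI to the reference
    standard's cluster MFI, per (sample, cluster, channel).

    A dot on the 1:1 line (log-ratio 0) means the cluster's MFI matches the
    standard; distance off the line measures MFI inconsistency.  Clusters with
    nonpositive MFI in either operand are dropped with a warning.
    """
    standard_mfi = np.asarray(standard_mfi, float)
    rows = []
    dropped = 0
    for sid, mfi in mfi_by_sample.items():
        mfi = np.asarray(mfi, float)
        if mfi.shape != standard_mfi.shape:
            raise ValueError(f"MFI shape mismatch for sample {sid!r}")
        for j in range(mfi.shape[0]):
            for c, ch in enumerate(channels):
                s, r = mfi[j, c], standard_mfi[j, c]
                if not (np.isfinite(s) and np.isfinite(r)):
                    continue
                if s <= 0 or r <= 0:
                    dropped += 1
                    continue
                rows.append((sid, j, ch, float(np.log10(s / r))))
    if dropped:
        warnings.warn(f"dropped {dropped} nonpositive MFI entries (log undefined)", stacklevel=2)
    return pd.DataFrame(rows, columns=["sample", "cluster", "channel", "log_ratio"])


def rmse_report(registered_stats: dict, nonregistered_stats: dict,
                reference_stats: tuple) -> tuple[float, float]:
    """Relative RMSE of cluster positions and sizes.

    For each sample set, distance RMSE is the root mean square of per-cluster
    Euclidean centroid distances to the reference, and size RMSE the root mean
    square of per-cluster size differences; relative RMSE divides the
    registered by the non-registered value, so values < 1 mean registration
    moved samples toward the reference.
    """
    ref_centroids, ref_sizes = reference_stats
    ref_centroids = np.asarray(ref_centroids, float)
    ref_sizes = np.asarray(ref_sizes, float)

    def _rmse(stats: dict) -> tuple[float, float]:
        d2, s2 = [], []
        for centroids, sizes in stats.values():
            centroids = np.asarray(centroids, float)
            ok = np.isfinite(centroids).all(axis=1) & np.isfinite(ref_centroids).all(axis=1)
            d2.extend(np.sum((centroids[ok] - ref_centroids[ok]) ** 2, axis=1))
            s2.extend((np.asarray(sizes, float)[ok] - ref_sizes[ok]) ** 2)
        return float(np.sqrt(np.mean(d2))), float(np.sqrt(np.mean(s2)))

    reg_d, reg_s = _rmse(registered_stats)
    non_d, non_s = _rmse(nonregistered_stats)
    if non_d == 0 or non_s == 0:
        raise ZeroDivisionError(
            "non-registered RMSE is zero: relative RMSE undefined "
            "(samples already coincide with the reference)"
        )
    return reg_d / non_d, reg_s / non_s


def capture_fraction(truth_event_ids, assignment: Assignment, target_cluster: int) -> float:
    """Fraction of a tracked ground-truth cohort whose hard label is the
    target cluster."""
    ids = np.asarray(truth_event_ids, dtype=int)
    if ids.size == 0:
        raise ValueError("empty tracked cohort")
    return float(np.mean(assignment.hard_labels[ids] == target_cluster))


# ---------------------------------------------------------------------------
# Plot renderers (matplotlib, Agg-safe)


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "Cluster centroid correlations"):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, cmap="viridis", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Pearson ρ")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_qc(qc_table: pd.DataFrame, path, title: str = "QC log-ratio plot"):
    """Rows = channels, columns = samples, dots = clusters; the horizontal
    line in each row is the 1:1 log-ratio."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    channels = list(qc_table["channel"].unique())
    samples = list(qc_table["sample"].unique())
    fig, axes = plt.subplots(len(channels), 1,
                             figsize=(max(4, 0.5 * len(samples)), 1.6 * len(channels)),
                             sharex=True, squeeze=False, layout="constrained")
    xpos = {s: i for i, s in enumerate(samples)}
    for r, ch in enumerate(channels):
        ax = axes[r, 0]
        sub = qc_table[qc_table["channel"] == ch]
        jitter = (sub["cluster"] % 7 - 3) * 0.02
        ax.scatter(sub["sample"].map(xpos) + jitter, sub["log_ratio"], s=6, alpha=0.6)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_ylabel(ch, fontsize=7)
    axes[-1, 0].set_xticks(range(len(samples)), samples, rotation=90, fontsize=6)
    fig.suptitle(title)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def group_comparison(sizes_by_sample: dict[str, np.ndarray], group_a: list[str],
                     group_b: list[str]) -> pd.DataFrame:
    """Thin demo: per-cluster two-sided Wilcoxon rank-sum between two sample
    groups with Benjamini–Hochberg correction, on cluster sizes.  Uses
    standard scipy/statsmodels routines; provided for exploratory use."""
    from scipy.stats import mannwhitneyu
    from statsmodels.stats.multitest import multipletests

    a = np.vstack([sizes_by_sample[s] for s in group_a])
    b = np.vstack([sizes_by_sample[s] for s in group_b])
    pvals, ratios = [], []
    for j in range(a.shape[1]):
        try:
            p = mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
        except ValueError:
            p = 1.0
        pvals.append(p)
        ga = np.exp(np.mean(np.log(np.maximum(a[:, j], 1e-9))))
        gb = np.exp(np.mean(np.log(np.maximum(b[:, j], 1e-9))))
        ratios.append(ga / gb)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"cluster": range(a.shape[1]), "p": pvals,
                         "p_adj": adj, "geomean_ratio": ratios})
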