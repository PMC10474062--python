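"""Per-gene mutual information against condition labels, and the
set-vs-rest MI-density comparison.

Expression is discretized into k=3 bins whose boundaries are fitted by
max-entropy (equal-frequency) binning on the pooled mean-centered
log-normalized values of *all* genes across the samples in the contrast;
the same global boundaries are applied to every gene.  Per gene, the
plug-in mutual information between the binned expression X and the
condition label Y is

    I(X:Y) = H(X) + H(Y) - H(X,Y)        (bits)

with empirical-frequency entropies and 0*log(0) = 0.  The "MI density"
of a gene set is its distribution of per-gene MI; a one-sided Wilcoxon
rank-sum test asks whether the set's MI is stochastically greater than
that of the remaining transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import NormalizedMatrix

#: supported contrasts: sample subset and the label column each one uses
CONTRASTS = ("condition4", "CP_vs_BC", "wt_vs_KO")

# product n_set * n_rest above which the rank-sum test switches from
# exact enumeration to the tie-corrected normal approximation
_EXACT_LIMIT = 200


@dataclass
class BinningScheme:
    """Global discretization shared by all genes of a contrast."""

    k: int
    boundaries: np.ndarray  # k-1 strictly increasing cut points
    source: str
    n_pooled: int

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value: x <= b1 -> 0, b1 < x <= b2 -> 1, x > b2 -> 2."""
        return np.searchsorted(self.boundaries, values, side="left")


@dataclass
class MIProfile:
    contrast: str
    samples_used: list[str]
    labels: np.ndarray
    mi: pd.Series  # per-gene MI in bits
    binning: BinningScheme
    log_base: int = 2


@dataclass
class DensityComparison:
    n_set: int
    n_rest: int
    rank_sum_statistic: float  # rank sum W of the set (mid-ranks)
    p_one_sided: float
    median_set: float
    median_rest: float
    alternative: str = "set_greater"
    method: str = "exact"


def fit_max_entropy_bins(values: np.ndarray, k: int = 3) -> BinningScheme:
    """Equal-frequency bin boundaries at the i/k empirical quantiles.

    Equal-frequency binning maximizes the entropy of the discretized
    variable, hence "max-entropy binning".  Boundaries are order
    statistics (inverted-CDF quantiles) of the pooled values.

    Raises
    ------
    ValueError
        With fewer than k distinct values, or when ties collapse two
        boundaries onto the same value.
    """
    pooled = np.asarray(values, dtype=float).ravel()
    pooled = pooled[np.isfinite(pooled)]
    if len(np.unique(pooled)) < k:
        raise ValueError(f"need at least {k} distinct values to fit {k} bins")
    qs = np.arange(1, k) / k
    boundaries = np.quantile(pooled, qs, method="inverted_cdf").astype(float)
    if np.any(np.diff(boundaries) <= 0):
        tied = boundaries[np.argmin(np.diff(boundaries))]
        raise ValueError(f"bin boundaries collapse under ties at value {tied!r}")
    return BinningScheme(
        k=k,
        boundaries=boundaries,
        source=f"pooled equal-frequency quantiles of {pooled.size} values",
        n_pooled=int(pooled.size),
    )


def _entropy_bits(counts: np.ndarray) -> float:
    """Plug-in entropy of a count vector, in bits; 0*log(0) = 0."""
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def contrast_samples(annotation: pd.DataFrame, contrast: str) -> tuple[list[str], np.ndarray]:
    """Sample subset and per-sample label array for a named contrast."""
    if contrast == "condition4":
        mask = np.ones(len(annotation), dtype=bool)
    elif contrast == "CP_vs_BC":
        mask = annotation["condition"].isin(["CP", "BC"]).to_numpy()
    elif contrast == "wt_vs_KO":
        mask = annotation["condition"].isin(["wt", "KO"]).to_numpy()
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    sub = annotation.loc[mask]
    labels = sub["condition"].to_numpy()
    if contrast == "condition4":
        expected = {"wt", "KO", "CP", "BC"}
    elif contrast == "CP_vs_BC":
        expected = {"CP", "BC"}
    else:
        expected = {"wt", "KO"}
    missing = expected - set(labels)
    if missing:
        raise ValueError(f"contrast {contrast!r}: annotation lacks level(s) {sorted(missing)}")
    return list(sub.index), labels


def compute_mi_profile(
    matrix: NormalizedMatrix,
    annotation: pd.DataFrame,
    contrast: str,
    binning: BinningScheme | None = None,
) -> MIProfile:
    """Mutual information of every gene with the contrast's condition label.

    If no binning scheme is given, one is fitted on the pooled centered
    values of the selected samples across all genes (so boundaries are
    shared by every gene and refit per contrast).
    """
    if not matrix.centered:
        raise ValueError("MI is computed on the mean-centered matrix")
    samples, labels = contrast_samples(annotation.loc[matrix.samples], contrast)
    vals = matrix.values[samples].to_numpy()
    if binning is None:
        binning = fit_max_entropy_bins(vals, k=3)
    if not np.all(np.isfinite(binning.boundaries)):
        raise ValueError("binning boundaries must be finite")

    xb = binning.assign(vals)  # genes x samples, in {0..k-1}
    levels, y = np.unique(labels, return_inverse=True)
    n_genes, n_samples = xb.shape
    k, n_lev = binning.k, len(levels)

    # per-gene joint contingency tables via one flat bincount
    flat = (np.arange(n_genes)[:, None] * (k * n_lev) + xb * n_lev + y[None, :]).ravel()
    joint = np.bincount(flat, minlength=n_genes * k * n_lev).reshape(n_genes, k, n_lev)

    hy = _entropy_bits(np.bincount(y, minlength=n_lev))
    px = joint.sum(axis=2) / n_samples  # genes x k
    with np.errstate(divide="ignore", invalid="ignore"):
        hx = -np.nansum(np.where(px > 0, px * np.log2(px), 0.0), axis=1)
        pxy = joint / n_samples
        hxy = -np.nansum(np.where(pxy > 0, pxy * np.log2(pxy), 0.0), axis=(1, 2))
    mi = hx + hy - hxy
    mi[(mi < 0) & (mi > -1e-12)] = 0.0
    return MIProfile(
        contrast=contrast,
        samples_used=samples,
        labels=labels,
        mi=pd.Series(mi, index=matrix.genes, name="mi_bits"),
        binning=binning,
    )


def mi_from_table(table: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a joint contingency table."""
    table = np.asarray(table, dtype=float)
    return (
        _entropy_bits(table.sum(axis=1))
        + _entropy_bits(table.sum(axis=0))
        - _entropy_bits(table.ravel())
    )


def compare_mi_density(profile: MIProfile, gene_set: list[str]) -> DensityComparison:
    """One-sided Wilcoxon rank-sum test: is the set's MI distribution
    shifted toward higher values than the remaining transcriptome's?

    Mid-ranks for ties.  Exact enumeration when the samples are tie-free
    and n_set * n_rest <= 200; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    universe = set(profile.mi.index)
    in_set = [g for g in gene_set if g in universe]
    if not in_set:
        missing = sorted(set(gene_set) - universe)
        raise ValueError(
            f"gene set has no overlap with the MI universe; missing ids "
            f"(first few): {missing[:5]}"
        )
    rest = profile.mi.index.difference(in_set)
    if len(rest) == 0:
        raise ValueError("gene set covers the whole universe: empty rest")

    x = profile.mi.loc[in_set].to_numpy()
    y = profile.mi.loc[rest].to_numpy()
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())

    if np.all(pooled == pooled[0]):
        p, method = 1.0, "degenerate_all_tied"
    else:
        tie_free = len(np.unique(pooled)) == len(pooled)
        if tie_free and len(x) * len(y) <= _EXACT_LIMIT:
            method = "exact"
            res = scipy.stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        else:
            method = "normal_approx"
            res = scipy.stats.mannwhitneyu(
                x, y, alternative="greater", method="asymptotic", use_continuity=True
            )
        p = float(min(res.pvalue, 1.0))

    return DensityComparison(
        n_set=len(x),
        n_rest=len(y),
        rank_sum_statistic=w,
        p_one_sided=p,
        median_set=float(np.median(x)),
        median_rest=float(np.median(y)),
        method=method,
    )
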