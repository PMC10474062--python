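"""DEG-balance check: is a gene set's information advantage explained by
simple over-representation of differentially expressed genes?

Includes a clearly tagged stand-in DEG caller (per-gene Welch t-test on
log-CPM with Benjamini-Hochberg correction) for synthetic data — a
deliberately simple substitute for count-model likelihood-ratio callers —
and an upper-tail hypergeometric over-representation test on the 2x2
gene-set x DEG table.  Externally computed DEG flags can be supplied
instead of the stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix


@dataclass
class DEGResult:
    table: pd.DataFrame  # gene_id index; p_value, q_value, log2_fold_change, is_deg
    alpha: float
    method: str  # "standin_welch" or "external"

    @property
    def n_deg(self) -> int:
        return int(self.table["is_deg"].sum())

    def deg_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])


@dataclass
class EnrichmentResult:
    N_universe: int
    K_deg: int
    n_set: int
    k_deg_in_set: int
    p_hypergeometric: float
    tail: str = "upper"


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_degs_standin(
    matrix: NormalizedMatrix,
    annotation: pd.DataFrame,
    groups: tuple[str, str],
    alpha: float = 0.05,
) -> DEGResult:
    """Stand-in DEG caller: per-gene Welch two-sample t-test on log-CPM.

    ``groups`` names two condition levels, tested as group2 vs group1
    (log2 fold-change = mean(group2) - mean(group1) in log2-CPM units).
    Genes with zero variance in both groups get p = 1 by policy.
    Significance: BH-adjusted q < alpha.
    """
    cond = annotation.loc[matrix.samples, "condition"]
    s1 = matrix.samples[cond == groups[0]]
    s2 = matrix.samples[cond == groups[1]]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"each level of {groups} needs at least 2 samples")
    a = matrix.values[s1].to_numpy()
    b = matrix.values[s2].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        res = scipy.stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[zero_var] = 1.0
    p[~np.isfinite(p)] = 1.0
    q = bh_adjust(p)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    table = pd.DataFrame(
        {
            "p_value": p,
            "q_value": q,
            "log2_fold_change": lfc,
            "is_deg": q < alpha,
        },
        index=matrix.genes,
    )
    return DEGResult(table=table, alpha=alpha, method="standin_welch")


def degs_from_flags(flags: pd.Series, alpha: float = 0.05) -> DEGResult:
    """Wrap externally computed DEG flags (bool per gene) as a DEGResult."""
    table = pd.DataFrame(
        {
            "p_value": np.where(flags, 0.0, 1.0),
            "q_value": np.where(flags, 0.0, 1.0),
            "log2_fold_change": np.nan,
            "is_deg": flags.astype(bool),
        },
        index=flags.index,
    )
    return DEGResult(table=table, alpha=alpha, method="external")


def hypergeom_test(
    N: int, K: int, n: int, k: int, tail: str = "upper"
) -> EnrichmentResult:
    """Hypergeometric test on DEG membership in a gene set.

    Drawing ``n`` set genes from a universe of ``N`` containing ``K``
    DEGs, the upper-tail p is P(X >= k) — over-representation of DEGs in
    the set.  ``tail='two_sided'`` doubles the smaller tail (capped at 1).
    Computed via scipy's hypergeometric survival function (stable in log
    space internally).
    """
    N, K, n, k = (int(v) for v in (N, K, n, k))
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n) and k >= max(0, n - (N - K))):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}, k={k}")
    dist = scipy.stats.hypergeom(N, K, n)
    upper = float(dist.sf(k - 1))  # P(X >= k)
    if tail == "upper":
        p = upper
    elif tail == "two_sided":
        lower = float(dist.cdf(k))  # P(X <= k)
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError("tail must be 'upper' or 'two_sided'")
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(
        N_universe=N, K_deg=K, n_set=n, k_deg_in_set=k, p_hypergeometric=p, tail=tail
    )
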