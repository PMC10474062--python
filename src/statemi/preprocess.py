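"""Normalization: raw counts -> mean-centered log2 counts-per-million.

The state-space and mutual-information stages both consume the
mean-centered log-normalized matrix produced here.  "log-normalized" is
realized as log2(CPM + pseudocount) with library-size (column-sum) size
factors by default; externally computed size factors (e.g. TMM-derived
effective library sizes) can be supplied to override them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class NormalizedMatrix:
    """Gene-by-sample log2-CPM matrix with its normalization provenance.

    Attributes
    ----------
    values : pd.DataFrame
        Genes x samples, log2(CPM + pseudocount) units (mean-centered per
        gene when ``centered`` is True).
    centered : bool
        Whether each gene row has had its across-sample mean subtracted.
    size_factors : pd.Series
        Per-sample positive scale factors used as CPM denominators.
    pseudocount : float
        Added inside the log to keep zeros finite.
    """

    values: pd.DataFrame
    centered: bool
    size_factors: pd.Series
    pseudocount: float

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def metadata(self) -> dict:
        return {
            "pseudocount": self.pseudocount,
            "centered": self.centered,
            "log_base": 2,
            "size_factor_method": "library_size_cpm",
        }


def normalize_log(
    counts: pd.DataFrame,
    pseudocount: float = 1.0,
    size_factors: pd.Series | None = None,
) -> NormalizedMatrix:
    """log2(count / size_factor * 1e6 + pseudocount), per gene and sample.

    Parameters
    ----------
    counts : pd.DataFrame
        Nonnegative raw counts, genes x samples.
    pseudocount : float
        Strictly positive; pseudocount 1 maps zero counts to exactly 0.
    size_factors : pd.Series, optional
        Per-sample denominators; defaults to library size (column sums).

    Raises
    ------
    ValueError
        On negative counts, a zero-total sample (named in the message),
        or invalid size factors.
    """
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("counts must be nonnegative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be strictly positive")

    if size_factors is None:
        sf = pd.Series(vals.sum(axis=0), index=counts.columns, name="size_factor")
    else:
        sf = pd.Series(size_factors, index=counts.columns).astype(float)
    zero = sf[sf <= 0]
    if len(zero) > 0:
        raise ValueError(
            f"sample(s) with non-positive size factor / zero total count: {list(zero.index)}"
        )

    cpm = vals / sf.to_numpy()[None, :] * 1e6
    logged = pd.DataFrame(
        np.log2(cpm + pseudocount), index=counts.index, columns=counts.columns
    )
    return NormalizedMatrix(
        values=logged, centered=False, size_factors=sf, pseudocount=pseudocount
    )


def mean_center(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Subtract each gene row's across-sample mean.

    Idempotent: re-centering an already centered matrix is a no-op.
    """
    centered_vals = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    return replace(matrix, values=centered_vals, centered=True)
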