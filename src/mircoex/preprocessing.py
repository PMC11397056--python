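"""Count filtering, TMM normalization, CPM, and the arcsinh transform."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors.

    ``tmm_factors`` are rescaled to geometric mean 1; the effective library
    size of a sample is ``library_sizes * tmm_factors``.
    """

    library_sizes: pd.Series
    tmm_factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if self.reference_sample not in self.library_sizes.index:
            raise ValueError(f"reference sample {self.reference_sample!r} not in sample IDs")

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm_factors


def validate_counts(cm: pd.DataFrame) -> None:
    """Check the count-matrix invariants (unique IDs, non-negative integers)."""
    if cm.index.duplicated().any():
        raise ValueError("duplicate feature IDs")
    if cm.columns.duplicated().any():
        raise ValueError("duplicate sample IDs")
    arr = cm.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")


def filter_low_counts(cm: pd.DataFrame, min_total: int = 50) -> pd.DataFrame:
    """Retain features whose total across ALL samples is strictly > ``min_total``.

    Order-preserving and idempotent; an empty result is allowed.
    """
    totals = cm.sum(axis=1)
    return cm.loc[totals > min_total]


def _tmm_one(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
             trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (log2 scale result, 2**)."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return np.nan
    y_s = obs[keep].astype(np.float64)
    y_r = ref[keep].astype(np.float64)
    p_s = y_s / n_obs
    p_r = y_r / n_ref
    m = np.log2(p_s / p_r)
    a = 0.5 * np.log2(p_s * p_r)
    # asymptotic binomial variance of M; weight = 1/variance
    v = (n_obs - y_s) / (n_obs * y_s) + (n_ref - y_r) / (n_ref * y_r)
    if np.max(np.abs(m)) < 1e-6:  # identical composition: factor exactly 1
        return 1.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return np.nan
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return np.nan
    return float(2.0 ** f)


def tmm_factors(cm: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against the reference, using only features positive in
    both, M (log2 ratio of library-size-scaled counts) and A (mean log2
    abundance) values are doubly trimmed — ``trim_m`` from each tail of M and
    ``trim_a`` from each tail of A — and the factor is 2 to the
    inverse-variance-weighted mean of the surviving M values.  Factors are
    rescaled to geometric mean 1.  The reference sample is the one whose
    75th-percentile/library-size ratio is closest to the mean of that ratio.
    """
    if cm.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = cm.sum(axis=0).astype(np.int64)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    arr = cm.to_numpy(dtype=np.float64)
    n = lib.to_numpy(dtype=np.float64)
    q75 = np.quantile(arr, 0.75, axis=0) / n
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref_sample = str(cm.columns[ref_idx])

    factors = np.ones(cm.shape[1])
    for j in range(cm.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        f = _tmm_one(arr[:, j], arr[:, ref_idx], n[j], n[ref_idx], trim_m, trim_a)
        if np.isnan(f):
            logger.warning(
                "sample %s shares no usable features with reference %s; factor set to 1",
                cm.columns[j], ref_sample)
            f = 1.0
        factors[j] = f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        library_sizes=lib,
        tmm_factors=pd.Series(factors, index=cm.columns),
        reference_sample=ref_sample,
    )


def cpm(cm: pd.DataFrame, nf: NormalizationFactors) -> pd.DataFrame:
    """Counts per million on the TMM-effective library size.

    ``value = count / (library_size * tmm_factor) * 1e6``.
    """
    if list(nf.library_sizes.index) != list(cm.columns):
        raise ValueError("normalization factors do not match count-matrix samples")
    eff = nf.effective_sizes.to_numpy(dtype=np.float64)
    if (eff <= 0).any():
        raise ValueError("zero or negative effective library size")
    return cm.astype(np.float64) / eff * 1e6


def asinh_transform(em: pd.DataFrame, base: str = "e") -> pd.DataFrame:
    """Elementwise ``log(x + sqrt(x^2 + 1))`` on non-negative expression values.

    ``base`` selects the logarithm base ("e", "2" or "10"); natural log makes
    this the inverse hyperbolic sine.  The transform is strictly increasing
    and maps 0 to 0.
    """
    arr = em.to_numpy(dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("asinh_transform is defined here only for non-negative input")
    out = np.arcsinh(arr)
    if base == "2":
        out = out / np.log(2.0)
    elif base == "10":
        out = out / np.log(10.0)
    elif base != "e":
        raise ValueError(f"unknown log base {base!r}")
    return pd.DataFrame(out, index=em.index, columns=em.columns)


def top_k_share(cm: pd.DataFrame, k: int) -> float:
    """Share of the grand total carried by the k features with largest totals.

    Ties are broken by feature ID so the result is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals = cm.sum(axis=1)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("total counts must be positive")
    if k > len(totals):
        logger.warning("k=%d exceeds feature count %d; using all features", k, len(totals))
        k = len(totals)
    # mergesort on an ID-sorted series gives ID-stable tie breaking
    order = totals.sort_index().sort_values(ascending=False, kind="mergesort")
    return float(order.iloc[:k].sum() / grand)
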