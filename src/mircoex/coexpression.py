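"""All-pairs miRNA x mRNA Pearson correlation with permutation empirical FDR.

Correlations are computed on transformed expression within one (group,
tissue) stratum; the null is built by permuting the sample pairing between
the two matrices, which preserves each matrix's internal structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EFDR_THRESHOLD_DEFAULT = 4e-5  # printed screening threshold


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided Student-t p-value.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom.
    |r| = 1 yields p floored at machine epsilon; zero-variance input is
    reported as (nan, 1.0) so callers can skip the pair.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return float("nan"), 1.0
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    p = _p_from_r(np.array([r]), n)[0]
    return r, float(p)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    eps = np.finfo(np.float64).eps
    rr = np.clip(r, -1.0, 1.0)
    denom = 1.0 - rr**2
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / np.maximum(denom, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(denom <= 0, eps, p)
    return np.clip(p, eps, 1.0)


def _aligned(mirna_em: pd.DataFrame, mrna_em: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    a, b = set(mirna_em.columns), set(mrna_em.columns)
    if a != b:
        raise ValueError(f"sample mismatch; only-miRNA={sorted(a - b)} only-mRNA={sorted(b - a)}")
    return mirna_em, mrna_em[mirna_em.columns]


def _drop_constant(em: pd.DataFrame, label: str) -> pd.DataFrame:
    sd = em.std(axis=1, ddof=0)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.info("dropping %d zero-variance %s features before pairing", n_const, label)
    return em.loc[sd > 0]


def _corr_matrix(mirna: np.ndarray, mrna: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix via standardized cross-product."""
    def std_rows(m):
        c = m - m.mean(axis=1, keepdims=True)
        s = np.sqrt((c**2).sum(axis=1, keepdims=True))
        return c / s
    return np.clip(std_rows(mirna) @ std_rows(mrna).T, -1.0, 1.0)


def all_pairs(mirna_em: pd.DataFrame, mrna_em: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p for every (miRNA, gene) pair on matched samples.

    Zero-variance features are dropped with a logged count.  Equivalent to a
    per-pair :func:`pearson_with_p` loop to 1e-10.
    """
    mirna_em, mrna_em = _aligned(mirna_em, mrna_em)
    mirna_em = _drop_constant(mirna_em, "miRNA")
    mrna_em = _drop_constant(mrna_em, "mRNA")
    n = mirna_em.shape[1]
    if n < 3:
        raise ValueError("need at least 3 matched samples")
    r = _corr_matrix(mirna_em.to_numpy(np.float64), mrna_em.to_numpy(np.float64))
    p = _p_from_r(r, n)
    mi = np.repeat(mirna_em.index.to_numpy(), mrna_em.shape[0])
    ge = np.tile(mrna_em.index.to_numpy(), mirna_em.shape[0])
    return pd.DataFrame({
        "mirna": mi,
        "gene": ge,
        "n": n,
        "r": r.ravel(),
        "p": p.ravel(),
    })


def empirical_fdr(table: pd.DataFrame, mirna_em: pd.DataFrame, mrna_em: pd.DataFrame,
                  n_rand: int = 10_000, seed: int | None = None,
                  permute: str = "mrna") -> pd.DataFrame:
    """Attach permutation-based empirical FDR values to a co-expression table.

    For each randomization the sample columns of one matrix are permuted
    relative to the other (default: the mRNA matrix) and all pair p-values
    are recomputed.  At each observed p-value t,
    ``eFDR(t) = mean_null_count(p <= t) / observed_count(p <= t)`` capped at
    1, then made monotone non-decreasing in p by a cumulative minimum from
    the largest p downward.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if permute not in ("mrna", "mirna"):
        raise ValueError("permute must be 'mrna' or 'mirna'")
    mirna_em, mrna_em = _aligned(mirna_em, mrna_em)
    mirna_em = _drop_constant(mirna_em, "miRNA")
    mrna_em = _drop_constant(mrna_em, "mRNA")
    n = mirna_em.shape[1]
    rng = np.random.default_rng(seed)

    obs_p = table["p"].to_numpy(np.float64)
    order = np.argsort(obs_p, kind="mergesort")
    sorted_p = obs_p[order]
    # ties inclusive: observed count at t = number of observed p <= t
    obs_count = np.searchsorted(sorted_p, sorted_p, side="right")

    a = mirna_em.to_numpy(np.float64)
    b = mrna_em.to_numpy(np.float64)
    null_counts = np.zeros(len(sorted_p), dtype=np.float64)
    for _ in range(n_rand):
        perm = rng.permutation(n)
        if permute == "mrna":
            r = _corr_matrix(a, b[:, perm])
        else:
            r = _corr_matrix(a[:, perm], b)
        pnull = np.sort(_p_from_r(r, n).ravel())
        null_counts += np.searchsorted(pnull, sorted_p, side="right")
    mean_null = null_counts / n_rand

    efdr_sorted = np.minimum(mean_null / obs_count, 1.0)
    # monotone non-decreasing in p: cumulative min from largest p down
    efdr_sorted = np.minimum.accumulate(efdr_sorted[::-1])[::-1]
    efdr = np.empty_like(efdr_sorted)
    efdr[order] = efdr_sorted
    out = table.copy()
    out["efdr"] = efdr
    return out


def infer_significant(table: pd.DataFrame,
                      efdr_threshold: float = EFDR_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Flag pairs with efdr strictly below the threshold."""
    if "efdr" not in table.columns:
        raise ValueError("table has no efdr column; run empirical_fdr first")
    out = table.copy()
    out["significant"] = out["efdr"] < efdr_threshold
    return out
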