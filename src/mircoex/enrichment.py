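"""Hypergeometric category enrichment with Holm FWER control."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

FWER_THRESHOLD_DEFAULT = 0.01


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene -> category TSV (columns: gene, category_id[, category_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "category_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    if "category_name" not in df.columns:
        df["category_name"] = df["category_id"]
    if df.duplicated(subset=["gene", "category_id"]).any():
        df = df.drop_duplicates(subset=["gene", "category_id"])
    return df.reset_index(drop=True)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, aligned to input order, capped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * (m - np.arange(m))
    adj = np.maximum.accumulate(scaled)
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def hypergeom_enrich(interest: set[str], background: set[str], ann: pd.DataFrame,
                     fwer_threshold: float = FWER_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``interest`` within ``background``.

    For each category with at least one background gene,
    ``p = P(X >= k)`` for ``X ~ Hypergeom(N, K, n)`` where N is the
    background size, K the background genes in the category, n the interest
    size and k the interest genes in the category.  Genes missing from the
    annotation count toward N but belong to no category.  Holm-adjusted FWER
    values are attached and significance uses ``fwer <= threshold``.
    """
    extra = interest - background
    if extra:
        raise ValueError(f"interest genes not in background: {sorted(extra)}")
    n_bg = len(background)
    n_int = len(interest)
    if n_int == 0:
        return pd.DataFrame(columns=["category_id", "category_name", "k", "K", "n", "N",
                                     "p", "fwer", "significant"])
    rows = []
    names = ann.drop_duplicates("category_id").set_index("category_id")["category_name"]
    for cat, sub in ann.groupby("category_id", sort=True):
        cat_genes = set(sub["gene"]) & background
        K = len(cat_genes)
        if K == 0:
            continue
        k = len(cat_genes & interest)
        p = float(hypergeom.sf(k - 1, n_bg, K, n_int))
        rows.append((cat, names[cat], k, K, n_int, n_bg, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["category_id", "category_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["fwer"] = holm_adjust(out["p"].to_numpy())
        out["significant"] = out["fwer"] <= fwer_threshold
        out = out.sort_values(["fwer", "p", "category_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["fwer"] = []
        out["significant"] = []
    return out
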