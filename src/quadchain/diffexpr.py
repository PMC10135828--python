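"""Differential expression (Wilcoxon rank-sum) and gene-set enrichment."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NormalizedMatrix, QuadchainError


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise QuadchainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def rank_sum_deg(normed: NormalizedMatrix, group_a: Sequence[str],
                 group_b: Sequence[str], min_pct: float = 0.1,
                 min_abs_log2fc: float = 0.25) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum markers of ``group_a`` vs ``group_b``.

    ``group_a`` is the group of interest: positive log2fc means higher in A.
    Genes expressed in fewer than ``min_pct`` of cells in *both* groups, or
    with |log2fc| below ``min_abs_log2fc``, are excluded before testing; BH
    is applied over the tested set only. The fold change is computed on mean
    expm1-normalized expression with a pseudocount of 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise QuadchainError("both groups must be non-empty")
    if len(group_a) < 3 or len(group_b) < 3:
        raise QuadchainError("each group needs >= 3 cells")
    if set(group_a) & set(group_b):
        raise QuadchainError("groups must be disjoint")

    xa = normed.dense_for(normed.gene_ids, group_a)
    xb = normed.dense_for(normed.gene_ids, group_b)
    pct_in = (xa > 0).mean(axis=1)
    pct_ref = (xb > 0).mean(axis=1)
    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    log2fc = np.log2(mean_a + 1) - np.log2(mean_b + 1)

    tested = ((pct_in >= min_pct) | (pct_ref >= min_pct)) & \
        (np.abs(log2fc) >= min_abs_log2fc)
    idx = np.nonzero(tested)[0]
    if idx.size:
        res = stats.mannwhitneyu(xa[idx], xb[idx], axis=1,
                                 alternative="two-sided", method="asymptotic")
        pvals = np.atleast_1d(res.pvalue)
        padj = bh_adjust(pvals)
    else:
        pvals = padj = np.array([])

    genes = [normed.gene_ids[i] for i in idx]
    lfc = log2fc[idx]
    out = pd.DataFrame({
        "gene": genes,
        "log2fc": lfc,
        "p": pvals,
        "p_adj": padj,
        "pct_in": pct_in[idx],
        "pct_ref": pct_ref[idx],
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "na")),
    })
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def hypergeom_enrich(query: Iterable[str], collections: Mapping[str, Iterable[str]],
                     background: Iterable[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Each collection set is intersected with the background before testing;
    BH is applied across the tested sets.
    """
    background = set(background)
    if not background:
        raise QuadchainError("empty background universe")
    query = set(query)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise QuadchainError(f"query genes outside background, e.g. {extra}")

    rows = []
    n_bg = len(background)
    n_q = len(query)
    for set_id in sorted(collections):
        members = set(collections[set_id]) & background
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=|set|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n_q))
        rows.append({"set_id": set_id, "overlap": k, "set_size": len(members),
                     "query_size": n_q, "background": n_bg, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
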