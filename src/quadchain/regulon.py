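"""Co-expression TF->target verification (regulon inference)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NormalizedMatrix, QuadchainError


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: dict[str, float]  # target -> importance >= 0


def coexpression_importance(normed: NormalizedMatrix, receiver_cells: Sequence[str],
                            tfs: Iterable[str], targets: Iterable[str],
                            method: str = "correlation", seed: int = 0
                            ) -> pd.DataFrame:
    """TF x target importance matrix over the receiver cells.

    ``correlation``: absolute Spearman rank correlation (deterministic).
    ``tree_ensemble``: per-target gradient-boosted-tree importances over the
    TF predictors, seeded. A constant TF scores 0 against every target, and
    a gene paired with itself scores 0.
    """
    receiver_cells = list(receiver_cells)
    if len(receiver_cells) < 20:
        raise QuadchainError("need >= 20 receiver cells for co-expression")
    present = set(normed.gene_ids)
    tfs = sorted(set(tfs) & present)
    targets = sorted(set(targets) & present)
    if not tfs or not targets:
        raise QuadchainError("no TFs or no targets present in the matrix")

    x_tf = normed.dense_for(tfs, receiver_cells)        # (n_tf, n_cells)
    x_tg = normed.dense_for(targets, receiver_cells)    # (n_tg, n_cells)
    imp = np.zeros((len(tfs), len(targets)))

    if method == "correlation":
        const_tf = np.ptp(x_tf, axis=1) == 0
        const_tg = np.ptp(x_tg, axis=1) == 0
        r_tf = stats.rankdata(x_tf, axis=1)
        r_tg = stats.rankdata(x_tg, axis=1)
        a = r_tf - r_tf.mean(axis=1, keepdims=True)
        b = r_tg - r_tg.mean(axis=1, keepdims=True)
        denom = np.sqrt((a ** 2).sum(axis=1))[:, None] * \
            np.sqrt((b ** 2).sum(axis=1))[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, (a @ b.T) / np.maximum(denom, 1e-300), 0.0)
        imp = np.abs(rho)
        imp[const_tf, :] = 0.0
        imp[:, const_tg] = 0.0
    elif method == "tree_ensemble":
        from sklearn.ensemble import GradientBoostingRegressor

        const_tf = np.ptp(x_tf, axis=1) == 0
        for j, tgt in enumerate(targets):
            y = x_tg[j]
            predictors = [i for i, tf in enumerate(tfs) if tf != tgt]
            if np.ptp(y) == 0 or not predictors:
                continue
            model = GradientBoostingRegressor(n_estimators=50, max_depth=3,
                                              random_state=seed)
            model.fit(x_tf[predictors].T, y)
            imp[predictors, j] = model.feature_importances_
        imp[const_tf, :] = 0.0
    else:
        raise QuadchainError(f"unknown method {method!r}")

    for i, tf in enumerate(tfs):
        for j, tgt in enumerate(targets):
            if tf == tgt:
                imp[i, j] = 0.0
    return pd.DataFrame(imp, index=pd.Index(tfs, name="tf"),
                        columns=pd.Index(targets, name="target"))


def build_regulons(importances: pd.DataFrame, top_k: int = 50,
                   min_importance: float = 0.1) -> dict[str, Regulon]:
    """Per-TF target sets: importance >= min_importance, top_k by importance.

    Ties break deterministically by target gene name; a TF never appears in
    its own regulon. Empty regulons are allowed.
    """
    if top_k < 1:
        raise QuadchainError("top_k must be >= 1")
    regulons: dict[str, Regulon] = {}
    for tf in importances.index:
        row = importances.loc[tf]
        kept = [(t, float(v)) for t, v in row.items()
                if v >= min_importance and t != tf]
        kept.sort(key=lambda tv: (-tv[1], tv[0]))
        regulons[tf] = Regulon(tf=tf, targets=dict(kept[:top_k]))
    return regulons


def regulon_pairs(regulons: dict[str, Regulon]) -> set[tuple[str, str]]:
    """Flat set of supported (tf, target) pairs."""
    return {(tf, t) for tf, reg in regulons.items() for t in reg.targets}
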