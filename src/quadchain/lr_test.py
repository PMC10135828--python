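"""Permutation-based ligand-receptor interaction scoring.

The interaction score of a pair between a sender and a receiver cluster is
the arithmetic mean of (cluster-mean ligand expression in sender,
cluster-mean receptor expression in receiver), set to zero unless both
cluster means are positive. Pairs are retained by the strict ``mean > 0``
rule; the permutation p-value is carried as metadata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import NormalizedMatrix, QuadchainError

log = logging.getLogger(__name__)


def _prepare(normed: NormalizedMatrix, cells: pd.DataFrame, pairs: pd.DataFrame,
             sender: str, receiver: str):
    need = {"ligand", "receptor"}
    if not need.issubset(pairs.columns):
        raise QuadchainError("pair list needs columns ligand, receptor")
    sender_cells = cells.loc[cells["cell_type"] == sender, "cell_id"].tolist()
    receiver_cells = cells.loc[cells["cell_type"] == receiver, "cell_id"].tolist()
    if not sender_cells:
        raise QuadchainError(f"no cells of sender type {sender!r}")
    if not receiver_cells:
        raise QuadchainError(f"no cells of receiver type {receiver!r}")

    present = set(normed.gene_ids)
    kept = pairs[["ligand", "receptor"]].drop_duplicates().reset_index(drop=True)
    missing = kept[~(kept["ligand"].isin(present) & kept["receptor"].isin(present))]
    for _, row in missing.iterrows():
        log.warning("dropping pair %s-%s: gene absent from matrix",
                    row["ligand"], row["receptor"])
    kept = kept[kept["ligand"].isin(present) & kept["receptor"].isin(present)]
    kept = kept.reset_index(drop=True)
    return sender_cells, receiver_cells, kept


def _pair_means(lig_expr: np.ndarray, rec_expr: np.ndarray,
                sender_mask: np.ndarray, receiver_mask: np.ndarray) -> np.ndarray:
    """Both-expressed interaction means for all pairs at once.

    ``lig_expr``/``rec_expr`` are (n_pairs, n_pool_cells) expression slices.
    """
    ml = lig_expr[:, sender_mask].mean(axis=1)
    mr = rec_expr[:, receiver_mask].mean(axis=1)
    means = 0.5 * (ml + mr)
    means[(ml <= 0) | (mr <= 0)] = 0.0
    return means


def interaction_means(normed: NormalizedMatrix, cells: pd.DataFrame,
                      pairs: pd.DataFrame, sender: str, receiver: str
                      ) -> pd.DataFrame:
    """Observed interaction means, retained iff strictly positive."""
    sender_cells, receiver_cells, kept = _prepare(normed, cells, pairs,
                                                 sender, receiver)
    pool = sender_cells + receiver_cells
    sender_mask = np.arange(len(pool)) < len(sender_cells)
    lig = normed.dense_for(kept["ligand"], pool)
    rec = normed.dense_for(kept["receptor"], pool)
    means = _pair_means(lig, rec, sender_mask, ~sender_mask) if len(kept) else \
        np.array([])
    out = kept.copy()
    out["sender"] = sender
    out["receiver"] = receiver
    out["mean"] = means
    out["retained"] = out["mean"] > 0
    return out


def permutation_test(normed: NormalizedMatrix, cells: pd.DataFrame,
                     pairs: pd.DataFrame, sender: str, receiver: str,
                     n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Empirical upper-tail p by shuffling type labels among the pooled cells.

    Labels are permuted jointly across the sender+receiver pool (the smallest
    exchangeable set); p = (1 + #{perm mean >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise QuadchainError("n_perm must be >= 100")
    sender_cells, receiver_cells, kept = _prepare(normed, cells, pairs,
                                                  sender, receiver)
    if len(sender_cells) < 2 or len(receiver_cells) < 2:
        raise QuadchainError("need >= 2 cells per type for label shuffling")
    pool = sender_cells + receiver_cells
    n_sender = len(sender_cells)
    sender_mask = np.arange(len(pool)) < n_sender

    lig = normed.dense_for(kept["ligand"], pool)
    rec = normed.dense_for(kept["receptor"], pool)
    observed = _pair_means(lig, rec, sender_mask, ~sender_mask) if len(kept) else \
        np.array([])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))
        mask = np.zeros(len(pool), dtype=bool)
        mask[perm[:n_sender]] = True
        exceed += _pair_means(lig, rec, mask, ~mask) >= observed

    out = kept.copy()
    out["sender"] = sender
    out["receiver"] = receiver
    out["mean"] = observed
    out["p"] = (1 + exceed) / (1 + n_perm)
    out["retained"] = out["mean"] > 0
    return out
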