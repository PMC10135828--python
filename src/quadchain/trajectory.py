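"""Pseudotime ordering of receiver cells on network signal genes.

Dimensionality reduction is PCA to two components; cells are grouped by
k-means, a minimum spanning tree is built on the cluster centroids, and
pseudotime is the geodesic centroid distance from the root state (the state
with the largest fraction of root-condition cells) plus a within-state
projection along the incoming tree edge.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import NormalizedMatrix, QuadchainError

log = logging.getLogger(__name__)


def signal_features(normed: NormalizedMatrix, receiver_cells: Sequence[str],
                    signal_genes: Iterable[str]) -> pd.DataFrame:
    """Cells x signal-genes slice with z-scored columns."""
    receiver_cells = list(receiver_cells)
    if len(receiver_cells) < 10:
        raise QuadchainError("need >= 10 cells for trajectory features")
    requested = sorted(set(signal_genes))
    present = [g for g in requested if g in set(normed.gene_ids)]
    missing = sorted(set(requested) - set(present))
    if missing:
        log.warning("%d signal gene(s) absent from matrix, e.g. %s",
                    len(missing), missing[:5])
    if len(present) < 2:
        raise QuadchainError("need >= 2 signal genes present in the matrix")
    x = normed.dense_for(present, receiver_cells).T  # cells x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    return pd.DataFrame(z, index=pd.Index(receiver_cells, name="cell_id"),
                        columns=present)


def pseudotime_order(features: pd.DataFrame, conditions: pd.Series,
                     root_condition: str = "nLung", n_states: int = 7,
                     seed: int = 0) -> pd.DataFrame:
    """Pseudotime via PCA -> k-means -> centroid MST -> root geodesics.

    ``conditions`` maps cell_id -> condition; the root state is the state
    with the highest fraction of root-condition cells. Deterministic for a
    fixed seed. Returns columns cell_id, state, pseudotime, dim1, dim2.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if n_states < 2:
        raise QuadchainError("n_states must be >= 2")
    n_cells = len(features)
    if n_cells < n_states:
        raise QuadchainError(f"{n_cells} cells is fewer than {n_states} states")
    cond = conditions.reindex(features.index)
    if cond.isna().any():
        raise QuadchainError("conditions missing for some feature cells")

    x = features.to_numpy(float)
    n_comp = min(2, x.shape[1])
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    if n_comp == 1:
        coords = np.column_stack([coords, np.zeros(n_cells)])

    km = KMeans(n_clusters=n_states, random_state=seed, n_init=10)
    labels = km.fit_predict(coords)
    centroids = km.cluster_centers_

    # root state: largest fraction of root-condition cells (ties: lower label)
    frac = np.zeros(n_states)
    for s in range(n_states):
        mask = labels == s
        if mask.any():
            frac[s] = float((cond.to_numpy()[mask] == root_condition).mean())
    root = int(np.argmax(frac))

    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    mst = minimum_spanning_tree(dist).toarray()
    mst = np.maximum(mst, mst.T)
    graph = np.where(mst > 0, mst, 0.0)
    geo, predecessors = shortest_path(graph, directed=False, return_predecessors=True,
                                      indices=root)
    geo = np.where(np.isfinite(geo), geo, 0.0)

    # direction of travel into each state: from its predecessor on the tree
    directions = np.zeros_like(centroids)
    children = {s: [] for s in range(n_states)}
    for s in range(n_states):
        p = predecessors[s]
        if p >= 0:
            children[int(p)].append(s)
    for s in range(n_states):
        p = predecessors[s]
        if p >= 0:
            v = centroids[s] - centroids[int(p)]
        elif children[s]:
            v = centroids[children[s][0]] - centroids[s]
        else:
            v = np.zeros(centroids.shape[1])
        norm = np.linalg.norm(v)
        directions[s] = v / norm if norm > 0 else v

    offset = np.einsum("ij,ij->i", coords - centroids[labels], directions[labels])
    pseudotime = geo[labels] + offset
    pseudotime = pseudotime - pseudotime.min()

    return pd.DataFrame({
        "cell_id": features.index,
        "state": labels + 1,
        "pseudotime": pseudotime,
        "dim1": coords[:, 0],
        "dim2": coords[:, 1],
    }).reset_index(drop=True)


def state_composition(result: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """State x condition proportion table, normalized within each condition."""
    merged = result.merge(cells[["cell_id", "condition"]], on="cell_id",
                          validate="one_to_one")
    table = (merged.groupby(["condition", "state"], observed=True).size()
             .unstack(fill_value=0))
    props = table.div(table.sum(axis=1), axis=0)
    return props
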