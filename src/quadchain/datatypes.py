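"""Core containers shared across the pipeline.

Tabular data (cell annotations, survival cohorts, DEG tables) are plain
:class:`pandas.DataFrame` objects with documented column contracts; only the
structures with non-trivial invariants get their own classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Fixed condition vocabulary (disease stages).
CONDITIONS = ("nLung", "tLung", "tL/B")

#: Edge layers of the prior knowledge network.
LAYERS = ("lr", "signaling", "gene_regulatory")

#: Node role tags.
ROLES = ("ligand", "receptor", "signaling", "tf", "target")

#: Required columns of a cell annotation table.
CELL_COLUMNS = ("cell_id", "cell_type", "condition", "patient_id")

#: Required columns of a survival table.
SURVIVAL_COLUMNS = ("patient_id", "time", "event", "biomarker")


class QuadchainError(ValueError):
    """Base class for contract violations raised by this package."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell matrix with identifiers.

    Parameters
    ----------
    gene_ids, cell_ids
        Row / column identifiers; must be unique.
    counts
        ``(n_genes, n_cells)`` sparse matrix of non-negative integers.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise QuadchainError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise QuadchainError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise QuadchainError("duplicate cell identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise QuadchainError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def subset_cells(self, keep: Iterable[str]) -> "CountMatrix":
        idx = self.cell_index()
        cols = [idx[c] for c in keep]
        return CountMatrix(self.gene_ids, [self.cell_ids[j] for j in cols],
                           self.counts[:, cols])


@dataclass
class NormalizedMatrix:
    """Depth-scaled log1p expression: value = ln(1 + count * scale / depth)."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: sp.spmatrix
    scale_factor: float = 10000.0

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise QuadchainError("normalized matrix shape inconsistent with ids")
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise QuadchainError("non-finite normalized values")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def dense_for(self, genes: Iterable[str], cells: Iterable[str]) -> np.ndarray:
        """Dense ``(len(genes), len(cells))`` slice in the given order."""
        gi, ci = self.gene_index(), self.cell_index()
        rows = [gi[g] for g in genes]
        cols = [ci[c] for c in cells]
        return np.asarray(self.values[np.ix_(rows, cols)].todense())


class PriorNetwork:
    """Typed, weighted, directed multilayer prior knowledge graph.

    Layers: ``lr`` (ligand -> receptor), ``signaling`` (receptor/signaling
    node -> signaling node/TF) and ``gene_regulatory`` (TF -> target gene).
    Node roles are induced by edge layers plus explicit tags for isolated
    signaling intermediates.
    """

    def __init__(self, edges: pd.DataFrame,
                 roles: Mapping[str, frozenset[str]] | None = None) -> None:
        required = {"source", "target", "weight", "layer"}
        if not required.issubset(edges.columns):
            raise QuadchainError(f"prior edge table needs columns {sorted(required)}")
        edges = edges.loc[:, ["source", "target", "weight", "layer"]].copy()
        edges = edges.reset_index(drop=True)
        if (edges["source"] == edges["target"]).any():
            raise QuadchainError("self-loop in prior network")
        if not edges["layer"].isin(LAYERS).all():
            bad = sorted(set(edges["layer"]) - set(LAYERS))
            raise QuadchainError(f"unknown edge layer(s): {bad}")
        w = edges["weight"].to_numpy(float)
        if not np.all((w > 0) & np.isfinite(w)):
            raise QuadchainError("edge weights must be positive and finite")
        if edges.duplicated(["source", "target", "layer"]).any():
            raise QuadchainError("duplicate edges in prior network")
        self.edges = edges
        self._roles: dict[str, set[str]] = {}
        for _, row in edges.iterrows():
            s, t, layer = row["source"], row["target"], row["layer"]
            if layer == "lr":
                self._roles.setdefault(s, set()).add("ligand")
                self._roles.setdefault(t, set()).add("receptor")
            elif layer == "gene_regulatory":
                self._roles.setdefault(s, set()).add("tf")
                self._roles.setdefault(t, set()).add("target")
            else:
                self._roles.setdefault(s, set())
                self._roles.setdefault(t, set())
        if roles:
            for node, tags in roles.items():
                self._roles.setdefault(node, set()).update(tags)
        # untagged nodes appearing only in the signaling layer are intermediates
        for node, tags in self._roles.items():
            if not tags:
                tags.add("signaling")
        self._check_layer_direction()

    def _check_layer_direction(self) -> None:
        for _, row in self.edges.iterrows():
            s, t, layer = row["source"], row["target"], row["layer"]
            if layer == "lr" and "ligand" not in self._roles[s]:
                raise QuadchainError(f"lr edge from non-ligand {s!r}")
            if layer == "gene_regulatory" and "tf" not in self._roles[s]:
                raise QuadchainError(f"gene_regulatory edge from non-TF {s!r}")

    # -- queries ---------------------------------------------------------
    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, tags in self._roles.items() if role in tags)

    @property
    def ligands(self) -> list[str]:
        return self.nodes_with_role("ligand")

    @property
    def receptors(self) -> list[str]:
        return self.nodes_with_role("receptor")

    @property
    def tfs(self) -> list[str]:
        return self.nodes_with_role("tf")

    @property
    def target_genes(self) -> list[str]:
        return self.nodes_with_role("target")

    @property
    def nodes(self) -> list[str]:
        return sorted(self._roles)

    def roles_of(self, node: str) -> frozenset[str]:
        return frozenset(self._roles.get(node, frozenset()))

    def layer_edges(self, *layers: str) -> pd.DataFrame:
        return self.edges[self.edges["layer"].isin(layers)].reset_index(drop=True)

    def to_networkx(self, *layers: str):
        """Directed graph over the requested layers (all by default)."""
        import networkx as nx

        sub = self.layer_edges(*(layers or LAYERS))
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in sub.iterrows():
            g.add_edge(row["source"], row["target"],
                       weight=float(row["weight"]), layer=row["layer"])
        return g

    def lr_pairs(self) -> pd.DataFrame:
        lr = self.layer_edges("lr")
        return lr.rename(columns={"source": "ligand", "target": "receptor"})[
            ["ligand", "receptor"]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PriorNetwork):
            return NotImplemented
        a = self.edges.sort_values(["layer", "source", "target"]).reset_index(drop=True)
        b = other.edges.sort_values(["layer", "source", "target"]).reset_index(drop=True)
        return a.equals(b) and self._roles == other._roles


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise QuadchainError(f"cell table missing columns {missing}")
    bad = sorted(set(cells["condition"]) - set(CONDITIONS))
    if bad:
        raise QuadchainError(f"unknown condition(s) {bad}; vocabulary is {CONDITIONS}")
    if cells["cell_id"].duplicated().any():
        raise QuadchainError("duplicate cell_id in cell table")
    return cells


def validate_survival_table(surv: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in surv.columns]
    if missing:
        raise QuadchainError(f"survival table missing columns {missing}")
    if (surv["time"] <= 0).any():
        raise QuadchainError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise QuadchainError("event indicator must be 0/1")
    return surv
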