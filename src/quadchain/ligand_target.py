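"""Prior-network diffusion scoring of ligand->target regulatory potential.

A personalized PageRank restarted at the ligand walks the lr + signaling
layers; the walk mass arriving at transcription factors is then propagated
through out-weight-normalized TF->gene edges to produce per-gene potentials.
Signaling paths are extracted exactly over the layered DAG.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import PriorNetwork, QuadchainError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PotentialVector:
    ligand: str
    scores: dict[str, float]  # gene -> potential, 0 when unreachable


@dataclass(frozen=True)
class SignalingPath:
    ligand: str
    receptor: str
    tf: str
    target: str
    weight: float  # product of edge weights along the path
    path: tuple[str, ...]


def _walk_matrix(prior: PriorNetwork):
    """Row-stochastic transition matrix over the lr+signaling node set."""
    edges = prior.layer_edges("lr", "signaling")
    nodes = sorted(set(edges["source"]) | set(edges["target"]) | set(prior.ligands))
    idx = {n: i for i, n in enumerate(nodes)}
    mat = np.zeros((len(nodes), len(nodes)))
    for _, row in edges.iterrows():
        mat[idx[row["source"]], idx[row["target"]]] += float(row["weight"])
    out = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(out > 0, mat / np.maximum(out, 1e-300), 0.0)
    dangling = (out.ravel() == 0)
    return nodes, idx, trans, dangling


def regulatory_potential(prior: PriorNetwork, ligand: str, damping: float = 0.85,
                         tol: float = 1e-10, max_iter: int = 10000
                         ) -> PotentialVector:
    """Restart-at-ligand walk scores propagated to gene_regulatory targets.

    Power iteration of p <- (1 - d) e + d (P^T p + dangling mass * e), where
    e is the indicator of the ligand; the potential of gene g is
    sum_tf p[tf] * w(tf -> g) / sum_g' w(tf -> g').
    """
    if "ligand" not in prior.roles_of(ligand):
        raise QuadchainError(f"{ligand!r} is not a ligand in the prior network")
    nodes, idx, trans, dangling = _walk_matrix(prior)
    genes = prior.target_genes

    e = np.zeros(len(nodes))
    e[idx[ligand]] = 1.0
    p = e.copy()
    for _ in range(max_iter):
        new = (1 - damping) * e + damping * (trans.T @ p + p[dangling].sum() * e)
        if np.abs(new - p).sum() < tol:
            p = new
            break
        p = new
    else:
        raise QuadchainError(
            f"power iteration did not converge in {max_iter} iterations")

    gr = prior.layer_edges("gene_regulatory")
    tf_out = gr.groupby("source")["weight"].sum()
    scores = {g: 0.0 for g in genes}
    for _, row in gr.iterrows():
        tf = row["source"]
        if tf not in idx:
            continue
        scores[row["target"]] += float(p[idx[tf]]) * float(row["weight"]) / float(tf_out[tf])
    return PotentialVector(ligand=ligand, scores=scores)


@dataclass(frozen=True)
class LigandActivity:
    ligand: str
    activity: float


def rank_ligands(potentials: Sequence[PotentialVector], receiver_degs: Iterable[str],
                 universe: Iterable[str], top_n: int = 30) -> list[LigandActivity]:
    """Rank ligands by Pearson correlation of potential with the DEG indicator.

    The correlation is taken over the sorted gene universe; a constant
    potential vector gets activity 0. Ties break by ligand name.
    """
    universe = sorted(set(universe))
    degs = set(receiver_degs)
    if not degs:
        raise QuadchainError("no receiver signal: empty DEG set")
    if not degs <= set(universe):
        extra = sorted(degs - set(universe))[:5]
        raise QuadchainError(f"receiver DEGs outside universe, e.g. {extra}")
    if not potentials:
        raise QuadchainError("need at least one ligand potential")

    indicator = np.array([1.0 if g in degs else 0.0 for g in universe])
    out = []
    for pot in potentials:
        vec = np.array([pot.scores.get(g, 0.0) for g in universe])
        if np.ptp(vec) == 0 or np.ptp(indicator) == 0:
            act = 0.0
        else:
            act = float(np.corrcoef(vec, indicator)[0, 1])
        out.append(LigandActivity(ligand=pot.ligand, activity=act))
    out.sort(key=lambda a: (-a.activity, a.ligand))
    return out[:top_n]


def extract_paths(prior: PriorNetwork, ligand: str, receptors: Iterable[str],
                  targets: Iterable[str], k_per_target: int = 1
                  ) -> list[SignalingPath]:
    """Best ligand->receptor->(signaling)->TF->target paths per target.

    Exact k-best search by weight product (Yen's algorithm on -log weights
    over the layered DAG). The first hop is restricted to the supplied
    receptor set; targets with no admissible path are dropped with a warning.
    """
    if k_per_target < 1:
        raise QuadchainError("k_per_target must be >= 1")
    if "ligand" not in prior.roles_of(ligand):
        raise QuadchainError(f"{ligand!r} is not a ligand in the prior network")
    receptors = set(receptors)
    g = nx.DiGraph()
    for _, row in prior.edges.iterrows():
        s, t, w, layer = row["source"], row["target"], float(row["weight"]), row["layer"]
        if layer == "lr" and (s != ligand or t not in receptors):
            continue
        g.add_edge(s, t, weight=w, cost=-math.log(w))

    out: list[SignalingPath] = []
    for target in sorted(set(targets)):
        if target not in g or ligand not in g:
            log.warning("target %s: no path from %s in prior; dropped", target, ligand)
            continue
        try:
            gen = nx.shortest_simple_paths(g, ligand, target, weight="cost")
            found = 0
            for path in gen:
                if len(path) < 4:
                    continue
                weight = 1.0
                for u, v in zip(path, path[1:]):
                    weight *= g[u][v]["weight"]
                out.append(SignalingPath(ligand=ligand, receptor=path[1],
                                         tf=path[-2], target=target,
                                         weight=weight, path=tuple(path)))
                found += 1
                if found >= k_per_target:
                    break
            if found == 0:
                log.warning("target %s: no quad path from %s; dropped", target, ligand)
        except nx.NetworkXNoPath:
            log.warning("target %s: no path from %s in prior; dropped", target, ligand)
    return out
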