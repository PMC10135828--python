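"""Synthetic ground-truth generators.

Produces layered prior networks, planted ligand->receptor->TF->target
cascades, multi-condition negative-binomial single-cell counts in which the
cascades are active with known effect sizes, and exponential survival
cohorts. Every generator takes an explicit seed and owns its RNG stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (CONDITIONS, CountMatrix, PriorNetwork, QuadchainError,
                        validate_cell_table)

log = logging.getLogger(__name__)

MITO_PREFIX = "MT-"

#: Presets for assigning active conditions to planted cascades.
ACTIVE_MAP_PRESETS = {
    "tLung-only": ({"tLung"},),
    "tL/B-only": ({"tL/B"},),
    "shared": ({"tLung", "tL/B"},),
    "cycle": ({"tLung"}, {"tL/B"}, {"tLung", "tL/B"}),
}


@dataclass(frozen=True)
class Cascade:
    """One planted regulatory chain with its full prior path."""

    ligand: str
    receptor: str
    tf: str
    targets: tuple[str, ...]
    path: tuple[str, ...]  # full ligand -> ... -> tf -> target path
    active_conditions: frozenset[str]

    def chains(self) -> set[tuple[str, str, str, str]]:
        return {(self.ligand, self.receptor, self.tf, t) for t in self.targets}


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth consumed by tests and the acceptance suite only."""

    cascades: tuple[Cascade, ...]
    effect_log2fc: float
    baseline_mean: float
    dispersion: float
    seed: int

    def all_chains(self) -> set[tuple[str, str, str, str]]:
        out: set[tuple[str, str, str, str]] = set()
        for c in self.cascades:
            out |= c.chains()
        return out

    def chains_active_between(self, reference: str, interest: str
                              ) -> dict[tuple[str, str, str, str], str]:
        """Chains differentially active between two conditions.

        Returns quad -> expected direction in ``interest`` relative to
        ``reference`` ("up" or "down"). A cascade active (or inactive) in
        both conditions is not differential and is omitted.
        """
        out: dict[tuple[str, str, str, str], str] = {}
        for c in self.cascades:
            in_ref = reference in c.active_conditions
            in_oi = interest in c.active_conditions
            if in_ref == in_oi:
                continue
            direction = "up" if in_oi else "down"
            for quad in c.chains():
                out[quad] = direction
        return out


def _bernoulli_edges(rng: np.random.Generator, sources: Sequence[str],
                     targets: Sequence[str], density: float) -> list[tuple[str, str]]:
    mask = rng.random((len(sources), len(targets))) < density
    return [(sources[i], targets[j]) for i, j in zip(*np.nonzero(mask))]


def generate_prior_network(n_ligands: int, n_receptors: int, n_signaling: int,
                           n_tfs: int, n_genes: int, edge_density: float,
                           seed: int) -> PriorNetwork:
    """Random layered prior: L -> R -> (S...) -> TF -> gene.

    Each admissible layer edge is drawn independently with probability
    ``edge_density``; weights are uniform(0.1, 1). Ligands left without a
    path to any gene get a minimal connecting path added (logged, never
    silently disconnected).
    """
    for name, v in [("n_ligands", n_ligands), ("n_receptors", n_receptors),
                    ("n_tfs", n_tfs), ("n_genes", n_genes)]:
        if v < 1:
            raise QuadchainError(f"{name} must be >= 1, got {v}")
    if n_signaling < 0:
        raise QuadchainError("n_signaling must be >= 0")
    if not 0 < edge_density <= 1:
        raise QuadchainError("edge_density must be in (0, 1]")

    rng = np.random.default_rng(seed)
    ligands = [f"L{i + 1}" for i in range(n_ligands)]
    receptors = [f"R{i + 1}" for i in range(n_receptors)]
    signaling = [f"S{i + 1}" for i in range(n_signaling)]
    tfs = [f"TF{i + 1}" for i in range(n_tfs)]
    genes = [f"G{i + 1}" for i in range(n_genes)]

    pairs: list[tuple[str, str, str]] = []
    for s, t in _bernoulli_edges(rng, ligands, receptors, edge_density):
        pairs.append((s, t, "lr"))
    if n_signaling:
        for s, t in _bernoulli_edges(rng, receptors, signaling, edge_density):
            pairs.append((s, t, "signaling"))
        for s, t in _bernoulli_edges(rng, signaling, tfs, edge_density):
            pairs.append((s, t, "signaling"))
    # direct receptor->TF shortcuts keep 3-hop chains representable
    for s, t in _bernoulli_edges(rng, receptors, tfs, edge_density):
        pairs.append((s, t, "signaling"))
    for s, t in _bernoulli_edges(rng, tfs, genes, edge_density):
        pairs.append((s, t, "gene_regulatory"))

    edge_set = {(s, t, l) for s, t, l in pairs}

    def reaches_gene(extra: set[tuple[str, str, str]], ligand: str) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(ligands + receptors + signaling + tfs + genes)
        g.add_edges_from((s, t) for s, t, _ in edge_set | extra)
        reachable = nx.descendants(g, ligand)
        return any(t in reachable for t in genes)

    # minimal connectivity repair per disconnected ligand
    for ligand in ligands:
        if reaches_gene(set(), ligand):
            continue
        r = receptors[rng.integers(len(receptors))]
        tf = tfs[rng.integers(len(tfs))]
        g = genes[rng.integers(len(genes))]
        repair = set()
        if (ligand, r, "lr") not in edge_set:
            repair.add((ligand, r, "lr"))
        if not any(e[0] == r and e[2] == "signaling" for e in edge_set):
            repair.add((r, tf, "signaling"))
        elif not reaches_gene(repair, ligand):
            repair.add((r, tf, "signaling"))
        if not reaches_gene(repair, ligand):
            repair.add((tf, g, "gene_regulatory"))
        edge_set |= repair
        log.info("prior repair: connected ligand %s via %d edge(s)", ligand, len(repair))
        if not reaches_gene(set(), ligand):  # pragma: no cover - defensive
            raise QuadchainError(f"failed to connect ligand {ligand}")

    order = {"lr": 0, "signaling": 1, "gene_regulatory": 2}
    edge_list = sorted(edge_set, key=lambda e: (order[e[2]], e[0], e[1]))
    weights = np.round(rng.uniform(0.1, 1.0, size=len(edge_list)), 6)
    edges = pd.DataFrame(edge_list, columns=["source", "target", "layer"])
    edges["weight"] = weights
    roles = {s: frozenset({"signaling"}) for s in signaling}
    return PriorNetwork(edges[["source", "target", "weight", "layer"]], roles=roles)


def enumerate_quad_paths(prior: PriorNetwork) -> dict[tuple[str, str, str, str],
                                                      tuple[tuple[str, ...], float]]:
    """All distinct (ligand, receptor, tf, gene) quads realizable in the prior.

    For each quad, the maximum-weight-product path realizing it is kept.
    Exhaustive simple-path enumeration: intended for the small layered graphs
    the generator produces.
    """
    g = prior.to_networkx()
    quads: dict[tuple[str, str, str, str], tuple[tuple[str, ...], float]] = {}
    gene_set = set(prior.target_genes)
    for ligand in prior.ligands:
        for gene in gene_set:
            if gene not in g:
                continue
            try:
                paths = nx.all_simple_paths(g, ligand, gene, cutoff=6)
                for path in paths:
                    if len(path) < 4:
                        continue
                    weight = 1.0
                    for u, v in zip(path, path[1:]):
                        weight *= g.get_edge_data(u, v)["weight"]
                    quad = (path[0], path[1], path[-2], path[-1])
                    if quad not in quads or weight > quads[quad][1]:
                        quads[quad] = (tuple(path), weight)
            except nx.NodeNotFound:
                continue
    return quads


def _resolve_active_map(active_map, n_cascades: int) -> list[frozenset[str]]:
    if isinstance(active_map, str):
        try:
            cycle = ACTIVE_MAP_PRESETS[active_map]
        except KeyError:
            raise QuadchainError(
                f"unknown active_map preset {active_map!r}; "
                f"options: {sorted(ACTIVE_MAP_PRESETS)}") from None
        assignments = [frozenset(cycle[i % len(cycle)]) for i in range(n_cascades)]
    else:
        assignments = [frozenset(a) for a in active_map]
        if len(assignments) != n_cascades:
            raise QuadchainError(
                f"active_map has {len(assignments)} entries for {n_cascades} cascades")
    for a in assignments:
        bad = a - set(CONDITIONS)
        if bad:
            raise QuadchainError(f"active_map references unknown condition(s) {sorted(bad)}")
    return assignments


def generate_truth(prior: PriorNetwork, n_cascades: int, effect_log2fc: float,
                   active_map="cycle", seed: int = 0,
                   baseline_mean: float = 1.0, dispersion: float = 2.0,
                   distinct_roles: bool = True) -> PlantedTruth:
    """Sample ``n_cascades`` distinct planted quad-chains from the prior.

    Distinct (ligand, gene) endpoints are sampled without replacement; the
    cascade path is the maximum-weight-product realization of that endpoint
    pair, so a weight-driven path search can in principle recover it. With
    ``distinct_roles`` (default) no gene plays the same role in two
    cascades — cascades sharing e.g. a TF but differing in active conditions
    are co-expression-confounded by construction and make the ground truth
    unidentifiable for any observational method.
    """
    if effect_log2fc <= 0:
        raise QuadchainError("effect_log2fc must be > 0")
    if n_cascades < 0:
        raise QuadchainError("n_cascades must be >= 0")
    quads = enumerate_quad_paths(prior)
    if n_cascades > len(quads):
        raise QuadchainError(
            f"requested {n_cascades} cascades but the prior holds only "
            f"{len(quads)} distinct ligand->...->gene quads")
    assignments = _resolve_active_map(active_map, n_cascades)
    rng = np.random.default_rng(seed)

    # best path per (ligand, gene) endpoint; sample endpoints w/o replacement
    best: dict[tuple[str, str], tuple[tuple[str, ...], float]] = {}
    for (lig, _, _, gene), (path, w) in quads.items():
        key = (lig, gene)
        if key not in best or w > best[key][1]:
            best[key] = (path, w)
    endpoints = sorted(best)
    if n_cascades > len(endpoints):
        raise QuadchainError(
            f"requested {n_cascades} cascades but only {len(endpoints)} "
            f"distinct ligand->gene endpoints exist")
    order = rng.permutation(len(endpoints))
    picked: list[tuple[str, ...]] = []
    used: dict[int, set[str]] = {0: set(), 1: set(), 2: set(), 3: set()}
    for idx in order:
        lig, gene = endpoints[idx]
        path, _ = best[(lig, gene)]
        quad = (path[0], path[1], path[-2], gene)
        if distinct_roles and any(quad[i] in used[i] for i in range(4)):
            continue
        picked.append(path)
        for i in range(4):
            used[i].add(quad[i])
        if len(picked) == n_cascades:
            break
    if len(picked) < n_cascades:
        raise QuadchainError(
            f"could only sample {len(picked)} of {n_cascades} cascades with "
            f"distinct roles; the prior offers too few disjoint quad paths")
    cascades = []
    for path, active in zip(picked, assignments):
        cascades.append(Cascade(ligand=path[0], receptor=path[1], tf=path[-2],
                                targets=(path[-1],), path=path,
                                active_conditions=active))
    return PlantedTruth(cascades=tuple(cascades), effect_log2fc=float(effect_log2fc),
                        baseline_mean=float(baseline_mean),
                        dispersion=float(dispersion), seed=seed)


def default_design(n_cells: int = 300, n_patients: int = 3,
                   sender_type: str = "Tumor", receiver_type: str = "Macrophage",
                   conditions: Sequence[str] = CONDITIONS) -> pd.DataFrame:
    """Balanced cells-per-(type, condition, patient) design table."""
    rows = []
    for cond in conditions:
        for ctype in (sender_type, receiver_type):
            per = [n_cells // n_patients] * n_patients
            per[0] += n_cells - sum(per)
            for p in range(n_patients):
                rows.append({"cell_type": ctype, "condition": cond,
                             "patient_id": f"P_{cond}_{p + 1}", "n_cells": per[p]})
    return pd.DataFrame(rows)


def simulate_counts(prior: PriorNetwork, truth: PlantedTruth, design: pd.DataFrame,
                    baseline_mean: float | None = None,
                    dispersion: float | None = None, seed: int = 0,
                    sender_type: str = "Tumor", receiver_type: str = "Macrophage",
                    n_mito: int = 10, total_genes: int = 500
                    ) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted condition-specific cascades.

    In a condition where a cascade is active, the ligand mean is multiplied
    by ``2**effect`` in sender cells and the receptor/TF/target means by the
    same factor in receiver cells; everything else sits at baseline. The gene
    universe is the prior's nodes plus ``MT-`` mitochondrial genes and inert
    filler genes padded up to ``total_genes`` so that depth/gene-count QC at
    default thresholds passes the overwhelming majority of cells.
    """
    baseline_mean = truth.baseline_mean if baseline_mean is None else float(baseline_mean)
    dispersion = truth.dispersion if dispersion is None else float(dispersion)
    if baseline_mean <= 0 or dispersion <= 0:
        raise QuadchainError("baseline_mean and dispersion must be positive")
    need = {"cell_type", "condition", "patient_id", "n_cells"}
    if not need.issubset(design.columns):
        raise QuadchainError(f"design table needs columns {sorted(need)}")
    bad = sorted(set(design["condition"]) - set(CONDITIONS))
    if bad:
        raise QuadchainError(f"design references unknown condition(s) {bad}")
    types = set(design["cell_type"])
    if sender_type not in types or receiver_type not in types:
        raise QuadchainError(
            f"design must include sender {sender_type!r} and receiver {receiver_type!r}")

    prior_genes = prior.nodes
    mito = [f"{MITO_PREFIX}{i + 1}" for i in range(n_mito)]
    n_fill = max(0, total_genes - len(prior_genes) - n_mito)
    filler = [f"NOISE{i + 1}" for i in range(n_fill)]
    genes = prior_genes + mito + filler
    gi = {g: i for i, g in enumerate(genes)}

    # mito means chosen so the expected mitochondrial fraction is ~5%
    target_frac = 0.05
    other_mass = baseline_mean * (len(genes) - n_mito)
    mito_mean = target_frac * other_mass / ((1 - target_frac) * n_mito)

    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    cell_rows: list[dict] = []
    counter = 0
    for _, row in design.iterrows():
        n = int(row["n_cells"])
        if n <= 0:
            continue
        mu = np.full(len(genes), baseline_mean)
        mu[[gi[g] for g in mito]] = mito_mean
        cond, ctype = row["condition"], row["cell_type"]
        for cascade in truth.cascades:
            if cond not in cascade.active_conditions:
                continue
            factor = 2.0 ** truth.effect_log2fc
            if ctype == sender_type:
                mu[gi[cascade.ligand]] *= factor
            elif ctype == receiver_type:
                for g in (cascade.receptor, cascade.tf, *cascade.targets):
                    mu[gi[g]] *= factor
        p = dispersion / (dispersion + mu)
        block = rng.negative_binomial(dispersion, p[:, None], size=(len(genes), n))
        blocks.append(block.astype(np.int32))
        for _ in range(n):
            counter += 1
            cell_rows.append({"cell_id": f"C{counter:06d}", "cell_type": ctype,
                              "condition": cond, "patient_id": row["patient_id"]})

    if not blocks:
        raise QuadchainError("design produced zero cells")
    dense = np.concatenate(blocks, axis=1)
    counts = sp.csr_matrix(dense)
    cells = pd.DataFrame(cell_rows)
    depth = np.asarray(dense.sum(axis=0)).ravel()
    mito_idx = [gi[g] for g in mito]
    mito_counts = dense[mito_idx].sum(axis=0)
    cells["n_umi"] = depth.astype(int)
    cells["n_genes"] = (dense > 0).sum(axis=0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        cells["pct_mito"] = np.where(depth > 0, mito_counts / np.maximum(depth, 1), 0.0)
    cm = CountMatrix(genes, cells["cell_id"].tolist(), counts)
    validate_cell_table(cells)
    return cm, cells


def simulate_survival(n_patients: int, beta: float, baseline_hazard: float = 0.01,
                      censor_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Exponential survival cohort: hazard = baseline * exp(beta * biomarker).

    Biomarkers are uniform(0, 1) (a proportion-like covariate). Censoring is
    uniform(0, u) with u tuned by bisection so the expected censored fraction
    matches ``censor_rate``.
    """
    if n_patients < 10:
        raise QuadchainError("n_patients must be >= 10")
    if not 0 <= censor_rate < 1:
        raise QuadchainError("censor_rate must be in [0, 1)")
    if baseline_hazard <= 0:
        raise QuadchainError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    biomarker = rng.uniform(0, 1, n_patients)
    hazard = baseline_hazard * np.exp(beta * biomarker)
    t_event = rng.exponential(1.0 / hazard)

    if censor_rate == 0:
        time, event = t_event, np.ones(n_patients, dtype=int)
    else:
        def censored_frac(u: float) -> float:
            lam_u = hazard * u
            return float(np.mean((1 - np.exp(-lam_u)) / lam_u))

        lo, hi = 1e-9, 1.0
        while censored_frac(hi) > censor_rate:
            hi *= 2
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_frac(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        u = 0.5 * (lo + hi)
        t_cens = rng.uniform(0, u, n_patients)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    return pd.DataFrame({
        "patient_id": [f"PT{i + 1:04d}" for i in range(n_patients)],
        "time": np.maximum(time, np.finfo(float).tiny),
        "event": event,
        "biomarker": biomarker,
    })
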