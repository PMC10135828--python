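"""Consensus assembly of ligand->receptor->TF->target networks.

Network 1.0 collects diffusion-derived quad-chains; 2.0 keeps chains whose
L-R pair survives the interaction-mean screen; 3.0 keeps chains whose
TF-target pair is regulon-supported; 4.0 keeps chains whose ligand is
differentially expressed in the sender and at least one downstream element
in the receiver. The chain sets are monotone: 4.0 <= 3.0 <= 2.0 <= 1.0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datatypes import QuadchainError
from .ligand_target import SignalingPath
from .regulon import Regulon, regulon_pairs

log = logging.getLogger(__name__)

Quad = tuple[str, str, str, str]


@dataclass(frozen=True)
class Chain:
    ligand: str
    receptor: str
    tf: str
    target: str
    weight: float
    lr_verified: bool = False
    tf_verified: bool = False
    deg_passed: bool = False
    direction: str = "na"  # up / down / na (receiver-side DE sign)

    def __post_init__(self) -> None:
        if len({self.ligand, self.receptor, self.tf, self.target}) != 4:
            raise QuadchainError(
                f"chain roles must be distinct genes: "
                f"{(self.ligand, self.receptor, self.tf, self.target)}")
        if self.direction not in ("up", "down", "na"):
            raise QuadchainError(f"invalid direction {self.direction!r}")

    @property
    def quad(self) -> Quad:
        return (self.ligand, self.receptor, self.tf, self.target)


@dataclass(frozen=True)
class QuadNetwork:
    version: str  # "1.0" .. "4.0"
    condition_reference: str
    condition_oi: str
    sender: str
    receiver: str
    chains: tuple[Chain, ...]

    def __post_init__(self) -> None:
        if self.version not in ("1.0", "2.0", "3.0", "4.0"):
            raise QuadchainError(f"invalid network version {self.version!r}")

    def quads(self) -> set[Quad]:
        return {c.quad for c in self.chains}

    def __len__(self) -> int:
        return len(self.chains)


def _sorted_chains(chains: Iterable[Chain]) -> tuple[Chain, ...]:
    return tuple(sorted(chains, key=lambda c: c.quad))


def build_network1(paths: Sequence[SignalingPath], condition_reference: str,
                   condition_oi: str, sender: str, receiver: str) -> QuadNetwork:
    """Deduplicated Network 1.0 from extracted signaling paths."""
    if not paths:
        raise QuadchainError("cannot build Network 1.0 from zero chains")
    best: dict[Quad, Chain] = {}
    for p in paths:
        quad = (p.ligand, p.receptor, p.tf, p.target)
        if quad not in best or p.weight > best[quad].weight:
            best[quad] = Chain(ligand=p.ligand, receptor=p.receptor, tf=p.tf,
                               target=p.target, weight=float(p.weight))
    return QuadNetwork(version="1.0", condition_reference=condition_reference,
                       condition_oi=condition_oi, sender=sender,
                       receiver=receiver, chains=_sorted_chains(best.values()))


def verify_lr(net1: QuadNetwork, scores: pd.DataFrame) -> QuadNetwork:
    """Network 2.0: keep chains whose (ligand, receptor) pair is retained.

    ``scores`` is an interaction-score table with columns ligand, receptor,
    retained (the strict mean > 0 rule).
    """
    if net1.version != "1.0":
        raise QuadchainError(f"verify_lr expects version 1.0, got {net1.version}")
    retained = {(r["ligand"], r["receptor"])
                for _, r in scores.iterrows() if bool(r["retained"])}
    kept = [replace(c, lr_verified=True) for c in net1.chains
            if (c.ligand, c.receptor) in retained]
    if not kept:
        log.warning("Network 2.0 is empty: no L-R pair passed verification")
    return replace(net1, version="2.0", chains=_sorted_chains(kept))


def verify_tf(net2: QuadNetwork, regulons: Mapping[str, Regulon]) -> QuadNetwork:
    """Network 3.0: keep chains whose (tf, target) pair is regulon-supported."""
    if net2.version != "2.0":
        raise QuadchainError(f"verify_tf expects version 2.0, got {net2.version}")
    supported = regulon_pairs(dict(regulons))
    kept = [replace(c, tf_verified=True) for c in net2.chains
            if (c.tf, c.target) in supported]
    if not kept:
        log.warning("Network 3.0 is empty: no TF-target pair is regulon-supported")
    return replace(net2, version="3.0", chains=_sorted_chains(kept))


def deg_filter(net3: QuadNetwork, sender_degs: pd.DataFrame,
               receiver_degs: pd.DataFrame, alpha: float = 0.05) -> QuadNetwork:
    """Network 4.0: ligand DE in sender and >= 1 downstream element DE in receiver.

    The chain direction is the receiver-side DE sign of the most significant
    differential element among receptor, TF and target.
    """
    if net3.version != "3.0":
        raise QuadchainError(f"deg_filter expects version 3.0, got {net3.version}")
    for name, table in (("sender", sender_degs), ("receiver", receiver_degs)):
        if table is None or not {"gene", "p_adj", "direction"}.issubset(table.columns):
            raise QuadchainError(f"missing or malformed {name} DEG table")
    sender_de = set(sender_degs.loc[sender_degs["p_adj"] < alpha, "gene"])
    recv = receiver_degs[receiver_degs["p_adj"] < alpha].set_index("gene")

    kept = []
    for c in net3.chains:
        if c.ligand not in sender_de:
            continue
        downstream = [g for g in (c.receptor, c.tf, c.target) if g in recv.index]
        if not downstream:
            continue
        top = min(downstream, key=lambda g: (float(recv.loc[g, "p_adj"]), g))
        kept.append(replace(c, deg_passed=True,
                            direction=str(recv.loc[top, "direction"])))
    return replace(net3, version="4.0", chains=_sorted_chains(kept))


def count_signals(net4: QuadNetwork) -> int:
    """Distinct genes appearing as receptor, TF or target (ligands excluded)."""
    if net4.version != "4.0":
        raise QuadchainError(f"count_signals expects version 4.0, got {net4.version}")
    genes: set[str] = set()
    for c in net4.chains:
        genes.update((c.receptor, c.tf, c.target))
    return len(genes)


def stage_networks(net4: QuadNetwork) -> dict[str, tuple[Chain, ...]]:
    """Split a 4.0 network into per-stage chain sets by receiver DE direction.

    Chains up in the condition of interest belong to the interest stage's
    network; chains down belong to the reference stage's.
    """
    if net4.version != "4.0":
        raise QuadchainError(f"stage_networks expects version 4.0, got {net4.version}")
    out = {net4.condition_reference: [], net4.condition_oi: []}
    for c in net4.chains:
        stage = net4.condition_oi if c.direction == "up" else net4.condition_reference
        out[stage].append(c)
    return {k: _sorted_chains(v) for k, v in out.items()}


def compare_stage_networks(net4_a: QuadNetwork, net4_b: QuadNetwork) -> dict:
    """Exact set partition of two 4.0 networks on their quad-chains."""
    for net in (net4_a, net4_b):
        if net.version != "4.0":
            raise QuadchainError("comparison requires version 4.0 networks")
    if (net4_a.sender, net4_a.receiver) != (net4_b.sender, net4_b.receiver):
        raise QuadchainError("networks have mismatched sender/receiver cell types")
    qa, qb = net4_a.quads(), net4_b.quads()
    dir_a = {c.quad: c.direction for c in net4_a.chains}
    dir_b = {c.quad: c.direction for c in net4_b.chains}
    direction_rows = []
    for quad in sorted(qa | qb):
        direction_rows.append({
            "ligand": quad[0], "receptor": quad[1], "tf": quad[2], "target": quad[3],
            "direction_a": dir_a.get(quad, "na"),
            "direction_b": dir_b.get(quad, "na"),
        })
    return {
        "shared": sorted(qa & qb),
        "a_specific": sorted(qa - qb),
        "b_specific": sorted(qb - qa),
        "directions": pd.DataFrame(direction_rows),
    }


# -- serialization -------------------------------------------------------

def network_to_dict(net: QuadNetwork) -> dict:
    return {
        "version": net.version,
        "condition_reference": net.condition_reference,
        "condition_oi": net.condition_oi,
        "sender": net.sender,
        "receiver": net.receiver,
        "chains": [
            {"ligand": c.ligand, "receptor": c.receptor, "tf": c.tf,
             "target": c.target, "weight": c.weight,
             "lr_verified": c.lr_verified, "tf_verified": c.tf_verified,
             "deg_passed": c.deg_passed, "direction": c.direction}
            for c in net.chains
        ],
    }


def network_from_dict(data: Mapping) -> QuadNetwork:
    chains = tuple(Chain(**c) for c in data["chains"])
    return QuadNetwork(version=data["version"],
                       condition_reference=data["condition_reference"],
                       condition_oi=data["condition_oi"], sender=data["sender"],
                       receiver=data["receiver"], chains=_sorted_chains(chains))


def write_network_json(net: QuadNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_network_json(path) -> QuadNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def network_to_edge_table(net: QuadNetwork) -> pd.DataFrame:
    """Flat edge list: one row per chain hop, for spreadsheet users."""
    rows = []
    for c in net.chains:
        flags = f"lr={int(c.lr_verified)};tf={int(c.tf_verified)};deg={int(c.deg_passed)}"
        for role_src, src, role_dst, dst in (
                ("ligand", c.ligand, "receptor", c.receptor),
                ("receptor", c.receptor, "tf", c.tf),
                ("tf", c.tf, "target", c.target)):
            rows.append({"stage": f"{net.condition_reference}->{net.condition_oi}",
                         "version": net.version, "role_src": role_src, "src": src,
                         "role_dst": role_dst, "dst": dst, "weight": c.weight,
                         "direction": c.direction, "flags": flags})
    return pd.DataFrame(rows)
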