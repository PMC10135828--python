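import json

import numpy as np
import pandas as pd
import pytest

from quadchain import consensus as cs
from quadchain.datatypes import QuadchainError
from quadchain.ligand_target import SignalingPath
from quadchain.regulon import Regulon


def path(l, r, t, g, w=0.5):
    return SignalingPath(ligand=l, receptor=r, tf=t, target=g, weight=w,
                         path=(l, r, t, g))


def net1_from(paths):
    return cs.build_network1(paths, "nLung", "tLung", "Tumor", "Macrophage")


def deg_table(rows):
    """rows: (gene, p_adj, direction)"""
    return pd.DataFrame([{"gene": g, "p": p, "p_adj": p, "direction": d}
                         for g, p, d in rows],
                        columns=["gene", "p", "p_adj", "direction"])


def scores_for(pairs, retained=True):
    return pd.DataFrame([{"ligand": l, "receptor": r, "mean": 1.0,
                          "retained": retained} for l, r in pairs])


FOUR_PATHS = [
    path("L1", "R1", "TF1", "G1"),
    path("L1", "R1", "TF1", "G2"),
    path("L2", "R2", "TF2", "G3"),
    path("L2", "R2", "TF2", "G4"),
]


class TestBuildNetwork1:
    def test_duplicates_removed(self):
        net = net1_from([path("L1", "R1", "TF1", "G1", 0.3),
                         path("L1", "R1", "TF1", "G1", 0.7),
                         path("L2", "R2", "TF2", "G2")])
        assert len(net) == 2
        kept = {c.quad: c.weight for c in net.chains}
        assert kept[("L1", "R1", "TF1", "G1")] == 0.7  # best weight kept

    def test_flags_all_false(self):
        net = net1_from(FOUR_PATHS)
        assert all(not (c.lr_verified or c.tf_verified or c.deg_passed)
                   for c in net.chains)

    def test_empty_errors(self):
        with pytest.raises(QuadchainError):
            net1_from([])

    def test_json_round_trip_lossless(self, tmp_path):
        net = net1_from(FOUR_PATHS)
        fp = tmp_path / "net.json"
        cs.write_network_json(net, fp)
        back = cs.read_network_json(fp)
        assert back == net
        # canonical: sorted keys, stable bytes
        cs.write_network_json(back, tmp_path / "net2.json")
        assert fp.read_text() == (tmp_path / "net2.json").read_text()


class TestVerifyLR:
    def test_empty_retained_empty_network(self):
        net2 = cs.verify_lr(net1_from(FOUR_PATHS), scores_for([]))
        assert len(net2) == 0
        assert net2.version == "2.0"

    def test_partial_retention_matches_set_difference(self):
        """Oracle: brute-force recomputation of surviving chains."""
        net1 = net1_from(FOUR_PATHS)
        scores = scores_for([("L1", "R1")])
        net2 = cs.verify_lr(net1, scores)
        expected = {c.quad for c in net1.chains
                    if (c.quad[0], c.quad[1]) in {("L1", "R1")}}
        assert net2.quads() == expected
        assert all(c.lr_verified for c in net2.chains)

    def test_never_grows(self):
        net1 = net1_from(FOUR_PATHS)
        scores = scores_for([("L1", "R1"), ("L2", "R2"), ("L9", "R9")])
        assert len(cs.verify_lr(net1, scores)) <= len(net1)

    def test_unretained_scores_ignored(self):
        net1 = net1_from(FOUR_PATHS)
        scores = scores_for([("L1", "R1")], retained=False)
        assert len(cs.verify_lr(net1, scores)) == 0

    def test_wrong_version_rejected(self):
        net2 = cs.verify_lr(net1_from(FOUR_PATHS), scores_for([("L1", "R1")]))
        with pytest.raises(QuadchainError):
            cs.verify_lr(net2, scores_for([("L1", "R1")]))


def all_verified_net2(paths=FOUR_PATHS):
    net1 = net1_from(paths)
    return cs.verify_lr(net1, scores_for([("L1", "R1"), ("L2", "R2")]))


class TestVerifyTF:
    def test_empty_regulons_empty_network(self):
        net3 = cs.verify_tf(all_verified_net2(), {})
        assert len(net3) == 0 and net3.version == "3.0"

    def test_supported_chains_survive(self):
        regs = {"TF1": Regulon("TF1", {"G1": 0.9}),
                "TF2": Regulon("TF2", {"G3": 0.8})}
        net3 = cs.verify_tf(all_verified_net2(), regs)
        assert net3.quads() == {("L1", "R1", "TF1", "G1"),
                                ("L2", "R2", "TF2", "G3")}
        assert all(c.tf_verified for c in net3.chains)

    def test_idempotent(self):
        regs = {"TF1": Regulon("TF1", {"G1": 0.9})}
        net3 = cs.verify_tf(all_verified_net2(), regs)
        again = cs.verify_tf(
            cs.QuadNetwork(version="2.0", condition_reference="nLung",
                           condition_oi="tLung", sender="Tumor",
                           receiver="Macrophage", chains=net3.chains), regs)
        assert again.quads() == net3.quads()


def net3_all(paths=FOUR_PATHS):
    regs = {"TF1": Regulon("TF1", {"G1": 0.9, "G2": 0.9}),
            "TF2": Regulon("TF2", {"G3": 0.9, "G4": 0.9})}
    return cs.verify_tf(all_verified_net2(paths), regs)


class TestDegFilter:
    def test_no_de_genes_empty(self):
        net4 = cs.deg_filter(net3_all(), deg_table([]), deg_table([]))
        assert len(net4) == 0 and net4.version == "4.0"

    def test_ligand_and_downstream_required(self):
        sender = deg_table([("L1", 0.001, "up")])
        receiver = deg_table([("G1", 0.001, "up")])
        net4 = cs.deg_filter(net3_all(), sender, receiver)
        assert net4.quads() == {("L1", "R1", "TF1", "G1")}
        c = net4.chains[0]
        assert c.deg_passed and c.direction == "up"
        # ligand DE alone is not enough
        net4b = cs.deg_filter(net3_all(), sender, deg_table([]))
        assert len(net4b) == 0
        # downstream DE alone is not enough
        net4c = cs.deg_filter(net3_all(), deg_table([]), receiver)
        assert len(net4c) == 0

    def test_direction_from_most_significant_receiver_element(self):
        sender = deg_table([("L1", 0.001, "up")])
        receiver = deg_table([("R1", 0.04, "up"), ("G1", 0.0001, "down")])
        net4 = cs.deg_filter(net3_all(), sender, receiver)
        assert net4.chains[0].direction == "down"

    def test_subset_of_net3(self):
        sender = deg_table([("L1", 0.001, "up"), ("L2", 0.001, "up")])
        receiver = deg_table([("G1", 0.001, "up"), ("TF2", 0.01, "down")])
        net3 = net3_all()
        net4 = cs.deg_filter(net3, sender, receiver)
        assert net4.quads() <= net3.quads()

    def test_missing_tables_error(self):
        with pytest.raises(QuadchainError):
            cs.deg_filter(net3_all(), None, deg_table([]))


class TestCountSignals:
    def test_single_chain_counts_three(self):
        net4 = cs.deg_filter(net3_all(), deg_table([("L1", 0.001, "up")]),
                             deg_table([("G1", 0.001, "up")]))
        assert cs.count_signals(net4) == 3

    def test_shared_tf_counted_once(self):
        paths = [path("L1", "R1", "TF1", "G1"), path("L1", "R2", "TF1", "G2")]
        net1 = net1_from(paths)
        net2 = cs.verify_lr(net1, scores_for([("L1", "R1"), ("L1", "R2")]))
        net3 = cs.verify_tf(net2, {"TF1": Regulon("TF1", {"G1": 1, "G2": 1})})
        net4 = cs.deg_filter(net3, deg_table([("L1", 0.001, "up")]),
                             deg_table([("G1", 0.001, "up"),
                                        ("G2", 0.001, "up")]))
        # R1, R2, TF1, G1, G2 -> 5 distinct signals, not 6
        assert cs.count_signals(net4) == 5

    def test_empty_network_zero(self):
        net4 = cs.deg_filter(net3_all(), deg_table([]), deg_table([]))
        assert cs.count_signals(net4) == 0


class TestMonotoneFilterChain:
    def test_subset_chain_invariant(self, prior, truth, normed, cells):
        from quadchain.pipeline import build_pair_network
        res = build_pair_network(normed, cells, prior, "nLung", "tLung",
                                 sender="Tumor", receiver="Macrophage",
                                 n_perm=100, seed=0)
        q1, q2 = res["net1"].quads(), res["net2"].quads()
        q3, q4 = res["net3"].quads(), res["net4"].quads()
        assert q4 <= q3 <= q2 <= q1
        assert all(c.lr_verified and c.tf_verified and c.deg_passed
                   for c in res["net4"].chains)


class TestStageNetworks:
    def test_split_by_direction(self):
        sender = deg_table([("L1", 0.001, "up"), ("L2", 0.001, "down")])
        receiver = deg_table([("G1", 0.001, "up"), ("G3", 0.001, "down")])
        net4 = cs.deg_filter(net3_all(), sender, receiver)
        split = cs.stage_networks(net4)
        assert {c.quad for c in split["tLung"]} == {("L1", "R1", "TF1", "G1")}
        assert {c.quad for c in split["nLung"]} == {("L2", "R2", "TF2", "G3")}


class TestCompareStageNetworks:
    @staticmethod
    def net4_with(quads, directions=None):
        directions = directions or {}
        chains = tuple(cs.Chain(*q, weight=0.5, lr_verified=True,
                                tf_verified=True, deg_passed=True,
                                direction=directions.get(q, "up"))
                       for q in quads)
        return cs.QuadNetwork(version="4.0", condition_reference="nLung",
                              condition_oi="tLung", sender="Tumor",
                              receiver="Macrophage", chains=chains)

    def test_identical_networks_no_specific(self):
        quads = [("L1", "R1", "TF1", "G1"), ("L2", "R2", "TF2", "G2")]
        cmp = cs.compare_stage_networks(self.net4_with(quads),
                                        self.net4_with(quads))
        assert cmp["a_specific"] == [] and cmp["b_specific"] == []
        assert len(cmp["shared"]) == 2

    def test_disjoint_networks_no_shared(self):
        a = self.net4_with([("L1", "R1", "TF1", "G1")])
        b = self.net4_with([("L2", "R2", "TF2", "G2")])
        cmp = cs.compare_stage_networks(a, b)
        assert cmp["shared"] == []
        assert len(cmp["a_specific"]) == 1 and len(cmp["b_specific"]) == 1

    def test_partition_sizes_sum_to_union(self):
        rng = np.random.default_rng(0)
        pool = [(f"L{i}", f"R{i}", f"TF{i}", f"G{i}") for i in range(10)]
        qa = [pool[i] for i in rng.choice(10, 6, replace=False)]
        qb = [pool[i] for i in rng.choice(10, 5, replace=False)]
        cmp = cs.compare_stage_networks(self.net4_with(qa), self.net4_with(qb))
        assert len(cmp["shared"]) + len(cmp["a_specific"]) + \
            len(cmp["b_specific"]) == len(set(qa) | set(qb))

    def test_mismatched_cell_types_error(self):
        a = self.net4_with([("L1", "R1", "TF1", "G1")])
        b = cs.QuadNetwork(version="4.0", condition_reference="nLung",
                           condition_oi="tLung", sender="Tumor", receiver="DC",
                           chains=a.chains)
        with pytest.raises(QuadchainError):
            cs.compare_stage_networks(a, b)


class TestChainInvariants:
    def test_distinct_roles_required(self):
        with pytest.raises(QuadchainError):
            cs.Chain("A", "A", "TF1", "G1", weight=0.5)

    def test_edge_table_three_rows_per_chain(self):
        net = net1_from(FOUR_PATHS)
        table = cs.network_to_edge_table(net)
        assert len(table) == 3 * len(net)
        assert set(table["role_src"]) == {"ligand", "receptor", "tf"}
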