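import networkx as nx
import numpy as np
import pandas as pd
import pytest

from quadchain import synthdata as sd
from quadchain.datatypes import QuadchainError


class TestGeneratePriorNetwork:
    def test_minimal_layered_graph_is_single_path(self):
        prior = sd.generate_prior_network(1, 1, 0, 1, 1, edge_density=1.0, seed=1)
        assert len(prior.edges) == 3
        assert set(map(tuple, prior.edges[["source", "target"]].values)) == {
            ("L1", "R1"), ("R1", "TF1"), ("TF1", "G1")}

    def test_same_seed_reproduces_edge_list(self):
        a = sd.generate_prior_network(4, 4, 6, 4, 30, 0.3, seed=5)
        b = sd.generate_prior_network(4, 4, 6, 4, 30, 0.3, seed=5)
        assert a.edges.equals(b.edges)

    def test_different_seed_differs(self):
        a = sd.generate_prior_network(4, 4, 6, 4, 30, 0.3, seed=5)
        b = sd.generate_prior_network(4, 4, 6, 4, 30, 0.3, seed=6)
        assert not a.edges.equals(b.edges)

    def test_every_ligand_reaches_a_gene_brute_force(self):
        """Oracle: exhaustive reachability on the raw digraph."""
        prior = sd.generate_prior_network(5, 5, 10, 5, 50, 0.2, seed=7)
        g = nx.DiGraph()
        g.add_nodes_from(prior.nodes)
        g.add_edges_from(map(tuple, prior.edges[["source", "target"]].values))
        genes = set(prior.target_genes)
        for ligand in prior.ligands:
            assert nx.descendants(g, ligand) & genes, f"{ligand} disconnected"

    @pytest.mark.parametrize("density", [0.01, 0.05])
    def test_repair_connects_sparse_priors(self, density):
        prior = sd.generate_prior_network(6, 6, 4, 6, 20, density, seed=11)
        g = prior.to_networkx()
        genes = set(prior.target_genes)
        for ligand in prior.ligands:
            assert nx.descendants(g, ligand) & genes

    def test_invariants(self):
        prior = sd.generate_prior_network(5, 5, 10, 5, 50, 0.2, seed=7)
        lr = prior.layer_edges("lr")
        assert lr["source"].str.startswith("L").all()
        assert lr["target"].str.startswith("R").all()
        gr = prior.layer_edges("gene_regulatory")
        assert gr["source"].str.startswith("TF").all()
        assert (prior.edges["weight"] > 0).all()
        assert (prior.edges["source"] != prior.edges["target"]).all()

    def test_bad_args_rejected(self):
        with pytest.raises(QuadchainError):
            sd.generate_prior_network(0, 1, 0, 1, 1, 0.5, seed=1)
        with pytest.raises(QuadchainError):
            sd.generate_prior_network(1, 1, 0, 1, 1, 0.0, seed=1)
        with pytest.raises(QuadchainError):
            sd.generate_prior_network(1, 1, 0, 1, 1, 1.5, seed=1)


class TestGenerateTruth:
    def test_zero_cascades_gives_empty_truth(self, prior):
        truth = sd.generate_truth(prior, 0, 2.0, seed=1)
        assert truth.cascades == ()
        assert truth.all_chains() == set()

    def test_cascade_paths_exist_in_prior(self, prior):
        """Oracle: membership check by exhaustive path enumeration."""
        truth = sd.generate_truth(prior, 3, 2.0, seed=3)
        assert len(truth.cascades) == 3
        assert len({c.chains().pop() for c in truth.cascades}) == 3
        g = prior.to_networkx()
        for c in truth.cascades:
            paths = list(nx.all_simple_paths(g, c.ligand, c.targets[0], cutoff=6))
            assert list(c.path) in [list(p) for p in paths], c
            assert c.path[1] == c.receptor and c.path[-2] == c.tf
            assert c.path[-1] == c.targets[0]

    def test_max_weight_path_selected(self, prior):
        """The planted path is the max-weight-product realization."""
        truth = sd.generate_truth(prior, 3, 2.0, seed=3)
        g = prior.to_networkx()
        for c in truth.cascades:
            full = list(c.path)
            w = np.prod([g[u][v]["weight"] for u, v in zip(full, full[1:])])
            for alt in nx.all_simple_paths(g, c.ligand, c.targets[0], cutoff=6):
                w_alt = np.prod([g[u][v]["weight"] for u, v in zip(alt, alt[1:])])
                assert w_alt <= w + 1e-12

    def test_distinct_roles(self, prior):
        truth = sd.generate_truth(prior, 3, 2.0, seed=3)
        for role in range(4):
            vals = [c.chains().pop()[role] for c in truth.cascades]
            assert len(set(vals)) == len(vals)

    def test_zero_effect_rejected(self, prior):
        with pytest.raises(QuadchainError):
            sd.generate_truth(prior, 1, 0.0, seed=1)

    def test_too_many_cascades_errors_with_deficit(self):
        tiny = sd.generate_prior_network(1, 1, 0, 1, 1, 1.0, seed=1)
        with pytest.raises(QuadchainError, match="1"):
            sd.generate_truth(tiny, 5, 2.0, seed=1)

    def test_active_map_presets_and_explicit(self, prior):
        t = sd.generate_truth(prior, 2, 2.0, active_map="tLung-only", seed=1)
        assert all(c.active_conditions == {"tLung"} for c in t.cascades)
        t = sd.generate_truth(prior, 2, 2.0,
                              active_map=[{"tLung"}, {"tL/B"}], seed=1)
        assert [set(c.active_conditions) for c in t.cascades] == \
            [{"tLung"}, {"tL/B"}]
        with pytest.raises(QuadchainError):
            sd.generate_truth(prior, 1, 2.0, active_map=[{"Mars"}], seed=1)


class TestSimulateCounts:
    def test_seed_reproducibility_bit_identical(self, prior, truth):
        design = sd.default_design(n_cells=20)
        a, ca = sd.simulate_counts(prior, truth, design, seed=9)
        b, cb = sd.simulate_counts(prior, truth, design, seed=9)
        assert (a.counts != b.counts).nnz == 0
        pd.testing.assert_frame_equal(ca, cb)

    def test_null_means_match_baseline(self, prior):
        """Oracle: NB closed-form mean within 3 MC standard errors."""
        empty = sd.generate_truth(prior, 0, 2.0, seed=1)
        design = pd.DataFrame([
            {"cell_type": "Tumor", "condition": "tLung", "patient_id": "P1",
             "n_cells": 500},
            {"cell_type": "Macrophage", "condition": "tLung", "patient_id": "P1",
             "n_cells": 500},
        ])
        counts, cells = sd.simulate_counts(prior, empty, design,
                                           baseline_mean=1.0, dispersion=2.0,
                                           seed=4)
        mat = np.asarray(counts.counts.todense())
        non_mito = [i for i, g in enumerate(counts.gene_ids)
                    if not g.startswith(sd.MITO_PREFIX)]
        mu, disp, n = 1.0, 2.0, 1000
        se = np.sqrt((mu + mu ** 2 / disp) / n)
        means = mat[non_mito].mean(axis=1)
        assert np.all(np.abs(means - mu) < 3.5 * se + 0.05)
        # NB variance check at pooled scale
        var = mat[non_mito].var(axis=1)
        assert abs(var.mean() - (mu + mu ** 2 / disp)) < 0.1

    def test_planted_effect_recovered(self, prior):
        """Oracle: empirical log2 ratio vs planted effect at 300 cells."""
        truth = sd.generate_truth(prior, 1, 2.0, active_map=[{"tLung"}], seed=3)
        casc = truth.cascades[0]
        design = sd.default_design(n_cells=300, n_patients=1,
                                   conditions=("nLung", "tLung"))
        counts, cells = sd.simulate_counts(prior, truth, design, seed=8)
        mat = np.asarray(counts.counts.todense())
        gi = counts.gene_index()

        def stratum_mean(gene, ctype, cond):
            mask = ((cells["cell_type"] == ctype)
                    & (cells["condition"] == cond)).to_numpy()
            return mat[gi[gene]][mask].mean()

        ratio = np.log2(stratum_mean(casc.ligand, "Tumor", "tLung")
                        / stratum_mean(casc.ligand, "Tumor", "nLung"))
        assert abs(ratio - 2.0) < 0.3
        for gene in (casc.receptor, casc.tf, *casc.targets):
            r = np.log2(stratum_mean(gene, "Macrophage", "tLung")
                        / stratum_mean(gene, "Macrophage", "nLung"))
            assert abs(r - 2.0) < 0.3

    def test_qc_passes_most_cells(self, counts, cells):
        from quadchain.preprocess import QCThresholds, qc_filter
        _, kept, report = qc_filter(counts, cells, QCThresholds())
        assert report["n_retained"] >= 0.95 * report["n_input"]

    def test_unknown_condition_rejected(self, prior, truth):
        design = pd.DataFrame([{"cell_type": "Tumor", "condition": "Mars",
                                "patient_id": "P1", "n_cells": 5}])
        with pytest.raises(QuadchainError):
            sd.simulate_counts(prior, truth, design, seed=1)

    def test_missing_receiver_rejected(self, prior, truth):
        design = pd.DataFrame([{"cell_type": "Tumor", "condition": "tLung",
                                "patient_id": "P1", "n_cells": 5}])
        with pytest.raises(QuadchainError):
            sd.simulate_counts(prior, truth, design, seed=1)


class TestNegativeBinomialMoments:
    def test_mean_variance_closed_form(self):
        """Invariant: NB sample moments match mu and mu + mu^2/disp."""
        rng = np.random.default_rng(0)
        mu, disp, n = 3.0, 2.0, 10000
        draws = rng.negative_binomial(disp, disp / (disp + mu), size=n)
        se_mean = np.sqrt((mu + mu ** 2 / disp) / n)
        assert abs(draws.mean() - mu) < 4 * se_mean
        assert abs(draws.var() - (mu + mu ** 2 / disp)) < 0.5


class TestSimulateSurvival:
    def test_no_censoring_all_events(self):
        surv = sd.simulate_survival(50, beta=0.0, censor_rate=0.0, seed=1)
        assert (surv["event"] == 1).all()
        assert (surv["time"] > 0).all()

    def test_censor_rate_approximate(self):
        surv = sd.simulate_survival(2000, beta=0.0, censor_rate=0.3, seed=2)
        assert abs((surv["event"] == 0).mean() - 0.3) < 0.05

    def test_protective_biomarker_orders_median_survival(self):
        """Oracle: closed-form hazard ordering under beta < 0."""
        surv = sd.simulate_survival(2000, beta=-1.0, censor_rate=0.0, seed=3)
        hi = surv[surv["biomarker"] > surv["biomarker"].median()]
        lo = surv[surv["biomarker"] <= surv["biomarker"].median()]
        assert hi["time"].median() > lo["time"].median()

    def test_null_beta_type_one_error(self):
        """Median-split log-rank rejects at ~5% under beta = 0."""
        from quadchain.population_stats import km_logrank
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            surv = sd.simulate_survival(40, beta=0.0, censor_rate=0.0,
                                        seed=1000 + rep)
            med = surv["biomarker"].median()
            groups = {p: ("hi" if b > med else "lo")
                      for p, b in zip(surv["patient_id"], surv["biomarker"])}
            if km_logrank(surv, groups).p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_preconditions(self):
        with pytest.raises(QuadchainError):
            sd.simulate_survival(5, beta=0.0, seed=1)
        with pytest.raises(QuadchainError):
            sd.simulate_survival(20, beta=0.0, censor_rate=1.0, seed=1)

    def test_seed_reproducibility(self):
        a = sd.simulate_survival(30, beta=-1.0, censor_rate=0.2, seed=5)
        b = sd.simulate_survival(30, beta=-1.0, censor_rate=0.2, seed=5)
        pd.testing.assert_frame_equal(a, b)
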