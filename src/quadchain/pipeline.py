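"""End-to-end orchestration: QC -> DEG -> L-R -> ranking -> paths -> regulons
-> Networks 1.0-4.0 -> stage comparison -> trajectory -> optional survival.

Every randomized stage derives its own seed from the config seed plus a
stable hash of the stage name, so stages are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import consensus, diffexpr, io, ligand_target, lr_test, population_stats
from . import preprocess, regulon, trajectory
from .datatypes import CONDITIONS, QuadchainError
from .preprocess import QCThresholds

log = logging.getLogger(__name__)

DEFAULT_PAIRS = (("nLung", "tLung"), ("tLung", "tL/B"))


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage RNG seed: config seed offset by a CRC32 of the stage name."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2 ** 32)


@dataclass
class PipelineConfig:
    counts_mtx: Path
    genes: Path
    barcodes: Path
    cells: Path
    prior: Path
    seed: int
    survival: Path | None = None
    genesets: Path | None = None
    sender: str = "Tumor"
    receiver: str = "Macrophage"
    condition_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    qc: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = 0.05
    top_n_ligands: int = 30
    n_perm: int = 1000
    top_k: int = 50
    min_importance: float = 0.1
    minprop: float = 0.1
    n_hvg: int = 3000
    n_states: int = 7
    k_per_target: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise QuadchainError("config must set a seed")
        paths = raw.get("paths", {})
        base = Path(path).parent
        def p(key, optional=False):
            if key not in paths:
                if optional:
                    return None
                raise QuadchainError(f"config paths must include {key!r}")
            return (base / paths[key]).resolve()
        th = raw.get("thresholds", {})
        qc = QCThresholds(
            mito_max=th.get("mito_max", 0.20),
            umi_range=tuple(th.get("umi_range", (100, 150000))),
            gene_range=tuple(th.get("gene_range", (200, 10000))))
        pairs = tuple(tuple(pr) for pr in raw.get("condition_pairs", DEFAULT_PAIRS))
        return cls(
            counts_mtx=p("counts_mtx"), genes=p("genes"), barcodes=p("barcodes"),
            cells=p("cells"), prior=p("prior"), survival=p("survival", True),
            genesets=p("genesets", True), seed=int(raw["seed"]),
            sender=raw.get("sender", "Tumor"),
            receiver=raw.get("receiver", "Macrophage"),
            condition_pairs=pairs, qc=qc,
            alpha=th.get("alpha", 0.05),
            top_n_ligands=th.get("top_n_ligands", 30),
            n_perm=th.get("n_perm", 1000),
            top_k=th.get("top_k", 50),
            min_importance=th.get("min_importance", 0.1),
            minprop=th.get("minprop", 0.1),
            n_hvg=th.get("n_hvg", 3000),
            n_states=th.get("n_states", 7),
            k_per_target=th.get("k_per_target", 1))

    def validate(self) -> None:
        for name in ("counts_mtx", "genes", "barcodes", "cells", "prior",
                     "survival", "genesets"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise QuadchainError(f"config path {name} does not exist: {path}")
        for ref, oi in self.condition_pairs:
            for c in (ref, oi):
                if c not in CONDITIONS:
                    raise QuadchainError(f"unknown condition {c!r} in condition_pairs")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _pair_tag(ref: str, oi: str) -> str:
    return f"{ref}_vs_{oi}".replace("/", "-")


def build_pair_network(normed, cells, prior, ref: str, oi: str, *,
                       sender: str, receiver: str, alpha: float = 0.05,
                       top_n_ligands: int = 30, n_perm: int = 1000,
                       top_k: int = 50, min_importance: float = 0.1,
                       k_per_target: int = 1, seed: int = 0) -> dict:
    """Networks 1.0-4.0 for one (reference, interest) condition pair.

    Returns the intermediate tables alongside the four networks so callers
    (CLI, acceptance suite) can inspect every stage.
    """
    def cells_of(ctype, conds):
        m = (cells["cell_type"] == ctype) & (cells["condition"].isin(conds))
        return cells.loc[m, "cell_id"].tolist()

    sender_degs = diffexpr.rank_sum_deg(
        normed, cells_of(sender, [oi]), cells_of(sender, [ref]))
    receiver_degs = diffexpr.rank_sum_deg(
        normed, cells_of(receiver, [oi]), cells_of(receiver, [ref]))

    # L-R screen among interest-stage cells
    pair_cells = cells[cells["condition"] == oi]
    scores = lr_test.permutation_test(
        normed, pair_cells, prior.lr_pairs(), sender, receiver,
        n_perm=n_perm, seed=derive_seed(seed, f"lrtest:{ref}:{oi}"))

    universe = set(prior.target_genes) & set(normed.gene_ids)
    recv_de = set(receiver_degs.loc[receiver_degs["p_adj"] < alpha, "gene"])
    target_degs = sorted(recv_de & universe)
    if not target_degs:
        raise QuadchainError(
            f"no receiver DEGs among prior target genes for pair ({ref}, {oi})")

    potentials = [ligand_target.regulatory_potential(prior, lig)
                  for lig in prior.ligands]
    activities = ligand_target.rank_ligands(
        potentials, target_degs, sorted(universe), top_n=top_n_ligands)
    pot_by_ligand = {p.ligand: p for p in potentials}

    retained = scores[scores["retained"]]
    paths = []
    for act in activities:
        receptors = set(retained.loc[retained["ligand"] == act.ligand, "receptor"])
        if not receptors:
            continue
        pot = pot_by_ligand[act.ligand]
        targets = [g for g in target_degs if pot.scores.get(g, 0.0) > 0]
        paths.extend(ligand_target.extract_paths(
            prior, act.ligand, receptors, targets, k_per_target=k_per_target))

    receiver_cells = cells_of(receiver, [ref, oi])
    importances = regulon.coexpression_importance(
        normed, receiver_cells, prior.tfs, prior.target_genes,
        method="correlation", seed=derive_seed(seed, f"regulon:{ref}:{oi}"))
    regulons = regulon.build_regulons(importances, top_k=top_k,
                                      min_importance=min_importance)

    net1 = consensus.build_network1(paths, ref, oi, sender, receiver)
    net2 = consensus.verify_lr(net1, scores)
    net3 = consensus.verify_tf(net2, regulons)
    net4 = consensus.deg_filter(net3, sender_degs, receiver_degs, alpha=alpha)
    return {
        "sender_degs": sender_degs, "receiver_degs": receiver_degs,
        "lr_scores": scores, "activities": activities, "regulons": regulons,
        "net1": net1, "net2": net2, "net3": net3, "net4": net4,
        "n_signals": consensus.count_signals(net4),
        "stage_networks": consensus.stage_networks(net4),
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, writing intermediates and a manifest to outdir."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "inputs": {name: {"path": str(getattr(config, name)),
                          "sha256": _hash_file(getattr(config, name))}
                   for name in ("counts_mtx", "genes", "barcodes", "cells", "prior")
                   },
        "stages": {},
    }
    if config.survival:
        manifest["inputs"]["survival"] = {"path": str(config.survival),
                                          "sha256": _hash_file(config.survival)}

    def record(stage: str, *files: str) -> None:
        manifest["stages"][stage] = sorted(files)
        log.info("stage %s complete: %s", stage, ", ".join(sorted(files)))

    try:
        counts = io.read_counts(config.counts_mtx, config.genes, config.barcodes)
        cells = io.read_cell_table(config.cells)
        prior = io.read_prior_network(config.prior)
        record("load")

        counts, cells, qc_report = preprocess.qc_filter(counts, cells, config.qc)
        (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        record("qc", "qc_report.json")

        normed = preprocess.normalize_log1p(counts)
        hvg = preprocess.select_hvg(normed, n=min(config.n_hvg, counts.n_genes))
        (outdir / "hvg.tsv").write_text("".join(f"{g}\n" for g in hvg))
        record("normalize_hvg", "hvg.tsv")

        nets4 = {}
        signal_genes: set[str] = set()
        for ref, oi in config.condition_pairs:
            tag = _pair_tag(ref, oi)
            res = build_pair_network(
                normed, cells, prior, ref, oi, sender=config.sender,
                receiver=config.receiver, alpha=config.alpha,
                top_n_ligands=config.top_n_ligands, n_perm=config.n_perm,
                top_k=config.top_k, min_importance=config.min_importance,
                k_per_target=config.k_per_target, seed=config.seed)
            files = []
            for key in ("sender_degs", "receiver_degs", "lr_scores"):
                fname = f"{key}_{tag}.tsv"
                res[key].to_csv(outdir / fname, sep="\t", index=False)
                files.append(fname)
            for ver in ("net1", "net2", "net3", "net4"):
                fname = f"network_{ver[-1]}.0_{tag}.json"
                consensus.write_network_json(res[ver], outdir / fname)
                files.append(fname)
            fname = f"network_4.0_{tag}.tsv"
            consensus.network_to_edge_table(res["net4"]).to_csv(
                outdir / fname, sep="\t", index=False)
            files.append(fname)
            record(f"network:{tag}", *files)
            nets4[(ref, oi)] = res["net4"]
            for c in res["net4"].chains:
                signal_genes.update((c.receptor, c.tf, c.target))

        if len(nets4) >= 2:
            keys = list(nets4)
            cmp = consensus.compare_stage_networks(nets4[keys[0]], nets4[keys[1]])
            payload = {k: ([list(q) for q in v] if k != "directions"
                           else v.to_dict(orient="records"))
                       for k, v in cmp.items()}
            (outdir / "network_comparison.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True))
            record("compare", "network_comparison.json")

        props = population_stats.proportions(
            cells, sorted(set(cells["cell_type"])))
        props.to_csv(outdir / "proportions.tsv", sep="\t", index=False)
        record("proportions", "proportions.tsv")

        if signal_genes:
            recv_cells = cells.loc[cells["cell_type"] == config.receiver, "cell_id"]
            feats = trajectory.signal_features(normed, recv_cells.tolist(),
                                               signal_genes)
            cond = cells.set_index("cell_id")["condition"]
            n_states = min(config.n_states, len(feats))
            result = trajectory.pseudotime_order(
                feats, cond, root_condition=config.condition_pairs[0][0],
                n_states=n_states, seed=derive_seed(config.seed, "trajectory"))
            result.to_csv(outdir / "pseudotime.tsv", sep="\t", index=False)
            comp = trajectory.state_composition(result, cells)
            comp.to_csv(outdir / "state_composition.tsv", sep="\t")
            record("trajectory", "pseudotime.tsv", "state_composition.tsv")
        else:
            log.warning("Network 4.0 empty in all pairs; trajectory skipped")

        if config.survival:
            surv = io.read_survival_table(config.survival)
            cut = population_stats.optimal_cutpoint(surv, minprop=config.minprop)
            groups = {pid: ("high" if b > cut["cutoff"] else "low")
                      for pid, b in zip(surv["patient_id"], surv["biomarker"])}
            km = population_stats.km_logrank(surv, groups)
            payload = {"cutpoint": cut,
                       "logrank_chi2": km.logrank_chi2, "p": km.p}
            (outdir / "survival.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True))
            record("survival", "survival.json")
    except Exception as exc:
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
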