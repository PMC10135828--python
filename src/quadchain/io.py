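"""Readers and writers for the plain-text interchange formats.

Counts travel as Matrix Market (.mtx) plus genes.tsv / barcodes.tsv; tables
as TSV; the prior network as an edge-list TSV (source, target, weight,
layer); gene sets as GMT; networks and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datatypes import (CountMatrix, PriorNetwork, QuadchainError,
                        validate_cell_table, validate_survival_table)
from .synthdata import Cascade, PlantedTruth


def read_counts(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    """Matrix Market counts with gene/barcode identifier files.

    MTX indices are 1-based on disk and 0-based internally (scipy handles
    the conversion). Dimension mismatches and duplicate identifiers raise
    errors naming the offending file.
    """
    try:
        mat = sio.mmread(mtx_path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise QuadchainError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    genes = [ln.split("\t")[0].strip() for ln in
             Path(genes_path).read_text().splitlines() if ln.strip()]
    barcodes = [ln.split("\t")[0].strip() for ln in
                Path(barcodes_path).read_text().splitlines() if ln.strip()]
    if mat.shape != (len(genes), len(barcodes)):
        raise QuadchainError(
            f"dimension mismatch: {mtx_path} is {mat.shape} but "
            f"{genes_path} has {len(genes)} genes and "
            f"{barcodes_path} has {len(barcodes)} barcodes")
    if len(set(genes)) != len(genes):
        raise QuadchainError(f"duplicate gene identifiers in {genes_path}")
    if len(set(barcodes)) != len(barcodes):
        raise QuadchainError(f"duplicate barcodes in {barcodes_path}")
    return CountMatrix(genes, barcodes, sp.csr_matrix(mat, dtype=np.int64))


def write_counts(counts: CountMatrix, mtx_path, genes_path, barcodes_path) -> None:
    sio.mmwrite(str(mtx_path), sp.coo_matrix(counts.counts), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in counts.gene_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in counts.cell_ids))


def read_cell_table(path) -> pd.DataFrame:
    return validate_cell_table(pd.read_csv(path, sep="\t"))


def write_cell_table(cells: pd.DataFrame, path) -> None:
    validate_cell_table(cells).to_csv(path, sep="\t", index=False)


def read_survival_table(path) -> pd.DataFrame:
    return validate_survival_table(pd.read_csv(path, sep="\t"))


def write_survival_table(surv: pd.DataFrame, path) -> None:
    validate_survival_table(surv).to_csv(path, sep="\t", index=False)


def read_prior_network(path) -> PriorNetwork:
    edges = pd.read_csv(path, sep="\t")
    return PriorNetwork(edges)


def write_prior_network(prior: PriorNetwork, path) -> None:
    prior.edges.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collections: name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise QuadchainError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_truth_json(truth: PlantedTruth, path) -> None:
    data = {
        "effect_log2fc": truth.effect_log2fc,
        "baseline_mean": truth.baseline_mean,
        "dispersion": truth.dispersion,
        "seed": truth.seed,
        "cascades": [
            {"ligand": c.ligand, "receptor": c.receptor, "tf": c.tf,
             "targets": list(c.targets), "path": list(c.path),
             "active_conditions": sorted(c.active_conditions)}
            for c in truth.cascades
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> PlantedTruth:
    with open(path) as fh:
        data = json.load(fh)
    cascades = tuple(
        Cascade(ligand=c["ligand"], receptor=c["receptor"], tf=c["tf"],
                targets=tuple(c["targets"]), path=tuple(c["path"]),
                active_conditions=frozenset(c["active_conditions"]))
        for c in data["cascades"])
    return PlantedTruth(cascades=cascades, effect_log2fc=data["effect_log2fc"],
                        baseline_mean=data["baseline_mean"],
                        dispersion=data["dispersion"], seed=data["seed"])
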