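"""Cell quality control, depth normalization and variable-gene selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, NormalizedMatrix, QuadchainError
from .synthdata import MITO_PREFIX

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive per-cell filters: mito fraction, UMI range, gene-count range."""

    mito_max: float = 0.20
    umi_range: tuple[int, int] = (100, 150000)
    gene_range: tuple[int, int] = (200, 10000)

    def __post_init__(self) -> None:
        if not 0 < self.mito_max <= 1:
            raise QuadchainError("mito_max must be in (0, 1]")
        if self.umi_range[0] > self.umi_range[1] or self.gene_range[0] > self.gene_range[1]:
            raise QuadchainError("QC ranges must be ordered (min <= max)")


def compute_qc_covariates(counts: CountMatrix) -> pd.DataFrame:
    """n_umi / n_genes / pct_mito per cell, mito genes by ``MT-`` prefix."""
    mat = counts.counts.tocsc()
    depth = np.asarray(mat.sum(axis=0)).ravel()
    n_genes = np.asarray((mat > 0).sum(axis=0)).ravel()
    mito_rows = [i for i, g in enumerate(counts.gene_ids) if g.startswith(MITO_PREFIX)]
    if mito_rows:
        mito = np.asarray(mat[mito_rows].sum(axis=0)).ravel()
    else:
        mito = np.zeros_like(depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(depth > 0, mito / np.maximum(depth, 1), 0.0)
    return pd.DataFrame({"cell_id": counts.cell_ids, "n_umi": depth.astype(int),
                         "n_genes": n_genes.astype(int), "pct_mito": pct})


def qc_filter(counts: CountMatrix, cells: pd.DataFrame,
              thresholds: QCThresholds = QCThresholds()
              ) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Drop cells failing any QC criterion (inclusive bounds).

    The report tallies removals by the *first* failing criterion in the
    fixed order mito -> umi -> genes.
    """
    cells = cells.copy()
    covars = ("pct_mito", "n_umi", "n_genes")
    if any(c not in cells.columns for c in covars):
        computed = compute_qc_covariates(counts).set_index("cell_id")
        for c in covars:
            if c not in cells.columns:
                cells[c] = cells["cell_id"].map(computed[c])
    cells = cells.set_index("cell_id", drop=False)
    order = [c for c in counts.cell_ids]
    cells = cells.loc[order]

    mito_fail = cells["pct_mito"].to_numpy() > thresholds.mito_max
    umi = cells["n_umi"].to_numpy()
    umi_fail = (umi < thresholds.umi_range[0]) | (umi > thresholds.umi_range[1])
    ng = cells["n_genes"].to_numpy()
    gene_fail = (ng < thresholds.gene_range[0]) | (ng > thresholds.gene_range[1])

    first_fail = np.full(len(order), "", dtype=object)
    first_fail[gene_fail] = "genes"
    first_fail[umi_fail] = "umi"
    first_fail[mito_fail] = "mito"
    keep = first_fail == ""

    report = {
        "n_input": int(len(order)),
        "removed": {reason: int((first_fail == reason).sum())
                    for reason in ("mito", "umi", "genes")},
        "n_retained": int(keep.sum()),
        "thresholds": {"mito_max": thresholds.mito_max,
                       "umi_range": list(thresholds.umi_range),
                       "gene_range": list(thresholds.gene_range)},
    }
    if not keep.any():
        raise QuadchainError(f"all cells removed by QC; report: {report}")
    kept_ids = [c for c, k in zip(order, keep) if k]
    filtered = counts.subset_cells(kept_ids)
    cells_out = cells.loc[kept_ids].reset_index(drop=True)
    return filtered, cells_out, report


def normalize_log1p(counts: CountMatrix, scale_factor: float = 10000.0
                    ) -> NormalizedMatrix:
    """value(g, c) = ln(1 + count(g, c) * scale_factor / depth(c))."""
    mat = counts.counts.tocsc().astype(np.float64)
    depth = np.asarray(mat.sum(axis=0)).ravel()
    if (depth == 0).any():
        zero = [counts.cell_ids[i] for i in np.nonzero(depth == 0)[0][:5]]
        raise QuadchainError(f"zero-depth cell(s) after QC, e.g. {zero}")
    scaled = mat.multiply(scale_factor / depth[None, :]).tocsr()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(counts.gene_ids, counts.cell_ids, scaled,
                            scale_factor=scale_factor)


def select_hvg(normed: NormalizedMatrix, n: int = 3000, n_bins: int = 20
               ) -> list[str]:
    """Top ``n`` genes by mean-binned z-scored dispersion, in rank order.

    Dispersion = variance / mean of the normalized values; genes are placed
    into ``n_bins`` equal-frequency mean bins and the dispersion is z-scored
    within each bin. Ties break lexicographically by gene name.
    """
    if n > len(normed.gene_ids):
        raise QuadchainError(f"requested {n} HVGs but only {len(normed.gene_ids)} genes")
    mat = normed.values.tocsr()
    n_cells = len(normed.cell_ids)
    mean = np.asarray(mat.mean(axis=1)).ravel()
    sq = mat.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = np.maximum(ex2 - mean ** 2, 0.0) * (n_cells / max(n_cells - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    if np.allclose(var, 0):
        raise QuadchainError("no variable genes: expression matrix is constant")

    df = pd.DataFrame({"gene": normed.gene_ids, "mean": mean, "disp": disp})
    # equal-frequency bins on mean; rank-based so gene order cannot matter.
    # Bins are capped so each holds >= ~5 genes: singleton bins would zero
    # out the z-score of exactly the extreme genes we want to rank.
    n_bins = max(1, min(n_bins, df["mean"].nunique(), len(df) // 5))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), q=max(n_bins, 1),
                        labels=False, duplicates="drop")
    stats = df.groupby("bin")["disp"].agg(["mean", "std"])
    df = df.join(stats, on="bin", rsuffix="_bin")
    sd = df["std"].replace(0, np.nan)
    df["z"] = ((df["disp"] - df["mean_bin"]) / sd).fillna(0.0)
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].head(n).tolist()
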