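"""Cell-composition statistics and survival analysis.

The Kaplan-Meier estimator, two-group log-rank test and maximally selected
cutpoint are implemented natively (they are small, and the test suite checks
them against both hand-worked arithmetic and an independent library).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import QuadchainError, validate_survival_table
from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


def proportions(cells: pd.DataFrame, compartment: Iterable[str],
                group_by: str = "condition") -> pd.DataFrame:
    """Per-patient cell-type fractions within a compartment.

    Fractions sum to one over the compartment for each (patient, group)
    stratum. Patients without compartment cells are omitted with a warning.
    """
    compartment = sorted(set(compartment))
    if not compartment:
        raise QuadchainError("compartment must be non-empty")
    known = set(cells["cell_type"])
    unknown = sorted(set(compartment) - known)
    if unknown:
        raise QuadchainError(f"unknown cell type(s) in compartment: {unknown}")

    sub = cells[cells["cell_type"].isin(compartment)]
    all_strata = cells[["patient_id", group_by]].drop_duplicates()
    counts = (sub.groupby(["patient_id", group_by, "cell_type"], observed=True)
              .size().rename("n").reset_index())
    totals = counts.groupby(["patient_id", group_by])["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals

    full = (all_strata.merge(pd.DataFrame({"cell_type": compartment}), how="cross")
            .merge(counts, on=["patient_id", group_by, "cell_type"], how="left"))
    has_cells = full.groupby(["patient_id", group_by])["n"].transform(
        lambda s: s.notna().any())
    dropped = full.loc[~has_cells, ["patient_id", group_by]].drop_duplicates()
    for _, row in dropped.iterrows():
        log.warning("patient %s (%s) has no compartment cells; omitted",
                    row["patient_id"], row[group_by])
    full = full[has_cells].copy()
    full["fraction"] = full["fraction"].fillna(0.0)
    out = full.rename(columns={group_by: "condition"})[
        ["patient_id", "condition", "cell_type", "fraction"]]
    return out.sort_values(["patient_id", "condition", "cell_type"]).reset_index(drop=True)


def compare_proportions(props: pd.DataFrame, cond_a: str, cond_b: str
                        ) -> pd.DataFrame:
    """Welch t-test of per-patient fractions per cell type, BH across types."""
    rows = []
    for ctype in sorted(props["cell_type"].unique()):
        a = props.query("cell_type == @ctype and condition == @cond_a")["fraction"]
        b = props.query("cell_type == @ctype and condition == @cond_b")["fraction"]
        if len(a) < 2 or len(b) < 2:
            raise QuadchainError(
                f"need >= 2 patients per condition for {ctype!r} "
                f"({len(a)} vs {len(b)})")
        low_power = len(a) == 2 or len(b) == 2
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"cell_type": ctype, "t": float(t), "p": float(p),
                     "n_a": len(a), "n_b": len(b), "low_power": low_power})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class KMResult:
    """Product-limit curves per group plus the two-group log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> columns time, at_risk, survival
    logrank_chi2: float
    p: float


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate over the distinct event times."""
    order = np.argsort(time, kind="mergesort")
    time, event = np.asarray(time)[order], np.asarray(event)[order]
    rows = [(0.0, len(time), 1.0)]
    s = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1 - d / at_risk
        rows.append((float(t), at_risk, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "survival"])


def _logrank(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
             ) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and upper-tail p."""
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        dead = (time == t) & (event == 1)
        d = dead.sum()
        d1 = (dead & in_group1).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_logrank(surv: pd.DataFrame, groups: Mapping[str, str] | pd.Series
               ) -> KMResult:
    """Kaplan-Meier curves and log-rank test for a two-group patient split."""
    surv = validate_survival_table(surv)
    labels = surv["patient_id"].map(dict(groups))
    if labels.isna().any():
        missing = surv.loc[labels.isna(), "patient_id"].tolist()[:5]
        raise QuadchainError(f"patients without group label, e.g. {missing}")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise QuadchainError(f"expected exactly 2 groups, got {uniq}")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise QuadchainError("both groups need >= 2 patients")
    if surv["event"].sum() < 1:
        raise QuadchainError("need at least one event")

    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    curves = {g: km_curve(time[labels == g], event[labels == g]) for g in uniq}
    chi2, p = _logrank(time, event, (labels == uniq[0]).to_numpy())
    return KMResult(curves=curves, logrank_chi2=chi2, p=p)


def optimal_cutpoint(surv: pd.DataFrame, minprop: float = 0.1
                     ) -> dict:
    """Maximally selected log-rank cutoff on the biomarker column.

    Scans midpoints between consecutive distinct biomarker values keeping
    both groups at size >= ceil(minprop * n); returns the cutoff maximizing
    the log-rank chi-square. The reported p is the naive (selection-biased)
    log-rank p and is flagged as such.
    """
    surv = validate_survival_table(surv)
    values = np.sort(surv["biomarker"].unique())
    if len(values) < 3:
        raise QuadchainError("biomarker needs >= 3 distinct values")
    n = len(surv)
    min_size = int(np.ceil(minprop * n))
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    biomarker = surv["biomarker"].to_numpy(float)

    best = None
    for cut in (values[:-1] + values[1:]) / 2:
        high = biomarker > cut
        if high.sum() < min_size or (~high).sum() < min_size:
            continue
        chi2, p = _logrank(time, event, high)
        if best is None or chi2 > best["chi2"]:
            best = {"cutoff": float(cut), "chi2": chi2, "p": p}
    if best is None:
        raise QuadchainError(
            f"no admissible cutoff with both groups >= {min_size} patients")
    best["p_is_selection_biased"] = True
    return best
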