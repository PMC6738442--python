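"""Mass-univariate correlation screening with multiple-testing control.

All (x, y) variable pairs between two phenotype tables are screened with
Pearson correlations on pairwise-complete observations; significance comes
from the exact t transform of r.  Familywise error is controlled by
Bonferroni and the false discovery rate by Benjamini–Hochberg, and results
can be exported in Manhattan-plot form (-log10 p arranged by y-variable,
coloured by modality block).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .change_scores import DECLINER, IMPROVER, GroupAssignment
from .types import PhenotypeTable

__all__ = [
    "pairwise_correlations",
    "multiple_testing",
    "ThresholdReport",
    "adjust_records_for_change",
    "subgroup_consistency",
    "manhattan_export",
    "manhattan_figure",
]

P_FLOOR = np.finfo(float).tiny  # keeps -log10(p) finite

RECORD_COLUMNS = [
    "var_x", "block_x", "var_y", "block_y",
    "r", "p", "n_eff", "neg_log10_p", "testable",
]


def _pairwise_complete_corr(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and pairwise-complete n for every column pair, via masked
    cross-products (no per-pair Python loop)."""
    Mx = np.isfinite(X).astype(float)
    My = np.isfinite(Y).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    Y0 = np.where(np.isfinite(Y), Y, 0.0)

    n = Mx.T @ My
    sx = X0.T @ My
    sy = Mx.T @ Y0
    sxx = (X0**2).T @ My
    syy = Mx.T @ (Y0**2)
    sxy = X0.T @ Y0

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        r = cov / np.sqrt(varx * vary)
    r[(n < 2)] = np.nan
    return r, n.astype(int)


def _p_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    dof = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    p = np.where(
        np.isfinite(t),
        2.0 * stats.t.sf(np.abs(t), np.maximum(dof, 1)),
        np.where(np.isnan(r), np.nan, 0.0),  # |r| == 1 -> t infinite
    )
    return np.maximum(p, P_FLOOR)


def pairwise_correlations(
    table_x: PhenotypeTable, table_y: PhenotypeTable, *, min_n: int = 4
) -> pd.DataFrame:
    """One correlation record per (x, y) variable pair.

    Uses pairwise-complete observations; pairs with fewer than ``min_n``
    complete pairs (or a constant variable within them) are kept in the
    output but flagged untestable and get no p-value.
    """
    if not table_x.subject_ids.equals(table_y.subject_ids):
        common = table_x.subject_ids.intersection(table_y.subject_ids)
        if len(common) == 0:
            raise ValueError("tables share no subjects")
        table_x = table_x.select_subjects(common)
        table_y = table_y.select_subjects(common)

    r, n = _pairwise_complete_corr(table_x.matrix(), table_y.matrix())
    testable = (n >= min_n) & np.isfinite(r)
    p = np.where(testable, _p_from_r(r, n), np.nan)

    ix, iy = np.meshgrid(
        np.arange(table_x.shape[1]), np.arange(table_y.shape[1]), indexing="ij"
    )
    rec = pd.DataFrame(
        {
            "var_x": table_x.variables.to_numpy()[ix.ravel()],
            "block_x": table_x.manifest["block"].to_numpy()[ix.ravel()],
            "var_y": table_y.variables.to_numpy()[iy.ravel()],
            "block_y": table_y.manifest["block"].to_numpy()[iy.ravel()],
            "r": r.ravel(),
            "p": p.ravel(),
            "n_eff": n.ravel(),
            "testable": testable.ravel(),
        }
    )
    with np.errstate(invalid="ignore"):
        rec["neg_log10_p"] = -np.log10(rec["p"])
    return rec


@dataclass
class ThresholdReport:
    alpha: float
    m: int
    bonferroni_p: float
    fdr_p: float | None  # largest BH-passing p, None when no discovery
    n_pass_fwe: int
    n_pass_fdr: int


def multiple_testing(
    records: pd.DataFrame, alpha: float = 0.05, *, m_eff: int | None = None
) -> ThresholdReport:
    """Flag records by Bonferroni FWE and Benjamini–Hochberg FDR.

    Writes ``pass_fwe`` / ``pass_fdr`` onto ``records`` in place and
    returns the thresholds.  ``m_eff`` substitutes an effective number of
    tests for the Bonferroni denominator (the step-up FDR always uses the
    actual test count).
    """
    testable = records["testable"].to_numpy()
    m = int(testable.sum())
    if m == 0:
        raise ValueError("no testable records")
    m_bonf = m if m_eff is None else int(m_eff)
    p = records.loc[testable, "p"].to_numpy()

    bonferroni_p = alpha / m_bonf
    pass_fwe = p <= bonferroni_p
    pass_fdr, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")[:4]

    records["pass_fwe"] = False
    records["pass_fdr"] = False
    records.loc[records.index[testable], "pass_fwe"] = pass_fwe
    records.loc[records.index[testable], "pass_fdr"] = pass_fdr

    fdr_p = float(p[pass_fdr].max()) if pass_fdr.any() else None
    return ThresholdReport(
        alpha=alpha,
        m=m_bonf,
        bonferroni_p=bonferroni_p,
        fdr_p=fdr_p,
        n_pass_fwe=int(pass_fwe.sum()),
        n_pass_fdr=int(pass_fdr.sum()),
    )


def adjust_records_for_change(
    table_x: PhenotypeTable, table_y: PhenotypeTable, cdelta: pd.Series
) -> pd.DataFrame:
    """Re-screen all pairs after residualizing both sets on a raw-difference
    change score (partial correlations, n - 3 degrees of freedom)."""
    c = cdelta.reindex(table_x.subject_ids)
    keep = c.notna()
    tx = table_x.select_subjects(table_x.subject_ids[keep])
    ty = table_y.select_subjects(table_y.subject_ids[keep])
    cv = c[keep].to_numpy(dtype=float)

    def _residualize(tab: PhenotypeTable) -> PhenotypeTable:
        vals = tab.matrix()
        design = np.column_stack([np.ones(len(cv)), cv])
        out = np.full_like(vals, np.nan)
        for j in range(vals.shape[1]):
            obs = np.isfinite(vals[:, j])
            beta, *_ = np.linalg.lstsq(design[obs], vals[obs, j], rcond=None)
            out[obs, j] = vals[obs, j] - design[obs] @ beta
        return tab.with_values(out)

    rec = pairwise_correlations(_residualize(tx), _residualize(ty))
    # one degree of freedom spent on the adjustment covariate
    ok = rec["testable"] & (rec["n_eff"] >= 5)
    dof = rec.loc[ok, "n_eff"].to_numpy() - 3
    r = rec.loc[ok, "r"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    rec.loc[ok, "p"] = np.maximum(2.0 * stats.t.sf(np.abs(t), dof), P_FLOOR)
    rec["neg_log10_p"] = -np.log10(rec["p"])
    return rec


def subgroup_consistency(
    table_x: PhenotypeTable,
    table_y: PhenotypeTable,
    groups: GroupAssignment,
    records: pd.DataFrame,
    *,
    min_group_n: int = 4,
) -> pd.DataFrame:
    """Per-group correlations for every whole-group-significant pair, with
    a Simpson's-paradox flag when both subgroup correlations have sign
    opposite to the pooled correlation (pooling artifact check)."""
    if "pass_fwe" not in records:
        raise ValueError("run multiple_testing before subgroup_consistency")
    sig = records[records["pass_fwe"]]
    rows = []
    for _, rec in sig.iterrows():
        entry = {
            "var_x": rec["var_x"],
            "var_y": rec["var_y"],
            "r_pooled": rec["r"],
        }
        group_rs: dict[str, float] = {}
        for label in (IMPROVER, DECLINER):
            ids = groups.subjects(label).intersection(table_x.subject_ids)
            if len(ids) < min_group_n:
                warnings.warn(f"group '{label}' has fewer than {min_group_n} subjects")
                entry[f"r_{label}"] = np.nan
                continue
            x = table_x.values.loc[ids, rec["var_x"]]
            y = table_y.values.loc[ids, rec["var_y"]]
            obs = x.notna() & y.notna()
            if obs.sum() < min_group_n or x[obs].std() == 0 or y[obs].std() == 0:
                entry[f"r_{label}"] = np.nan
                continue
            group_rs[label] = float(np.corrcoef(x[obs], y[obs])[0, 1])
            entry[f"r_{label}"] = group_rs[label]
        entry["simpson_flag"] = bool(
            len(group_rs) == 2
            and all(np.sign(v) == -np.sign(rec["r"]) != 0 for v in group_rs.values())
        )
        rows.append(entry)
    cols = ["var_x", "var_y", "r_pooled", "r_improver", "r_decliner", "simpson_flag"]
    return pd.DataFrame(rows, columns=cols)


def manhattan_export(
    records: pd.DataFrame, report: ThresholdReport
) -> pd.DataFrame:
    """Plot-ready table: x-position grouped by y-variable, -log10 p on the
    y-axis, block colour key, and horizontal threshold lines (FWE always;
    FDR only when it adds discoveries beyond Bonferroni)."""
    rec = records[records["testable"]].copy()
    y_order = {v: i for i, v in enumerate(pd.unique(rec["var_y"]))}
    rec["group_index"] = rec["var_y"].map(y_order)
    rec = rec.sort_values(["group_index", "var_x"], kind="stable")
    rec["x_position"] = np.arange(len(rec))
    rec["color_key"] = rec["block_x"]
    rec["fwe_line"] = -np.log10(report.bonferroni_p)
    draw_fdr = report.fdr_p is not None and report.n_pass_fdr > report.n_pass_fwe
    rec["fdr_line"] = -np.log10(report.fdr_p) if draw_fdr else np.nan
    cols = [
        "x_position", "group_index", "var_x", "var_y", "color_key",
        "r", "p", "neg_log10_p", "pass_fwe", "pass_fdr", "fwe_line", "fdr_line",
    ]
    return rec[[c for c in cols if c in rec.columns]].reset_index(drop=True)


def manhattan_figure(manhattan: pd.DataFrame, path: str) -> None:
    """Render the Manhattan table to a vector-graphics file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for block, sub in manhattan.groupby("color_key"):
        ax.scatter(sub["x_position"], sub["neg_log10_p"], s=4, label=str(block))
    ax.axhline(manhattan["fwe_line"].iloc[0], color="k", lw=1, label="FWE")
    if manhattan["fdr_line"].notna().any():
        ax.axhline(manhattan["fdr_line"].iloc[0], color="k", lw=1, ls="--", label="FDR")
    ax.set_xlabel("variable pairs (grouped by y-variable)")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
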