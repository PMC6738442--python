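"""Normalisation, deconfounding and matrix completion.

Pipeline order contract: rank-based inverse normal transform (Blom) →
confound regression → soft-impute (only on the multivariate path; the
univariate screen works on pairwise-complete observations instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .types import ConfoundSet, PhenotypeTable

__all__ = [
    "quantile_normalize",
    "quantile_normalize_table",
    "deconfound",
    "soft_impute",
    "SoftImputeInfo",
    "preprocess_tables",
]


# ---------------------------------------------------------------------------
# rank-based inverse normal transform
# ---------------------------------------------------------------------------

def quantile_normalize(column: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse Gaussian transform of one column.

    Non-missing entries are replaced by Phi^-1((r - 3/8) / (m + 1/4)) where
    r is the average rank among the m observed values; ties share their
    average rank, and missing entries stay missing.  The result is a
    monotone function of the input ranks, which makes every downstream
    correlation invariant to monotone transforms of the raw measurement.
    """
    x = np.asarray(column, dtype=float)
    obs = np.isfinite(x)
    m = int(obs.sum())
    if m < 3:
        raise ValueError(f"need at least 3 observed values, got {m}")
    vals = x[obs]
    if np.nanmax(vals) == np.nanmin(vals):
        raise ValueError("constant column cannot be quantile-normalized")
    ranks = rankdata(vals, method="average")
    out = np.full_like(x, np.nan)
    out[obs] = ndtri((ranks - 0.375) / (m + 0.25))
    return out


def quantile_normalize_table(table: PhenotypeTable) -> PhenotypeTable:
    """Apply :func:`quantile_normalize` to every column."""
    vals = table.matrix()
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[:, j] = quantile_normalize(vals[:, j])
    return table.with_values(out)


def _normalize_confounds(confounds: ConfoundSet) -> np.ndarray:
    g = confounds.matrix()
    out = np.empty_like(g)
    for k in range(g.shape[1]):
        col = g[:, k]
        if np.nanmax(col) == np.nanmin(col):
            out[:, k] = 0.0  # constant confound carries no information
        else:
            out[:, k] = quantile_normalize(col)
    return out


# ---------------------------------------------------------------------------
# confound regression
# ---------------------------------------------------------------------------

def deconfound(
    table: PhenotypeTable,
    confounds: ConfoundSet,
    *,
    normalize_confounds: bool = True,
) -> PhenotypeTable:
    """Replace every column by its least-squares residual on
    [intercept | confounds].

    Confounds are themselves quantile-normalized first (same treatment as
    the variables).  Missing entries stay missing; the regression for a
    column uses its observed rows only.  A rank-deficient design triggers a
    warning and a pseudoinverse fit.
    """
    confounds = confounds.aligned_to(table)
    g = _normalize_confounds(confounds) if normalize_confounds else confounds.matrix()
    n = table.shape[0]
    design = np.column_stack([np.ones(n), g])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient confound matrix; using pseudoinverse fit")

    vals = table.matrix()
    out = np.full_like(vals, np.nan)
    complete_rows = np.isfinite(vals).all(axis=1)
    if complete_rows.all():
        beta, *_ = np.linalg.lstsq(design, vals, rcond=None)
        out = vals - design @ beta
    else:
        for j in range(vals.shape[1]):
            obs = np.isfinite(vals[:, j])
            beta, *_ = np.linalg.lstsq(design[obs], vals[obs, j], rcond=None)
            out[obs, j] = vals[obs, j] - design[obs] @ beta
    return table.with_values(out)


# ---------------------------------------------------------------------------
# soft-impute matrix completion
# ---------------------------------------------------------------------------

@dataclass
class SoftImputeInfo:
    converged: bool
    n_iter: int
    lam: float
    frobenius_change: float


def _mean_fill(vals: np.ndarray, mask_missing: np.ndarray) -> np.ndarray:
    filled = vals.copy()
    col_means = np.nanmean(np.where(mask_missing, np.nan, vals), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    filled[mask_missing] = np.broadcast_to(col_means, vals.shape)[mask_missing]
    return filled


def _soft_impute_fixed(
    filled: np.ndarray,
    vals: np.ndarray,
    mask_missing: np.ndarray,
    lam: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, float, bool]:
    """Iterate fill → SVD → soft-threshold singular values → restore
    observed at one fixed lambda, until the relative Frobenius change of
    the iterate drops below tol."""
    change = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        s_thr = np.maximum(s - lam, 0.0)
        recon = (u * s_thr) @ vt
        new = np.where(mask_missing, recon, vals)
        denom = max(np.linalg.norm(filled), 1e-12)
        change = np.linalg.norm(new - filled) / denom
        filled = new
        if change < tol:
            return filled, it, change, True
    return filled, it, change, False


def _soft_impute_core(
    vals: np.ndarray,
    mask_missing: np.ndarray,
    lam: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, SoftImputeInfo]:
    """Soft-impute with warm-started continuation.

    The shrinkage level is walked down a geometric path from half the top
    singular value to the target ``lam``, warm-starting each leg from the
    previous solution.  This keeps the iterate effectively low-rank along
    the way, so small target lambdas converge to the minimum-nuclear-norm
    completion instead of stalling near the identity map.
    """
    filled = _mean_fill(vals, mask_missing)
    s1 = np.linalg.svd(filled, compute_uv=False)[0]
    lam0 = 0.5 * s1
    if lam >= lam0 or s1 == 0:
        path = [lam]
    else:
        n_steps = max(2, min(10, int(np.ceil(np.log(lam0 / max(lam, 1e-12)) / np.log(3.0)))))
        path = list(np.geomspace(lam0, max(lam, 1e-12), n_steps))
        path[-1] = lam
    total_iter = 0
    change = 0.0
    ok = True
    for leg, lam_k in enumerate(path):
        budget = max(1, (max_iter - total_iter) // max(1, len(path) - leg))
        if lam_k == path[-1]:
            budget = max(1, max_iter - total_iter)
        filled, it, change, ok = _soft_impute_fixed(
            filled, vals, mask_missing, lam_k, tol, budget
        )
        total_iter += it
    if not ok:
        warnings.warn(f"soft-impute did not converge in {max_iter} iterations")
    return filled, SoftImputeInfo(ok, total_iter, lam, change)


def _choose_lambda(
    vals: np.ndarray,
    mask_missing: np.ndarray,
    tol: float,
    max_iter: int,
    seed: int = 0,
) -> float:
    """Pick the shrinkage level on a small internal grid by minimising
    reconstruction error on 5% of observed entries held out as missing."""
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(~mask_missing)
    n_hold = max(1, int(0.05 * len(obs_idx)))
    hold = obs_idx[rng.choice(len(obs_idx), size=n_hold, replace=False)]
    mask_cv = mask_missing.copy()
    mask_cv[hold[:, 0], hold[:, 1]] = True
    vals_cv = vals.copy()
    vals_cv[mask_cv] = np.nan

    s1 = np.linalg.svd(np.where(mask_cv, 0.0, vals), compute_uv=False)[0]
    grid = s1 * np.array([0.02, 0.05, 0.1, 0.2, 0.4])
    best_lam, best_err = grid[0], np.inf
    for lam in grid:
        with warnings.catch_warnings():
            # the short CV runs are deliberately truncated
            warnings.simplefilter("ignore", UserWarning)
            completed, _ = _soft_impute_core(vals_cv, mask_cv, lam, tol, min(max_iter, 100))
        err = np.mean((completed[hold[:, 0], hold[:, 1]] - vals[hold[:, 0], hold[:, 1]]) ** 2)
        if err < best_err:
            best_lam, best_err = lam, err
    return float(best_lam)


def soft_impute(
    table: PhenotypeTable,
    *,
    lam: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[PhenotypeTable, SoftImputeInfo]:
    """Complete missing entries by iterative SVD with soft-thresholded
    singular values (low-rank matrix completion).

    Observed entries are never changed.  When ``lam`` is None a small grid
    is searched, scoring each candidate by held-out error on 5% of the
    observed entries.  Returns the completed table and convergence info.
    """
    vals = table.matrix()
    mask_missing = ~np.isfinite(vals)
    n_obs_per_col = (~mask_missing).sum(axis=0)
    if (n_obs_per_col == 0).any():
        bad = table.variables[n_obs_per_col == 0].tolist()
        raise ValueError(f"fully missing column(s): {bad[:5]}")
    if (n_obs_per_col < 2).any():
        bad = table.variables[n_obs_per_col < 2].tolist()
        raise ValueError(f"column(s) with fewer than 2 observed values: {bad[:5]}")

    if not mask_missing.any():
        return table.copy(), SoftImputeInfo(True, 0, 0.0 if lam is None else lam, 0.0)

    if lam is None:
        lam = _choose_lambda(vals, mask_missing, tol, max_iter)
    completed, info = _soft_impute_core(vals, mask_missing, lam, tol, max_iter)
    return table.with_values(completed), info


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def preprocess_tables(
    table: PhenotypeTable,
    confounds: ConfoundSet,
    *,
    impute: bool = False,
    lam: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[PhenotypeTable, SoftImputeInfo | None]:
    """quantile_normalize → deconfound → (optionally) soft_impute."""
    out = quantile_normalize_table(table)
    out = deconfound(out, confounds)
    info = None
    if impute:
        out, info = soft_impute(out, lam=lam, tol=tol, max_iter=max_iter)
    return out, info
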