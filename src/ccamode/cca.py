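"""PCA-reduced canonical correlation analysis with permutation FWE.

Each preprocessed phenotype matrix is first compressed to its top
principal-component scores (default 30) to avoid a rank-deficient CCA
solution at n ~ 200 subjects.  CCA then finds weight matrices A, B such
that the canonical variates U = X_p A and V = Y_p B maximise corr(U_i, V_i)
mode by mode.  Inference is by a max-statistic permutation test: rows of
one matrix are shuffled relative to the other, and every observed
canonical correlation is compared against the permutation null
distribution of the *largest* canonical correlation, giving familywise
error p-values corrected for the search over all modes.

Post-hoc, each mode is related back to the observed variables through
structure loadings (correlations between polarity-adjusted variables and
the variates), aggregated into per-subdomain importances, and compared
across subgroups with Tucker's congruence coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .change_scores import DECLINER, IMPROVER, GroupAssignment
from .types import PhenotypeTable

__all__ = [
    "PCAReduction",
    "CCAResult",
    "pca_reduce",
    "fit_cca",
    "permutation_fwe",
    "structure_loadings",
    "orient_mode_sign",
    "subdomain_importance",
    "factor_congruence",
    "cca_analysis",
    "CCAAnalysis",
]


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class PCAReduction:
    scores: np.ndarray  # subjects x d, ordered by decreasing variance
    basis: np.ndarray  # variables x d
    variance_explained: np.ndarray  # per-component fraction
    cumulative_variance: np.ndarray
    d: int
    subject_ids: pd.Index


def pca_reduce(table: PhenotypeTable, d: int = 30) -> PCAReduction:
    """Column-centered SVD; scores are the top-d left singular vectors
    scaled by their singular values."""
    if not table.is_complete():
        raise ValueError("PCA requires a complete table (impute first)")
    X = table.matrix()
    n, p = X.shape
    if d > min(n, p):
        raise ValueError(f"d={d} exceeds min(subjects, variables)={min(n, p)}")
    if d > n / 6:
        warnings.warn(f"d={d} is large relative to n={n} (guideline d <= n/6)")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    return PCAReduction(
        scores=u[:, :d] * s[:d],
        basis=vt[:d].T,
        variance_explained=frac[:d],
        cumulative_variance=np.cumsum(frac)[:d],
        d=d,
        subject_ids=table.subject_ids,
    )


# ---------------------------------------------------------------------------
# canonical correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CCAResult:
    A: np.ndarray  # dx x k weights (U = Xc @ A)
    B: np.ndarray  # dy x k weights (V = Yc @ B)
    U: np.ndarray  # subjects x k canonical variates, unit variance
    V: np.ndarray
    rc: np.ndarray  # canonical correlations, descending
    p_fwe: np.ndarray | None = None
    n_perm: int = 0

    @property
    def n_modes(self) -> int:
        return len(self.rc)


def _orthonormal_basis(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Economic pivoted QR of the centered matrix, trimmed to effective
    rank. Returns (Q, R, pivot, rank)."""
    Xc = X - X.mean(axis=0)
    q, r, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < Xc.shape[1]:
        warnings.warn(
            f"rank-deficient matrix (rank {rank} < {Xc.shape[1]}); "
            "reducing to effective rank"
        )
    return q[:, :rank], r[:rank, :rank], piv, rank


def fit_cca(xp: np.ndarray, yp: np.ndarray) -> CCAResult:
    """Classical CCA via QR-then-SVD of the orthonormalised cross-product.

    Numerically equivalent to solving the generalized eigenproblem
    Sxx^-1 Sxy Syy^-1 Syx but stable for ill-conditioned inputs.  Variates
    have unit sample variance.  Sign convention: the largest-magnitude
    element of each column of A is made positive, and B follows so that
    corr(U_i, V_i) = +rc_i.
    """
    xp = np.asarray(xp, dtype=float)
    yp = np.asarray(yp, dtype=float)
    if xp.shape[0] != yp.shape[0]:
        raise ValueError("xp and yp must have the same number of subjects")
    n = xp.shape[0]
    qx, rx, pivx, rank_x = _orthonormal_basis(xp)
    qy, ry, pivy, rank_y = _orthonormal_basis(yp)
    k = min(rank_x, rank_y)

    uu, s, vvt = np.linalg.svd(qx.T @ qy)
    rc = np.clip(s[:k], 0.0, 1.0)

    # back-substitute through R (undoing the pivot) and scale variates to
    # unit sample variance: columns of Qx @ uu have norm 1.
    scale = np.sqrt(n - 1)
    A = np.zeros((xp.shape[1], k))
    B = np.zeros((yp.shape[1], k))
    # dependent (trimmed) columns keep zero weight
    A[pivx[:rank_x]] = linalg.solve_triangular(rx, uu[:rank_x, :k]) * scale
    B[pivy[:rank_y]] = linalg.solve_triangular(ry, vvt.T[:rank_y, :k]) * scale

    # sign convention
    for i in range(k):
        ja = np.argmax(np.abs(A[:, i]))
        if A[ja, i] < 0:
            A[:, i] *= -1
            B[:, i] *= -1  # keep corr(U_i, V_i) positive

    Uc = (xp - xp.mean(axis=0)) @ A
    Vc = (yp - yp.mean(axis=0)) @ B
    return CCAResult(A=A, B=B, U=Uc, V=Vc, rc=rc)


def permutation_fwe(
    xp: np.ndarray,
    yp: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    order: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Max-statistic permutation familywise p-values for every CCA mode.

    Rows of ``yp`` are permuted uniformly ``n_perm`` times; for each
    permutation the largest canonical correlation is recorded, and
    p_fwe_i = (1 + #{null max >= rc_i}) / (n_perm + 1).  Because the
    observed rc are descending, the p-values are non-decreasing in i.
    Returns (p_fwe, null_max_distribution).

    ``order`` optionally gives a canonical subject ordering (e.g.
    ``np.argsort(subject_ids)``): permutations are then applied in that
    frame, so reordering the rows of both matrices identically leaves the
    p-values bit-identical, not just equal in distribution.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives poor p-value resolution")
    rng = np.random.default_rng(seed)
    observed = fit_cca(xp, yp)

    # orthonormal bases: row-permuting yp permutes the rows of its basis
    # (column means are permutation-invariant), so each null draw costs one
    # small matmul + SVD instead of a full refit.
    qx, _, _, _ = _orthonormal_basis(xp)
    qy, _, _, _ = _orthonormal_basis(yp)
    n = qx.shape[0]
    if order is not None:
        qx, qy = qx[order], qy[order]
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null_max[b] = np.linalg.svd(qx.T @ qy[perm], compute_uv=False)[0]
    null_max = np.clip(null_max, 0.0, 1.0)

    exceed = (null_max[None, :] >= observed.rc[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)
    return p_fwe, null_max


# ---------------------------------------------------------------------------
# post-hoc: loadings, importances, congruence
# ---------------------------------------------------------------------------

def structure_loadings(
    table: PhenotypeTable,
    variate: np.ndarray,
    *,
    mode: int = 1,
    apply_polarity: bool = True,
    report_threshold: float = 0.2,
) -> pd.DataFrame:
    """Canonical structure coefficients: Pearson correlation between each
    (polarity-adjusted) observed variable and a canonical variate.

    ``reported`` flags |loading| >= 0.2, the conventional cutoff below
    which a variable's contribution is not interpreted.
    """
    vals = table.matrix()
    if apply_polarity:
        vals = vals * table.polarity[None, :]
    v = np.asarray(variate, dtype=float)
    if len(v) != vals.shape[0]:
        raise ValueError("variate length does not match subject count")

    vc = v - v.mean()
    loadings = np.full(vals.shape[1], np.nan)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        obs = np.isfinite(col)
        if obs.sum() < 3:
            continue
        x = col[obs] - col[obs].mean()
        y = vc[obs] - vc[obs].mean() if not obs.all() else vc
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        if denom < 1e-300:
            continue  # constant variable: loading undefined
        loadings[j] = float(np.dot(x, y) / denom)

    out = table.manifest.copy()
    out["mode"] = mode
    out["loading"] = loadings
    out["r2"] = loadings**2
    out["reported"] = np.abs(loadings) >= report_threshold
    return out


def orient_mode_sign(
    nonidp_loadings: pd.DataFrame, anchor_subdomain: str = "cognition"
) -> int:
    """Global sign of a mode, fixed so that the mean loading of the anchor
    subdomain (cognition) is positive — the 'positive-negative' orientation
    in which favourable qualities load positively."""
    sub = nonidp_loadings[nonidp_loadings["subdomain"] == anchor_subdomain]
    mean_loading = sub["loading"].mean(skipna=True)
    if not np.isfinite(mean_loading) or mean_loading == 0:
        return 1
    return 1 if mean_loading > 0 else -1


def subdomain_importance(loadings: pd.DataFrame) -> pd.DataFrame:
    """Per-subdomain mean squared loading, split by loading sign.

    The positive bar is the sum of r^2 over positively-loading members
    divided by the subdomain's total member count (so an all-positive
    subdomain's bar equals its plain mean r^2); the negative bar likewise.
    """
    rows = []
    for subdomain, grp in loadings.groupby("subdomain", sort=False):
        n_tot = len(grp)
        lo = grp["loading"].to_numpy()
        r2 = grp["r2"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pos = float(np.nansum(np.where(lo > 0, r2, 0.0)) / n_tot)
            neg = float(np.nansum(np.where(lo < 0, r2, 0.0)) / n_tot)
        if n_tot == 0 or not np.isfinite(lo).any():
            warnings.warn(f"subdomain '{subdomain}' has no usable loadings")
            pos = neg = 0.0
        rows.append(
            {
                "subdomain": subdomain,
                "n_variables": n_tot,
                "positive_r2_mean": pos,
                "negative_r2_mean": neg,
            }
        )
    return pd.DataFrame(rows)


def factor_congruence(loadings_a: np.ndarray, loadings_b: np.ndarray) -> float:
    """Tucker congruence phi = a.b / sqrt((a.a)(b.b)) with pairwise
    deletion of missing loadings; phi = 1 iff the vectors are proportional
    with a positive factor."""
    a = np.asarray(loadings_a, dtype=float)
    b = np.asarray(loadings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("loading vectors must be 1-D, equal length >= 2")
    obs = np.isfinite(a) & np.isfinite(b)
    a, b = a[obs], b[obs]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm loading vector: congruence undefined")
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class CCAAnalysis:
    """Full multivariate stage: PCA reductions, CCA fit with permutation
    p-values, oriented mode-1 loadings, subdomain importances and (when
    groups are supplied) subgroup loadings with congruence coefficients."""

    pca_idp: PCAReduction
    pca_nonidp: PCAReduction
    cca: CCAResult
    loadings_idp: pd.DataFrame
    loadings_nonidp: pd.DataFrame
    importance_idp: pd.DataFrame
    importance_nonidp: pd.DataFrame
    mode_sign: int = 1
    subgroup_loadings: dict = field(default_factory=dict)
    congruence_idp: float | None = None
    congruence_nonidp: float | None = None


def cca_analysis(
    idp_table: PhenotypeTable,
    nonidp_table: PhenotypeTable,
    *,
    d: int = 30,
    n_perm: int = 10000,
    seed: int = 0,
    groups: GroupAssignment | None = None,
    loading_tables: tuple[PhenotypeTable, PhenotypeTable] | None = None,
) -> CCAAnalysis:
    """Run PCA -> CCA -> permutation FWE -> post-hoc loadings.

    ``idp_table``/``nonidp_table`` must be preprocessed and complete (CCA
    path).  ``loading_tables`` optionally supplies the pre-imputation
    deconfounded tables against which structure loadings are computed;
    by default the CCA input tables are used.
    """
    pca_x = pca_reduce(idp_table, d)
    pca_y = pca_reduce(nonidp_table, d)
    result = fit_cca(pca_x.scores, pca_y.scores)
    order = np.argsort(idp_table.subject_ids.to_numpy())
    result.p_fwe, _ = permutation_fwe(
        pca_x.scores, pca_y.scores, n_perm, seed, order=order
    )
    result.n_perm = n_perm

    load_x_tab, load_y_tab = loading_tables or (idp_table, nonidp_table)
    u1, v1 = result.U[:, 0], result.V[:, 0]
    loadings_x = structure_loadings(load_x_tab, u1, mode=1)
    loadings_y = structure_loadings(load_y_tab, v1, mode=1)

    sign = orient_mode_sign(loadings_y)
    if sign < 0:
        for df_ in (loadings_x, loadings_y):
            df_["loading"] *= -1
        u1, v1 = -u1, -v1
        result.U[:, 0], result.V[:, 0] = u1, v1
        result.A[:, 0] *= -1
        result.B[:, 0] *= -1

    analysis = CCAAnalysis(
        pca_idp=pca_x,
        pca_nonidp=pca_y,
        cca=result,
        loadings_idp=loadings_x,
        loadings_nonidp=loadings_y,
        importance_idp=subdomain_importance(loadings_x),
        importance_nonidp=subdomain_importance(loadings_y),
        mode_sign=sign,
    )

    if groups is not None:
        per_group: dict[str, dict[str, pd.DataFrame]] = {}
        for label in (IMPROVER, DECLINER):
            ids = groups.subjects(label).intersection(idp_table.subject_ids)
            if len(ids) < 4:
                warnings.warn(f"subgroup '{label}' too small for post-hoc loadings")
                continue
            sel = idp_table.subject_ids.isin(ids)
            per_group[label] = {
                "idp": structure_loadings(load_x_tab.select_subjects(ids), u1[sel], mode=1),
                "nonidp": structure_loadings(load_y_tab.select_subjects(ids), v1[sel], mode=1),
            }
        analysis.subgroup_loadings = per_group
        if len(per_group) == 2:
            li = [per_group[g]["idp"]["loading"].to_numpy() for g in (IMPROVER, DECLINER)]
            ln = [per_group[g]["nonidp"]["loading"].to_numpy() for g in (IMPROVER, DECLINER)]
            analysis.congruence_idp = factor_congruence(*li)
            analysis.congruence_nonidp = factor_congruence(*ln)
    return analysis
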