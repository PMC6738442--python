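"""Cognitive change scores and extreme-group selection.

Two change measures are implemented:

* residualized change (RCA): the standardized residual of the follow-up
  score regressed on the baseline score — uncorrelated with baseline by
  construction, and the basis for selecting "improver" and "decliner"
  subgroups;
* raw difference scores (RDS): later minus earlier wave after z-scoring
  each wave — negatively correlated with baseline under imperfect
  reliability (regression to the mean), which is why RCA drives subject
  selection while RDS is only used as an adjustment covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChangeScoreSet",
    "GroupAssignment",
    "residualized_change",
    "raw_difference_change",
    "change_scores_from_panel",
    "select_extreme_groups",
    "adjust_for_change",
]

IMPROVER, DECLINER, EXCLUDED = "improver", "decliner", "excluded"


@dataclass
class ChangeScoreSet:
    """Residualized change plus simple-regression statistics.

    ``residualized_z`` has mean 0 / SD 1 over the fitting sample;
    ``beta`` is the standardized slope so ``r2 == beta**2``.
    """

    residualized_z: pd.Series
    beta: float
    r2: float
    zero_variance: bool = False
    cdelta: pd.DataFrame | None = None  # raw-difference scores, one per column


@dataclass
class GroupAssignment:
    labels: pd.Series  # improver / decliner / excluded
    cutoff: float

    @property
    def n_improvers(self) -> int:
        return int((self.labels == IMPROVER).sum())

    @property
    def n_decliners(self) -> int:
        return int((self.labels == DECLINER).sum())

    @property
    def n_excluded(self) -> int:
        return int((self.labels == EXCLUDED).sum())

    @property
    def n_retained(self) -> int:
        return self.n_improvers + self.n_decliners

    def subjects(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def _zscore(x: np.ndarray) -> np.ndarray:
    # population SD (ddof=0): a two-point wave [0, 2] maps to [-1, 1]
    sd = x.std()
    if sd == 0:
        raise ValueError("constant wave cannot be z-scored")
    return (x - x.mean()) / sd


def residualized_change(baseline: pd.Series, followup: pd.Series) -> ChangeScoreSet:
    """Standardized residual of follow-up regressed on baseline.

    Fit on complete pairs; residuals are divided by their sample SD, so the
    result is exactly mean-0 / SD-1 and exactly uncorrelated with baseline.
    Subjects missing either wave get a missing change score.
    """
    baseline, followup = baseline.align(followup, join="inner")
    obs = baseline.notna() & followup.notna()
    if obs.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    x = baseline[obs].to_numpy(dtype=float)
    y = followup[obs].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValueError("constant baseline: regression is degenerate")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sd = resid.std()
    zero_variance = sd < 1e-12
    z = resid if zero_variance else resid / sd
    if zero_variance:
        warnings.warn("residuals have zero variance; standardization skipped")

    beta = float(slope * x.std() / y.std()) if y.std() > 0 else 0.0
    r2 = float(beta**2)
    out = pd.Series(np.nan, index=baseline.index, name="residualized_z")
    out[obs] = z
    return ChangeScoreSet(out, beta=beta, r2=r2, zero_variance=zero_variance)


def raw_difference_change(wave_a: pd.Series, wave_b: pd.Series) -> pd.Series:
    """Normalized later-minus-earlier difference: z(wave_b) - z(wave_a),
    z-scored on the complete-pair subset; missing in either wave propagates."""
    wave_a, wave_b = wave_a.align(wave_b, join="inner")
    obs = wave_a.notna() & wave_b.notna()
    if obs.sum() < 2:
        raise ValueError("need at least 2 complete pairs")
    za = _zscore(wave_a[obs].to_numpy(dtype=float))
    zb = _zscore(wave_b[obs].to_numpy(dtype=float))
    out = pd.Series(np.nan, index=wave_a.index, name="cdelta")
    out[obs] = zb - za
    return out


def change_scores_from_panel(panel: pd.DataFrame) -> ChangeScoreSet:
    """Full change-score set from a 4-wave IQ panel (columns iq11, iq20,
    iq57, iq63): residualized change of iq57 on iq20 plus the three raw
    difference scores C∆1 = iq57−iq20, C∆2 = iq63−iq57, C∆3 = iq20−iq11."""
    cs = residualized_change(panel["iq20"], panel["iq57"])
    cs.cdelta = pd.DataFrame(
        {
            "cdelta1": raw_difference_change(panel["iq20"], panel["iq57"]),
            "cdelta2": raw_difference_change(panel["iq57"], panel["iq63"]),
            "cdelta3": raw_difference_change(panel["iq11"], panel["iq20"]),
        }
    )
    return cs


def select_extreme_groups(
    change: ChangeScoreSet,
    cutoff: float = 3.0,
    *,
    n_top: int | None = None,
    n_bottom: int | None = None,
) -> GroupAssignment:
    """Label subjects improver / decliner / excluded from residualized change.

    Subjects with |z| > cutoff are excluded as extreme scores.  By default
    every retained subject is kept and split at z = 0 (improvers z > 0).
    ``n_top``/``n_bottom`` instead select only the strongest improvers and
    decliners (true extreme-groups sampling); everyone else is excluded.
    """
    z = change.residualized_z
    labels = pd.Series(EXCLUDED, index=z.index, name="group", dtype=object)
    retained = z.notna() & (z.abs() <= cutoff)
    if n_top is not None or n_bottom is not None:
        zr = z[retained].sort_values()
        if n_bottom:
            labels[zr.index[: int(n_bottom)]] = DECLINER
        if n_top:
            labels[zr.index[-int(n_top):]] = IMPROVER
    else:
        labels[retained & (z > 0)] = IMPROVER
        labels[retained & (z <= 0)] = DECLINER
    ga = GroupAssignment(labels, cutoff)
    if ga.n_retained == 0:
        raise ValueError("extreme-group selection retained no subjects")
    return ga


def adjust_for_change(
    x: pd.Series, y: pd.Series, cdelta: pd.Series
) -> tuple[float, float, int]:
    """Partial correlation of x and y given a change score.

    Both variables are residualized on [intercept | cdelta]; returns the
    Pearson r of the residuals with a two-sided p from t on n - 3 degrees
    of freedom, plus the complete-triple count.  A constant change score
    falls back to the plain correlation (with a warning).
    """
    df = pd.concat({"x": x, "y": y, "c": cdelta}, axis=1).dropna()
    n = len(df)
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    xv, yv, cv = (df[k].to_numpy(dtype=float) for k in ("x", "y", "c"))
    if cv.std() < 1e-12:
        warnings.warn("constant adjustment covariate; returning plain correlation")
        r = float(np.corrcoef(xv, yv)[0, 1])
        dof = n - 2
    else:
        design = np.column_stack([np.ones(n), cv])
        bx, *_ = np.linalg.lstsq(design, xv, rcond=None)
        by, *_ = np.linalg.lstsq(design, yv, rcond=None)
        r = float(np.corrcoef(xv - design @ bx, yv - design @ by)[0, 1])
        dof = n - 3
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = np.finfo(float).tiny
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, max(p, np.finfo(float).tiny), n
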