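"""Synthetic cohort generator.

Emulates the data structure of a late-midlife birth-cohort imaging study:
a subjects x IDP matrix (imaging-derived phenotypes in five modality
blocks), a subjects x non-IDP matrix (cognitive, demographic, health and
lifestyle measures), four nuisance confounds, and a four-wave longitudinal
IQ panel used for extreme-group selection.

The generating model for each variable j is a single- (or multi-) factor
model with confound contamination,

    x_ij = a_j * z_i + sum_k c_jk * g_ik + eps_ij

with latent mode score z, confounds g_k and noise eps all standard normal.
For a single factor with unit noise the best linear combination of a set
correlates with z at rho = sqrt(a'a / (a'a + 1)), so the population first
canonical correlation between the two sets is rho_x * rho_y.  The planted
loadings and latent scores are kept in a ground-truth side channel that the
analysis stages never see, which makes parameter-recovery tests possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CONFOUND_NAMES, ConfoundSet, PhenotypeTable

__all__ = [
    "BlockSpec",
    "GeneratorConfig",
    "LatentTruth",
    "CohortBundle",
    "default_block_manifest",
    "mode_strength_for_rho",
    "strengths_for_canonical_correlation",
    "generate_cohort",
    "generate_iq_panel",
    "inject_missingness",
]

IQ_WAVES = ("iq11", "iq20", "iq57", "iq63")

#: Diffusivity indices summarised per white-matter tract.
TBSS_INDICES = ("FA", "MO", "MD", "L1", "L2", "L3")


@dataclass(frozen=True)
class BlockSpec:
    """One variable block: name, variable set ('idp'/'nonidp'), subdomain,
    number of variables, and fraction of members with negative polarity
    (lower raw value = favourable)."""

    name: str
    var_set: str
    subdomain: str
    count: int
    frac_negative: float = 0.0


def default_block_manifest() -> list[BlockSpec]:
    """Block layout of the emulated study: 453 IDPs across five imaging
    blocks and 70 non-IDPs across four subdomains."""
    return [
        # -- imaging-derived phenotypes (453) --
        BlockSpec("SIENAX", "idp", "global_volume", 10, 0.0),
        BlockSpec("FIRST", "idp", "subcortical_volume", 15, 0.0),
        BlockSpec("FAST", "idp", "gm_roi_volume", 139, 0.0),
        # white-matter hyperintensity load: higher is worse
        BlockSpec("BIANCA", "idp", "wmh_load", 1, 1.0),
        BlockSpec("TBSS", "idp", "wm_microstructure", 288, 0.5),
        # -- non-imaging measures (70) --
        # about half the cognitive battery is latency/error scored
        BlockSpec("cognition", "nonidp", "cognition", 31, 0.45),
        BlockSpec("demographic", "nonidp", "demographic", 8, 0.25),
        BlockSpec("health", "nonidp", "health", 22, 0.5),
        BlockSpec("lifestyle", "nonidp", "lifestyle", 9, 0.44),
    ]


def mode_strength_for_rho(rho: float) -> float:
    """Total loading norm m = sqrt(a'a) giving set-latent correlation rho.

    Inverts rho = m / sqrt(m^2 + 1).
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    return rho / math.sqrt(1.0 - rho * rho)


def strengths_for_canonical_correlation(rc: float) -> tuple[float, float]:
    """Symmetric (mode_strength_idp, mode_strength_nonidp) pair planting a
    population first canonical correlation of ``rc``."""
    if not 0 <= rc < 1:
        raise ValueError("rc must be in [0, 1)")
    m = mode_strength_for_rho(math.sqrt(rc))
    return m, m


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``mode_strength_*`` is the Euclidean norm of the planted loading vector
    of a set; see :func:`strengths_for_canonical_correlation` for the map
    to a population canonical correlation.  ``frac_loaded`` is the fraction
    of variables in each set carrying the latent mode.  ``confound_effects``
    are per-confound loading scales; one sentinel variable per confound is
    additionally given a strong loading so confound leakage is present by
    construction.  ``n_modes`` > 1 plants additional orthogonal latent
    modes (at geometrically decaying strength) for power studies.
    """

    n_subjects: int = 193
    block_manifest: list[BlockSpec] = field(default_factory=default_block_manifest)
    mode_strength_idp: float = 1.2
    mode_strength_nonidp: float = 1.2
    frac_loaded: float = 0.3
    confound_effects: tuple[float, float, float, float] = (0.3, 0.3, 0.3, 0.3)
    missing_rate_idp: float = 0.0
    missing_rate_nonidp: float = 0.2
    iq_corr_20_57: float = 0.71
    n_modes: int = 1
    ordinal_levels: int = 0
    seed: int = 0

    @property
    def n_idp(self) -> int:
        return sum(b.count for b in self.block_manifest if b.var_set == "idp")

    @property
    def n_nonidp(self) -> int:
        return sum(b.count for b in self.block_manifest if b.var_set == "nonidp")

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        for rate in (self.missing_rate_idp, self.missing_rate_nonidp):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate {rate} outside [0, 1]")
        if not 0.0 <= self.frac_loaded <= 1.0:
            raise ValueError("frac_loaded must be in [0, 1]")
        if not -1.0 < self.iq_corr_20_57 < 1.0 or not math.isfinite(self.iq_corr_20_57):
            raise ValueError("iq_corr_20_57 must be finite and in (-1, 1)")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.n_idp < 1 or self.n_nonidp < 1:
            raise ValueError("block manifest must provide idp and nonidp blocks")

    def with_counts(self, n_idp: int, n_nonidp: int) -> "GeneratorConfig":
        """Shrink the manifest to ``n_idp``/``n_nonidp`` variables while
        keeping the relative block layout (for fast tests)."""
        blocks: list[BlockSpec] = []
        for var_set, total in (("idp", n_idp), ("nonidp", n_nonidp)):
            members = [b for b in self.block_manifest if b.var_set == var_set]
            orig_total = sum(b.count for b in members)
            remaining = total
            for i, b in enumerate(members):
                if i == len(members) - 1:
                    cnt = remaining
                else:
                    cnt = max(1, round(total * b.count / orig_total))
                    cnt = min(cnt, remaining - (len(members) - 1 - i))
                remaining -= cnt
                if cnt > 0:
                    blocks.append(replace(b, count=cnt))
        return replace(self, block_manifest=blocks)


@dataclass
class LatentTruth:
    """Ground truth of the generator, never consumed by analysis stages."""

    z: np.ndarray  # (n_subjects, n_modes) latent mode scores
    loadings_idp: np.ndarray  # (n_idp, n_modes)
    loadings_nonidp: np.ndarray  # (n_nonidp, n_modes)
    confound_loadings_idp: np.ndarray  # (n_idp, 4)
    confound_loadings_nonidp: np.ndarray  # (n_nonidp, 4)


@dataclass
class CohortBundle:
    """Everything one synthetic study produces, with aligned subjects."""

    idp_table: PhenotypeTable
    nonidp_table: PhenotypeTable
    confounds: ConfoundSet
    iq_panel: pd.DataFrame
    latent_truth: LatentTruth
    config: GeneratorConfig

    def __post_init__(self) -> None:
        ids = self.idp_table.subject_ids
        for other in (
            self.nonidp_table.subject_ids,
            self.confounds.subject_ids,
            self.iq_panel.index,
        ):
            if not ids.equals(other):
                raise ValueError("subject IDs are not aligned across tables")


# ---------------------------------------------------------------------------
# manifest construction
# ---------------------------------------------------------------------------

def _build_manifest(blocks: list[BlockSpec], var_set: str) -> pd.DataFrame:
    rows = []
    for b in blocks:
        if b.var_set != var_set:
            continue
        if b.name == "TBSS":
            # one variable per (tract, diffusivity index); shrunk manifests
            # simply truncate the tract x index grid
            for k in range(b.count):
                tract, idx = divmod(k, len(TBSS_INDICES))
                name = TBSS_INDICES[idx]
                # FA is 'higher = more coherent'; diffusivities flagged
                # lower-is-better in midlife atrophy terms
                pol = 1 if name in ("FA", "MO", "L1") else -1
                rows.append((f"TBSS_tract{tract + 1:02d}_{name}", b.name, b.subdomain, pol))
        else:
            n_neg = round(b.count * b.frac_negative)
            for i in range(b.count):
                pol = -1 if i < n_neg else 1
                rows.append((f"{b.name}_{i + 1:03d}", b.name, b.subdomain, pol))
    return pd.DataFrame(rows, columns=["variable", "block", "subdomain", "polarity"])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _planted_loadings(
    rng: np.random.Generator, n_var: int, strength: float, frac: float, n_modes: int
) -> np.ndarray:
    """Loading matrix with a random loaded subset per mode; each mode's
    loading vector is scaled to the requested total norm (decaying by
    1/2 per extra mode)."""
    A = np.zeros((n_var, n_modes))
    n_loaded = max(1, round(frac * n_var)) if strength > 0 else 0
    for m in range(n_modes):
        if n_loaded == 0:
            continue
        idx = rng.choice(n_var, size=n_loaded, replace=False)
        raw = rng.normal(size=n_loaded)
        norm = np.linalg.norm(raw)
        target = strength * 0.5**m
        if norm > 0:
            A[idx, m] = raw / norm * target
    return A


def _confound_loadings(
    rng: np.random.Generator, n_var: int, effects: np.ndarray
) -> np.ndarray:
    C = rng.normal(size=(n_var, 4)) * effects[None, :]
    # sentinel variables guarantee detectable leakage per confound
    for k in range(4):
        if effects[k] > 0 and n_var > k:
            C[k, k] = max(abs(C[k, k]), 0.8)
    return C


def _ordinalize(x: np.ndarray, levels: int) -> np.ndarray:
    """Threshold a continuous latent at equal-mass cut points, emulating
    ordinal survey items (analysis treats everything as ranks anyway)."""
    qs = np.quantile(x, np.linspace(0, 1, levels + 1)[1:-1])
    return np.searchsorted(qs, x).astype(float)


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Draw one cohort. The same config (including seed) yields a
    bit-identical bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")

    man_idp = _build_manifest(config.block_manifest, "idp")
    man_non = _build_manifest(config.block_manifest, "nonidp")
    effects = np.asarray(config.confound_effects, dtype=float)

    z = rng.normal(size=(n, config.n_modes))
    g = rng.normal(size=(n, 4))

    A_idp = _planted_loadings(
        rng, len(man_idp), config.mode_strength_idp, config.frac_loaded, config.n_modes
    )
    A_non = _planted_loadings(
        rng, len(man_non), config.mode_strength_nonidp, config.frac_loaded, config.n_modes
    )
    C_idp = _confound_loadings(rng, len(man_idp), effects)
    C_non = _confound_loadings(rng, len(man_non), effects)

    X = z @ A_idp.T + g @ C_idp.T + rng.normal(size=(n, len(man_idp)))
    Y = z @ A_non.T + g @ C_non.T + rng.normal(size=(n, len(man_non)))

    # a handful of survey-style non-IDPs become ordinal by thresholding
    if config.ordinal_levels >= 2:
        is_survey = man_non["block"].isin(["demographic", "health", "lifestyle"])
        ordinal_cols = np.flatnonzero(is_survey.to_numpy())[:6]
        for j in ordinal_cols:
            Y[:, j] = _ordinalize(Y[:, j], config.ordinal_levels)

    idp = PhenotypeTable(pd.DataFrame(X, index=ids, columns=man_idp["variable"]), man_idp)
    non = PhenotypeTable(pd.DataFrame(Y, index=ids, columns=man_non["variable"]), man_non)

    idp = inject_missingness(idp, config.missing_rate_idp, _child_seed(config.seed, 1))
    non = inject_missingness(non, config.missing_rate_nonidp, _child_seed(config.seed, 2))

    confounds = ConfoundSet(pd.DataFrame(g, index=ids, columns=list(CONFOUND_NAMES)))
    iq_panel = generate_iq_panel(n, config.iq_corr_20_57, _child_seed(config.seed, 3))
    iq_panel.index = ids

    truth = LatentTruth(
        z=z,
        loadings_idp=A_idp,
        loadings_nonidp=A_non,
        confound_loadings_idp=C_idp,
        confound_loadings_nonidp=C_non,
    )
    return CohortBundle(idp, non, confounds, iq_panel, truth, config)


def _child_seed(seed: int, k: int) -> int:
    """Counter-based child seed, kept below 2**31."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def generate_iq_panel(n: int, target_corr_20_57: float, seed: int) -> pd.DataFrame:
    """Four correlated Gaussian IQ wave scores (ages ~11, ~20, ~57, ~63).

    A shared-factor model gives every wave a loading sqrt(|r|) on a common
    intelligence factor so that the population correlation between the
    age-20 and age-57 waves equals ``target_corr_20_57``.
    """
    if not math.isfinite(target_corr_20_57) or not -1 < target_corr_20_57 < 1:
        raise ValueError("target correlation must be finite and in (-1, 1)")
    rng = np.random.default_rng(seed)
    lam = math.sqrt(abs(target_corr_20_57))
    sign = 1.0 if target_corr_20_57 >= 0 else -1.0
    gfac = rng.normal(size=n)
    noise = rng.normal(size=(n, 4))
    resid = math.sqrt(max(0.0, 1.0 - lam * lam))
    scores = np.empty((n, 4))
    for j, _wave in enumerate(IQ_WAVES):
        s = sign if _wave == "iq57" else 1.0  # negative targets flip one wave
        scores[:, j] = s * lam * gfac + resid * noise[:, j]
    ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(scores, index=ids, columns=list(IQ_WAVES))


def inject_missingness(table: PhenotypeTable, rate: float, seed: int) -> PhenotypeTable:
    """Mask each entry missing-completely-at-random with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"missing rate {rate} outside [0, 1]")
    if rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(table.shape) < rate
    vals = table.matrix()
    vals[mask] = np.nan
    return table.with_values(vals)
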