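"""End-to-end orchestration: simulate → preprocess → extreme groups →
univariate screen → CCA, with TSV persistence and a reproducible report.

All tabular artifacts are tab-separated text with a header row and the
subject ID in the first column; missing values are written as "NA" and
both "NA" and empty fields parse back as missing.  Every output file
starts with a comment line carrying the config hash so a report can be
traced to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cca as cca_mod
from . import change_scores as cs_mod
from . import preprocess as pp_mod
from . import univariate as uv_mod
from .synthetic import CohortBundle, GeneratorConfig, generate_cohort
from .types import CONFOUND_NAMES, ConfoundSet, PhenotypeTable

__all__ = [
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_confounds_tsv",
    "write_confounds_tsv",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "stage_seed",
]

NA_VALUES = ["NA", ""]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    # pandas silently mangles duplicate headers, so check them ourselves
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            raise ValueError(f"no header row in {path}")
    seen: set[str] = set()
    for name in header[1:]:
        if name in seen:
            raise ValueError(f"duplicate column '{name}' in {path}")
        seen.add(name)
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=NA_VALUES, keep_default_na=False,
        index_col=0,
    )


def _write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", float_format="%.10g")


def read_phenotype_tsv(
    values_path: str | Path, manifest_path: str | Path
) -> PhenotypeTable:
    """Load a phenotype matrix and its variable manifest."""
    values = _read_tsv(values_path).astype(float)
    manifest = pd.read_csv(
        manifest_path, sep="\t", comment="#", na_values=NA_VALUES,
        keep_default_na=False,
    )
    manifest["polarity"] = manifest["polarity"].astype(int)
    return PhenotypeTable(values, manifest)


def write_phenotype_tsv(
    table: PhenotypeTable,
    values_path: str | Path,
    manifest_path: str | Path | None = None,
    *,
    comment: str | None = None,
) -> None:
    _write_tsv(table.values, values_path, comment)
    if manifest_path is not None:
        _write_tsv(table.manifest.set_index("variable"), manifest_path, comment)


def read_confounds_tsv(path: str | Path) -> ConfoundSet:
    df = _read_tsv(path).astype(float)
    return ConfoundSet(df[list(CONFOUND_NAMES)])


def write_confounds_tsv(
    confounds: ConfoundSet, path: str | Path, *, comment: str | None = None
) -> None:
    _write_tsv(confounds.values, path, comment)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible run.  Exactly one of ``generator`` (synthetic
    cohort) or ``input_dir`` (TSVs from a previous simulate) is used."""

    out_dir: str = "ccamode_run"
    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    alpha: float = 0.05
    d: int = 30
    n_perm: int = 10000
    cutoff: float = 3.0
    master_seed: int = 0
    run_univariate: bool = True
    run_cca: bool = True
    adjust_cdelta: int | None = None  # 1, 2 or 3 to also run adjusted screen

    def validate(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("supply exactly one of generator config or input_dir")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)

    def config_hash(self) -> str:
        blob = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        enc = json.dumps(blob, sort_keys=True, default=str).encode()
        return hashlib.sha256(enc).hexdigest()[:12]


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Counter-based per-stage seed (< 2**31), so toggling one stage never
    perturbs another stage's random stream."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(100 + stage_index,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    config_hash: str
    stage_timings: dict = field(default_factory=dict)
    n_subjects: int = 0
    n_idp: int = 0
    n_nonidp: int = 0
    impute_lambda: float | None = None
    impute_iterations: int | None = None
    group_counts: dict = field(default_factory=dict)
    n_univariate_records: int = 0
    threshold: dict = field(default_factory=dict)
    significant_pairs: list = field(default_factory=list)
    rc: list = field(default_factory=list)
    p_fwe: list = field(default_factory=list)
    top_loadings: list = field(default_factory=list)
    congruence: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = [
            "# ccamode run report",
            f"config hash: {self.config_hash}",
            f"subjects: {self.n_subjects}; IDPs: {self.n_idp}; non-IDPs: {self.n_nonidp}",
            f"groups: {self.group_counts}",
        ]
        if self.impute_lambda is not None:
            lines.append(
                f"soft-impute: lambda={self.impute_lambda:.4g}, "
                f"iterations={self.impute_iterations}"
            )
        if self.n_univariate_records:
            lines.append(f"univariate records: {self.n_univariate_records}")
            lines.append(f"thresholds: {self.threshold}")
            lines.append(f"significant pairs (FWE): {len(self.significant_pairs)}")
            for pair in self.significant_pairs[:20]:
                lines.append(f"  - {pair}")
        if self.rc:
            lines.append(
                f"CCA modes: {len(self.rc)}; rc_1 = {self.rc[0]:.3f}; "
                f"p_fwe_1 = {self.p_fwe[0]:.4g}"
            )
            lines.append(f"congruence: {self.congruence}")
            lines.append("top mode-1 loadings:")
            for item in self.top_loadings[:10]:
                lines.append(f"  - {item}")
        lines.append(f"stage timings (s): { {k: round(v, 2) for k, v in self.stage_timings.items()} }")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_bundle_tables(input_dir: Path):
    idp = read_phenotype_tsv(input_dir / "idp.tsv", input_dir / "idp_manifest.tsv")
    non = read_phenotype_tsv(input_dir / "nonidp.tsv", input_dir / "nonidp_manifest.tsv")
    conf = read_confounds_tsv(input_dir / "confounds.tsv")
    panel = _read_tsv(input_dir / "iq_panel.tsv").astype(float)
    return idp, non, conf, panel


def save_bundle(bundle: CohortBundle, out_dir: str | Path, comment: str | None = None) -> None:
    out = Path(out_dir)
    write_phenotype_tsv(
        bundle.idp_table, out / "idp.tsv", out / "idp_manifest.tsv", comment=comment
    )
    write_phenotype_tsv(
        bundle.nonidp_table, out / "nonidp.tsv", out / "nonidp_manifest.tsv", comment=comment
    )
    write_confounds_tsv(bundle.confounds, out / "confounds.tsv", comment=comment)
    _write_tsv(bundle.iq_panel, out / "iq_panel.tsv", comment)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the staged analysis with persisted intermediates.

    Identical config (including seeds) yields an identical report apart
    from timings, and byte-identical TSV outputs.
    """
    config.validate()
    chash = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=chash)
    t0 = time.perf_counter()

    # -- stage 1: cohort ------------------------------------------------
    if config.generator is not None:
        gen = config.generator
        bundle = generate_cohort(gen)
        save_bundle(bundle, out / "cohort", comment=chash)
        idp, non, conf, panel = (
            bundle.idp_table, bundle.nonidp_table, bundle.confounds, bundle.iq_panel,
        )
    else:
        idp, non, conf, panel = _load_bundle_tables(Path(config.input_dir))
    report.n_subjects, report.n_idp = idp.shape
    report.n_nonidp = non.shape[1]
    report.stage_timings["cohort"] = time.perf_counter() - t0

    # -- stage 2: preprocess --------------------------------------------
    t0 = time.perf_counter()
    idp_pre, _ = pp_mod.preprocess_tables(idp, conf, impute=False)
    non_pre, _ = pp_mod.preprocess_tables(non, conf, impute=False)
    write_phenotype_tsv(idp_pre, out / "idp_preprocessed.tsv", comment=chash)
    write_phenotype_tsv(non_pre, out / "nonidp_preprocessed.tsv", comment=chash)
    report.stage_timings["preprocess"] = time.perf_counter() - t0

    # -- stage 3: change scores + extreme groups ------------------------
    t0 = time.perf_counter()
    change = cs_mod.change_scores_from_panel(panel)
    groups = cs_mod.select_extreme_groups(change, cutoff=config.cutoff)
    eg = pd.DataFrame(
        {"residualized_z": change.residualized_z, "group": groups.labels}
    ).join(change.cdelta)
    _write_tsv(eg, out / "change_scores.tsv", chash)
    report.group_counts = {
        "improvers": groups.n_improvers,
        "decliners": groups.n_decliners,
        "excluded": groups.n_excluded,
    }
    report.stage_timings["egd"] = time.perf_counter() - t0

    # -- stage 4: univariate screen -------------------------------------
    if config.run_univariate:
        t0 = time.perf_counter()
        records = uv_mod.pairwise_correlations(idp_pre, non_pre)
        thresh = uv_mod.multiple_testing(records, alpha=config.alpha)
        _write_tsv(records.set_index("var_x"), out / "univariate_records.tsv", chash)
        manhattan = uv_mod.manhattan_export(records, thresh)
        _write_tsv(manhattan.set_index("x_position"), out / "manhattan.tsv", chash)
        try:
            uv_mod.manhattan_figure(manhattan, str(out / "manhattan.svg"))
        except Exception as exc:  # plotting is never load-bearing
            warnings.warn(f"manhattan figure not rendered: {exc}")
        consistency = uv_mod.subgroup_consistency(idp_pre, non_pre, groups, records)
        if len(consistency):
            _write_tsv(consistency.set_index("var_x"), out / "subgroup_consistency.tsv", chash)
        if config.adjust_cdelta is not None:
            cd = change.cdelta[f"cdelta{config.adjust_cdelta}"]
            adj = uv_mod.adjust_records_for_change(idp_pre, non_pre, cd)
            uv_mod.multiple_testing(adj, alpha=config.alpha)
            _write_tsv(adj.set_index("var_x"), out / "univariate_adjusted.tsv", chash)
        report.n_univariate_records = len(records)
        report.threshold = {
            "alpha": thresh.alpha,
            "m": thresh.m,
            "bonferroni_p": thresh.bonferroni_p,
            "n_pass_fwe": thresh.n_pass_fwe,
            "n_pass_fdr": thresh.n_pass_fdr,
        }
        sig = records[records["pass_fwe"]].sort_values("p")
        report.significant_pairs = [
            f"{r.var_x} x {r.var_y}: r={r.r:.3f}, p={r.p:.3g}"
            for r in sig.itertuples()
        ]
        report.stage_timings["univariate"] = time.perf_counter() - t0

    # -- stage 5: CCA ----------------------------------------------------
    if config.run_cca:
        t0 = time.perf_counter()
        idp_cca, info_x = pp_mod.soft_impute(idp_pre) if not idp_pre.is_complete() else (idp_pre, None)
        non_cca, info_y = pp_mod.soft_impute(non_pre) if not non_pre.is_complete() else (non_pre, None)
        info = info_y or info_x
        if info is not None:
            report.impute_lambda = info.lam
            report.impute_iterations = info.n_iter
        analysis = cca_mod.cca_analysis(
            idp_cca,
            non_cca,
            d=config.d,
            n_perm=config.n_perm,
            seed=stage_seed(config.master_seed, 5),
            groups=groups,
            loading_tables=(idp_pre, non_pre),
        )
        rc_tab = pd.DataFrame(
            {"mode": np.arange(1, analysis.cca.n_modes + 1),
             "rc": analysis.cca.rc, "p_fwe": analysis.cca.p_fwe}
        ).set_index("mode")
        _write_tsv(rc_tab, out / "cca_modes.tsv", chash)
        _write_tsv(
            pd.concat([analysis.loadings_idp, analysis.loadings_nonidp]).set_index("variable"),
            out / "cca_loadings.tsv", chash,
        )
        _write_tsv(
            pd.concat([analysis.importance_idp, analysis.importance_nonidp]).set_index("subdomain"),
            out / "subdomain_importance.tsv", chash,
        )
        variates = pd.DataFrame(
            {"U1": analysis.cca.U[:, 0], "V1": analysis.cca.V[:, 0],
             "group": groups.labels.reindex(idp_cca.subject_ids)},
            index=idp_cca.subject_ids,
        )
        _write_tsv(variates, out / "cca_variates.tsv", chash)

        report.rc = [float(v) for v in analysis.cca.rc]
        report.p_fwe = [float(v) for v in analysis.cca.p_fwe]
        all_loads = pd.concat(
            [analysis.loadings_nonidp, analysis.loadings_idp], ignore_index=True
        )
        top = all_loads.loc[all_loads["loading"].abs().sort_values(ascending=False).index]
        report.top_loadings = [
            f"{r.variable} ({r.block}): loading={r.loading:.3f}, r2={r.r2 * 100:.1f}%"
            for r in top.head(10).itertuples()
        ]
        report.congruence = {
            "idp": analysis.congruence_idp,
            "nonidp": analysis.congruence_nonidp,
        }
        report.stage_timings["cca"] = time.perf_counter() - t0

    (out / "report.md").write_text(report.to_markdown())
    return report
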