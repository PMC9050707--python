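"""End-to-end orchestration: data -> preprocessing -> differential ->
composite -> modules -> enrichment -> integration -> report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as mstats
from .io import Dataset, load_dataset, split_subsamples, write_table
from .simulate import SimulationConfig, simulate_dataset, simulate_proteome
from .preprocess import impute_and_log, combat_adjust
from .differential import (
    build_design,
    class_direction_tally,
    run_discovery_replication,
    sensitivity_analysis,
)
from .composite import select_best_model, score_group_association, DEFAULT_K_GRID
from .ica import ConsensusICA
from .enrichment import cross_omics_correlation, enrich_modules, recurrent_feature_report

logger = logging.getLogger("metabomod")

__all__ = ["PipelineConfig", "run_pipeline", "generate_report", "cohort_table"]


@dataclass
class PipelineConfig:
    """Every pipeline constant in one place; nothing is hard-coded downstream.

    Either ``simulation`` (a :class:`SimulationConfig`) or ``paths`` (keys
    ``matrix``, ``metadata``, ``annotation``) must be provided.
    """

    schema_version: int = 1
    seed: int = 0
    simulation: SimulationConfig | None = None
    paths: dict[str, str] | None = None
    covariates: tuple[str, ...] = ("age", "race", "bmi")
    # decision thresholds
    discovery_fdr: float = 0.1
    replication_p: float = 0.05
    module_p: float = 0.05
    enrichment_p: float = 0.05
    correlation_p: float = 0.05
    # composite score
    K_grid: tuple = DEFAULT_K_GRID
    panels: tuple = ("HD4", "CLP", "combined")
    alpha_grid: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
    n_lambda: int = 50
    # consensus ICA
    ica_runs: int = 50
    variance_fraction: float = 0.80
    sd_multiplier: float = 2.0
    match_r: float = 0.90
    support_frac: float = 0.80
    include_proteome: bool = True
    sensitivity_covariates: tuple[str, ...] = (
        "gerd",
        "diabetes",
        "heart_disease",
        "hypertension",
        "dust_exposure",
    )

    def __post_init__(self) -> None:
        for name in (
            "discovery_fdr",
            "replication_p",
            "module_p",
            "enrichment_p",
            "correlation_p",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.simulation is None and self.paths is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            for key in ("module_size_range", "protein_module_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "module_group_effect" in sim and sim["module_group_effect"] is not None:
                sim["module_group_effect"] = tuple(sim["module_group_effect"])
            raw["simulation"] = SimulationConfig(**sim)
        for key in ("covariates", "K_grid", "panels", "alpha_grid", "sensitivity_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _log_stage(name: str, t0: float, **shapes) -> None:
    desc = " ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, desc)


def cohort_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Descriptive case/control statistics per subsample and overall.

    Age and BMI are compared by Welch t-test from the group summaries; the
    caucasian/other split by Yates-corrected chi-squared.
    """
    rows = []
    scopes = [("all", samples)] + [
        (s, samples[samples["subsample"] == s]) for s in ("discovery", "replication")
    ]
    for scope, sub in scopes:
        if sub.empty:
            continue
        case = sub[sub["group"] == "case"]
        ctrl = sub[sub["group"] == "control"]
        if case.empty or ctrl.empty:
            continue
        for var in ("age", "bmi"):
            res = mstats.welch_t_from_summary(
                case[var].mean(), case[var].std(), len(case),
                ctrl[var].mean(), ctrl[var].std(), len(ctrl),
            )
            rows.append(
                {
                    "scope": scope, "variable": var,
                    "case_mean": case[var].mean(), "case_sd": case[var].std(),
                    "control_mean": ctrl[var].mean(), "control_sd": ctrl[var].std(),
                    "n_case": len(case), "n_control": len(ctrl),
                    "p": res.p_value,
                }
            )
        a = int((case["race"] == "caucasian").sum())
        b = int((case["race"] != "caucasian").sum())
        c = int((ctrl["race"] == "caucasian").sum())
        d = int((ctrl["race"] != "caucasian").sum())
        try:
            p_race = mstats.chi2_yates_2x2(a, b, c, d).p_value
        except ValueError:
            p_race = np.nan
        rows.append(
            {
                "scope": scope, "variable": "race_caucasian",
                "case_mean": a, "case_sd": np.nan,
                "control_mean": c, "control_sd": np.nan,
                "n_case": len(case), "n_control": len(ctrl),
                "p": p_race,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis; returns the bundle of results.

    Stages: acquire data (simulate or load) -> impute -> differential
    (discovery/replication/combined + sensitivity + class tallies) ->
    composite grid -> consensus ICA modules on the batch-adjusted metabolome
    (and the proteome when present) -> pathway enrichment -> cross-omics
    module correlation. Every stochastic stage derives from ``config.seed``.
    """
    t0 = time.time()
    bundle: dict = {"config": config}
    try:
        if config.paths is not None:
            dataset = load_dataset(
                config.paths["matrix"], config.paths["metadata"], config.paths["annotation"]
            )
            truth = None
            proteome = None
        else:
            dataset, truth = simulate_dataset(config.simulation)
            proteome = None
            if config.include_proteome:
                proteome, prot_truth = simulate_proteome(
                    config.simulation, truth, dataset.samples
                )
                bundle["proteome_truth"] = prot_truth
        bundle["dataset"] = dataset
        bundle["truth"] = truth
        _log_stage("data", t0, samples=dataset.n_samples, features=dataset.n_features)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    try:
        t1 = time.time()
        matrix = impute_and_log(
            dataset.abundance, batch=dataset.samples["subsample"], already_logged=True
        )
        dataset = Dataset(matrix, dataset.samples, dataset.annotation)
        _log_stage("preprocess", t1)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        t1 = time.time()
        diff = run_discovery_replication(
            dataset,
            covariates=config.covariates,
            fdr=config.discovery_fdr,
            replication_p=config.replication_p,
        )
        bundle["differential"] = diff
        hits = diff["table"].index[diff["table"]["discovery_hit"]].tolist()
        interest = hits or diff["combined"].table.sort_values("p").head(5).index.tolist()
        sens = {}
        for extra in config.sensitivity_covariates:
            if extra not in dataset.samples.columns:
                continue
            res = sensitivity_analysis(
                matrix, dataset.samples, config.covariates, extra, features=interest
            )
            if res is not None:
                sens[extra] = res.table
        bundle["sensitivity"] = sens
        tallies = {}
        for sp in dataset.annotation["super_pathway"].unique():
            tallies[sp] = class_direction_tally(
                diff["combined"].table, dataset.annotation, "super_pathway", sp,
                fdr=config.discovery_fdr,
            )
        bundle["class_tallies"] = pd.DataFrame(tallies).T
        _log_stage("differential", t1, hits=len(hits))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'differential' failed: {exc}") from exc

    try:
        t1 = time.time()
        disc, rep = split_subsamples(dataset)
        y_tr = (disc.samples["group"] == "case").astype(int)
        y_te = (rep.samples["group"] == "case").astype(int)
        best, report, grid = select_best_model(
            disc.abundance, y_tr, rep.abundance, y_te,
            annotation=dataset.annotation,
            K_grid=config.K_grid, panels=config.panels, seed=config.seed,
            alpha_grid=config.alpha_grid, n_lambda=config.n_lambda,
        )
        assoc = score_group_association(
            report.scores, rep.samples, covariates=config.covariates
        )
        bundle["composite"] = {
            "model": best,
            "evaluation": report,
            "grid": grid,
            "association": assoc,
        }
        _log_stage("composite", t1, cells=len(grid), best_auc=f"{report.auc:.3f}")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'composite' failed: {exc}") from exc

    try:
        t1 = time.time()
        cov = build_design(dataset.samples, config.covariates).drop(
            columns=["const", "group"]
        )
        adjusted, _ = combat_adjust(
            dataset.abundance, dataset.samples["subsample"], covariates=cov
        )
        decomp = ConsensusICA(
            adjusted,
            variance_fraction=config.variance_fraction,
            n_runs=config.ica_runs,
            match_r=config.match_r,
            support_frac=config.support_frac,
            master_seed=config.seed,
        ).fit()
        modules = decomp.modules(config.sd_multiplier)
        trait = decomp.trait_association(
            dataset.samples, covariates=config.covariates, p_threshold=config.module_p
        )
        enr = enrich_modules(modules, dataset.annotation, level="sub_pathway")
        bundle["ica"] = {
            "decomposition": decomp,
            "modules": modules,
            "trait": trait,
            "enrichment": enr,
        }
        _log_stage("ica", t1, q=decomp.q, retained=len(modules))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'ica' failed: {exc}") from exc

    if config.include_proteome and config.paths is None:
        try:
            t1 = time.time()
            pdec = ConsensusICA(
                proteome.abundance,
                variance_fraction=config.variance_fraction,
                n_runs=config.ica_runs,
                match_r=config.match_r,
                support_frac=config.support_frac,
                master_seed=config.seed + 1,
            ).fit()
            pmods = pdec.modules(config.sd_multiplier)
            cross = cross_omics_correlation(
                decomp.sample_scores, pdec.sample_scores, p_threshold=config.correlation_p
            )
            recurrent = recurrent_feature_report(pmods)
            bundle["integration"] = {
                "protein_decomposition": pdec,
                "protein_modules": pmods,
                "cross_omics": cross,
                "recurrent": recurrent,
            }
            _log_stage("integration", t1, protein_modules=len(pmods))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'integration' failed: {exc}") from exc

    bundle["cohort_stats"] = cohort_table(dataset.samples)
    bundle["report"] = generate_report(bundle)

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle["config"]
    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=str))
    write_table(bundle["cohort_stats"], outdir / "cohort_stats.tsv")
    write_table(bundle["differential"]["table"], outdir / "differential.tsv", sort_by="p_discovery")
    write_table(bundle["class_tallies"], outdir / "class_tallies.tsv")
    comp = bundle["composite"]
    write_table(comp["grid"], outdir / "composite_grid.tsv")
    write_table(comp["model"].weights.to_frame("weight"), outdir / "composite_weights.tsv")
    ica = bundle["ica"]
    write_table(ica["decomposition"].sources, outdir / "module_sources.tsv")
    write_table(ica["decomposition"].sample_scores, outdir / "module_scores.tsv")
    write_table(ica["trait"], outdir / "module_trait.tsv", sort_by="p")
    if len(ica["enrichment"]):
        write_table(ica["enrichment"], outdir / "module_enrichment.tsv")
    if "integration" in bundle:
        integ = bundle["integration"]
        write_table(integ["cross_omics"].pairs, outdir / "cross_omics.tsv")
        if len(integ["recurrent"]):
            write_table(integ["recurrent"], outdir / "recurrent_features.tsv")
    (outdir / "report.txt").write_text(bundle["report"])


def generate_report(bundle: dict) -> str:
    """Human-readable run summary mirroring the analysis narrative."""
    lines: list[str] = ["# metabomod pipeline report", ""]
    cfg = bundle["config"]
    lines.append(
        f"seed={cfg.seed} thresholds: discovery FDR<{cfg.discovery_fdr}, "
        f"replication p<{cfg.replication_p}, module p<{cfg.module_p}, "
        f"enrichment p<{cfg.enrichment_p}, correlation p<{cfg.correlation_p}"
    )
    lines.append("")
    lines.append("## Cohort")
    if "cohort_stats" in bundle:
        lines.append(bundle["cohort_stats"].to_string(float_format=lambda v: f"{v:.3f}"))
    else:
        lines.append("(missing: cohort statistics)")
    lines.append("")
    lines.append("## Differential analysis")
    if "differential" in bundle:
        table = bundle["differential"]["table"]
        n_hit = int(table["discovery_hit"].sum())
        n_rep = int(table["replicated"].sum())
        lines.append(
            f"{len(table)} features; {n_hit} discovery hits; {n_rep} replicated"
        )
        show = table[table["discovery_hit"]] if n_hit else table.nsmallest(
            5, "p_discovery"
        )
        lines.append(show.to_string(float_format=lambda v: f"{v:.4g}"))
    else:
        lines.append("(missing: differential results)")
    lines.append("")
    lines.append("## Composite score")
    if "composite" in bundle:
        comp = bundle["composite"]
        lines.append(comp["model"].summary())
        lines.append(comp["evaluation"].summary())
        coef, se, p = comp["association"]["group"]
        lines.append(f"score ~ group association: coef={coef:.3f} (se {se:.3f}, p={p:.3g})")
        lines.append(
            "grid (test AUC is optimistically biased for the selected cell):"
        )
        lines.append(comp["grid"].to_string(float_format=lambda v: f"{v:.3f}"))
    else:
        lines.append("(missing: composite results)")
    lines.append("")
    lines.append("## Metabolite modules (consensus ICA)")
    if "ica" in bundle:
        ica = bundle["ica"]
        lines.append(ica["decomposition"].summary())
        sig = ica["trait"][ica["trait"]["significant"]]
        lines.append(f"modules associated with group: {list(sig.index)}")
        if "truth" in bundle and bundle["truth"] is not None:
            truth = bundle["truth"]
            rows = []
            for k, mem in enumerate(truth.module_members):
                s = set(mem)
                best_name, best_j = "-", 0.0
                for name, rec in ica["modules"]:
                    j = len(s & set(rec)) / len(s | set(rec)) if (s or rec) else 0.0
                    if j > best_j:
                        best_name, best_j = name, j
                rows.append(
                    f"planted module {k + 1} (n={len(mem)}) -> {best_name} "
                    f"(Jaccard {best_j:.2f})"
                )
            lines.append("planted vs recovered:")
            lines.extend("  " + r for r in rows)
        if len(ica["enrichment"]):
            top = ica["enrichment"].groupby("module").head(3)
            lines.append(top.to_string(float_format=lambda v: f"{v:.3g}"))
    else:
        lines.append("(missing: module results)")
    lines.append("")
    lines.append("## Metabolome-proteome integration")
    if "integration" in bundle:
        integ = bundle["integration"]
        sig = integ["cross_omics"].significant()
        lines.append(
            f"{len(integ['protein_modules'])} protein modules; "
            f"{len(sig)} significant cross-omics pairs "
            f"(n={integ['cross_omics'].n_samples} shared samples)"
        )
        if len(sig):
            lines.append(sig.to_string(float_format=lambda v: f"{v:.3g}"))
    else:
        lines.append("(not run: no proteome)")
    return "\n".join(lines) + "\n"
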