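"""End-to-end orchestration of the two-phase approach.

One configuration drives: case/control derivation, probe QC, surrogate
variable estimation, the minimally adjusted scan, catalog trait harvesting,
and the cohort hypothesis-testing battery — plus the three sensitivity
re-runs (comorbidity exclusion, less-severe cases, pre-measurement
reporters only). Identical seed and inputs give byte-identical stage
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cases, catalog, cohort, ewas, qc, sva

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "run_sensitivity"]

log = logging.getLogger("ewas_hypogen")

VARIANTS = ("comorbidity_excluded", "less_severe", "pre_measurement_only")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, settings and output location for one full run."""

    beta: Path
    annotation: Path
    pheno: Path
    outdir: Path
    conditions: dict[str, dict] = field(default_factory=dict)
    catalog_path: Path | None = None
    catalog_api: str | None = None
    variable_map: dict[str, str] = field(default_factory=dict)
    threshold: float = 1e-5
    eligibility_minimum: int = 5
    adjusters: list[str] = field(default_factory=lambda: ["sep", "aam_months"])
    a_priori: list[str] = field(default_factory=list)
    n_sv: int | None = None  # None: estimate by parallel analysis
    sva_permutations: int = 20
    sva_iterations: int = 5
    sva_quantile: float = 0.95
    comorbidity_exclusions: list[str] = field(default_factory=list)
    measurement_wave: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta", "annotation", "pheno", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.catalog_path is not None:
            self.catalog_path = Path(self.catalog_path)
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        missing = [
            str(p)
            for p in (self.beta, self.annotation, self.pheno, self.catalog_path)
            if p is not None and not Path(p).exists()
        ]
        for cond, spec in self.conditions.items():
            rp = spec.get("responses")
            if rp is not None and not Path(rp).exists():
                missing.append(str(rp))
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def store(self) -> catalog.CatalogStore:
        if self.catalog_path is not None:
            return catalog.TSVCatalogStore(self.catalog_path)
        if self.catalog_api:
            return catalog.RESTCatalogStore(self.catalog_api)
        raise ValueError("config provides neither catalog_path nor catalog_api")


@dataclass
class RunReport:
    seed: int
    conditions: dict[str, dict] = field(default_factory=dict)
    error: str | None = None
    wall_clock: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _status_from_column(pheno: pd.DataFrame, column: str) -> pd.DataFrame:
    col = pheno[column]
    status = pd.Series("excluded", index=pheno.index, dtype=object)
    status[col == 1] = "case"
    status[col == 0] = "control"
    return pd.DataFrame({"status": status, "first_report_wave": np.nan, "reason": ""})


def _derive_condition_status(
    config: RunConfig, pheno: pd.DataFrame, cond_spec: dict, rules: cases.CaseRules
) -> pd.DataFrame:
    if "responses" in cond_spec and cond_spec["responses"]:
        responses = cases.read_responses(cond_spec["responses"])
        status = cases.derive_status(responses, rules)
        return status.reindex(pheno.index).fillna({"status": "excluded", "reason": "no responses"})
    column = cond_spec.get("status_column")
    if column is None or column not in pheno.columns:
        raise ValueError(f"condition needs a responses file or a status_column; got {cond_spec}")
    status = _status_from_column(pheno, column)
    if rules.comorbidity_exclusions:
        mask = status.index.astype(str).isin(rules.comorbidity_exclusions)
        status.loc[mask, "status"] = "excluded"
        status.loc[mask, "reason"] = "comorbidity exclusion"
    return status


def _apply_variant(status: pd.DataFrame, variant: str | None) -> pd.DataFrame:
    if variant != "less_severe":
        return status
    out = status.copy()
    was_case = out["status"] == "case"
    out.loc[out["status"] == "less_severe", "status"] = "case"
    out.loc[was_case, "status"] = "excluded"
    out.loc[was_case, "reason"] = "primary case excluded in less-severe variant"
    return out


def _rules_for(config: RunConfig, variant: str | None) -> cases.CaseRules:
    return cases.CaseRules(
        comorbidity_exclusions=(
            frozenset(map(str, config.comorbidity_exclusions))
            if variant == "comorbidity_excluded"
            else frozenset()
        ),
        exclude_post_measurement=(variant == "pre_measurement_only"),
        measurement_wave=dict(config.measurement_wave),
    )


def run_pipeline(config: RunConfig, variant: str | None = None) -> RunReport:
    """Execute every stage for every configured condition.

    Writes per-condition stage outputs (status, QC report, surrogate
    variables, scan results, QQ data, harvested traits, association and
    summary tables) under ``outdir`` (or ``outdir/<variant>``) and returns
    the run report. Any stage error aborts; the stage name and cause are
    recorded in the report, which is still written.
    """
    outdir = config.outdir / variant if variant else config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    stage = "load_inputs"
    try:
        t0 = time.perf_counter()
        beta = pd.read_csv(config.beta, sep="\t", index_col=0)
        annotation = qc.read_annotation(config.annotation)
        pheno = pd.read_csv(config.pheno, index_col=0)
        pheno.index = pheno.index.astype(str)
        beta.columns = beta.columns.astype(str)
        store = config.store()
        report.wall_clock[stage] = time.perf_counter() - t0
        rules = _rules_for(config, variant)

        for cond, cond_spec in config.conditions.items():
            cstats: dict = {}
            stage = f"{cond}:case_definitions"
            t0 = time.perf_counter()
            status = _derive_condition_status(config, pheno, cond_spec, rules)
            status = _apply_variant(status, variant)
            status.to_csv(outdir / f"{cond}_status.csv")
            counts = status["status"].value_counts()
            cstats["cases"] = int(counts.get("case", 0))
            cstats["controls"] = int(counts.get("control", 0))
            cstats["less_severe"] = int(counts.get("less_severe", 0))
            cstats["excluded"] = int(counts.get("excluded", 0))
            log.info("%s: %s", stage, dict(counts))
            report.wall_clock[stage] = time.perf_counter() - t0

            stage = f"{cond}:methylation_qc"
            t0 = time.perf_counter()
            filtered, filter_report = qc.filter_probes(beta, annotation)
            cleaned, outlier_report = qc.remove_outliers(filtered)
            cstats["probes_removed"] = filter_report.removed
            cstats["probes_retained"] = filter_report.retained
            cstats["outlier_cells"] = int(sum(outlier_report.outlier_cells.values()))
            log.info("%s: removed=%s retained=%d", stage, filter_report.removed, filter_report.retained)
            report.wall_clock[stage] = time.perf_counter() - t0

            stage = f"{cond}:surrogate_variables"
            t0 = time.perf_counter()
            cc = status[status["status"].isin(["case", "control"])].index
            cc = [s for s in cleaned.columns if s in set(cc)]
            sub = cleaned[cc]
            case = (status.loc[cc, "status"] == "case").astype(float)
            design = ewas.build_design(pheno.loc[cc], case)
            n_sv = config.n_sv
            if n_sv is None:
                n_sv = sva.estimate_n_sv(
                    sub, design, n_permutations=config.sva_permutations,
                    seed=config.seed, quantile=config.sva_quantile,
                )
            svs = None
            if n_sv > 0:
                svs = sva.compute_svs(sub, design, n_sv, max_iterations=config.sva_iterations)
                svs.seed = config.seed
                svs.data.to_csv(outdir / f"{cond}_svs.tsv", sep="\t")
                (outdir / f"{cond}_svs.json").write_text(
                    json.dumps({"n_sv": n_sv, "method": svs.method, "seed": config.seed})
                )
            cstats["n_sv"] = int(n_sv)
            log.info("%s: n_sv=%d", stage, n_sv)
            report.wall_clock[stage] = time.perf_counter() - t0

            stage = f"{cond}:ewas"
            t0 = time.perf_counter()
            result = ewas.run_ewas(sub, pheno, status, svs=svs, threshold=config.threshold)
            result.table = qc.flag_chen(result.table, annotation)
            result.to_tsv(outdir / f"{cond}_ewas.tsv", annotation=annotation)
            result.qq_data().to_csv(outdir / f"{cond}_qq.tsv", sep="\t", index=False)
            hits = result.select_hits()
            cstats["lambda"] = result.lambda_
            cstats["hits"] = len(hits)
            log.info("%s: lambda=%.3f hits=%d", stage, result.lambda_, len(hits))
            report.wall_clock[stage] = time.perf_counter() - t0

            stage = f"{cond}:catalog_lookup"
            t0 = time.perf_counter()
            hypotheses = catalog.harvest_traits(hits, annotation, store, condition=cond)
            hypotheses.to_tsv(outdir / f"{cond}_traits.tsv")
            cstats["traits"] = len(hypotheses)
            log.info("%s: traits=%d", stage, len(hypotheses))
            report.wall_clock[stage] = time.perf_counter() - t0

            stage = f"{cond}:hypothesis_testing"
            t0 = time.perf_counter()
            test_pheno = pheno.copy()
            cond_col = f"{cond}__status"
            test_pheno[cond_col] = np.nan
            test_pheno.loc[status["status"] == "case", cond_col] = 1.0
            test_pheno.loc[status["status"] == "control", cond_col] = 0.0
            results, unmapped = cohort.run_battery(
                test_pheno,
                hypotheses,
                config.variable_map,
                conditions=[cond_col],
                adjusters=config.adjusters,
                a_priori=config.a_priori,
                minimum=config.eligibility_minimum,
            )
            results["condition"] = cond
            results.to_csv(outdir / f"{cond}_associations.tsv", sep="\t", index=False)
            unmapped.to_csv(outdir / f"{cond}_unmapped.tsv", sep="\t", index=False)
            for _, r in unmapped.iterrows():
                log.warning("%s: unmapped trait %r (%s)", stage, r["trait"], r["reason"])
            tested_vars = [c for c in results["exposure"].unique()]
            if tested_vars:
                summary = cohort.summarize(test_pheno, cond_col, variables=tested_vars)
                summary.to_csv(outdir / f"{cond}_summary.tsv", sep="\t")
            forest = results[~results["omitted"]]
            forest.to_csv(outdir / f"{cond}_forest.tsv", sep="\t", index=False)
            cstats["tests_run"] = int((~results["omitted"]).sum())
            cstats["tests_omitted"] = int(results["omitted"].sum())
            cstats["traits_unmapped"] = len(unmapped)
            report.wall_clock[stage] = time.perf_counter() - t0

            report.conditions[cond] = cstats
    except Exception as err:  # noqa: BLE001 - report stage and cause, then abort
        report.error = f"stage {stage!r}: {err}"
        report.to_json(outdir / "run_report.json")
        raise PipelineError(stage, err) from err

    report.to_json(outdir / "run_report.json")
    return report


def run_sensitivity(config: RunConfig, variant: str) -> RunReport:
    """Re-run the affected stages under one sensitivity variant.

    ``comorbidity_excluded`` drops the configured comorbid samples from the
    case/control sets; ``less_severe`` swaps the case group for the
    symptom-without-doctor stratum; ``pre_measurement_only`` excludes
    samples whose first symptom report postdates their methylation
    measurement. Outputs go to ``outdir/<variant>``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return run_pipeline(config, variant=variant)
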