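"""Run configuration and the end-to-end pipeline.

A run is driven either by a SimParams block (synthetic cohort) or by real
input paths — never both. Every run writes a manifest (config hash, seed,
package versions, and row counts at each filter step) sufficient to
reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import read_cohort_tsv, read_genotypes, read_sumstats, write_cohort_tsv
from .observational import default_predictor_specs, multivariable_fit, univariable_fits
from .prs import clump, compute_prs, harmonize
from .proxymr import control_checks, run_proxy_mr
from .synthdata import SimParams, generate_cohort

log = logging.getLogger("gxemr")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int
    out_dir: str = "results"
    sim: SimParams | None = None
    cohort_path: str | None = None
    genotypes_path: str | None = None
    genotypes_dialect: str = "plink-raw"
    sumstats_path: str | None = None
    column_map: dict = field(default_factory=dict)
    instrument: str = "snp:rs16969968"
    covariates: list = field(default_factory=list)
    p_thresh: float = 5e-8
    r2_thresh: float = 0.001
    window_kb: float = 1000.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        has_sim = self.sim is not None
        has_paths = self.cohort_path is not None
        if has_sim == has_paths:
            raise ConfigError(
                "exactly one of a SimParams block or input paths must drive the run")
        if self.seed is None:
            raise ConfigError("a master seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError(f"{path}: 'seed' is mandatory")
        sim_block = raw.pop("sim", None)
        sim = None
        if sim_block is not None:
            sim_block.setdefault("seed", raw["seed"])
            for key in ("allele_freqs", "snp_weights", "snp_ids", "effect_alleles"):
                if key in sim_block and sim_block[key] is not None:
                    sim_block[key] = tuple(sim_block[key])
            sim = SimParams(**sim_block)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(sim=sim, **raw)

    def digest(self) -> str:
        payload = dict(vars(self))
        payload["sim"] = dataclasses.asdict(self.sim) if self.sim else None
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__
    return {"gxemr": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> observational -> (prs) -> proxymr and write the
    result bundle plus a reproducibility manifest to ``config.out_dir``.

    Returns the manifest. Stage errors abort with the stage name; the
    manifest up to the failing stage is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_sha256": config.digest(), "seed": config.seed,
                      "versions": _versions(), "stages": {}, "row_counts": {}}
    stage = "setup"
    try:
        stage = "cohort"
        if config.sim is not None:
            cohort = generate_cohort(config.sim)
            df = cohort.phenotypes
            dosages = cohort.dosage_frame()
            alleles = dict(zip(cohort.snp_ids, cohort.effect_alleles))
            write_cohort_tsv(cohort.to_frame(), out / "cohort.tsv")
        else:
            df = read_cohort_tsv(config.cohort_path, config.column_map)
            dosages, alleles = (read_genotypes(config.genotypes_path,
                                               config.genotypes_dialect)
                                if config.genotypes_path else (pd.DataFrame(), {}))
            dosages = dosages.reset_index(drop=True)
        manifest["row_counts"]["cohort"] = int(len(df))
        log.info("cohort: %d rows, %d SNP columns", len(df), dosages.shape[1])

        stage = "observational"
        specs = [s for s in default_predictor_specs()
                 if s.name in df.columns and df[s.name].nunique() > 1]
        uni = univariable_fits(df, "left_handed", specs)
        multi = multivariable_fit(df, "left_handed", specs)
        rows = []
        for fit in uni + [multi]:
            for r in fit.results:
                rows.append({"term": r.term, "OR": r.odds_ratio,
                             "ci_low": r.ci_low, "ci_high": r.ci_high,
                             "p": r.p_value, "n": r.n_used,
                             "model_id": r.model_id,
                             "pseudo_r2": fit.pseudo_r2})
        pd.DataFrame(rows).to_csv(out / "observational_results.tsv", sep="\t",
                                  index=False, na_rep="NA")
        manifest["row_counts"]["observational_complete_cases"] = multi.n_used
        manifest["stages"]["observational"] = {
            "pseudo_r2": multi.pseudo_r2, "n_models": len(uni) + 1}

        stage = "prs"
        if config.sumstats_path:
            records, rejects = read_sumstats(config.sumstats_path, config.column_map)
            result = clump(records, dosages, config.p_thresh,
                           config.r2_thresh, config.window_kb)
            kept = [r for r in records if r.snp_id in result.index_snps]
            report = harmonize(kept, alleles)
            scores = compute_prs(dosages, report.kept)
            scores.rename_axis("IID").reset_index().to_csv(
                out / "prs_scores.tsv", sep="\t", index=False, na_rep="NA")
            result.report_frame().to_csv(out / "clump_report.tsv", sep="\t",
                                         index=False)
            report.frame().to_csv(out / "harmonize_report.tsv", sep="\t",
                                  index=False, na_rep="NA")
            manifest["stages"]["prs"] = {
                "n_sumstats": len(records), "n_rejected_rows": int(len(rejects)),
                "n_index_snps": len(result.index_snps),
                "n_score_snps": len(report.kept)}
            instrument_values = scores.to_numpy()
            instrument_label = "prs"
        else:
            snp = (config.instrument.split(":", 1)[1]
                   if config.instrument.startswith("snp:") else config.instrument)
            if snp not in dosages.columns:
                raise ConfigError(f"instrument SNP {snp!r} not in dosage columns")
            instrument_values = dosages[snp].to_numpy()
            instrument_label = f"snp:{snp}"

        stage = "proxymr"
        cov = df[list(config.covariates)] if config.covariates else None
        mr = run_proxy_mr(df, instrument_values, covariates=cov,
                          instrument_label=instrument_label)
        mr.frame().to_csv(out / "mr_results.tsv", sep="\t", index=False,
                          na_rep="NA")
        checks = control_checks(df, instrument_values, covariates=cov,
                                instrument_label=instrument_label)
        checks.to_csv(out / "control_checks.tsv", sep="\t", index=False,
                      na_rep="NA")
        manifest["row_counts"]["exposed"] = mr.assoc_exposed.n
        manifest["row_counts"]["unexposed"] = mr.assoc_unexposed.n
        manifest["row_counts"]["smoking_status_missing"] = mr.n_dropped
        manifest["stages"]["proxymr"] = {
            "instrument": instrument_label,
            "beta_corrected": mr.corrected.beta_corrected,
            "se_corrected": mr.corrected.se}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
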