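"""End-to-end orchestration: simulate -> profiles -> matrices -> phenotype
prep -> REML fits -> prediction -> bivariate proxy model -> report.

The pipeline is driven by a single YAML config (see
``configs/demo.yaml``); every stage writes its output under ``out_dir``
and the final report collects heritability, microbiability, prediction
accuracy/slope, genetic and phenotypic correlations and the relative
efficacy of indirect selection, each traceable to a stage file.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .kinship import GenotypeMatrix, build_grm, build_mrm
from .mixed_models import blup_predict, reml_bivariate, reml_univariate
from .phenotypes import adjust_phenotype, build_design, scale_by_lot
from .profiles import filter_tags, sample_qc
from .simulate import (SimulationConfig, simulate_metagenome,
                       simulate_population)
from .validation import (cv_folds, evaluate_predictions, forward_split,
                         relative_efficacy)

logger = logging.getLogger("rmcblup")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class DataError(ValueError):
    """Input data is missing or inconsistent."""


DEFAULT_FIXED_EFFECTS = ["C(birth_rank)", "C(age_of_dam)", "bdev",
                         "flock*birth_year*sex"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "rmcblup_run"
    simulate: dict | None = None
    inputs: dict | None = None
    trait: dict = field(default_factory=lambda: {"name": "CH4",
                                                 "overall_mean": 7.5,
                                                 "percentage": False})
    fixed_effects: list = field(default_factory=lambda: list(DEFAULT_FIXED_EFFECTS))
    qc: dict = field(default_factory=dict)
    scheme: dict = field(default_factory=lambda: {"type": "FP"})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.read_yaml(path)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config needs either a 'simulate' block or "
                              "'inputs' paths")
        for key, lo, hi in (("presence_threshold", 0, 1),
                            ("maf_min", 0, 1), ("call_rate_min", 0, 1)):
            v = self.qc.get(key)
            if v is not None and not lo <= v <= hi:
                raise ConfigError(f"qc.{key} must lie in [{lo}, {hi}]")
        if self.scheme.get("type") not in ("FP", "CV"):
            raise ConfigError("scheme.type must be 'FP' or 'CV'")


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
        genotypes, pheno, truth = simulate_population(sim)
        tcm = simulate_metagenome(truth, sim)
        io.write_genotypes(genotypes, out / "genotypes.tsv")
        io.write_table(pheno, out / "phenotypes.tsv")
        io.write_tag_counts(tcm, out / "tag_counts.tsv")
        io.write_yaml(
            {"true_h2": truth.true_h2, "true_m2": truth.true_m2,
             "true_rg": truth.true_rg},
            out / "truth.yaml",
        )
        return GenotypeMatrix(calls=genotypes), pheno, tcm
    paths = config.inputs or {}
    for key in ("genotypes", "phenotypes", "tag_counts"):
        if key not in paths:
            raise ConfigError(f"inputs.{key} missing from config")
        if not Path(paths[key]).exists():
            raise DataError(f"input file not found: {paths[key]}")
    geno = io.read_genotypes(paths["genotypes"])
    pheno = io.read_table(paths["phenotypes"])
    tcm = io.read_tag_counts(paths["tag_counts"])
    return geno, pheno, tcm


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the report dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logger.info("pipeline start (seed=%d)", config.seed)

    geno, pheno, tcm = _load_inputs(config, out)
    if "y" not in pheno.columns:
        raise DataError("phenotype table lacks a 'y' column")

    # --- profiles ------------------------------------------------------
    min_reads = config.qc.get("min_reads", 100_000)
    presence = config.qc.get("presence_threshold", 0.25)
    tcm, qc_report = sample_qc(tcm, min_reads=min_reads)
    io.write_table(qc_report, out / "sample_qc.tsv")
    profiled = tcm.sample_ids.intersection(pheno.index)
    if len(profiled) == 0:
        raise DataError("no profiled sample matches a phenotyped animal")

    # --- split plan ----------------------------------------------------
    scheme = config.scheme.get("type", "FP")
    if scheme == "FP":
        year = config.scheme.get("validation_year",
                                 int(pheno["birth_year"].max()))
        plan = forward_split(pheno, year)
    else:
        plan = cv_folds(pheno, n_folds=config.scheme.get("n_folds", 11),
                        seed=config.seed)
    io.write_table(plan.assignments.to_frame(), out / "split_plan.tsv")

    # Tag filtering reference: training samples (FP) or all samples (CV).
    if scheme == "FP":
        reference = plan.training_ids().intersection(tcm.sample_ids)
    else:
        reference = tcm.sample_ids
    tcm_f = filter_tags(tcm, reference, presence_threshold=presence)
    # Cohort normalization needs >=2 profiled samples per cohort; QC can
    # orphan a cohort, in which case its remaining samples are dropped.
    cohort_of = pheno.loc[tcm_f.sample_ids, "cohort"]
    ok = cohort_of.map(cohort_of.value_counts()) >= 2
    if not ok.all():
        logger.warning("dropping %d samples in cohorts orphaned by QC",
                       int((~ok).sum()))
        from .profiles import TagCountMatrix
        tcm_f = TagCountMatrix(counts=tcm_f.counts.loc[ok],
                               total_reads=tcm_f.total_reads.loc[ok])
    logger.info("profiles: %d samples x %d tags after QC/filtering",
                *tcm_f.counts.shape)

    # --- relationship matrices ----------------------------------------
    mrm = build_mrm(tcm_f, pheno.loc[tcm_f.sample_ids, "cohort"])
    grm = build_grm(geno, maf_min=config.qc.get("maf_min", 0.01),
                    call_rate_min=config.qc.get("call_rate_min", 0.70))
    io.write_relationship(mrm, out / "mrm.tsv")
    io.write_relationship(grm, out / "grm.tsv")

    # --- phenotype prep ------------------------------------------------
    overall_mean = config.trait.get("overall_mean", 7.5)
    scaled = scale_by_lot(pheno["y"], pheno["lot_id"], overall_mean)
    if config.trait.get("percentage"):
        scaled = scaled * 100.0
    design = build_design(pheno, config.fixed_effects)
    y_star = adjust_phenotype(scaled, design)
    prep = pheno.copy()
    prep["y_scaled"] = scaled
    prep["y_star"] = y_star
    io.write_table(prep, out / "phenotypes_prepared.tsv")

    # --- full-data heritability and microbiability ---------------------
    design_g = build_design(pheno.loc[grm.ids], config.fixed_effects)
    fit_h2 = reml_univariate(y_star.loc[grm.ids], design_g, grm)
    mrm_ids = mrm.ids
    design_m = build_design(pheno.loc[mrm_ids], config.fixed_effects)
    fit_m2 = reml_univariate(y_star.loc[mrm_ids], design_m, mrm)
    io.write_yaml({"heritability": _fit_dict(fit_h2),
                   "microbiability": _fit_dict(fit_m2)},
                  out / "variance_components.yaml")

    # --- prediction ----------------------------------------------------
    predictions: dict[str, pd.Series] = {}
    evaluation = {}
    for label, rel in (("genomic", grm), ("metagenomic", mrm)):
        preds = _predict_scheme(label, rel, y_star, pheno, plan,
                                config.fixed_effects)
        predictions[label] = preds
        groups = pheno.loc[preds.index, "cohort"] if scheme == "FP" \
            else plan.assignments.loc[preds.index]
        result = evaluate_predictions(preds, y_star.loc[preds.index], groups)
        evaluation[label] = {
            "accuracy": result.accuracy, "accuracy_se": result.accuracy_se,
            "slope": result.slope, "slope_se": result.slope_se,
            "n": int(len(preds)),
        }
        io.write_table(result.per_group, out / f"prediction_{label}.tsv")

    # --- bivariate proxy model -----------------------------------------
    m_hat = predictions["metagenomic"]
    biv_ids = m_hat.index.intersection(grm.ids)
    G_val = grm.submatrix(biv_ids)
    biv = reml_bivariate(y_star.loc[biv_ids], m_hat.loc[biv_ids], G_val)
    eff = relative_efficacy(biv.rho_g, biv.h2_1, biv.h2_2)

    report = {
        "seed": config.seed,
        "scheme": scheme,
        "trait": config.trait,
        "n_animals": int(len(pheno)),
        "n_profiled": int(len(profiled)),
        "n_tags_retained": int(tcm_f.counts.shape[1]),
        "heritability": _fit_dict(fit_h2),
        "microbiability": _fit_dict(fit_m2),
        "prediction": evaluation,
        "bivariate": {
            "h2_direct": biv.h2_1, "h2_direct_se": biv.se_h2_1,
            "h2_proxy": biv.h2_2, "h2_proxy_se": biv.se_h2_2,
            "genetic_correlation": biv.rho_g,
            "genetic_correlation_se": biv.se_rho_g,
            "phenotypic_correlation": biv.rho_p,
            "phenotypic_correlation_se": biv.se_rho_p,
            "phenotypic_var": list(biv.phenotypic_var),
            "n": biv.n,
        },
        "relative_efficacy": eff,
    }
    report = io._to_plain(report)
    io.write_yaml(report, out / "report.yaml")
    _write_text_report(report, out / "report.txt")
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return report


def _fit_dict(fit) -> dict:
    return {
        "sigma2_random": fit.sigma2_r, "sigma2_residual": fit.sigma2_e,
        "ratio": fit.ratio, "ratio_se": fit.se_ratio, "loglik": fit.loglik,
    }


def _predict_scheme(label, rel, y_star, pheno, plan, fixed_effects):
    """Train univariate kernel model(s) per the split plan and predict the
    validation animals; returns the concatenated predictions."""
    preds = []
    folds = [None] if plan.scheme == "FP" else plan.folds
    for fold in folds:
        train = plan.training_ids(fold).intersection(rel.ids)
        target = plan.validation_ids(fold).intersection(rel.ids)
        if len(train) < 10 or len(target) == 0:
            raise DataError(
                f"{label} prediction: degenerate split (train={len(train)}, "
                f"validate={len(target)})"
            )
        design = build_design(pheno.loc[train], fixed_effects)
        K_tr = rel.submatrix(train)
        fit = reml_univariate(y_star.loc[train], design, K_tr,
                              kind=rel.kind, ids=train)
        preds.append(blup_predict(fit, rel, train, target))
    return pd.concat(preds)


def _write_text_report(report: dict, path: Path) -> None:
    lines = [
        "rmcblup pipeline report",
        "=======================",
        f"seed: {report['seed']}   scheme: {report['scheme']}   "
        f"trait: {report['trait'].get('name')}",
        f"animals: {report['n_animals']}  profiled: {report['n_profiled']}  "
        f"tags retained: {report['n_tags_retained']}",
        "",
        f"heritability  (GRM): {report['heritability']['ratio']:.3f} "
        f"(se {report['heritability']['ratio_se']:.3f})",
        f"microbiability (MRM): {report['microbiability']['ratio']:.3f} "
        f"(se {report['microbiability']['ratio_se']:.3f})",
        "",
    ]
    for label, ev in report["prediction"].items():
        lines.append(
            f"{label:>12} prediction: accuracy {ev['accuracy']:.3f} "
            f"(se {ev['accuracy_se']:.3f}), slope {ev['slope']:.3f} "
            f"(se {ev['slope_se']:.3f}), n={ev['n']}"
        )
    b = report["bivariate"]
    lines += [
        "",
        f"bivariate (n={b['n']}): h2_direct {b['h2_direct']:.3f} "
        f"(se {b['h2_direct_se']:.3f}), h2_proxy {b['h2_proxy']:.3f} "
        f"(se {b['h2_proxy_se']:.3f})",
        f"genetic correlation {b['genetic_correlation']:.3f} "
        f"(se {b['genetic_correlation_se']:.3f}), phenotypic correlation "
        f"{b['phenotypic_correlation']:.3f} (se "
        f"{b['phenotypic_correlation_se']:.3f})",
        "",
        f"relative efficacy of indirect selection: "
        f"{report['relative_efficacy']:.3f}",
        "",
    ]
    path.write_text("\n".join(lines))
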