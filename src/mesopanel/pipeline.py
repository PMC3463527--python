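"""End-to-end reproducible run: simulate -> calibrate/normalize -> QC ->
discover -> train -> predict -> evaluate.

A run is driven by a :class:`RunConfig` (YAML-serializable, unknown keys
rejected) and one master seed fanned out per stage.  Every stage's inputs
and outputs are content-hashed into a provenance record, together with the
blinding-audit log: the discovery stages are handed training samples only,
and any access to held-out ids is a recorded violation that fails the run.
Identical config + seed reproduce byte-identical score files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audit import BlindingAudit
from .classifier import oob_performance, predict, train_panel_model
from .data import RfuMatrix, write_annotation, write_rfu_matrix, write_split, StudySplit
from .discovery import gini_rank, panel_size_scan, select_candidates, univariate_screen
from .evaluate import (
    ConfusionCounts,
    evaluate_cohort,
    pool_cohorts,
    confusion_metrics,
    pool_stage_tables,
    screening_estimates,
)
from .normalize import calibrate_plates, median_normalize
from .qc import (
    QcReport,
    apply_qc,
    filter_ks_control_sets,
    filter_paired_draws,
    pca_artifact_screen,
    write_qc_report,
)
from .simulate import CohortSpec, generate_paired_draws, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the study defaults."""

    out_dir: str = "run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    design: dict = field(
        default_factory=lambda: {
            "training": [60, 60],
            "verification": [19, 20],
            "validation": [38, 62],
        }
    )
    order: str = "calibrate-first"  # or "normalize-first"
    ks_threshold: float = 0.45
    paired_alpha: float = 0.05
    min_shift: float = 0.5
    pca_r: float = 0.5
    pca_mads: float = 3.0
    pca_covariates: list = field(default_factory=lambda: ["site", "plate_id"])
    q_threshold: float = 0.01
    univariate_test: str = "either"
    n_trees: int = 1000
    panel_size: int = 13
    scan_sizes: list = field(default_factory=lambda: [1, 2, 3, 5, 8, 13, 21, 34, 55, 64])
    threshold_rule: str = "youden"
    prevalence: float = 0.014
    run_pca_screen: bool = True
    # PCA analyte-loading flags are advisory by default: samples driving an
    # artifact component are removed, after which the flagged analytes are
    # typically clean again and the KS filter catches any residual
    apply_pca_analyte_flags: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study flow and return the provenance record.

    Writes all stage outputs (matrices, QC report, discovery tables, model,
    score files, evaluation report) under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    provenance: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": {},
        "audit": [],
    }
    hashes: dict[str, str] = {}

    def record(stage: str, t0: float, files: list[Path]) -> None:
        provenance["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {f.name: _sha256_file(f) for f in files},
        }
        hashes.update({f.name: _sha256_file(f) for f in files})

    try:
        # ---- simulate -------------------------------------------------
        t0 = time.time()
        spec = CohortSpec(**{"seed": config.seed, **config.cohort})
        design = {k: tuple(v) for k, v in config.design.items()}
        cohorts = generate_study(spec, design)
        paired_matrix, paired_ann = generate_paired_draws(spec)
        files = []
        for name, (matrix, ann, _) in cohorts.items():
            write_rfu_matrix(matrix, out / f"{name}.matrix.tsv")
            write_annotation(ann, out / f"{name}.ann.tsv")
            files += [out / f"{name}.matrix.tsv", out / f"{name}.ann.tsv"]
        write_rfu_matrix(paired_matrix, out / "paired.matrix.tsv")
        write_annotation(paired_ann, out / "paired.ann.tsv")
        record("simulate", t0, files + [out / "paired.matrix.tsv", out / "paired.ann.tsv"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    try:
        # ---- calibrate + normalize ------------------------------------
        t0 = time.time()
        processed: dict[str, RfuMatrix] = {}
        anns: dict[str, pd.DataFrame] = {}
        for name, (matrix, ann, _) in cohorts.items():
            if config.order == "calibrate-first":
                m = calibrate_plates(matrix, ann).calibrated
                m = median_normalize(m).normalized
            elif config.order == "normalize-first":
                m = median_normalize(matrix).normalized
                m = calibrate_plates(m, ann).calibrated
            else:
                raise ValueError(f"unknown order {config.order!r}")
            # calibrator wells have served their purpose once plates are
            # calibrated; downstream stages see study samples only
            study_ids = ann.loc[
                ann["class_label"].isin(["CASE", "CONTROL"]), "sample_id"
            ]
            processed[name] = m.subset(samples=list(study_ids))
            anns[name] = ann
            write_rfu_matrix(m, out / f"{name}.norm.tsv")
        record("normalize", t0, [out / f"{n}.norm.tsv" for n in cohorts])
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("normalize", e) from e

    try:
        # ---- QC -------------------------------------------------------
        t0 = time.time()
        train_m, train_ann = processed["training"], anns["training"]
        report = QcReport()
        # PCA screen first: artifact-laden samples (e.g. a degraded archival
        # subcohort) are removed before the distributional filters so they
        # cannot inflate inter-site distances on otherwise clean analytes
        if config.run_pca_screen:
            pca_rep = pca_artifact_screen(
                train_m, train_ann,
                covariates=tuple(config.pca_covariates),
                r_threshold=config.pca_r, score_mads=config.pca_mads,
            )
            if not config.apply_pca_analyte_flags:
                pca_rep = QcReport(
                    excluded_samples=pca_rep.excluded_samples,
                    pca_summary=pca_rep.pca_summary,
                )
            report = report.merge(pca_rep)
            train_m = apply_qc(train_m, QcReport(excluded_samples=report.excluded_samples))
        report = report.merge(
            filter_ks_control_sets(train_m, train_ann, threshold=config.ks_threshold)
        )
        report = report.merge(
            filter_paired_draws(
                paired_matrix, paired_ann,
                alpha=config.paired_alpha, min_abs_log2_shift=config.min_shift,
            )
        )
        write_qc_report(report, out / "qc_report.tsv")
        qcd = {name: apply_qc(m, report) for name, m in processed.items()}
        for name, m in qcd.items():
            write_rfu_matrix(m, out / f"{name}.qc.tsv")
        record("qc", t0, [out / "qc_report.tsv"] + [out / f"{n}.qc.tsv" for n in qcd])
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("qc", e) from e

    try:
        # ---- discovery (training samples only, audited) ---------------
        t0 = time.time()
        train_qc = qcd["training"]
        train_ids = [
            s for s in train_qc.sample_ids
            if train_ann.set_index("sample_id").loc[s, "class_label"] in ("CASE", "CONTROL")
        ]
        audit = BlindingAudit.for_training(train_ids)
        disc_matrix = train_qc.subset(samples=train_ids)
        split = StudySplit(
            tuple(train_ids),
            tuple(s for s in qcd["verification"].sample_ids),
            tuple(s for s in qcd["validation"].sample_ids),
            config.seed,
        )
        write_split(split, out / "split.tsv")

        uni = univariate_screen(disc_matrix, train_ann, audit=audit)
        uni.to_csv(out / "univariate.tsv", sep="\t", index=False)
        candidates = select_candidates(uni, config.q_threshold, config.univariate_test)
        pd.DataFrame({"analyte_id": list(candidates.analyte_ids)}).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
        ranking = gini_rank(
            disc_matrix, train_ann, candidates,
            n_trees=config.n_trees, seed=config.seed, audit=audit,
        )
        ranking.table.to_csv(out / "ranking.tsv", sep="\t", index=False)
        sizes = tuple(sorted({min(k, len(ranking)) for k in config.scan_sizes}))
        override = config.panel_size if config.panel_size in sizes else None
        scan = panel_size_scan(
            disc_matrix, train_ann, ranking, sizes=sizes,
            n_trees=config.n_trees, seed=config.seed,
            override_k=override, audit=audit,
        )
        scan.table.to_csv(out / "panel_scan.tsv", sep="\t", index=False)
        panel = ranking.top(scan.chosen_k)
        record(
            "discover", t0,
            [out / f for f in ("univariate.tsv", "candidates.tsv", "ranking.tsv",
                               "panel_scan.tsv", "split.tsv")],
        )
        provenance["stages"]["discover"]["n_candidates"] = len(candidates.analyte_ids)
        provenance["stages"]["discover"]["chosen_k"] = scan.chosen_k
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("discover", e) from e

    try:
        # ---- train ----------------------------------------------------
        t0 = time.time()
        rule = config.threshold_rule
        threshold_rule = rule if rule == "youden" else float(rule.split(":", 1)[1])
        model = train_panel_model(
            disc_matrix, train_ann, panel,
            n_trees=config.n_trees, threshold_rule=threshold_rule, seed=config.seed,
        )
        model.save(out / "model.joblib")
        model_hash = model.model_hash()
        pd.DataFrame({"analyte_id": list(panel)}).to_csv(
            out / "panel.tsv", sep="\t", index=False
        )
        record("train", t0, [out / "panel.tsv"])
        provenance["stages"]["train"]["model_hash"] = model_hash
        provenance["stages"]["train"]["threshold"] = model.threshold
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("train", e) from e

    try:
        # ---- predict + evaluate --------------------------------------
        t0 = time.time()
        reports = {}
        all_counts, stage_tables = [], []
        train_oob = oob_performance(model, disc_matrix, train_ann)
        for name in cohorts:
            m = qcd[name]
            ann = anns[name]
            eligible = ann[ann["class_label"].isin(["CASE", "CONTROL"])]["sample_id"]
            m = m.subset(samples=[s for s in m.sample_ids if s in set(eligible)])
            scores = predict(model, m)
            # threshold immutability: the model's decision function is frozen
            assert model.model_hash() == model_hash, "model mutated during scoring"
            scores.to_csv(out / f"scores_{name}.tsv", sep="\t", index=False)
            rep = evaluate_cohort(
                scores, ann, cohort=name, prevalence=config.prevalence, seed=config.seed
            )
            reports[name] = rep
            all_counts.append(rep.counts)
            stage_tables.append(rep.stage_table)
        pooled = pool_cohorts(all_counts)
        pooled_metrics = confusion_metrics(pooled)
        combined_stage = pool_stage_tables(stage_tables)
        combined_screening = screening_estimates(
            pooled.tp / pooled.cases, pooled.tn / pooled.controls, config.prevalence
        )
        final = {
            "cohorts": {n: r.to_dict() for n, r in reports.items()},
            "training_oob": train_oob,
            "combined": {
                "counts": {k: getattr(pooled, k) for k in ("tp", "fn", "tn", "fp")},
                "metrics": {
                    k: {"estimate": m.estimate, "ci_low": m.ci_low, "ci_high": m.ci_high}
                    for k, m in pooled_metrics.items()
                },
                "stage_table": combined_stage.to_dict(orient="records"),
                "screening": {
                    "prevalence": combined_screening.prevalence,
                    "ppv": combined_screening.ppv,
                    "npv": combined_screening.npv,
                    "population_accuracy": combined_screening.population_accuracy,
                },
            },
        }
        (out / "report.json").write_text(json.dumps(final, indent=2, default=float))
        record(
            "evaluate", t0,
            [out / f"scores_{n}.tsv" for n in cohorts] + [out / "report.json"],
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("evaluate", e) from e
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    provenance["audit"] = audit.log
    if any(entry["violation"] for entry in audit.log):
        raise PipelineError("discover", RuntimeError("blinding violation recorded"))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=float))
    return provenance
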