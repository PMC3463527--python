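"""Synthetic serum-proteomic cohort generator.

Emulates the statistical structure of a multi-center aptamer-proteomic
case-control study: ~1045 log-normal analytes, a spiked subset of true and
weak disease markers with stage-graded effect sizes, site and plate batch
effects, per-plate reference calibrator wells, a protein-degradation
artifact confined to one control site, and draw-procedure (intra-operative
vs pre-operative) shifts in a subset of analytes.

All structure is additive on the log2 scale and exponentiated to RFU.  One
master seed fans out into named substreams so that adding a component never
perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RfuMatrix, validate_annotation

# fixed substream keys: adding new components must append, never renumber
_K_BASELINE = 0
_K_MARKERS = 1
_K_SITES = 2
_K_ARTIFACT = 3
_K_DEGRADATION = 4
_K_COHORT = 10  # + cohort stream index
_K_PAIRED = 100

#: pathologic stage distribution of cases (roughly one third stage I/II,
#: matching a surgical mesothelioma case mix)
STAGE_PROBS = {"I": 0.11, "II": 0.23, "III": 0.42, "IV": 0.22, "UNKNOWN": 0.02}
HISTOLOGY_PROBS = {"EPITHELIAL": 0.6, "BIPHASIC": 0.25, "SARCOMATOID": 0.1, "UNKNOWN": 0.05}


@dataclass
class CohortSpec:
    """Parameters of the synthetic study.

    Effect sizes are additive shifts in log2-RFU units.  Of the
    ``n_true_markers`` strong markers, ``n_down_markers`` are down-regulated
    in cases (mirroring a 9-up / 4-down panel); weak markers get random
    signs.  The stage gradient multiplies the case effect so signal grows
    with disease burden.
    """

    n_cases: int = 60
    n_controls: int = 60
    n_analytes: int = 1045
    n_true_markers: int = 13
    n_weak_markers: int = 51
    n_down_markers: int = 4
    effect_size: float = 1.0
    weak_effect_size: float = 0.5
    stage_gradient: dict[str, float] = field(
        default_factory=lambda: {"I": 0.5, "II": 0.75, "III": 1.0, "IV": 1.25, "UNKNOWN": 1.0}
    )
    n_sites: int = 3
    site_offset_sd: float = 0.1
    n_plates: int = 3
    plate_bias_sd: float = 0.2
    calibrators_per_plate: int = 8
    degraded_fraction: float = 1.0
    degradation_analyte_fraction: float = 0.2
    degradation_shift: float = -1.5
    n_artifact_analytes: int = 30
    draw_shift: float = 1.5
    intra_op_case_fraction: float = 0.5
    n_paired_subjects: int = 12
    paired_subject_sd: float = 0.3
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.5
    calibrator_noise_sd: float = 0.1
    assay_version: str = "V1"
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_cases, self.n_controls, self.n_analytes, self.n_true_markers,
            self.n_weak_markers, self.n_artifact_analytes, self.n_sites,
            self.n_plates, self.calibrators_per_plate, self.n_paired_subjects,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_true_markers + self.n_weak_markers > self.n_analytes:
            raise ValueError("more spiked markers than analytes")
        if self.n_down_markers > self.n_true_markers:
            raise ValueError("n_down_markers exceeds n_true_markers")
        if not 0.0 <= self.degraded_fraction <= 1.0:
            raise ValueError("degraded_fraction must be in [0, 1]")
        if self.n_sites < 1 or self.n_plates < 1:
            raise ValueError("need at least one site and one plate")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Injected structure, for parameter-recovery tests."""

    true_marker_ids: tuple[str, ...]
    weak_marker_ids: tuple[str, ...]
    artifact_analyte_ids: tuple[str, ...]
    degradation_analyte_ids: tuple[str, ...]
    degraded_sample_ids: tuple[str, ...]
    plate_log2_bias: dict[str, float]
    marker_effects: dict[str, float]  # signed log2 shift at stage multiplier 1


@dataclass
class _StudyParams:
    """Cohort-independent latent parameters drawn once from the seed."""

    baselines: np.ndarray  # per-analyte log2 means
    analyte_ids: list[str]
    site_names: list[str]
    site_offsets: np.ndarray  # (n_sites, n_analytes)
    marker_idx: np.ndarray
    weak_idx: np.ndarray
    marker_effects: np.ndarray  # signed, aligned with [marker_idx, weak_idx]
    artifact_idx: np.ndarray
    degradation_idx: np.ndarray


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def draw_parameters(spec: CohortSpec) -> _StudyParams:
    """Draw the latent study parameters (shared across cohorts)."""
    spec.validate()
    p = spec.n_analytes
    analyte_ids = [f"A{i:04d}" for i in range(p)]
    baselines = _rng(spec.seed, _K_BASELINE).normal(
        spec.baseline_log2_mean, spec.baseline_log2_sd, size=p
    )
    site_names = [f"SYNTH-S{i + 1}" for i in range(spec.n_sites)]
    site_offsets = _rng(spec.seed, _K_SITES).normal(
        0.0, spec.site_offset_sd, size=(spec.n_sites, p)
    )

    rng_m = _rng(spec.seed, _K_MARKERS)
    all_marker_idx = rng_m.choice(p, size=spec.n_true_markers + spec.n_weak_markers, replace=False)
    marker_idx = all_marker_idx[: spec.n_true_markers]
    weak_idx = all_marker_idx[spec.n_true_markers :]
    signs = np.ones(spec.n_true_markers)
    down = rng_m.choice(spec.n_true_markers, size=spec.n_down_markers, replace=False)
    signs[down] = -1.0
    weak_signs = rng_m.choice([-1.0, 1.0], size=spec.n_weak_markers)
    marker_effects = np.concatenate(
        [signs * spec.effect_size, weak_signs * spec.weak_effect_size]
    )

    non_marker = np.setdiff1d(np.arange(p), all_marker_idx)
    rng_a = _rng(spec.seed, _K_ARTIFACT)
    artifact_idx = np.sort(
        rng_a.choice(non_marker, size=min(spec.n_artifact_analytes, len(non_marker)), replace=False)
    )
    remaining = np.setdiff1d(non_marker, artifact_idx)
    rng_d = _rng(spec.seed, _K_DEGRADATION)
    n_deg = min(int(round(spec.degradation_analyte_fraction * p)), len(remaining))
    degradation_idx = np.sort(rng_d.choice(remaining, size=n_deg, replace=False))
    return _StudyParams(
        baselines=baselines,
        analyte_ids=analyte_ids,
        site_names=site_names,
        site_offsets=site_offsets,
        marker_idx=marker_idx,
        weak_idx=weak_idx,
        marker_effects=marker_effects,
        artifact_idx=artifact_idx,
        degradation_idx=degradation_idx,
    )


def _sample_cohort(
    spec: CohortSpec,
    params: _StudyParams,
    n_cases: int,
    n_controls: int,
    tag: str,
    stream: int,
) -> tuple[RfuMatrix, pd.DataFrame, GroundTruth]:
    rng = _rng(spec.seed, _K_COHORT + stream)
    p = spec.n_analytes
    # the last site is an additional control-only subcohort carrying the
    # degradation artifact (emulating an archived control set removed after
    # QC); its size is degraded_fraction of the per-site control count and
    # it is extra to n_controls, so the clean cohort keeps its design size
    clean_sites = params.site_names[:-1] if spec.n_sites > 1 else params.site_names
    degraded_site = params.site_names[-1]
    n_extra = (
        int(round(spec.degraded_fraction * n_controls / max(len(clean_sites), 1)))
        if spec.n_sites > 1
        else 0
    )
    n = n_cases + n_controls + n_extra
    sample_ids = (
        [f"{tag}-MM-{i:03d}" for i in range(n_cases)]
        + [f"{tag}-CTRL-{i:03d}" for i in range(n_controls + n_extra)]
    )
    is_case = np.arange(n) < n_cases
    is_extra = np.arange(n) >= n_cases + n_controls

    site = np.array(
        list(rng.choice(clean_sites, size=n_cases + n_controls))
        + [degraded_site] * n_extra
    )

    plate_names = [f"{tag}-P{j + 1}" for j in range(spec.n_plates)]
    plate = np.array(plate_names)[rng.integers(0, spec.n_plates, size=n)]
    plate_bias = dict(
        zip(plate_names, rng.normal(0.0, spec.plate_bias_sd, size=spec.n_plates))
    )

    stages = list(STAGE_PROBS)
    stage = np.where(
        is_case,
        rng.choice(stages, size=n, p=list(STAGE_PROBS.values())),
        "NA",
    )
    histologies = list(HISTOLOGY_PROBS)
    histology = np.where(
        is_case,
        rng.choice(histologies, size=n, p=list(HISTOLOGY_PROBS.values())),
        "NA",
    )
    draw = np.where(
        is_case,
        np.where(rng.random(n) < spec.intra_op_case_fraction, "INTRA_OP", "PRE_OP"),
        "CLINIC",
    )

    degraded = is_extra.copy()

    log2v = np.tile(params.baselines, (n, 1))
    site_index = {s: i for i, s in enumerate(params.site_names)}
    log2v += params.site_offsets[[site_index[s] for s in site]]
    # case effect, graded by stage
    stage_mult = np.array(
        [spec.stage_gradient.get(s, 1.0) if c else 0.0 for s, c in zip(stage, is_case)]
    )
    marker_cols = np.concatenate([params.marker_idx, params.weak_idx]).astype(int)
    log2v[:, marker_cols] += np.outer(stage_mult, params.marker_effects)
    # draw-procedure shift on artifact analytes
    log2v[np.ix_(draw == "INTRA_OP", params.artifact_idx)] += spec.draw_shift
    # degradation artifact
    log2v[np.ix_(degraded, params.degradation_idx)] += spec.degradation_shift
    log2v += np.array([plate_bias[pl] for pl in plate])[:, None]
    log2v += rng.normal(0.0, spec.noise_sd, size=(n, p))

    # calibrator wells: fixed known log-means (the analyte baselines) plus
    # plate bias and a small replicate noise
    cal_ids: list[str] = []
    cal_rows: list[np.ndarray] = []
    cal_plates: list[str] = []
    for pl in plate_names:
        for k in range(spec.calibrators_per_plate):
            cal_ids.append(f"{tag}-CAL-{pl.split('-')[-1]}-{k:02d}")
            cal_plates.append(pl)
            cal_rows.append(
                params.baselines
                + plate_bias[pl]
                + rng.normal(0.0, spec.calibrator_noise_sd, size=p)
            )

    values = np.vstack([log2v, np.vstack(cal_rows)]) if cal_rows else log2v
    all_ids = sample_ids + cal_ids
    matrix = RfuMatrix(
        pd.DataFrame(np.exp2(values), index=all_ids, columns=params.analyte_ids)
    )

    ann = pd.DataFrame(
        {
            "sample_id": all_ids,
            "class_label": ["CASE" if c else "CONTROL" for c in is_case]
            + ["CALIBRATOR"] * len(cal_ids),
            "site": list(site) + ["SYNTH-LAB"] * len(cal_ids),
            "draw_type": list(draw) + ["NA"] * len(cal_ids),
            "subject_id": [f"{tag}-SUBJ-{i:03d}" for i in range(n)]
            + ["CALIBRATOR"] * len(cal_ids),
            "plate_id": list(plate) + cal_plates,
            "stage": list(stage) + ["NA"] * len(cal_ids),
            "histology": list(histology) + ["NA"] * len(cal_ids),
            "assay_version": [spec.assay_version] * len(all_ids),
        }
    )
    ann = validate_annotation(ann)

    ids = np.array(params.analyte_ids)
    truth = GroundTruth(
        true_marker_ids=tuple(ids[params.marker_idx]),
        weak_marker_ids=tuple(ids[params.weak_idx]),
        artifact_analyte_ids=tuple(ids[params.artifact_idx]),
        degradation_analyte_ids=tuple(ids[params.degradation_idx]),
        degraded_sample_ids=tuple(np.array(all_ids)[: n][degraded]),
        plate_log2_bias=plate_bias,
        marker_effects=dict(zip(ids[marker_cols], params.marker_effects)),
    )
    return matrix, ann, truth


def generate_cohort(
    spec: CohortSpec, tag: str = "D", stream: int = 0
) -> tuple[RfuMatrix, pd.DataFrame, GroundTruth]:
    """Generate one case-control cohort with calibrator wells.

    Fully reproducible from ``spec.seed``; the ``stream`` index selects an
    independent sampling substream so multiple cohorts can share the same
    latent study parameters (baselines, marker identities, effects).
    """
    params = draw_parameters(spec)
    return _sample_cohort(spec, params, spec.n_cases, spec.n_controls, tag, stream)


def generate_study(
    spec: CohortSpec,
    design: dict[str, tuple[int, int]] | None = None,
) -> dict[str, tuple[RfuMatrix, pd.DataFrame, GroundTruth]]:
    """Generate training / verification / validation cohorts plus paired draws.

    ``design`` maps cohort name to (n_cases, n_controls); the default mirrors
    a 60/60 training, 19/20 verification, 38/62 validation design.  All
    cohorts share latent parameters; only sampling noise, batch assignments
    and subjects differ.
    """
    if design is None:
        design = {"training": (60, 60), "verification": (19, 20), "validation": (38, 62)}
    params = draw_parameters(spec)
    out = {}
    for stream, (name, (nc, nk)) in enumerate(design.items()):
        # the degraded archival subcohort belongs to discovery only; blinded
        # cohorts are generated clean
        cohort_spec = spec if name == "training" else spec.replace(degraded_fraction=0.0)
        out[name] = _sample_cohort(cohort_spec, params, nc, nk, name[:5].upper(), stream)
    return out


def generate_paired_draws(spec: CohortSpec) -> tuple[RfuMatrix, pd.DataFrame]:
    """Generate paired pre-op / intra-op control draws from shared subjects.

    Two rows per subject sharing ``subject_id``; artifact analytes are
    shifted by ``draw_shift`` in the intra-op row, all other analytes differ
    only by within-subject noise.
    """
    spec.validate()
    if spec.n_paired_subjects < 1:
        raise ValueError("n_paired_subjects must be >= 1")
    params = draw_parameters(spec)
    rng = _rng(spec.seed, _K_PAIRED)
    p = spec.n_analytes
    ns = spec.n_paired_subjects
    subject_effect = rng.normal(0.0, spec.paired_subject_sd, size=(ns, p))
    ids, rows, draws, subjects = [], [], [], []
    for s in range(ns):
        base = params.baselines + subject_effect[s]
        for draw in ("PRE_OP", "INTRA_OP"):
            row = base + rng.normal(0.0, spec.noise_sd, size=p)
            if draw == "INTRA_OP":
                row = row.copy()
                row[params.artifact_idx] += spec.draw_shift
            ids.append(f"PAIR-{s:02d}-{draw}")
            rows.append(row)
            draws.append(draw)
            subjects.append(f"PAIR-SUBJ-{s:02d}")
    matrix = RfuMatrix(
        pd.DataFrame(np.exp2(np.vstack(rows)), index=ids, columns=params.analyte_ids)
    )
    ann = validate_annotation(
        pd.DataFrame(
            {
                "sample_id": ids,
                "class_label": "CONTROL",
                "site": "SYNTH-S2",
                "draw_type": draws,
                "subject_id": subjects,
                "plate_id": "PAIR-P1",
                "stage": "NA",
                "histology": "NA",
                "assay_version": spec.assay_version,
            }
        )
    )
    return matrix, ann
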