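"""Preanalytic-variability quality control.

Serum proteomic case-control studies built on archived multi-center samples
are vulnerable to preanalytic artifacts: inter-site handling differences,
draw-procedure shifts (intra-operative vs clinic draws), plate effects and
outright protein degradation.  This module screens analytes and samples for
such artifacts *without ever inspecting case/control labels* — only
technical covariates (control site, draw type, plate) are used, so the
filters cannot leak the discovery contrast.

Three screens are provided:

* an inter-control-site Kolmogorov–Smirnov distance filter (exclude an
  analyte when any pair of control sites differs by D > 0.45),
* a paired pre-op/intra-op filter (Wilcoxon signed-rank plus a minimum
  median log2-shift gate),
* a PCA artifact screen that flags components correlated with technical
  covariates, then samples with outlying scores and analytes with extreme
  loadings on those components.

All distributional computations are on log2(RFU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .data import RfuMatrix

logger = logging.getLogger(__name__)

REASON_KS = "KS_CONTROL_SETS"
REASON_PAIRED = "PAIRED_DRAW"
REASON_PCA = "PCA_ARTIFACT"

_EXCL_ANALYTE_COLS = ["analyte_id", "reason", "statistic"]
_EXCL_SAMPLE_COLS = ["sample_id", "reason", "statistic"]


@dataclass
class QcReport:
    """Exclusions with reasons and the statistics that triggered them."""

    excluded_analytes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_EXCL_ANALYTE_COLS)
    )
    excluded_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_EXCL_SAMPLE_COLS)
    )
    ks_table: pd.DataFrame | None = None
    paired_table: pd.DataFrame | None = None
    pca_summary: pd.DataFrame | None = None

    def merge(self, other: "QcReport") -> "QcReport":
        def cat(a, b, cols):
            frames = [f for f in (a, b) if f is not None and len(f)]
            return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)

        return QcReport(
            excluded_analytes=cat(
                self.excluded_analytes, other.excluded_analytes, _EXCL_ANALYTE_COLS
            ),
            excluded_samples=cat(
                self.excluded_samples, other.excluded_samples, _EXCL_SAMPLE_COLS
            ),
            ks_table=other.ks_table if other.ks_table is not None else self.ks_table,
            paired_table=other.paired_table if other.paired_table is not None else self.paired_table,
            pca_summary=other.pca_summary if other.pca_summary is not None else self.pca_summary,
        )


def ks_distance(x, y) -> float:
    """Two-sample Kolmogorov–Smirnov distance.

    The supremum absolute difference between the empirical CDFs of ``x``
    and ``y``; lies in [0, 1], is symmetric, and is invariant under any
    strictly monotone transform applied jointly to both samples.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("ks_distance requires nonempty samples")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / len(x)
    cdf_y = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def filter_ks_control_sets(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    threshold: float = 0.45,
    min_per_site: int = 5,
) -> QcReport:
    """Exclude analytes whose control distributions differ across sites.

    For every analyte the KS distance is computed on log2 values for every
    pair of eligible control sites; the analyte is excluded iff the maximum
    pairwise distance is strictly greater than ``threshold``.
    """
    ann = ann.set_index("sample_id", drop=False)
    controls = ann[ann["class_label"] == "CONTROL"]
    controls = controls[controls["sample_id"].isin(matrix.sample_ids)]
    sites = {
        s: list(g["sample_id"])
        for s, g in controls.groupby("site")
        if len(g) >= min_per_site
    }
    if len(sites) < 2:
        raise ValueError(
            f"need >=2 control sites with >={min_per_site} samples, got {len(sites)}"
        )
    log2 = matrix.log2()
    site_names = sorted(sites)
    site_arrays = {s: log2.loc[sites[s]].to_numpy() for s in site_names}

    rows = []
    for j, analyte in enumerate(matrix.analyte_ids):
        best_d, best_pair = 0.0, (site_names[0], site_names[1])
        for a in range(len(site_names)):
            for b in range(a + 1, len(site_names)):
                d = ks_distance(
                    site_arrays[site_names[a]][:, j], site_arrays[site_names[b]][:, j]
                )
                if d > best_d:
                    best_d, best_pair = d, (site_names[a], site_names[b])
        rows.append((analyte, best_d, f"{best_pair[0]}|{best_pair[1]}"))
    ks_table = pd.DataFrame(rows, columns=["analyte_id", "max_ks_distance", "site_pair"])
    excluded = ks_table[ks_table["max_ks_distance"] > threshold]
    report = QcReport(
        excluded_analytes=pd.DataFrame(
            {
                "analyte_id": excluded["analyte_id"],
                "reason": REASON_KS,
                "statistic": excluded["max_ks_distance"],
            }
        ).reset_index(drop=True),
        ks_table=ks_table,
    )
    logger.info(
        "KS control-set filter: %d/%d analytes excluded at D>%g",
        len(excluded), len(ks_table), threshold,
    )
    return report


def filter_paired_draws(
    paired_matrix: RfuMatrix,
    ann: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2_shift: float = 0.5,
) -> QcReport:
    """Exclude analytes shifted between matched intra-op and pre-op draws.

    Per analyte, paired log2 ratios (intra-op minus pre-op, by subject) are
    tested with the Wilcoxon signed-rank test; the analyte is excluded iff
    p < ``alpha`` AND the absolute median ratio is at least
    ``min_abs_log2_shift``.  The conjunction guards against excluding
    analytes for consistent but trivially small shifts.
    """
    ann = ann.set_index("sample_id", drop=False)
    ann = ann.loc[[s for s in paired_matrix.sample_ids if s in ann.index]]
    pre = ann[ann["draw_type"] == "PRE_OP"].set_index("subject_id")["sample_id"]
    intra = ann[ann["draw_type"] == "INTRA_OP"].set_index("subject_id")["sample_id"]
    subjects = sorted(set(pre.index) & set(intra.index))
    if len(subjects) < 2:
        raise ValueError("need >=2 subjects with both draw types")
    log2 = paired_matrix.log2()
    diffs = (
        log2.loc[intra.loc[subjects].to_numpy()].to_numpy()
        - log2.loc[pre.loc[subjects].to_numpy()].to_numpy()
    )

    medians = np.median(diffs, axis=0)
    pvals = np.ones(diffs.shape[1])
    for j in range(diffs.shape[1]):
        d = diffs[:, j]
        if np.allclose(d, 0.0):
            pvals[j] = 1.0
        else:
            pvals[j] = stats.wilcoxon(d, zero_method="wilcox", method="auto").pvalue
    paired_table = pd.DataFrame(
        {
            "analyte_id": paired_matrix.analyte_ids,
            "median_paired_log2_ratio": medians,
            "p_value": pvals,
        }
    )
    mask = (pvals < alpha) & (np.abs(medians) >= min_abs_log2_shift)
    excluded = paired_table[mask]
    logger.info(
        "paired-draw filter: %d/%d analytes excluded (alpha=%g, min shift=%g)",
        len(excluded), len(paired_table), alpha, min_abs_log2_shift,
    )
    return QcReport(
        excluded_analytes=pd.DataFrame(
            {
                "analyte_id": excluded["analyte_id"],
                "reason": REASON_PAIRED,
                "statistic": excluded["median_paired_log2_ratio"],
            }
        ).reset_index(drop=True),
        paired_table=paired_table,
    )


def _correlation_ratio(scores: np.ndarray, labels: np.ndarray) -> float:
    """eta: sqrt of between-group over total sum of squares (0 if degenerate)."""
    total = np.sum((scores - scores.mean()) ** 2)
    if total <= 0:
        return 0.0
    between = 0.0
    for g in np.unique(labels):
        sel = scores[labels == g]
        between += len(sel) * (sel.mean() - scores.mean()) ** 2
    return float(np.sqrt(between / total))


def pca_artifact_screen(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    covariates: tuple[str, ...] = ("site", "plate_id", "draw_type"),
    r_threshold: float = 0.5,
    score_mads: float = 3.0,
    min_variance_ratio: float = 0.01,
    loading_decile: float = 0.9,
    max_components: int = 30,
    association_samples: str = "controls",
) -> QcReport:
    """Flag samples and analytes loading on technical-covariate components.

    Principal components of the log2, analyte-standardized matrix are
    screened: a component explaining at least ``min_variance_ratio`` of the
    variance is flagged when its scores correlate with a technical covariate
    (correlation ratio eta > ``r_threshold``).  On flagged components,
    samples whose scores are more than ``score_mads`` robust MADs from the
    median are flagged, as are analytes in the top decile of absolute
    loading.  Flags are advisory: exclusion happens in :func:`apply_qc`.

    By default the component-covariate association is evaluated on control
    samples only (``association_samples="controls"``): technical covariates
    can be confounded with disease status (e.g. intra-operative draws or
    case-enriched sites), and restricting the association to controls
    ensures a component carrying genuine disease signal is never flagged as
    an artifact.  Pass ``"all"`` to associate over every sample.
    """
    if matrix.shape[0] < 10:
        raise ValueError("PCA screen requires at least 10 samples")
    log2 = matrix.log2().to_numpy()
    sd = log2.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("degenerate (constant) matrix")
    keep = sd > 0
    X = (log2[:, keep] - log2[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(max_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_

    ann = ann.set_index("sample_id", drop=False).loc[list(matrix.sample_ids)]
    if association_samples == "controls":
        assoc = (ann["class_label"] == "CONTROL").to_numpy()
        if assoc.sum() < 3:  # degenerate annotation: fall back to all samples
            assoc = np.ones(len(ann), dtype=bool)
    elif association_samples == "all":
        assoc = np.ones(len(ann), dtype=bool)
    else:
        raise ValueError(f"unknown association_samples {association_samples!r}")
    summary_rows = []
    flagged_comps = []
    for j in range(n_comp):
        if evr[j] < min_variance_ratio:
            continue
        best_cov, best_eta = "", 0.0
        for cov in covariates:
            eta = _correlation_ratio(scores[assoc, j], ann[cov].to_numpy()[assoc])
            if eta > best_eta:
                best_cov, best_eta = cov, eta
        flagged = best_eta > r_threshold
        summary_rows.append((j + 1, evr[j], best_cov, best_eta, flagged))
        if flagged:
            flagged_comps.append(j)
    pca_summary = pd.DataFrame(
        summary_rows,
        columns=["component", "variance_ratio", "best_covariate", "eta", "flagged"],
    )

    sample_rows, analyte_rows = [], []
    analyte_ids = np.array(matrix.analyte_ids)[keep]
    for j in flagged_comps:
        s = scores[:, j]
        med = np.median(s)
        mad = stats.median_abs_deviation(s, scale="normal")
        if mad > 0:
            z = np.abs(s - med) / mad
            for sid, zi in zip(matrix.sample_ids, z):
                if zi > score_mads:
                    sample_rows.append((sid, REASON_PCA, float(zi)))
        load = np.abs(pca.components_[j])
        cut = np.quantile(load, loading_decile)
        for aid, li in zip(analyte_ids, load):
            if li >= cut:
                analyte_rows.append((aid, REASON_PCA, float(li)))

    excluded_samples = (
        pd.DataFrame(sample_rows, columns=_EXCL_SAMPLE_COLS)
        .drop_duplicates("sample_id")
        .reset_index(drop=True)
    )
    excluded_analytes = (
        pd.DataFrame(analyte_rows, columns=_EXCL_ANALYTE_COLS)
        .drop_duplicates("analyte_id")
        .reset_index(drop=True)
    )
    logger.info(
        "PCA screen: %d flagged components, %d samples, %d analytes",
        len(flagged_comps), len(excluded_samples), len(excluded_analytes),
    )
    return QcReport(
        excluded_analytes=excluded_analytes,
        excluded_samples=excluded_samples,
        pca_summary=pca_summary,
    )


def apply_qc(matrix: RfuMatrix, report: QcReport) -> RfuMatrix:
    """Drop excluded analytes and samples from the matrix."""
    drop_analytes = set(report.excluded_analytes["analyte_id"]) & set(matrix.analyte_ids)
    drop_samples = set(report.excluded_samples["sample_id"]) & set(matrix.sample_ids)
    if report.excluded_analytes is not None and len(report.excluded_analytes):
        by_reason = report.excluded_analytes.groupby("reason").size().to_dict()
        logger.info("applying QC: dropping %d analytes %s", len(drop_analytes), by_reason)
    if drop_samples:
        logger.info("applying QC: dropping %d samples", len(drop_samples))
    keep_s = [s for s in matrix.sample_ids if s not in drop_samples]
    keep_a = [a for a in matrix.analyte_ids if a not in drop_analytes]
    return matrix.subset(samples=keep_s, analytes=keep_a)


def write_qc_report(report: QcReport, path) -> None:
    """Long-format exclusion table: id, kind, reason, statistic."""
    rows = [
        {"id": r.analyte_id, "kind": "analyte", "reason": r.reason, "statistic": r.statistic}
        for r in report.excluded_analytes.itertuples()
    ] + [
        {"id": r.sample_id, "kind": "sample", "reason": r.reason, "statistic": r.statistic}
        for r in report.excluded_samples.itertuples()
    ]
    pd.DataFrame(rows, columns=["id", "kind", "reason", "statistic"]).to_csv(
        path, sep="\t", index=False
    )
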