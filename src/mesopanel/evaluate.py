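"""Diagnostic performance statistics for blinded cohort evaluation.

Covers everything a fixed-threshold screening classifier reports: confusion
metrics with Wald confidence intervals (percent scale, clipped to [0, 100]),
cohort pooling on summed counts, stage-stratified detection rates, empirical
ROC curves with AUC and DeLong (or stratified-bootstrap) confidence
intervals, alternative operating points under a specificity constraint, and
prevalence-adjusted screening arithmetic (PPV/NPV/population accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

#: z for a two-sided 95% interval, at the precision used for reporting
Z_95 = 1.959964

#: default screening prevalence: the malignant-mesothelioma rate observed in
#: CT screening of asbestos-exposed individuals (1.4%)
DEFAULT_PREVALENCE = 0.014


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int
    cohort: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def cases(self) -> int:
        return self.tp + self.fn

    @property
    def controls(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_scores(cls, scores: pd.DataFrame, ann: pd.DataFrame, cohort: str = "") -> "ConfusionCounts":
        ann = ann.set_index("sample_id", drop=False)
        lab = ann.loc[list(scores["sample_id"]), "class_label"]
        if not lab.isin(["CASE", "CONTROL"]).all():
            raise ValueError("scores include non case/control samples")
        truth = (lab == "CASE").to_numpy()
        pred = scores["label"].to_numpy().astype(bool)
        return cls(
            tp=int((truth & pred).sum()),
            fn=int((truth & ~pred).sum()),
            tn=int((~truth & ~pred).sum()),
            fp=int((~truth & pred).sum()),
            cohort=cohort,
        )


@dataclass
class MetricCI:
    """A proportion on the percent scale with a clipped Wald interval."""

    estimate: float
    ci_low: float
    ci_high: float

    def display(self) -> str:
        return f"{self.estimate:.1f} ({self.ci_low:.1f}–{self.ci_high:.1f})"

    def rounded(self) -> tuple[float, float, float]:
        return (round(self.estimate, 1), round(self.ci_low, 1), round(self.ci_high, 1))


def wald_ci_pct(successes: int, n: int, ci_level: float = 0.95) -> MetricCI:
    """Wald binomial interval, percent scale, clipped to [0, 100]."""
    if n < 1:
        raise ZeroDivisionError("zero denominator in proportion")
    p = successes / n
    z = Z_95 if ci_level == 0.95 else float(stats.norm.ppf(1 - (1 - ci_level) / 2))
    half = z * np.sqrt(p * (1 - p) / n)
    return MetricCI(
        estimate=100 * p,
        ci_low=float(np.clip(100 * (p - half), 0, 100)),
        ci_high=float(np.clip(100 * (p + half), 0, 100)),
    )


def confusion_metrics(counts: ConfusionCounts, ci_level: float = 0.95) -> dict[str, MetricCI]:
    """Sensitivity, specificity and accuracy with Wald CIs (percent)."""
    n = counts.cases + counts.controls
    return {
        "sensitivity": wald_ci_pct(counts.tp, counts.cases, ci_level),
        "specificity": wald_ci_pct(counts.tn, counts.controls, ci_level),
        "accuracy": wald_ci_pct(counts.tp + counts.tn, n, ci_level),
    }


def pool_cohorts(counts: list[ConfusionCounts]) -> ConfusionCounts:
    """Element-wise sum; pooled metrics come from summed counts, never from
    averaging per-cohort percentages."""
    if not counts:
        raise ValueError("need at least one cohort")
    return ConfusionCounts(
        tp=sum(c.tp for c in counts),
        fn=sum(c.fn for c in counts),
        tn=sum(c.tn for c in counts),
        fp=sum(c.fp for c in counts),
        cohort="combined",
    )


STAGE_ORDER = ("I", "II", "III", "IV", "UNKNOWN")


def stage_sensitivity(scores: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Detected/total cases per pathologic stage (0/0 strata -> NaN pct)."""
    cols = ann[["sample_id", "class_label", "stage"]].reset_index(drop=True)
    merged = scores.merge(cols, on="sample_id", how="left")
    cases = merged[merged["class_label"] == "CASE"]
    rows = []
    for stage in STAGE_ORDER:
        g = cases[cases["stage"] == stage]
        detected = int(g["label"].sum())
        total = len(g)
        pct = 100 * detected / total if total else float("nan")
        rows.append((stage, detected, total, pct))
    return pd.DataFrame(rows, columns=["stage", "detected", "total", "pct"])


def pool_stage_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Combined detection table: strata pooled across cohorts by summed counts."""
    cat = pd.concat(tables, ignore_index=True)
    agg = cat.groupby("stage", sort=False)[["detected", "total"]].sum().reindex(list(STAGE_ORDER))
    agg["pct"] = 100 * agg["detected"] / agg["total"].where(agg["total"] > 0)
    return agg.reset_index()


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray  # prediction positive iff score >= cutoff
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str = "delong"

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "cutoff": self.cutoffs})


def _auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def delong_auc_se(y: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """AUC (Mann–Whitney with half-credit ties) and its DeLong standard error."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (all_r[:m] - r_pos) / n  # placement of each positive among negatives
    v10 = 1.0 - (all_r[m:] - r_neg) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc), float(np.sqrt(var))


def roc_auc(
    scores: pd.DataFrame,
    ann: pd.DataFrame,
    ci: str = "delong",
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocCurve:
    """Empirical ROC over all distinct cutoffs with an AUC confidence interval.

    ``ci`` is ``"delong"`` (default, deterministic) or ``"bootstrap"``
    (stratified percentile bootstrap with ``n_boot`` resamples).
    """
    ann = ann.set_index("sample_id", drop=False)
    lab = ann.loc[list(scores["sample_id"]), "class_label"]
    y = (lab == "CASE").to_numpy().astype(int)
    s = scores["score"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC requires both classes")
    fpr, tpr, cut = _sk_roc_curve(y, s, drop_intermediate=False)
    auc, se = delong_auc_se(y, s)
    z = Z_95 if ci_level == 0.95 else float(stats.norm.ppf(1 - (1 - ci_level) / 2))
    if ci == "delong":
        lo, hi = auc - z * se, auc + z * se
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_i, neg_i = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [
                    rng.choice(pos_i, size=len(pos_i), replace=True),
                    rng.choice(neg_i, size=len(neg_i), replace=True),
                ]
            )
            boots[b] = delong_auc_se(y[idx], s[idx])[0]
        alpha = (1 - ci_level) / 2
        lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        cutoffs=cut,
        auc=auc,
        ci_low=float(np.clip(lo, 0, 1)),
        ci_high=float(np.clip(hi, 0, 1)),
        ci_method=ci,
    )


def operating_point(roc: RocCurve, min_specificity: float) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing sensitivity subject to
    specificity >= ``min_specificity``; ties broken toward higher specificity."""
    if min_specificity > 1:
        raise ValueError("specificity constraint cannot exceed 1")
    spec = 1.0 - roc.fpr
    ok = np.flatnonzero(spec >= min_specificity)
    if len(ok) == 0:
        raise ValueError("constraint unsatisfiable on this curve")
    best = ok[np.lexsort((-spec[ok], -roc.tpr[ok]))][0]
    return float(roc.cutoffs[best]), float(roc.tpr[best]), float(spec[best])


@dataclass
class ScreeningEstimates:
    prevalence: float
    ppv: float
    npv: float
    population_accuracy: float


def screening_estimates(
    sensitivity: float, specificity: float, prevalence: float = DEFAULT_PREVALENCE
) -> ScreeningEstimates:
    """Prevalence-adjusted PPV, NPV and population accuracy.

    Boundary prevalences 0 and 1 return the documented limit values
    (PPV -> 0/1, NPV -> 1/0 respectively).
    """
    se, sp, pi = sensitivity, specificity, prevalence
    for name, v in (("sensitivity", se), ("specificity", sp)):
        if not 0 < v < 1 and v not in (0.0, 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if not 0 <= pi <= 1:
        raise ValueError("prevalence must lie in [0, 1]")
    if pi == 0.0:
        return ScreeningEstimates(pi, 0.0, 1.0, sp)
    if pi == 1.0:
        return ScreeningEstimates(pi, 1.0, 0.0, se)
    ppv = se * pi / (se * pi + (1 - sp) * (1 - pi))
    npv = sp * (1 - pi) / (sp * (1 - pi) + (1 - se) * pi)
    acc = se * pi + sp * (1 - pi)
    return ScreeningEstimates(pi, ppv, npv, acc)


@dataclass
class EvalReport:
    """Full per-cohort evaluation: counts, metrics, ROC, stage table."""

    counts: ConfusionCounts
    metrics: dict[str, MetricCI]
    roc: RocCurve
    stage_table: pd.DataFrame
    screening: ScreeningEstimates | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "cohort": self.counts.cohort,
            "counts": {k: getattr(self.counts, k) for k in ("tp", "fn", "tn", "fp")},
            "metrics": {
                k: {"estimate": m.estimate, "ci_low": m.ci_low, "ci_high": m.ci_high}
                for k, m in self.metrics.items()
            },
            "auc": {
                "value": self.roc.auc,
                "ci_low": self.roc.ci_low,
                "ci_high": self.roc.ci_high,
                "method": self.roc.ci_method,
            },
            "stage_table": self.stage_table.to_dict(orient="records"),
        }
        if self.screening is not None:
            d["screening"] = {
                "prevalence": self.screening.prevalence,
                "ppv": self.screening.ppv,
                "npv": self.screening.npv,
                "population_accuracy": self.screening.population_accuracy,
            }
        d.update(self.extras)
        return d


def evaluate_cohort(
    scores: pd.DataFrame,
    ann: pd.DataFrame,
    cohort: str = "",
    prevalence: float | None = None,
    ci: str = "delong",
    seed: int = 0,
) -> EvalReport:
    """Assemble the full report for one scored cohort."""
    counts = ConfusionCounts.from_scores(scores, ann, cohort)
    metrics = confusion_metrics(counts)
    roc = roc_auc(scores, ann, ci=ci, seed=seed)
    stages = stage_sensitivity(scores, ann)
    screening = None
    if prevalence is not None:
        screening = screening_estimates(
            counts.tp / counts.cases, counts.tn / counts.controls, prevalence
        )
    return EvalReport(counts, metrics, roc, stages, screening)
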