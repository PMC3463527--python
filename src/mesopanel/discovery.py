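"""Candidate-marker discovery and panel ranking.

The discovery path is: univariate screening (two-sample KS test and Welch
t-test on log2 RFU, Benjamini–Hochberg adjusted) to a candidate set, a
single random forest over all candidates whose Gini importance (mean
decrease in node impurity) fixes one ranking, and a panel-size scan over
nested top-k panels scored by out-of-bag AUC.  Ranking once from a single
forest, rather than stepwise reselection, keeps the panels nested and the
procedure resistant to overfitting.

Every operation accepts an optional :class:`~mesopanel.audit.BlindingAudit`
and refuses to run on samples outside the training split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .audit import BlindingAudit
from .data import RfuMatrix
from .evaluate import delong_auc_se

DEFAULT_N_TREES = 1000


def _case_control(matrix: RfuMatrix, ann: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ann = ann.set_index("sample_id", drop=False).loc[list(matrix.sample_ids)]
    keep = ann["class_label"].isin(["CASE", "CONTROL"]).to_numpy()
    y = (ann["class_label"].to_numpy()[keep] == "CASE").astype(int)
    return keep, y


def univariate_screen(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    audit: BlindingAudit | None = None,
) -> pd.DataFrame:
    """Per-analyte KS and Welch t-tests of case vs control on log2 values.

    Returns a table with raw p-values, BH-adjusted q-values for each test,
    the direction of regulation (sign of the median log2 difference) and
    the case/control median fold change on the RFU scale.
    """
    if audit is not None:
        audit.check("univariate_screen", matrix.sample_ids)
    keep, y = _case_control(matrix, ann)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    log2 = matrix.log2().to_numpy()[keep]
    cases, controls = log2[y == 1], log2[y == 0]

    t_p = stats.ttest_ind(cases, controls, equal_var=False, axis=0).pvalue
    t_p = np.nan_to_num(np.asarray(t_p, dtype=float), nan=1.0)  # zero-variance -> 1
    ks_p = np.ones(log2.shape[1])
    for j in range(log2.shape[1]):
        x, z = cases[:, j], controls[:, j]
        if np.ptp(x) == 0 and np.ptp(z) == 0 and x[0] == z[0]:
            continue  # identical constant values: p = 1 by convention
        ks_p[j] = stats.ks_2samp(x, z).pvalue
    ks_p = np.nan_to_num(ks_p, nan=1.0)

    med_diff = np.median(cases, axis=0) - np.median(controls, axis=0)
    fold = 2.0 ** med_diff  # median(case)/median(control); log2-median commutes
    direction = np.where(med_diff > 0, "UP", np.where(med_diff < 0, "DOWN", "NA"))
    return pd.DataFrame(
        {
            "analyte_id": matrix.analyte_ids,
            "t_p": t_p,
            "ks_p": ks_p,
            "t_q": multipletests(t_p, method="fdr_bh")[1],
            "ks_q": multipletests(ks_p, method="fdr_bh")[1],
            "direction": direction,
            "fold_change": fold,
            "median_log2_diff": med_diff,
        }
    )


@dataclass
class CandidateSet:
    analyte_ids: tuple[str, ...]
    rule: dict


def select_candidates(
    table: pd.DataFrame, q_threshold: float = 0.01, test: str = "either"
) -> CandidateSet:
    """Analytes with adjusted q below threshold under the chosen test(s)."""
    if test == "t":
        mask = table["t_q"] < q_threshold
    elif test == "ks":
        mask = table["ks_q"] < q_threshold
    elif test == "either":
        mask = (table["t_q"] < q_threshold) | (table["ks_q"] < q_threshold)
    else:
        raise ValueError(f"unknown test {test!r}")
    ids = tuple(table.loc[mask, "analyte_id"])
    return CandidateSet(ids, {"q_threshold": q_threshold, "test": test})


@dataclass
class ImportanceRanking:
    table: pd.DataFrame  # analyte_id, importance, rank (1..K)
    oob_error: float
    seed: int

    def top(self, k: int) -> tuple[str, ...]:
        if k > len(self.table):
            raise ValueError(f"k={k} exceeds ranking size {len(self.table)}")
        return tuple(self.table.sort_values("rank").head(k)["analyte_id"])

    def __len__(self) -> int:
        return len(self.table)


def gini_rank(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    candidates: CandidateSet,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    audit: BlindingAudit | None = None,
) -> ImportanceRanking:
    """Rank candidates by Gini importance from one random forest.

    A single forest (bootstrap per tree, Gini split criterion, sqrt(p)
    features per split) is built on log2 values of all candidates; the
    importance of each candidate is its mean decrease in Gini impurity over
    the forest.  Deterministic given ``seed``.
    """
    if not candidates.analyte_ids:
        raise ValueError("candidate set is empty")
    if audit is not None:
        audit.check("gini_rank", matrix.sample_ids)
    sub = matrix.subset(analytes=list(candidates.analyte_ids))
    keep, y = _case_control(sub, ann)
    X = sub.log2().to_numpy()[keep]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")
    table = pd.DataFrame(
        {
            "analyte_id": np.array(candidates.analyte_ids)[order],
            "importance": imp[order],
            "rank": np.arange(1, len(imp) + 1),
        }
    )
    return ImportanceRanking(table, oob_error=1.0 - forest.oob_score_, seed=seed)


@dataclass
class PanelScan:
    table: pd.DataFrame  # k, oob_auc, auc_se
    chosen_k: int

    def panel(self, ranking: ImportanceRanking, k: int | None = None) -> tuple[str, ...]:
        return ranking.top(self.chosen_k if k is None else k)


def _oob_scores(forest: RandomForestClassifier) -> np.ndarray:
    s = forest.oob_decision_function_[:, 1]
    return np.nan_to_num(s, nan=0.5)  # samples never out-of-bag (rare) score 0.5


def panel_size_scan(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    ranking: ImportanceRanking,
    sizes: tuple[int, ...] = (1, 2, 3, 5, 8, 13, 21, 34, 55, 64),
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    override_k: int | None = None,
    audit: BlindingAudit | None = None,
) -> PanelScan:
    """Out-of-bag AUC of nested top-k panels over a size grid.

    Panels are nested prefixes of the single fixed ranking.  The chosen k is
    the smallest whose OOB AUC is within one standard error (DeLong) of the
    maximum, unless ``override_k`` pins it (default pipeline behaviour pins
    13).
    """
    if audit is not None:
        audit.check("panel_size_scan", matrix.sample_ids)
    sizes = tuple(k for k in sizes if k <= len(ranking))
    if not sizes:
        raise ValueError("no panel size is <= the ranking length")
    keep, y = _case_control(matrix, ann)
    rows = []
    for k in sizes:
        panel = list(ranking.top(k))
        X = matrix.subset(analytes=panel).log2().to_numpy()[keep]
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        ).fit(X, y)
        scores = _oob_scores(forest)
        auc, se = delong_auc_se(y, scores)
        rows.append((k, auc, se))
    table = pd.DataFrame(rows, columns=["k", "oob_auc", "auc_se"])
    if override_k is not None:
        if override_k not in sizes:
            raise ValueError(f"override_k={override_k} not in scanned sizes {sizes}")
        chosen = override_k
    else:
        best = table["oob_auc"].idxmax()
        floor = table.loc[best, "oob_auc"] - table.loc[best, "auc_se"]
        chosen = int(table.loc[table["oob_auc"] >= floor, "k"].min())
    return PanelScan(table, chosen_k=int(chosen))
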