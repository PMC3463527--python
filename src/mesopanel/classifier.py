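"""Fixed-panel random-forest classifier with a pre-specified threshold.

The model is a random forest over the log2 RFU values of a fixed marker
panel.  The decision threshold is set once at training time — by default at
the out-of-bag Youden-maximal cutoff, operationalizing "equal importance to
sensitivity and specificity" — and is immutable thereafter: scoring blinded
verification or validation samples never re-fits it.  Scores are vote
fractions (the share of trees voting disease), and prediction reads only
the RFU matrix, never annotations, so there is no access path from scoring
to class labels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .data import RfuMatrix

DEFAULT_N_TREES = 1000


def _hash_ids(ids) -> str:
    return hashlib.sha256("\n".join(sorted(ids)).encode()).hexdigest()


@dataclass
class PanelModel:
    panel: tuple[str, ...]
    forest: RandomForestClassifier
    threshold: float
    threshold_rule: str
    training_ids_hash: str
    seed: int
    assay_version: str = "V1"
    config: dict = field(default_factory=dict)

    def model_hash(self) -> str:
        """Hash of the frozen decision function (panel, threshold, forest params)."""
        h = hashlib.sha256()
        h.update(repr(self.panel).encode())
        h.update(repr(round(self.threshold, 12)).encode())
        h.update(repr(sorted(self.config.items())).encode())
        h.update(self.training_ids_hash.encode())
        return h.hexdigest()

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PanelModel":
        model = joblib.load(path)
        if not isinstance(model, PanelModel):
            raise TypeError(f"{path} does not contain a PanelModel")
        return model


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Cutoff maximizing sensitivity + specificity over observed scores.

    Ties are broken first toward minimal |sensitivity - specificity|, then
    toward the lower cutoff.  Prediction is positive at score >= cutoff; a
    sentinel just above the maximum score (all-negative rule) is included.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    cutoffs = np.unique(scores)
    cutoffs = np.append(cutoffs, np.nextafter(cutoffs[-1], np.inf))
    n_pos, n_neg = y.sum(), (~y).sum()
    best = None
    for c in cutoffs:
        pred = scores >= c
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        key = (-(sens + spec), abs(sens - spec), c)
        if best is None or key < best[0]:
            best = (key, c)
    return float(best[1])


def train_panel_model(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    panel: tuple[str, ...],
    n_trees: int = DEFAULT_N_TREES,
    threshold_rule: str | float = "youden",
    seed: int = 0,
) -> PanelModel:
    """Train the fixed-panel forest and freeze its decision threshold.

    ``threshold_rule`` is ``"youden"`` (out-of-bag Youden-maximal cutoff) or
    a fixed float in (0, 1).  Out-of-bag scores are used so the threshold is
    not set on resubstitution estimates.
    """
    missing = set(panel) - set(matrix.analyte_ids)
    if missing:
        raise KeyError(f"panel analytes missing from matrix: {sorted(missing)}")
    ann = ann.set_index("sample_id", drop=False).loc[list(matrix.sample_ids)]
    keep = ann["class_label"].isin(["CASE", "CONTROL"]).to_numpy()
    y = (ann["class_label"].to_numpy()[keep] == "CASE").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = matrix.subset(analytes=list(panel)).log2().to_numpy()[keep]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    if isinstance(threshold_rule, str):
        if threshold_rule != "youden":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        oob = np.nan_to_num(forest.oob_decision_function_[:, 1], nan=0.5)
        threshold = youden_threshold(oob, y)
        rule = "youden"
    else:
        threshold = float(threshold_rule)
        if not 0 < threshold < 1:
            raise ValueError("fixed threshold must lie in (0, 1)")
        rule = f"fixed:{threshold}"
    version = ann["assay_version"].iloc[0] if len(ann) else "V1"
    return PanelModel(
        panel=tuple(panel),
        forest=forest,
        threshold=threshold,
        threshold_rule=rule,
        training_ids_hash=_hash_ids(np.array(matrix.sample_ids)[keep]),
        seed=seed,
        assay_version=str(version),
        config={"n_trees": n_trees, "max_features": "sqrt"},
    )


def predict(model: PanelModel, matrix: RfuMatrix) -> pd.DataFrame:
    """Score samples: vote fraction for disease and thresholded label.

    Reads only the RFU matrix; a missing panel analyte is a hard error
    (no silent imputation).
    """
    missing = set(model.panel) - set(matrix.analyte_ids)
    if missing:
        raise KeyError(f"panel analytes missing from matrix: {sorted(missing)}")
    X = matrix.subset(analytes=list(model.panel)).log2().to_numpy()
    votes = np.zeros(len(X))
    for tree in model.forest.estimators_:
        votes += tree.predict(X)
    score = votes / len(model.forest.estimators_)
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "score": score,
            "label": (score >= model.threshold).astype(int),
        }
    )


def oob_performance(model: PanelModel, matrix: RfuMatrix, ann: pd.DataFrame) -> dict:
    """Out-of-bag sensitivity/specificity at the frozen threshold, plus AUC."""
    from .evaluate import delong_auc_se

    ann = ann.set_index("sample_id", drop=False).loc[list(matrix.sample_ids)]
    keep = ann["class_label"].isin(["CASE", "CONTROL"]).to_numpy()
    y = (ann["class_label"].to_numpy()[keep] == "CASE").astype(int)
    oob = np.nan_to_num(model.forest.oob_decision_function_[:, 1], nan=0.5)
    pred = oob >= model.threshold
    auc, se = delong_auc_se(y, oob)
    return {
        "oob_sensitivity": float(pred[y == 1].mean()),
        "oob_specificity": float((~pred[y == 0]).mean()),
        "oob_auc": auc,
        "oob_auc_se": se,
    }


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("spearman requires two equal-length samples of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def bridge_versions(
    model_v1: PanelModel,
    matrix_v1: RfuMatrix,
    matrix_v2: RfuMatrix,
    ann: pd.DataFrame,
    retrain_seed: int | None = None,
    correlation_floor: float = 0.9,
) -> tuple[PanelModel, dict]:
    """Re-train the panel in a new assay version and verify score concordance.

    The same panel is retrained on the bridging samples measured in the V2
    format; equivalence is judged by the Spearman rank correlation between
    V1 scores (V1 model on V1 measurements) and V2 scores (retrained model
    on V2 measurements) over the shared samples, flagged when below
    ``correlation_floor``.
    """
    shared = [s for s in matrix_v1.sample_ids if s in set(matrix_v2.sample_ids)]
    if not shared:
        raise ValueError("no shared bridging samples between versions")
    seed = model_v1.seed if retrain_seed is None else retrain_seed
    model_v2 = train_panel_model(
        matrix_v2,
        ann,
        panel=model_v1.panel,
        n_trees=model_v1.config.get("n_trees", DEFAULT_N_TREES),
        threshold_rule="youden",
        seed=seed,
    )
    model_v2.assay_version = "V2"
    s1 = predict(model_v1, matrix_v1.subset(samples=shared))["score"]
    s2 = predict(model_v2, matrix_v2.subset(samples=shared))["score"]
    rho = spearman(s1, s2)
    report = {
        "n_shared": len(shared),
        "spearman": rho,
        "floor": correlation_floor,
        "flagged": bool(rho < correlation_floor),
    }
    return model_v2, report
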