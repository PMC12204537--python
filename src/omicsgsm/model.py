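"""M component: the final classifier and its seven-metric panel.

The model is a random forest fit on the union of the filtered features
of the top-ranked pro-groups and evaluated on the iteration's outer
holdout.  The panel reports accuracy, specificity, sensitivity, AUC,
precision, recall and F-measure together with the confusion counts; by
construction recall equals sensitivity and the F-measure is the harmonic
mean of precision and recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from ._features import stack_features
from .io import OmicsMatrix, SampleLabels
from .prog import ProGroup

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "specificity", "sensitivity", "auc",
                "precision", "recall", "f_measure")


@dataclass
class PerformanceReport:
    accuracy: float
    specificity: float
    sensitivity: float
    auc: float | None
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FinalModel:
    """A fitted forest plus the feature list it expects."""

    forest: RandomForestClassifier
    features: tuple[str, ...]
    classes: tuple[str, str]


def train_final_model(
    top_pro_groups: list[ProGroup],
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
    n_trees: int = 100,
    seed: int = 0,
) -> FinalModel:
    """Fit a forest on the deduplicated union of top pro-group features."""
    union: set[str] = set()
    for pg in top_pro_groups:
        union.update(pg.filtered_features or pg.feature_set)
    if not union:
        raise ValueError("empty feature union across top pro-groups")
    features = tuple(sorted(union))
    X = stack_features(features, matrices, labels.sample_ids)
    y = labels.labels.to_numpy()
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2**31))
    forest.fit(X, y)
    return FinalModel(forest, features, tuple(sorted(labels.classes)))


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Confusion-count metric panel (AUC excluded).

    Undefined ratios (zero denominators) are reported as 0.0.
    """
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": (tp + tn) / total if total else 0.0,
        "specificity": spec,
        "sensitivity": sens,
        "precision": prec,
        "recall": sens,
        "f_measure": f,
    }


def evaluate_model(
    model: FinalModel,
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
    positive_class: str | None = None,
) -> PerformanceReport:
    """Evaluate on held-out samples.

    The positive class defaults to the lexicographically first label.
    AUC is the area under the ROC curve of the positive-class
    probability (trapezoidal); with a single-class test set it is
    reported as None with a warning.
    """
    pos = positive_class or model.classes[0]
    X = stack_features(model.features, matrices, labels.sample_ids)
    y = labels.labels.to_numpy()
    pred = model.forest.predict(X)
    pos_col = list(model.forest.classes_).index(pos)
    prob = model.forest.predict_proba(X)[:, pos_col]

    tp = int(((pred == pos) & (y == pos)).sum())
    fp = int(((pred == pos) & (y != pos)).sum())
    tn = int(((pred != pos) & (y != pos)).sum())
    fn = int(((pred != pos) & (y == pos)).sum())
    panel = metrics_from_counts(tp, fp, tn, fn)
    if len(np.unique(y)) < 2:
        logger.warning("single-class test set: AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(y == pos, prob))
    return PerformanceReport(auc=auc, tp=tp, fp=fp, tn=tn, fn=fn,
                             positive_class=pos, **panel)


def evaluate_iterations(
    iteration_results,
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
    n_trees: int = 100,
    n_top: int = 10,
    positive_class: str | None = None,
) -> dict:
    """Train and evaluate the final model of every outer iteration.

    Returns ``{"per_iteration": [...], "mean": {...}, "sd": {...}}``
    with per-metric means and standard deviations across iterations
    (AUC-less iterations are skipped in the AUC aggregate).
    """
    reports = []
    for it in iteration_results:
        if not it.records:
            continue
        top_names = [r.name for r in sorted(it.records, key=lambda r: r.rank)[:n_top]]
        top = [it.pro_groups[n] for n in top_names]
        seed = it.iteration
        model = train_final_model(top, matrices, labels.restrict(it.train_ids),
                                  n_trees=n_trees, seed=seed)
        rep = evaluate_model(model, matrices, labels.restrict(it.test_ids),
                             positive_class=positive_class)
        reports.append({"iteration": it.iteration, **rep.to_dict()})
    if not reports:
        raise ValueError("no iteration produced a model")
    mean, sd = {}, {}
    for name in METRIC_NAMES:
        vals = [r[name] for r in reports if r[name] is not None]
        mean[name] = float(np.mean(vals)) if vals else None
        sd[name] = float(np.std(vals, ddof=0)) if vals else None
    return {"per_iteration": reports, "mean": mean, "sd": sd}
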