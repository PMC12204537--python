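"""S component: score each size-normalized pro-group.

A pro-group's score is the mean accuracy of a random-forest classifier
over repeated stratified shuffle splits (internal Monte-Carlo
cross-validation, 90/10 by default) of the outer training set restricted
to the pro-group's filtered features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from ._features import stack_features
from .io import OmicsMatrix, SampleLabels
from .prog import ProGroup


@dataclass
class ProGroupRecord:
    """Score and within-iteration rank of one pro-group."""

    name: str
    iteration: int
    score: float
    rank: int = 0
    filtered_features: tuple[str, ...] = ()


def score_pro_group(
    pro_group: ProGroup,
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
    n_splits: int = 10,
    test_fraction: float = 0.1,
    n_trees: int = 100,
    seed: int = 0,
) -> float:
    """Mean internal-CV accuracy of a forest on the pro-group's features.

    Splits are stratified (so a balanced null stays at 0.5) and fully
    seeded: the split stream uses ``seed`` and the forest for split ``j``
    uses ``seed + j``, making every score bit-reproducible.
    """
    features = pro_group.filtered_features or tuple(sorted(pro_group.feature_set))
    if not features:
        raise ValueError(f"pro-group {pro_group.name!r} has no features to score")
    if len(labels.sample_ids) < 10:
        raise ValueError("fewer than 10 training samples; cannot run internal CV")
    X = stack_features(features, matrices, labels.sample_ids)
    y = labels.labels.to_numpy()
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed % (2**31)
    )
    total = 0.0
    for j, (tr, te) in enumerate(splitter.split(X, y)):
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=(seed + j) % (2**31))
        forest.fit(X[tr], y[tr])
        total += float((forest.predict(X[te]) == y[te]).mean())
    return total / n_splits


def rank_pro_groups(records: list[ProGroupRecord]) -> list[ProGroupRecord]:
    """Assign ranks 1..G by descending score, ties broken by name."""
    if not records:
        raise ValueError("no records to rank")
    ordered = sorted(records, key=lambda r: (-r.score, r.name))
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]
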