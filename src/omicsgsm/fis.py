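"""Feature importance scoring (FIS): size-normalize pro-groups.

Every feature of a pro-group is scored by its mean decrease in Gini
impurity over a random-forest ensemble fit on the pro-group's own
features; the top k survive.  Raw (unnormalized) impurity decreases are
used for selection — selection is scale-invariant either way, and the
raw values keep a constant feature at exactly 0.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._features import stack_features
from .io import OmicsMatrix, SampleLabels
from .prog import ProGroup

FeatureImportance = dict[str, float]


def compute_fis(
    pro_group: ProGroup,
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
    n_trees: int = 100,
    seed: int = 0,
) -> FeatureImportance:
    """Mean decrease in Gini impurity per feature of ``pro_group``.

    The forest is fit on the pro-group's feature rows stacked across the
    three layers against the class labels of the (training) samples in
    ``labels``.  Importances are per-tree impurity decreases summed
    within each tree and averaged over trees; always >= 0.
    """
    features = sorted(pro_group.feature_set)
    X = stack_features(features, matrices, labels.sample_ids)
    y = labels.labels.to_numpy()
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    raw = np.zeros(len(features))
    for tree in forest.estimators_:
        raw += tree.tree_.compute_feature_importances(normalize=False)
    raw /= len(forest.estimators_)
    return {fid: float(v) for fid, v in zip(features, raw)}


def filter_top_k(pro_group: ProGroup, fis: FeatureImportance, k: int) -> ProGroup:
    """Populate ``filtered_features`` with the k highest-FIS features.

    If the pro-group has at most k features all are retained.  Ties at
    the k-th score are broken by lexicographically smaller feature id so
    the result is deterministic and independent of input ordering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = pro_group.feature_set - set(fis)
    if missing:
        raise KeyError(f"FIS missing for features: {sorted(missing)[:5]}")
    ranked = sorted(pro_group.feature_set, key=lambda fid: (-fis[fid], fid))
    return ProGroup(
        name=pro_group.name,
        member_pairs=pro_group.member_pairs,
        gene_list=pro_group.gene_list,
        feature_set=pro_group.feature_set,
        filtered_features=tuple(sorted(ranked[:k])),
    )
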