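"""Internal helper: resolve feature ids across layers into a design matrix."""

from __future__ import annotations

import numpy as np

from .io import OmicsMatrix


def resolve_kind(feature: str, matrices: tuple[OmicsMatrix, ...]) -> str:
    for m in matrices:
        if feature in m.data.index:
            return m.kind
    raise KeyError(f"feature {feature!r} not found in any omics layer")


def stack_features(
    features: list[str] | tuple[str, ...],
    matrices: tuple[OmicsMatrix, ...],
    sample_ids: list[str],
) -> np.ndarray:
    """Samples x features design matrix, rows pulled from whichever layer
    holds each feature.  Feature order follows ``features``."""
    index = {}
    for m in matrices:
        for fid in m.data.index:
            index.setdefault(fid, m)
    rows = []
    for fid in features:
        layer = index.get(fid)
        if layer is None:
            kinds = ", ".join(m.kind for m in matrices)
            raise KeyError(f"feature {fid!r} not present in any layer ({kinds})")
        rows.append(layer.data.loc[fid, sample_ids].to_numpy(dtype=float))
    return np.asarray(rows).T
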