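"""Pro-grouping: correlation-driven miRNA/CpG-to-gene association and
merging of pair-groups with shared gene lists.

A miRNA (or CpG site) is associated with every gene whose expression
profile correlates with it at |r| >= threshold across the training
samples.  Each (miRNA, CpG) pair whose associated gene sets intersect
forms a *pair-group* carrying the intersection; pair-groups with
identical gene lists are merged into a *pro-group* whose name is the
comma-joined sorted list of its ``<mirna>_<cpg>`` pair names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import OmicsMatrix

logger = logging.getLogger(__name__)

# source feature id -> {gene id -> correlation}
AssociationMap = dict[str, dict[str, float]]


@dataclass(frozen=True)
class PairGroup:
    """One (miRNA, CpG) pair and the genes both are associated with."""

    mirna_id: str
    cpg_id: str
    gene_list: tuple[str, ...]  # sorted

    @property
    def name(self) -> str:
        return f"{self.mirna_id}_{self.cpg_id}"


@dataclass
class ProGroup:
    """A merged set of pair-groups sharing a gene list.

    ``feature_set`` spans all three layers: the common genes plus the
    member miRNAs and CpGs.  ``filtered_features`` is populated by the
    feature-importance filter and is empty until then.
    """

    name: str
    member_pairs: tuple[PairGroup, ...]
    gene_list: tuple[str, ...]
    feature_set: frozenset[str]
    filtered_features: tuple[str, ...] = field(default_factory=tuple)

    @property
    def size(self) -> int:
        return len(self.feature_set)


def _correlation_matrix(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """All-pairs correlation between rows of ``a`` and rows of ``b``.

    Zero-variance rows yield NaN correlations (handled by the caller).
    """
    if method == "spearman":
        a = stats.rankdata(a, axis=1)
        b = stats.rankdata(b, axis=1)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a * a).sum(axis=1))
    sb = np.sqrt((b * b).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a @ b.T) / np.outer(sa, sb)
    return r


def associate_to_genes(
    source: OmicsMatrix,
    mrna: OmicsMatrix,
    sample_ids: list[str],
    method: str = "spearman",
    threshold: float = 0.5,
    require_negative: bool = False,
) -> AssociationMap:
    """Associate each source feature (miRNA or CpG) with correlated genes.

    Correlations are computed over ``sample_ids`` only (the training
    samples of the current iteration, so test data never influences the
    grouping).  Constant features are skipped with a log message rather
    than propagating NaNs.  With ``require_negative`` only negative
    correlations at |r| >= threshold are kept (miRNA repression).
    """
    if len(sample_ids) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    src = source.restrict_samples(sample_ids)
    genes = mrna.restrict_samples(sample_ids)
    r = _correlation_matrix(src.data.to_numpy(), genes.data.to_numpy(), method)
    n_constant = int(np.isnan(r).all(axis=1).sum())
    if n_constant:
        logger.info("skipping %d constant %s features", n_constant, source.kind)
    keep = np.abs(r) >= threshold
    if require_negative:
        keep &= r < 0
    keep &= np.isfinite(r)
    out: AssociationMap = {}
    gene_ids = genes.feature_ids
    for i, fid in enumerate(src.feature_ids):
        cols = np.flatnonzero(keep[i])
        if cols.size:
            out[fid] = {gene_ids[j]: float(r[i, j]) for j in cols}
    return out


def build_pair_groups(
    mirna_assoc: AssociationMap, cpg_assoc: AssociationMap
) -> list[PairGroup]:
    """One pair-group per (miRNA, CpG) pair with common associated genes."""
    groups: list[PairGroup] = []
    for mirna_id in sorted(mirna_assoc):
        m_genes = set(mirna_assoc[mirna_id])
        for cpg_id in sorted(cpg_assoc):
            shared = m_genes & set(cpg_assoc[cpg_id])
            if shared:
                groups.append(PairGroup(mirna_id, cpg_id, tuple(sorted(shared))))
    return groups


def _make_pro_group(members: list[PairGroup], gene_list: tuple[str, ...]) -> ProGroup:
    members = sorted(members, key=lambda p: p.name)
    features = set(gene_list)
    for p in members:
        features.add(p.mirna_id)
        features.add(p.cpg_id)
    return ProGroup(
        name=", ".join(p.name for p in members),
        member_pairs=tuple(members),
        gene_list=gene_list,
        feature_set=frozenset(features),
    )


def merge_pro_groups(
    groups: list[PairGroup],
    mode: str = "identical",
    jaccard_threshold: float = 0.5,
) -> list[ProGroup]:
    """Merge pair-groups into pro-groups.

    Default mode merges pair-groups whose gene lists are exactly equal
    (an equivalence-class computation, so the result is independent of
    input order).  ``jaccard`` mode instead single-links pair-groups
    whose gene lists overlap at Jaccard >= threshold; the pro-group gene
    list is then the union over members.  Output sorted by name.
    """
    if mode == "identical":
        by_genes: dict[tuple[str, ...], list[PairGroup]] = {}
        for g in groups:
            by_genes.setdefault(g.gene_list, []).append(g)
        merged = [_make_pro_group(members, genes) for genes, members in by_genes.items()]
    elif mode == "jaccard":
        merged = _merge_jaccard(groups, jaccard_threshold)
    else:
        raise ValueError(f"unknown merge mode {mode!r}")
    return sorted(merged, key=lambda p: p.name)


def _merge_jaccard(groups: list[PairGroup], threshold: float) -> list[ProGroup]:
    n = len(groups)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [set(g.gene_list) for g in groups]
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if inter and inter / len(sets[i] | sets[j]) >= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out = []
    for idx in clusters.values():
        genes = tuple(sorted(set().union(*(sets[i] for i in idx))))
        out.append(_make_pro_group([groups[i] for i in idx], genes))
    return out
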