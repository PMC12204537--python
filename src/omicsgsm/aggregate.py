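"""Outer loop and cross-iteration aggregation.

Each outer iteration downsamples to 1:1, splits 90/10, builds and merges
pro-groups on the training samples only, size-normalizes them by FIS,
scores and ranks them.  Across iterations every pro-group accumulates a
frequency, an average score, an average rank, per-feature appearance
counts, and a Robust Rank Aggregation (RRA) score; lower RRA scores mark
pro-groups consistently ranked near the top.

The RRA score of an item with sorted normalized ranks
r_(1) <= ... <= r_(m) over m lists is rho = min_k P[Binomial(m, r_(k)) >= k]
with a Bonferroni correction, score = min(1, rho * m).  An item missing
from a list contributes a normalized rank of 1.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fis import compute_fis, filter_top_k
from .io import OmicsMatrix, PipelineConfig, SampleLabels, downsample_balanced, outer_split
from .prog import ProGroup, associate_to_genes, build_pair_groups, merge_pro_groups
from .scoring import ProGroupRecord, rank_pro_groups, score_pro_group

logger = logging.getLogger(__name__)


@dataclass
class IterationResult:
    """Everything one outer iteration produces."""

    iteration: int
    records: list[ProGroupRecord]          # ranked, all pro-groups
    pro_groups: dict[str, ProGroup]        # filtered, keyed by name
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class RankSummary:
    """Cross-iteration summary of one pro-group."""

    name: str
    frequency: int
    average_score: float
    rra_score: float
    average_rank: float
    feature_counts: dict[str, int] = field(default_factory=dict)

    def associated_features(self) -> str:
        """Render feature counts in the ``FEAT(n)`` convention, ordered by
        count descending then id."""
        items = sorted(self.feature_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ", ".join(f"{fid}({n})" for fid, n in items)


def _group_seed(iteration_seed: int, name: str) -> int:
    return (iteration_seed ^ zlib.crc32(name.encode())) % (2**31)


def run_pipeline_iteration(
    config: PipelineConfig,
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
    iteration: int,
) -> IterationResult:
    """Run one outer iteration on harmonized data.

    Associations, grouping, FIS and scoring all see only the iteration's
    training samples; the outer test ids are returned untouched for the
    final model evaluation.
    """
    seed = config.iteration_seed(iteration)
    mrna, mirna, cpg = matrices
    balanced = downsample_balanced(labels, seed)
    train_ids, test_ids = outer_split(balanced, config.outer_test_fraction, seed)

    mirna_assoc = associate_to_genes(
        mirna, mrna, train_ids, config.correlation_method,
        config.correlation_threshold, config.require_negative_mirna,
    )
    cpg_assoc = associate_to_genes(
        cpg, mrna, train_ids, config.correlation_method, config.correlation_threshold,
    )
    pair_groups = build_pair_groups(mirna_assoc, cpg_assoc)
    pro_groups = merge_pro_groups(pair_groups, config.merge_mode, config.jaccard_threshold)
    if not pro_groups:
        logger.warning("iteration %d: no pro-groups formed", iteration)
        return IterationResult(iteration, [], {}, train_ids, test_ids)

    train_labels = labels.restrict(train_ids)
    records: list[ProGroupRecord] = []
    filtered: dict[str, ProGroup] = {}
    for pg in pro_groups:
        gseed = _group_seed(seed, pg.name)
        fis = compute_fis(pg, matrices, train_labels, config.n_trees, gseed)
        pg_f = filter_top_k(pg, fis, config.k_top_features)
        score = score_pro_group(
            pg_f, matrices, train_labels,
            config.n_internal_splits, config.internal_test_fraction,
            config.n_trees, gseed,
        )
        filtered[pg_f.name] = pg_f
        records.append(ProGroupRecord(pg_f.name, iteration, score,
                                      filtered_features=pg_f.filtered_features))
    return IterationResult(iteration, rank_pro_groups(records), filtered, train_ids, test_ids)


def rra_score_from_ranks(normalized_ranks) -> float:
    """RRA score of one item from its normalized ranks across lists.

    ``normalized_ranks`` holds one value in (0, 1] per list (1.0 for
    lists the item is missing from).  Returns min(1, m * min_k beta_k).
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    m = len(r)
    if m == 0:
        raise ValueError("need at least one rank")
    k = np.arange(1, m + 1)
    beta = stats.binom.sf(k - 1, m, r)   # P[Binom(m, r_(k)) >= k]
    return min(1.0, float(beta.min()) * m)


def rra_scores(rank_lists: list[list[str]], universe: list[str] | None = None) -> dict[str, float]:
    """Robust Rank Aggregation score for every item in ``universe``.

    ``rank_lists`` are per-iteration ordered name lists (best first).
    The universe defaults to all names appearing in any list; its size N
    normalizes ranks to (0, 1].  Scores lie in [0, 1]; lower is more
    significant.
    """
    if universe is None:
        universe = sorted({name for lst in rank_lists for name in lst})
    if not universe:
        raise ValueError("empty item universe")
    nonempty = [lst for lst in rank_lists if lst]
    if not nonempty:
        raise ValueError("need at least one nonempty rank list")
    n = len(universe)
    out: dict[str, float] = {}
    for item in universe:
        r = [
            (lst.index(item) + 1) / n if item in lst else 1.0
            for lst in nonempty
        ]
        out[item] = rra_score_from_ranks(r)
    return out


def aggregate_iterations(
    iterations: list[IterationResult],
    truncation_depth: int = 10,
    n_top: int = 10,
) -> list[RankSummary]:
    """Summarize pro-groups across iterations (top-list convention).

    Each iteration's ranked list is truncated to its top
    ``truncation_depth`` pro-groups; frequency, averages and the RRA
    universe are computed over those truncated lists.  Returns the top
    ``n_top`` summaries sorted by RRA score ascending (ties by average
    rank, then name).
    """
    if not any(it.records for it in iterations):
        raise ValueError("no iteration produced any pro-group records")
    rank_lists: list[list[str]] = []
    per_group: dict[str, list[ProGroupRecord]] = {}
    for it in iterations:
        top = sorted(it.records, key=lambda r: r.rank)[:truncation_depth]
        rank_lists.append([r.name for r in top])
        for r in top:
            per_group.setdefault(r.name, []).append(r)
    rra = rra_scores(rank_lists)
    summaries = []
    for name, recs in per_group.items():
        counts: dict[str, int] = {}
        for r in recs:
            for fid in r.filtered_features:
                counts[fid] = counts.get(fid, 0) + 1
        summaries.append(RankSummary(
            name=name,
            frequency=len(recs),
            average_score=float(np.mean([r.score for r in recs])),
            rra_score=rra[name],
            average_rank=float(np.mean([r.rank for r in recs])),
            feature_counts=counts,
        ))
    summaries.sort(key=lambda s: (s.rra_score, s.average_rank, s.name))
    return summaries[:n_top]


def summaries_to_table(summaries: list[RankSummary]):
    """Summary rows as a DataFrame with the report's column schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "Pro-group": s.name,
                "Frequency": s.frequency,
                "Average Score": s.average_score,
                "RRA Score": s.rra_score,
                "Avg Rank": s.average_rank,
                "Associated Features": s.associated_features(),
            }
            for s in summaries
        ]
    )


def run_pipeline(
    config: PipelineConfig,
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
) -> tuple[list[IterationResult], list[RankSummary]]:
    """Run all outer iterations and aggregate the rankings."""
    from .io import harmonize_samples

    matrices, labels = harmonize_samples(matrices, labels)
    iterations = [
        run_pipeline_iteration(config, matrices, labels, i)
        for i in range(config.n_outer_iterations)
    ]
    summaries = aggregate_iterations(
        iterations, truncation_depth=config.n_top_progroups, n_top=config.n_top_progroups
    )
    return iterations, summaries
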