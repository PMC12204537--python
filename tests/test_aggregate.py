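import math
import random

import numpy as np
import pytest

from omicsgsm import PipelineConfig, aggregate_iterations, rra_scores
from omicsgsm.aggregate import IterationResult, rra_score_from_ranks, run_pipeline_iteration, summaries_to_table
from omicsgsm.scoring import ProGroupRecord
from omicsgsm.synthetic import SyntheticSpec, generate_multiomics


def binom_tail(k: int, m: int, p: float) -> float:
    """P[Binomial(m, p) >= k] by explicit summation."""
    return sum(math.comb(m, i) * p**i * (1 - p) ** (m - i) for i in range(k, m + 1))


def rra_oracle(rank_lists, universe):
    """Independent brute-force RRA: explicit binomial tails, no scipy."""
    n = len(universe)
    m = len(rank_lists)
    out = {}
    for item in universe:
        r = sorted((lst.index(item) + 1) / n if item in lst else 1.0
                   for lst in rank_lists)
        rho = min(binom_tail(k + 1, m, r[k]) for k in range(m))
        out[item] = min(1.0, rho * m)
    return out


class TestRraScores:
    def test_worked_example(self):
        """Normalized ranks (0.1, 0.5, 0.9) over 3 lists -> rho 0.271 -> 0.813."""
        assert rra_score_from_ranks([0.1, 0.5, 0.9]) == pytest.approx(0.813, abs=1e-12)

    def test_always_last_scores_one(self):
        lists = [["a", "b"], ["a", "b"], ["a", "b"]]
        assert rra_scores(lists)["b"] == 1.0

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = random.Random(0)
        for _ in range(50):
            n = rng.randint(2, 20)
            m = rng.randint(1, 6)
            universe = [f"i{j}" for j in range(n)]
            lists = []
            for _ in range(m):
                lst = universe[:]
                rng.shuffle(lst)
                lists.append(lst[: rng.randint(1, n)])
            got = rra_scores(lists, universe)
            want = rra_oracle(lists, universe)
            for item in universe:
                assert got[item] == pytest.approx(want[item], abs=1e-12)

    def test_improving_ranks_never_hurts(self):
        """Monotonicity: moving an item up in one list cannot raise its score."""
        rng = random.Random(1)
        universe = [f"i{j}" for j in range(8)]
        for _ in range(25):
            lists = []
            for _ in range(4):
                lst = universe[:]
                rng.shuffle(lst)
                lists.append(lst)
            item = rng.choice(universe)
            base = rra_scores(lists, universe)[item]
            k = rng.randrange(len(lists))
            pos = lists[k].index(item)
            if pos > 0:
                lists[k].insert(0, lists[k].pop(pos))
            improved = rra_scores(lists, universe)[item]
            assert improved <= base + 1e-12

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            rra_scores([[]])


def record(name, iteration, score, rank, feats=()):
    return ProGroupRecord(name, iteration, score, rank, tuple(feats))


def iteration(i, records):
    return IterationResult(i, records, {}, [], [])


class TestAggregateIterations:
    def test_frequency_and_average_score(self):
        its = [iteration(i, [record("pgA", i, 0.93, 1, ["MLPH"])]) for i in range(4)]
        (s,) = aggregate_iterations(its)
        assert s.frequency == 4
        assert s.average_score == pytest.approx(0.93)

    def test_average_rank_is_mean_of_ranks(self):
        ranks = [1, 2, 2, 2]
        its = [
            iteration(i, [record("pgA", i, 0.9, r),
                          record("pgB", i, 0.95, 3 - r)])
            for i, r in enumerate(ranks)
        ]
        summaries = {s.name: s for s in aggregate_iterations(its)}
        assert summaries["pgA"].average_rank == pytest.approx(1.75)

    def test_feature_count_rendering(self):
        its = [iteration(i, [record("pgA", i, 0.9, 1,
                                    ["FEAT"] if i < 8 else ["OTHER"])])
               for i in range(9)]
        (s,) = aggregate_iterations(its)
        assert "FEAT(8)" in s.associated_features()
        assert s.feature_counts["FEAT"] <= s.frequency

    def test_truncation_limits_frequency(self):
        # pgC always ranked below the truncation depth -> never counted
        its = [iteration(i, [record("pgA", i, 0.9, 1), record("pgB", i, 0.8, 2),
                             record("pgC", i, 0.7, 3)]) for i in range(3)]
        names = {s.name for s in aggregate_iterations(its, truncation_depth=2)}
        assert names == {"pgA", "pgB"}

    def test_invariant_to_iteration_order(self):
        its = [iteration(i, [record("pgA", i, 0.8 + i / 100, 1)]) for i in range(5)]
        fwd = aggregate_iterations(its)
        rev = aggregate_iterations(its[::-1])
        assert fwd == rev

    def test_sorted_by_rra_ascending(self):
        its = [iteration(i, [record("good", i, 0.95, 1), record("bad", i, 0.6, 2)])
               for i in range(5)]
        out = aggregate_iterations(its)
        assert [s.name for s in out] == ["good", "bad"]
        assert out[0].rra_score <= out[1].rra_score

    def test_all_empty_iterations_rejected(self):
        with pytest.raises(ValueError):
            aggregate_iterations([iteration(0, [])])

    def test_table_schema(self):
        its = [iteration(0, [record("pgA", 0, 0.9, 1, ["g1"])])]
        df = summaries_to_table(aggregate_iterations(its))
        assert list(df.columns) == ["Pro-group", "Frequency", "Average Score",
                                    "RRA Score", "Avg Rank", "Associated Features"]


class TestRunPipelineIteration:
    def test_no_associations_yields_empty_iteration(self, caplog):
        spec = SyntheticSpec(n_samples_per_class=15, n_genes=20, n_mirnas=4,
                             n_cpgs=4, planted_modules=[], seed=2)
        mats, labels, _ = generate_multiomics(spec)
        cfg = PipelineConfig(correlation_threshold=0.99, n_trees=10)
        with caplog.at_level("WARNING"):
            res = run_pipeline_iteration(cfg, mats, labels, 0)
        assert res.records == []
        assert "no pro-groups" in caplog.text

    def test_same_seed_same_records(self, small_dataset):
        mats, labels, _ = small_dataset
        cfg = PipelineConfig(master_seed=4, n_trees=30)
        r1 = run_pipeline_iteration(cfg, mats, labels, 0)
        r2 = run_pipeline_iteration(cfg, mats, labels, 0)
        assert r1.records == r2.records
        assert r1.train_ids == r2.train_ids

    def test_planted_module_ranks_first(self, small_dataset):
        mats, labels, truth = small_dataset
        cfg = PipelineConfig(master_seed=1, n_trees=30)
        res = run_pipeline_iteration(cfg, mats, labels, 0)
        assert res.records
        top = min(res.records, key=lambda r: r.rank)
        assert top.name == truth["modules"][0]["expected_pro_group"]
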