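"""Two-stage marker selection, pruning and the baseline selectors."""

import math
from itertools import combinations

import numpy as np
import pytest

from dtpics import (
    InsufficientLociError,
    MarkerSet,
    NoInformativeLocusError,
    Partition,
    SelectionConfig,
    apply_split,
    distinguishes,
    dtpics_select,
    hps_select,
    min_markers_lower_bound,
    rs_select,
    select_split_locus,
    stage1_screen,
    stage2_prune,
)
from dtpics.genotype import MISSING
from dtpics.polymorphism import picsum_scores

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the library's own set logic)
# ---------------------------------------------------------------------------


def brute_distinguishing_subsets(matrix, pool):
    """All subsets of ``pool`` whose restricted rows are pairwise distinct."""
    rows = [tuple(r) for r in matrix.calls]
    n_distinct = len(set(rows))
    cols = {l: matrix.locus_col(l) for l in pool}
    good = []
    for k in range(len(pool) + 1):
        for subset in combinations(pool, k):
            restricted = {tuple(row[cols[l]] for l in subset) for row in rows}
            if len(restricted) == n_distinct:
                good.append(frozenset(subset))
    return good


def brute_min_size(matrix):
    """Size of the smallest distinguishing subset (exhaustive search)."""
    rows = [tuple(r) for r in matrix.calls]
    n_distinct = len(set(rows))
    m = matrix.n_loci
    for k in range(m + 1):
        for subset in combinations(range(m), k):
            if len({tuple(row[j] for j in subset) for row in rows}) == n_distinct:
                return k
    raise AssertionError("unreachable: full set always distinguishes")


# ---------------------------------------------------------------------------
# select_split_locus
# ---------------------------------------------------------------------------


class TestSelectSplitLocus:
    def test_within_top_fraction_against_full_sort(self, small_panel):
        sub = small_panel.subset_loci(small_panel.locus_ids[:20])
        part = Partition.single(sub.n_samples)
        scores = picsum_scores(sub, part)
        order = np.sort(scores)[::-1]
        cut_score = order[math.ceil(0.1 * 20) - 1]
        for seed in range(10):
            lid = select_split_locus(sub, part, set(), np.random.default_rng(seed), 0.1)
            assert scores[sub.locus_col(lid)] >= cut_score

    def test_deterministic_under_seed(self, small_panel):
        part = Partition.single(small_panel.n_samples)
        a = select_split_locus(small_panel, part, set(), np.random.default_rng(5), 0.1)
        b = select_split_locus(small_panel, part, set(), np.random.default_rng(5), 0.1)
        assert a == b

    def test_all_equal_scores_returns_some_candidate(self, make_binary_matrix):
        m = make_binary_matrix(
            ["a", "b"], [("x", (0, 1)), ("y", (1, 0)), ("z", (0, 1))]
        )
        part = Partition.single(2)
        lid = select_split_locus(m, part, set(), np.random.default_rng(0), 0.1)
        assert lid in {"x", "y", "z"}

    def test_zero_scores_signal_termination(self, make_binary_matrix):
        m = make_binary_matrix(["a", "b"], [("x", (0, 0))])
        with pytest.raises(NoInformativeLocusError):
            select_split_locus(m, Partition.single(2), set(), np.random.default_rng(0), 0.1)

    def test_excluded_loci_are_never_selected(self, toy8x7):
        part = Partition.single(8)
        excluded = {"SNP1", "SNP2", "SNP3", "SNP4"}
        for seed in range(5):
            lid = select_split_locus(toy8x7, part, excluded, np.random.default_rng(seed), 1.0)
            assert lid not in excluded


# ---------------------------------------------------------------------------
# apply_split
# ---------------------------------------------------------------------------


class TestApplySplit:
    def test_first_split_of_toy_panel(self, toy8x7):
        part = apply_split(Partition.single(8), toy8x7, "SNP1")
        groups = sorted(sorted(g.tolist()) for g in part.groups)
        assert groups == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_monomorphic_locus_is_a_no_op(self, make_binary_matrix):
        m = make_binary_matrix(["a", "b", "c"], [("x", (0, 0, 0)), ("y", (0, 1, 1))])
        part = Partition.single(3)
        assert apply_split(part, m, "x").n_leaves == 1

    def test_cover_is_conserved(self, small_panel):
        part = Partition.single(small_panel.n_samples)
        for lid in small_panel.locus_ids[:6]:
            part = apply_split(part, small_panel, lid)
            joined = np.sort(np.concatenate(part.groups))
            assert np.array_equal(joined, np.arange(small_panel.n_samples))

    def test_missing_calls_form_their_own_child(self, make_binary_matrix):
        m = make_binary_matrix(["a", "b", "c", "d"], [("x", (0, 0, 1, 1))])
        m.calls[3, 0] = MISSING
        part = apply_split(Partition.single(4), m, "x")
        groups = sorted(sorted(g.tolist()) for g in part.groups)
        assert groups == [[0, 1], [2], [3]]


# ---------------------------------------------------------------------------
# stage 1 + stage 2
# ---------------------------------------------------------------------------


class TestStages:
    def test_toy_panel_fully_split_and_pruned(self, toy8x7):
        """The 8-variety toy splits to singletons and prunes to 3 markers."""
        config = SelectionConfig(top_fraction=0.10, seed=0)
        oracle_sets = brute_distinguishing_subsets(toy8x7, toy8x7.locus_ids)
        minimal = min(len(s) for s in oracle_sets)
        assert minimal == 3
        for seed in range(8):
            rng = np.random.default_rng(seed)
            screened, part, unsplittable = stage1_screen(toy8x7, set(), rng, config)
            assert part.is_fully_split()
            assert unsplittable == []
            assert len(set(screened.locus_ids)) == len(screened.locus_ids)
            pruned = stage2_prune(toy8x7, screened, rng)
            assert frozenset(pruned.locus_ids) in oracle_sets
            # irreducible: removing any single marker breaks distinguishability
            for lid in pruned.locus_ids:
                rest = [l for l in pruned.locus_ids if l != lid]
                assert frozenset(rest) not in oracle_sets

    def test_redundant_snp_is_pruned_from_screened_set(self, toy8x7):
        """Pruning {SNP1..SNP4} always drops exactly one redundant marker."""
        oracle_sets = brute_distinguishing_subsets(
            toy8x7, ["SNP1", "SNP2", "SNP3", "SNP4"]
        )
        screened = MarkerSet(["SNP1", "SNP2", "SNP3", "SNP4"])
        for seed in range(12):
            pruned = stage2_prune(toy8x7, screened, np.random.default_rng(seed))
            assert len(pruned) == 3
            assert frozenset(pruned.locus_ids) in oracle_sets

    def test_already_irreducible_set_unchanged(self, toy8x7):
        screened = MarkerSet(["SNP1", "SNP3", "SNP4"])
        pruned = stage2_prune(toy8x7, screened, np.random.default_rng(1))
        assert pruned.locus_ids == ["SNP1", "SNP3", "SNP4"]

    def test_identical_varieties_are_reported_unsplittable(self, make_binary_matrix):
        m = make_binary_matrix(
            ["a", "b", "dup1", "dup2"],
            [("x", (0, 1, 1, 1)), ("y", (1, 1, 0, 0)), ("z", (0, 0, 1, 1))],
        )
        screened, part, unsplittable = stage1_screen(
            m, set(), np.random.default_rng(0), SelectionConfig()
        )
        assert unsplittable == [["dup1", "dup2"]]

    def test_screened_size_lower_bound(self, small_panel):
        config = SelectionConfig(seed=3)
        screened, part, _ = stage1_screen(small_panel, set(), np.random.default_rng(3), config)
        assert part.is_fully_split()
        assert len(screened) >= min_markers_lower_bound(small_panel.n_samples, 2)

    def test_empty_matrix_rejected(self, small_panel):
        empty = small_panel.subset_loci([])
        with pytest.raises(ValueError):
            stage1_screen(empty, set(), np.random.default_rng(0), SelectionConfig())


# ---------------------------------------------------------------------------
# distinguishes
# ---------------------------------------------------------------------------


class TestDistinguishes:
    def test_all_loci_distinguish_distinct_panel(self, small_panel):
        ok, collisions = distinguishes(small_panel, small_panel.locus_ids)
        assert ok and collisions == []

    def test_empty_locus_list_collides_everything(self, small_panel):
        ok, collisions = distinguishes(small_panel, [])
        assert not ok
        assert len(collisions) == 1
        assert sorted(collisions[0]) == sorted(small_panel.samples)

    def test_known_colliding_pair_listed(self, make_binary_matrix):
        m = make_binary_matrix(
            ["a", "b", "c", "d"],
            [("x", (0, 0, 1, 1)), ("y", (0, 1, 0, 1)), ("z", (0, 1, 1, 0))],
        )
        ok, collisions = distinguishes(m, ["x", "y"])
        assert ok  # x,y alone separate all four
        ok, collisions = distinguishes(m, ["x"])
        assert not ok
        assert sorted(sorted(g) for g in collisions) == [["a", "b"], ["c", "d"]]

    def test_full_duplicates_are_not_collisions(self, make_binary_matrix):
        m = make_binary_matrix(["a", "dup1", "dup2"], [("x", (0, 1, 1))])
        ok, collisions = distinguishes(m, ["x"])
        assert ok and collisions == []


# ---------------------------------------------------------------------------
# dtpics_select and baselines
# ---------------------------------------------------------------------------


class TestDtpicsSelect:
    def test_deterministic_under_config_seed(self, small_panel):
        config = SelectionConfig(n_sets=2, seed=9)
        a = dtpics_select(small_panel, config)
        b = dtpics_select(small_panel, config)
        assert [s.locus_ids for s in a] == [s.locus_ids for s in b]

    def test_disjoint_sets_share_no_locus(self, small_panel):
        sets = dtpics_select(small_panel, SelectionConfig(n_sets=3, seed=1))
        for s, t in combinations(sets, 2):
            assert set(s.locus_ids).isdisjoint(t.locus_ids)
        for s in sets:
            ok, _ = distinguishes(small_panel, s.locus_ids)
            assert ok

    def test_insufficient_loci_reports_completed_sets(self, make_binary_matrix):
        # 'a' and 'b' differ only at locus u: a second disjoint set is
        # impossible once u is consumed by the first one
        m = make_binary_matrix(
            ["a", "b", "c"],
            [("u", (0, 1, 1)), ("v", (0, 0, 1)), ("w", (1, 1, 0))],
        )
        with pytest.raises(InsufficientLociError) as err:
            dtpics_select(m, SelectionConfig(n_sets=2, seed=0))
        assert len(err.value.completed) == 1

    def test_oracle_agreement_on_tiny_instances(self):
        """Greedy output is always valid, irreducible, >= exhaustive minimum."""
        from dtpics import SynthConfig, generate_panel

        rng = np.random.default_rng(2024)
        for trial in range(15):
            n_var = int(rng.integers(4, 11))
            n_loci = int(rng.integers(6, 13))
            panel, _ = generate_panel(
                SynthConfig(n_varieties=n_var, n_loci=n_loci, seed=int(rng.integers(2**31)))
            )
            sets = dtpics_select(panel, SelectionConfig(seed=trial))
            s = sets[0]
            ok, _ = distinguishes(panel, s.locus_ids)
            assert ok
            for lid in s.locus_ids:
                rest = [l for l in s.locus_ids if l != lid]
                assert not distinguishes(panel, rest)[0]
            assert len(s) >= brute_min_size(panel)


class TestBaselines:
    def test_hps_pool_respects_threshold(self, small_panel):
        from dtpics.polymorphism import pic_table

        table = pic_table(small_panel)
        chosen = hps_select(small_panel, 12, threshold=0.45, rng=np.random.default_rng(0))
        for lid in chosen:
            assert table[small_panel.locus_col(lid)] > 0.45

    def test_hps_rejects_oversized_request(self, small_panel):
        with pytest.raises(ValueError, match="exceed"):
            hps_select(small_panel, small_panel.n_loci + 1, rng=np.random.default_rng(0))

    def test_rs_full_draw_and_determinism(self, small_panel):
        full = rs_select(small_panel, small_panel.n_loci, np.random.default_rng(0))
        assert sorted(full.locus_ids) == sorted(small_panel.locus_ids)
        a = rs_select(small_panel, 10, np.random.default_rng(4))
        b = rs_select(small_panel, 10, np.random.default_rng(4))
        assert a.locus_ids == b.locus_ids
        with pytest.raises(ValueError):
            rs_select(small_panel, small_panel.n_loci + 1, np.random.default_rng(0))

    def test_rs_inclusion_frequency_is_uniform(self, toy8x7):
        counts = np.zeros(toy8x7.n_loci)
        draws = 600
        for seed in range(draws):
            s = rs_select(toy8x7, 2, np.random.default_rng(seed))
            for lid in s:
                counts[toy8x7.locus_col(lid)] += 1
        freq = counts / draws
        assert np.allclose(freq, 2 / 7, atol=0.06)


def test_lower_bound_formula():
    assert min_markers_lower_bound(1000, 2) == 10
    assert min_markers_lower_bound(8, 2) == 3
    assert min_markers_lower_bound(9, 2) == 4
    assert min_markers_lower_bound(1, 2) == 0
    assert min_markers_lower_bound(27, 3) == 3
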