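"""Accuracy metrics, genotype modification, and the simulation experiments."""

import numpy as np
import pytest

from dtpics import (
    MarkerSet,
    distinguishing_accuracy,
    identification_accuracy,
    mean_accuracy,
    modify_genotypes,
    run_combination_experiment,
    run_gradient_experiment,
    run_mixture_experiment,
)
from dtpics.identification import IdentificationResult


def _result(query, best, tie=False):
    return IdentificationResult(query, best, 100.0, 10, None, None, tie, False)


class TestDistinguishingAccuracy:
    def test_distinct_panel_scores_100(self, small_panel):
        assert distinguishing_accuracy(small_panel, small_panel.locus_ids) == 100.0

    def test_single_shared_vector_scores_0(self, make_binary_matrix):
        m = make_binary_matrix(["a", "b", "c"], [("x", (0, 0, 0)), ("y", (1, 1, 1))])
        assert distinguishing_accuracy(m, ["x", "y"]) == 0.0

    def test_one_colliding_pair_scores_50(self, make_binary_matrix):
        # restricted to {x, y}: a and b collide while c and d stay unique
        m = make_binary_matrix(
            ["a", "b", "c", "d"],
            [("x", (0, 0, 1, 1)), ("y", (0, 0, 0, 1)), ("z", (0, 1, 0, 0))],
        )
        assert distinguishing_accuracy(m, ["x", "y"]) == 50.0

    def test_reference_mode_matches_self_mode_when_unmodified(self, small_panel):
        loci = small_panel.locus_ids[:15]
        sub = small_panel.subset_loci(loci)
        self_mode = distinguishing_accuracy(small_panel, loci)
        ref_mode = distinguishing_accuracy(sub, loci, reference=sub)
        assert self_mode == ref_mode


class TestIdentificationAccuracy:
    def test_all_and_none_correct(self):
        truth = {"q1": "v1", "q2": "v2"}
        assert identification_accuracy(
            [_result("q1", "v1"), _result("q2", "v2")], truth
        ) == 100.0
        assert identification_accuracy(
            [_result("q1", "v9"), _result("q2", "v9")], truth
        ) == 0.0

    def test_64_of_68_correct(self):
        truth = {f"q{i}": f"v{i}" for i in range(68)}
        results = [
            _result(f"q{i}", f"v{i}" if i < 64 else "other") for i in range(68)
        ]
        assert identification_accuracy(results, truth) == pytest.approx(94.12, abs=0.005)

    def test_ties_count_as_incorrect(self):
        truth = {"q": "v"}
        assert identification_accuracy([_result("q", "v", tie=True)], truth) == 0.0

    def test_missing_truth_entry_raises(self):
        with pytest.raises(KeyError):
            identification_accuracy([_result("q", "v")], {})


class TestModifyGenotypes:
    def test_rate_zero_is_identity(self, small_panel):
        loci = small_panel.locus_ids[:30]
        out = modify_genotypes(small_panel, loci, 0.0, np.random.default_rng(0))
        assert out == small_panel

    def test_exact_modification_count_per_variety(self, small_panel):
        loci = small_panel.locus_ids[:60]
        out = modify_genotypes(small_panel, loci, 0.10, np.random.default_rng(1))
        cols = [small_panel.locus_col(l) for l in loci]
        diffs = (out.calls[:, cols] != small_panel.calls[:, cols]).sum(axis=1)
        assert (diffs == 6).all()
        other = [j for j in range(small_panel.n_loci) if j not in cols]
        assert np.array_equal(out.calls[:, other], small_panel.calls[:, other])

    def test_half_up_rounding(self, small_panel):
        loci = small_panel.locus_ids[:10]
        out = modify_genotypes(small_panel, loci, 0.05, np.random.default_rng(2))
        cols = [small_panel.locus_col(l) for l in loci]
        diffs = (out.calls[:, cols] != small_panel.calls[:, cols]).sum(axis=1)
        assert (diffs == 1).all()  # round(0.5) -> 1, half away from zero

    def test_deterministic_under_seed(self, small_panel):
        loci = small_panel.locus_ids[:20]
        a = modify_genotypes(small_panel, loci, 0.15, np.random.default_rng(3))
        b = modify_genotypes(small_panel, loci, 0.15, np.random.default_rng(3))
        assert a == b

    def test_monomorphic_only_markers_rejected(self, make_binary_matrix):
        m = make_binary_matrix(["a", "b"], [("x", (0, 0)), ("y", (1, 1))])
        with pytest.raises(ValueError, match="modifiable"):
            modify_genotypes(m, ["x", "y"], 0.5, np.random.default_rng(0))


@pytest.fixture(scope="module")
def mixture_df(small_panel):
    from dtpics import SelectionConfig, dtpics_select, hps_select

    sets = dtpics_select(small_panel, SelectionConfig(seed=5))
    pool = hps_select(small_panel, 60, rng=np.random.default_rng(0))
    return run_mixture_experiment(
        small_panel, sets[0], pool.locus_ids,
        rates=(0.05, 0.10, 0.15), repeats=3, rng=np.random.default_rng(6),
    )


class TestMixtureExperiment:
    def test_output_shape(self, mixture_df):
        # 5 mixtures x (raw + 3 rates) x 3 repeats
        assert len(mixture_df) == 5 * 4 * 3
        assert set(mixture_df["label"]) == {
            "all DT", "2/3 DT + 1/3 hPIC", "1/3 DT + 2/3 hPIC", "all hPIC", "all RS"
        }

    def test_all_dt_raw_accuracy_is_100(self, mixture_df):
        raw = mixture_df[(mixture_df["label"] == "all DT")
                         & (mixture_df["modification_rate"] == 0.0)]
        assert (raw["distinguishing_accuracy"] == 100.0).all()

    def test_mean_is_average_over_cells(self, mixture_df):
        means = mean_accuracy(mixture_df)
        for label, group in mixture_df.groupby("label"):
            assert means[label] == pytest.approx(group["distinguishing_accuracy"].mean())

    def test_accuracies_bounded(self, mixture_df):
        acc = mixture_df["distinguishing_accuracy"]
        assert ((acc >= 0) & (acc <= 100)).all()


class TestCombinationExperiment:
    def test_pairwise_combination_count(self, make_binary_matrix):
        m = make_binary_matrix(
            [f"s{i}" for i in range(4)],
            [(f"L{j}", tuple(int(b) for b in np.random.default_rng(j).integers(0, 2, 4)))
             for j in range(13)],
        )
        sets = [MarkerSet([f"L{j}"], set_index=j + 1) for j in range(13)]
        df = run_combination_experiment(
            m, sets, k=2, rates=(), repeats=1, rng=np.random.default_rng(0)
        )
        assert df["label"].nunique() == 78  # C(13, 2)

    def test_k1_reduces_to_per_set_evaluation(self, small_panel, make_binary_matrix):
        from dtpics import SelectionConfig, dtpics_select

        sets = dtpics_select(small_panel, SelectionConfig(n_sets=2, seed=2))
        df = run_combination_experiment(
            small_panel, sets, k=1, rates=(0.1,), repeats=2,
            rng=np.random.default_rng(0),
        )
        assert df["label"].nunique() == 2

    def test_union_never_hurts_on_same_modified_calls(self, small_panel):
        """Paired comparison: a set union is at least as accurate as either part."""
        from dtpics import SelectionConfig, dtpics_select

        sets = dtpics_select(small_panel, SelectionConfig(n_sets=2, seed=8))
        union = sets[0].locus_ids + sets[1].locus_ids
        sub = small_panel.subset_loci(union)
        rng = np.random.default_rng(11)
        union_acc, part_acc = [], []
        for _ in range(20):
            modified = modify_genotypes(sub, union, 0.10, rng)
            union_acc.append(distinguishing_accuracy(modified, union, reference=sub))
            part_acc.append(
                distinguishing_accuracy(modified, sets[0].locus_ids, reference=sub)
            )
        assert np.mean(union_acc) >= np.mean(part_acc)


class TestGradientExperiment:
    def test_full_pool_draw_is_deterministic(self, small_panel):
        pool = small_panel.locus_ids[:12]
        df = run_gradient_experiment(pool, small_panel, sizes=[12], repeats=3,
                                     rng=np.random.default_rng(0))
        assert df["distinguishing_accuracy"].nunique() == 1

    def test_same_seed_same_curve(self, small_panel):
        pool = small_panel.locus_ids[:40]
        a = run_gradient_experiment(pool, small_panel, [5, 10, 20], repeats=3,
                                    rng=np.random.default_rng(9))
        b = run_gradient_experiment(pool, small_panel, [5, 10, 20], repeats=3,
                                    rng=np.random.default_rng(9))
        assert a.equals(b)

    def test_accuracy_trends_upward_with_panel_size(self, small_panel):
        pool = small_panel.locus_ids[:40]
        df = run_gradient_experiment(pool, small_panel, [2, 8, 25], repeats=10,
                                     rng=np.random.default_rng(10))
        means = df.groupby("n_markers")["distinguishing_accuracy"].mean()
        assert means[2.0] <= means[8.0] <= means[25.0]

    def test_oversized_request_rejected(self, small_panel):
        with pytest.raises(ValueError, match="exceeds"):
            run_gradient_experiment(small_panel.locus_ids[:5], small_panel, [6],
                                    rng=np.random.default_rng(0))
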