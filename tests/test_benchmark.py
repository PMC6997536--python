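"""Common-interaction sets, stratified replicates and comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miragg import (
    BenchmarkSet,
    ReplicateSpec,
    attach_labels,
    dunnett_posthoc,
    evaluate_all,
    intersect_common,
    paired_ttest,
    rm_anova,
    run_benchmark,
    subsample_replicates,
)


def scored_frame(pairs, scores):
    mirnas, genes = zip(*pairs)
    return pd.DataFrame({"mirna": mirnas, "gene": genes, "score": scores})


def random_parent(rng, n=2000, prevalence=0.05, methods=("m1", "m2")):
    idx = pd.MultiIndex.from_tuples(
        [("mir", f"g{i}") for i in range(n)], names=["mirna", "gene"]
    )
    labels = np.zeros(n, int)
    labels[rng.choice(n, int(n * prevalence), replace=False)] = 1
    scores = pd.DataFrame({m: rng.random(n) for m in methods}, index=idx)
    return BenchmarkSet(scores=scores, labels=labels)


class TestIntersect:
    def test_keeps_only_shared_keys(self):
        a = scored_frame([("m", "A"), ("m", "B"), ("m", "C")], [1, 2, 3])
        b = scored_frame([("m", "B"), ("m", "C"), ("m", "D")], [9, 8, 7])
        bs = intersect_common({"a": a, "b": b})
        assert list(bs.scores.index.get_level_values("gene")) == ["B", "C"]
        assert bs.methods == ["a", "b"]

    def test_identical_lists_intersect_to_identity(self):
        a = scored_frame([("m", "A"), ("m", "B")], [1, 2])
        bs = intersect_common({"x": a, "y": a.copy()})
        assert len(bs) == 2

    def test_single_shared_key_carries_all_scores(self):
        lists = {
            "a": scored_frame([("m", "A"), ("m", "K")], [1, 5]),
            "b": scored_frame([("m", "B"), ("m", "K")], [2, 6]),
            "c": scored_frame([("m", "C"), ("m", "K")], [3, 7]),
        }
        bs = intersect_common(lists)
        assert len(bs) == 1
        assert bs.scores.iloc[0].tolist() == [5.0, 6.0, 7.0]

    def test_empty_intersection_warns(self):
        a = scored_frame([("m", "A")], [1])
        b = scored_frame([("m", "B")], [2])
        with pytest.warns(UserWarning, match="empty"):
            bs = intersect_common({"a": a, "b": b})
        assert len(bs) == 0

    def test_labels_attach_by_pair_membership(self):
        a = scored_frame([("m", "A"), ("m", "B")], [1, 2])
        bs = intersect_common({"x": a, "y": a.copy()})
        bs = attach_labels(bs, pd.DataFrame({"mirna": ["m"], "gene": ["B"]}))
        assert bs.labels.tolist() == [0, 1]


class TestSubsample:
    def test_prevalence_matched_to_nearest_count(self, rng):
        parent = random_parent(rng, n=4000, prevalence=0.05)
        reps = subsample_replicates(parent, ReplicateSpec(5, 1000, seed=3))
        for rep in reps:
            assert rep.labels.sum() == 50
            assert len(rep) == 1000

    def test_same_seed_reproduces_replicates(self, rng):
        parent = random_parent(rng)
        a = subsample_replicates(parent, ReplicateSpec(3, 500, seed=9))
        b = subsample_replicates(parent, ReplicateSpec(3, 500, seed=9))
        for x, y in zip(a, b):
            assert x.scores.equals(y.scores)
            assert np.array_equal(x.labels, y.labels)

    def test_full_size_subset_equals_parent(self, rng):
        parent = random_parent(rng, n=300)
        reps = subsample_replicates(parent, ReplicateSpec(2, 300, seed=0))
        for rep in reps:
            assert rep.scores.sort_index().equals(parent.scores.sort_index())

    def test_oversized_subset_rejected(self, rng):
        parent = random_parent(rng, n=100)
        with pytest.raises(ValueError, match="exceeds"):
            subsample_replicates(parent, ReplicateSpec(1, 101, seed=0))


class TestEvaluateAll:
    def test_identical_replicates_have_zero_sd(self, rng):
        parent = random_parent(rng, n=400)
        reps = subsample_replicates(parent, ReplicateSpec(3, 400, seed=1))
        table = evaluate_all(reps)
        sd = table.groupby("method")["auc"].std()
        assert np.allclose(sd, 0.0)

    def test_dominant_method_wins_every_replicate(self, rng):
        n = 2000
        idx = pd.MultiIndex.from_tuples(
            [("mir", f"g{i}") for i in range(n)], names=["mirna", "gene"]
        )
        labels = np.zeros(n, int)
        labels[rng.choice(n, 100, replace=False)] = 1
        noise = rng.random(n)
        scores = pd.DataFrame(
            {"good": noise - 2.0 * labels, "bad": rng.random(n)}, index=idx
        )
        parent = BenchmarkSet(scores=scores, labels=labels)
        table = evaluate_all(subsample_replicates(parent, ReplicateSpec(5, 800, seed=2)))
        wide = table.pivot(index="replicate", columns="method", values="auc")
        assert (wide["good"] > wide["bad"]).all()

    def test_perfect_method_scores_unit_auc(self):
        idx = pd.MultiIndex.from_tuples(
            [("m", f"g{i}") for i in range(50)], names=["mirna", "gene"]
        )
        labels = np.r_[np.ones(5, int), np.zeros(45, int)]
        scores = pd.DataFrame({"perfect": np.arange(50, dtype=float)}, index=idx)
        parent = BenchmarkSet(scores=scores, labels=labels)
        table = evaluate_all([parent, parent])
        assert np.allclose(table["auc"], 1.0)


class TestRmAnova:
    def test_no_treatment_effect_gives_f_zero_p_one(self):
        x = np.tile(np.arange(5, dtype=float)[:, None], (1, 3))
        res = rm_anova(x)
        assert res.F == 0.0 and res.p == 1.0

    def test_two_methods_equal_squared_paired_t(self, rng):
        a, b = rng.random(8), rng.random(8)
        res = rm_anova(np.c_[a, b])
        t, p, _ = paired_ttest(a, b)
        assert res.F == pytest.approx(t**2)
        assert res.p == pytest.approx(p)

    def test_matches_manual_sum_of_squares(self):
        # 4 subjects x 3 conditions within-subject table
        x = np.array([[8.0, 7.0, 6.0], [9.0, 9.0, 8.0], [6.0, 5.0, 3.0], [5.0, 6.0, 4.0]])
        n, k = x.shape
        grand = x.mean()
        ss_m = n * ((x.mean(0) - grand) ** 2).sum()
        ss_s = k * ((x.mean(1) - grand) ** 2).sum()
        ss_e = ((x - grand) ** 2).sum() - ss_m - ss_s
        f_manual = (ss_m / (k - 1)) / (ss_e / ((k - 1) * (n - 1)))
        res = rm_anova(x)
        assert res.F == pytest.approx(f_manual)
        assert res.df_method == 2 and res.df_error == 6

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        n, k = 10, 4
        x = rng.random((n, k)) + np.linspace(0, 0.3, k)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "method": np.tile(np.arange(k), n),
                "y": x.ravel(),
            }
        )
        sm_res = AnovaRM(long, "y", "subject", within=["method"]).fit()
        res = rm_anova(x)
        assert res.F == pytest.approx(float(sm_res.anova_table["F Value"].iloc[0]))
        assert res.p == pytest.approx(float(sm_res.anova_table["Pr > F"].iloc[0]))

    def test_invariance_to_shift_and_subject_relabeling(self, rng):
        x = rng.random((6, 3))
        base = rm_anova(x)
        shifted = rm_anova(x + 100.0)
        permuted = rm_anova(x[rng.permutation(6)])
        assert shifted.F == pytest.approx(base.F)
        assert permuted.F == pytest.approx(base.F)

    def test_incomplete_table_rejected(self):
        x = np.random.default_rng(0).random((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError):
            rm_anova(x)


class TestPairedT:
    def test_hand_computed_example(self):
        t, p, flag = paired_ttest([1.0, 2.5], [0.5, 1.0])  # differences 0.5, 1.5
        assert t == pytest.approx(2.0)
        assert not flag
        assert p == pytest.approx(2 * stats.t.sf(2.0, df=1))

    def test_exact_tie_flagged(self):
        t, p, flag = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert flag and t == 0.0 and p == 1.0

    def test_constant_shift_flagged_degenerate(self):
        t, p, flag = paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert flag and p == 0.0 and np.isinf(t)


class TestDunnett:
    def test_single_contrast_equals_paired_t(self, rng):
        table = pd.DataFrame({"ctrl": rng.random(10), "other": rng.random(10)})
        res = dunnett_posthoc(table, control="ctrl")
        t, p, _ = paired_ttest(table["other"], table["ctrl"])
        assert res.loc["other", "p_adjusted"] == pytest.approx(p)
        assert res.loc["other", "t"] == pytest.approx(t)

    def test_identical_columns_not_significant(self):
        col = np.arange(6, dtype=float)
        table = pd.DataFrame({"ctrl": col, "a": col.copy(), "b": col.copy()})
        res = dunnett_posthoc(table, control="ctrl", n_draws=2000, seed=1)
        assert (res["p_adjusted"] == 1.0).all()
        assert not res["significant"].any()

    def test_adjusted_never_below_raw(self, rng):
        table = pd.DataFrame({m: rng.random(12) for m in ["ctrl", "a", "b", "c"]})
        res = dunnett_posthoc(table, control="ctrl", n_draws=20_000, seed=2)
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()

    def test_control_must_exist(self, rng):
        table = pd.DataFrame({m: rng.random(5) for m in ["a", "b"]})
        with pytest.raises(ValueError, match="control"):
            dunnett_posthoc(table, control="zz")

    def test_familywise_error_near_nominal_under_global_null(self):
        # k = 3 methods with independent standard-normal columns
        rng = np.random.default_rng(77)
        n_runs, n_subj = 2000, 20
        false_hits = 0
        for run in range(n_runs):
            table = pd.DataFrame(
                rng.standard_normal((n_subj, 3)), columns=["ctrl", "a", "b"]
            )
            res = dunnett_posthoc(table, control="ctrl", n_draws=2000, seed=run)
            false_hits += int(res["significant"].any())
        fwer = false_hits / n_runs
        assert 0.03 <= fwer <= 0.07


class TestRunBenchmark:
    def test_report_structure_and_determinism(self, rng):
        pairs = [("m", f"g{i}") for i in range(1500)]
        labels_idx = rng.choice(1500, 75, replace=False)
        label_df = pd.DataFrame(
            {"mirna": ["m"] * 75, "gene": [f"g{i}" for i in labels_idx]}
        )
        lab = np.zeros(1500)
        lab[labels_idx] = 1
        scored = {
            "good": scored_frame(pairs, rng.random(1500) - 1.5 * lab),
            "mid": scored_frame(pairs, rng.random(1500) - 0.5 * lab),
            "rand": scored_frame(pairs, rng.random(1500)),
        }
        spec = ReplicateSpec(n_replicates=4, subset_size=600, seed=5)
        r1 = run_benchmark(scored, label_df, spec, control="good")
        r2 = run_benchmark(scored, label_df, spec, control="good")
        assert r1 == r2
        assert set(r1["comparisons"]) == {"mid", "rand"}
        assert r1["anova"]["p"] <= 1.0
        assert r1["summary"]["good"]["auc_mean"] > r1["summary"]["rand"]["auc_mean"]
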