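"""Moderated scoring engine: score identities, s0 selection, permutation
q-values, local FDR, Holm correction and the Wilcoxon supplement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import exomir
from exomir import GroupDesign
from exomir.datasets import load_sam_scores_three_group


def make_design(labels):
    return GroupDesign.from_labels(np.asarray(labels))


THREE_GROUP = make_design(["C"] * 6 + ["BD"] * 6 + ["SZ"] * 8)


class TestGroupZscores:
    def test_constant_mirna_scores_zero(self):
        X = np.vstack([np.full(20, 7.0), np.random.default_rng(0).normal(size=20)])
        z = exomir.group_zscores(X, THREE_GROUP, s0=0.5)
        assert np.allclose(z.iloc[0], 0.0)

    def test_two_group_toy_matches_direct_formula(self):
        # independent spreadsheet-style evaluation of the definition
        g1, g2 = [1.0, 2.0, 3.0], [5.0, 6.0, 7.0]
        X = np.array([g1 + g2])
        design = make_design(["a"] * 3 + ["b"] * 3)
        z = exomir.group_zscores(X, design, s0=0.0)
        grand = np.mean(g1 + g2)
        ssw = sum((v - np.mean(g1)) ** 2 for v in g1) + \
            sum((v - np.mean(g2)) ** 2 for v in g2)
        s = np.sqrt(ssw / (6 - 2) / 6)
        assert z.loc[0, "a"] == pytest.approx((np.mean(g1) - grand) / s)
        assert z.loc[0, "b"] == pytest.approx((np.mean(g2) - grand) / s)

    def test_weighted_sum_identity_exact_on_random_data(self):
        rng = np.random.default_rng(5)
        X = rng.lognormal(size=(50, 20))
        z = exomir.group_zscores(X, THREE_GROUP, s0=0.1).to_numpy()
        weighted = z @ np.array([6.0, 6.0, 8.0])
        assert np.abs(weighted).max() < 1e-6 * 20

    def test_published_mir31_row_satisfies_weighted_identity(self):
        tbl = load_sam_scores_three_group().set_index("mirna")
        row = tbl.loc["hsa-miR-31"]
        assert row["z_SZ"] == pytest.approx(3.55283)
        assert abs(6 * row["z_C"] + 6 * row["z_BD"] + 8 * row["z_SZ"]) < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            make_design(["a", "a", "b"])


class TestComputeS0:
    def test_constant_scales_return_common_value(self):
        # every feature is the same profile: identical pooled scales
        row = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 1.0, 5.0, 3.0] * 2 + [2.0] * 4)
        X = np.tile(row, (12, 1))
        design = make_design(["a"] * 10 + ["b"] * 10)
        s = exomir.pooled_scale(X, design)
        assert np.allclose(s, s[0])
        assert exomir.compute_s0(X, design) == pytest.approx(s[0])

    def test_within_scale_range(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 20)) * rng.lognormal(1, 1, size=(100, 1))
        s = exomir.pooled_scale(X, THREE_GROUP)
        s0 = exomir.compute_s0(X, THREE_GROUP)
        assert s.min() <= s0 <= s.max()

    def test_chosen_s0_lightens_score_tails_on_null_panel(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(500, 20)) * rng.lognormal(0, 1.5, size=(500, 1))
        s0 = exomir.compute_s0(X, THREE_GROUP)
        z_s0 = np.abs(exomir.group_zscores(X, THREE_GROUP, s0).to_numpy())
        z_raw = np.abs(exomir.group_zscores(X, THREE_GROUP, 0.0).to_numpy())
        assert (z_s0 > 3).sum() < (z_raw > 3).sum()

    def test_degenerate_all_zero_scales_rejected(self):
        X = np.ones((5, 20))
        with pytest.raises(ValueError):
            exomir.compute_s0(X, THREE_GROUP)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 20))
        a = exomir.permute_null(X, THREE_GROUP, B=100, seed=4, s0=0.1)
        b = exomir.permute_null(X, THREE_GROUP, B=100, seed=4, s0=0.1)
        assert np.array_equal(a.scores, b.scores)

    def test_shape_contract(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 20))
        null = exomir.permute_null(X, THREE_GROUP, B=100, seed=0, s0=0.1)
        assert null.scores.shape == (100, 10)

    def test_exhaustive_enumeration_for_small_designs(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5, 6))
        design = make_design(["a"] * 3 + ["b"] * 3)
        null = exomir.permute_null(X, design, B=100, seed=0, s0=0.1)
        assert null.exhaustive
        assert null.scores.shape == (20, 5)  # C(6,3) = 20 labelings

    def test_insufficient_permutations_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 20))
        with pytest.raises(ValueError):
            exomir.permute_null(X, THREE_GROUP, B=50, seed=0, s0=0.1)

    def test_null_design_observed_matches_permuted_distribution(self):
        # two-sample KS between observed statistics and one permutation draw
        agree = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(200, 20)) * rng.lognormal(0, 1, size=(200, 1))
            s0 = exomir.compute_s0(X, THREE_GROUP)
            z = exomir.group_zscores(X, THREE_GROUP, s0)
            D = np.abs(z.to_numpy()).max(axis=1)
            null = exomir.permute_null(X, THREE_GROUP, B=100, seed=seed, s0=s0)
            p = stats.ks_2samp(D, null.scores[0]).pvalue
            agree += int(p > 0.01)
        assert agree >= 19


class TestQvalues:
    def test_spiked_feature_beating_every_null_gets_zero(self, fitted_sam):
        est, norm, meta, truth = fitted_sam
        D = est.scores_
        beats_all = D > est.null_.scores.max()
        if beats_all.any():
            assert (est.qvalues_[beats_all] == 0).all()

    def test_monotone_in_rank_and_bounded(self, fitted_sam):
        est, *_ = fitted_sam
        order = np.argsort(-est.scores_)
        q_sorted = est.qvalues_[order]
        assert (np.diff(q_sorted) >= -1e-12).all()
        assert (est.qvalues_ >= 0).all() and (est.qvalues_ <= 100).all()

    def test_pure_null_panel_has_high_median_q(self, run_pipeline):
        norm, meta, _ = run_pipeline(seed=21, n_spiked_per_group={})
        est = exomir.SamMulticlass(n_permutations=1000, random_state=21)
        est.fit(norm.to_numpy().T, meta["group"].to_numpy())
        assert np.median(est.qvalues_) >= 50.0


class TestLocalFdr:
    def test_bounded_for_arbitrary_input(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 20))
        s0 = exomir.compute_s0(X, THREE_GROUP)
        D = np.abs(exomir.group_zscores(X, THREE_GROUP, s0).to_numpy()).max(axis=1)
        null = exomir.permute_null(X, THREE_GROUP, B=200, seed=1, s0=s0)
        lf = exomir.local_fdr(D, null, window=10)
        assert ((lf >= 0) & (lf <= 100)).all()

    def test_null_panel_middling_ranks_near_saturation(self, run_pipeline):
        norm, meta, _ = run_pipeline(seed=22, n_spiked_per_group={})
        est = exomir.SamMulticlass(n_permutations=1000, random_state=22)
        est.fit(norm.to_numpy().T, meta["group"].to_numpy())
        order = np.argsort(-est.scores_)
        m = len(order)
        middling = est.local_fdr_[order][m // 3: 2 * m // 3]
        assert np.median(middling) >= 70.0

    def test_strong_spike_has_low_local_fdr(self, run_pipeline):
        norm, meta, truth = run_pipeline(
            seed=23, n_spiked_per_group={"SZ": 20}, effect_size_log2=3.0,
            noise_sd=0.2)
        X = norm.to_numpy()
        gd = make_design(meta["group"].to_numpy())
        s0 = exomir.compute_s0(X, gd)
        D = np.abs(exomir.group_zscores(X, gd, s0).to_numpy()).max(axis=1)
        null = exomir.permute_null(X, gd, B=1000, seed=23, s0=s0)
        lf = exomir.local_fdr(D, null, window=10)
        assert lf[np.argmax(D)] < 10.0

    def test_window_bounds_enforced(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 20))
        null = exomir.permute_null(X, THREE_GROUP, B=100, seed=0, s0=0.1)
        D = np.ones(30)
        with pytest.raises(ValueError):
            exomir.local_fdr(D, null, window=5)
        with pytest.raises(ValueError):
            exomir.local_fdr(D, null, window=31)


class TestRankTable:
    def test_ties_break_lexicographically_and_rows_conserved(self):
        z = pd.DataFrame({"a": [1.0, 1.0, -2.0], "b": [-1.0, -1.0, 2.0]})
        tbl = exomir.rank_table(["zeta", "alpha", "big"], z,
                               q=[5.0, 5.0, 0.0], lfdr=[10.0, 10.0, 1.0])
        assert len(tbl) == 3
        assert list(tbl["miRNA"]) == ["big", "alpha", "zeta"]

    def test_single_strong_spike_ranks_first(self, run_pipeline):
        norm, meta, truth = run_pipeline(
            seed=24, n_spiked_per_group={"SZ": 1}, effect_size_log2=4.0,
            noise_sd=0.2)
        est = exomir.SamMulticlass(n_permutations=1000, random_state=24)
        est.fit(norm.to_numpy().T, meta["group"].to_numpy())
        tbl = est.results_table(norm.index)
        (spiked,) = truth.spiked_mirnas
        assert tbl.iloc[0]["miRNA"] == spiked


class TestHolmStepdown:
    def test_rank_one_threshold_is_alpha_over_m(self):
        # first comparison uses alpha/m: 0.05/312 = 1.6026e-4
        assert exomir.holm_stepdown({"x": 1.60e-4}, 0.05, 312) == {"x"}
        assert exomir.holm_stepdown({"x": 1.61e-4}, 0.05, 312) == set()

    def test_all_ones_rejects_nothing(self):
        assert exomir.holm_stepdown({"a": 1.0, "b": 1.0}, 0.05, 2) == set()

    def test_stepdown_stops_at_first_failure(self):
        p = {"a": 1e-6, "b": 0.04, "c": 0.05}
        # 0.04 > 0.05/2 so only the first rejects even though 0.05 <= 0.05/1
        assert exomir.holm_stepdown(p, 0.05, 3) == {"a"}

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_bruteforce_and_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests
        alpha, m = 0.05, len(pvals)
        named = {f"k{i}": p for i, p in enumerate(pvals)}
        got = exomir.holm_stepdown(named, alpha, m)
        # independent oracle: repeatedly pop the smallest p
        expect = set()
        remaining = dict(named)
        rank = 1
        while remaining:
            key = min(remaining, key=remaining.get)
            if remaining[key] <= alpha / (m - rank + 1):
                expect.add(key)
                del remaining[key]
                rank += 1
            else:
                break
        assert got == expect
        reject, *_ = multipletests(pvals, alpha=alpha, method="holm")
        sm_set = {f"k{i}" for i in range(m) if reject[i]}
        assert got == sm_set

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValueError):
            exomir.holm_stepdown({"a": 1.5}, 0.05, 1)


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        X = np.array([[3.0] * 6])
        design = make_design(["a"] * 3 + ["b"] * 3)
        out = exomir.wilcoxon_twoclass(X, ["m"], design, "a", "b")
        assert out["m"][1] == pytest.approx(1.0)

    def test_extreme_separation_exact_p(self):
        # {1,2,3} vs {10,11,12}: most extreme of C(6,3)=20 assignments,
        # two-sided p = 2/20 = 0.1
        X = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        design = make_design(["a"] * 3 + ["b"] * 3)
        W, p = exomir.wilcoxon_twoclass(X, ["m"], design, "a", "b")["m"]
        assert W == 6.0
        assert p == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        row = rng.normal(size=14)
        X = np.vstack([row, np.exp(row)])
        design = make_design(["a"] * 6 + ["b"] * 8)
        out = exomir.wilcoxon_twoclass(X, ["raw", "exp"], design, "a", "b")
        assert out["raw"] == pytest.approx(out["exp"])

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(5, 12))
        design = make_design(["a"] * 6 + ["b"] * 6)
        ours = exomir.wilcoxon_twoclass(X, range(5), design, "a", "b")
        for i, row in enumerate(X):
            ref = stats.mannwhitneyu(row[:6], row[6:],
                                     alternative="two-sided", method="exact")
            assert ours[i][1] == pytest.approx(ref.pvalue)

    def test_undersized_group_rejected(self):
        X = np.ones((1, 5))
        design = make_design(["a"] * 2 + ["b"] * 3)
        with pytest.raises(ValueError):
            exomir.wilcoxon_twoclass(X, ["m"], design, "a", "b")


def test_estimator_end_to_end_recovers_spikes(fitted_sam):
    est, norm, meta, truth = fitted_sam
    tbl = est.results_table(norm.index)
    q0 = set(tbl.loc[tbl["q-value(%)"] == 0, "miRNA"])
    spiked = set(truth.spiked_mirnas)
    # the default spiked design (SZ:14, BD:7) should dominate the q=0 set
    assert len(q0 & spiked) >= 0.7 * len(spiked)
    ranked_ids = list(tbl["miRNA"])
    top = set(ranked_ids[: len(spiked) + 5])
    assert len(top & spiked) >= 0.9 * len(spiked)
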