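import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from alcyte import assoc
from alcyte.assoc import (
    call_states,
    combine_modes,
    fit_beta_mixture,
    pair_test,
    run_mode,
)


class TestBetaMixture:
    def test_single_beta_selects_one_component(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).beta(20, 5, 200)
            if fit_beta_mixture(x).n_components_ == 1:
                hits += 1
        assert hits >= 45

    def test_two_component_means_recovered(self, rng):
        # analytic component means: 25/29 ≈ 0.862 and 4/29 ≈ 0.138
        x = np.concatenate([rng.beta(25, 4, 100), rng.beta(4, 25, 100)])
        fit = fit_beta_mixture(x)
        assert fit.n_components_ == 2
        assert abs(fit.means_[0] - 4 / 29) < 0.05
        assert abs(fit.means_[1] - 25 / 29) < 0.05

    def test_constant_vector_collapses(self):
        fit = fit_beta_mixture(np.full(30, 0.5))
        assert fit.n_components_ == 1
        assert fit.means_[0] == pytest.approx(0.5, abs=1e-6)

    def test_loglik_nondecreasing(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.beta(10, 3, 60), r.beta(2, 8, 60)])
            fit = fit_beta_mixture(x)
            diffs = np.diff(fit.loglik_path_)
            assert (diffs >= -1e-6 * np.maximum(1.0, np.abs(fit.loglik_path_[:-1]))).all()

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            fit_beta_mixture(np.full(5, 0.4))

    def test_weights_sum_to_one_means_sorted(self, rng):
        x = np.concatenate([rng.beta(20, 4, 80), rng.beta(3, 20, 40)])
        fit = fit_beta_mixture(x)
        assert fit.weights_.sum() == pytest.approx(1.0)
        assert (np.diff(fit.means_) >= 0).all()


def _high_low(shift_frac=0.0, shift=0.3, n_high=120, n_low=300, seed=0,
              dual_frac=0.0):
    r = np.random.default_rng(seed)
    low = np.clip(r.normal(0.5, 0.04, n_low), 0.001, 0.999)
    high = np.clip(r.normal(0.5, 0.04, n_high), 0.001, 0.999)
    n_shift = int(shift_frac * n_high)
    high[:n_shift] = np.clip(high[:n_shift] + shift, 0.001, 0.999)
    n_dual = int(dual_frac * n_high)
    if n_dual:
        high[n_shift:n_shift + n_dual] = np.clip(
            high[n_shift:n_shift + n_dual] - abs(shift), 0.001, 0.999
        )
    hs = pd.Series(high, index=[f"h{i}" for i in range(n_high)])
    ls = pd.Series(low, index=[f"l{i}" for i in range(n_low)])
    return hs, ls


class TestCallStates:
    def test_null_is_all_normal(self):
        hs, ls = _high_low(seed=1)
        sc = call_states(hs, ls)
        assert (sc.states == "normal").all()
        assert sc.prev_hypo == 0 and sc.prev_hyper == 0

    def test_planted_hyper_prevalence_recovered(self):
        hs, ls = _high_low(shift_frac=0.3, shift=0.3, seed=2)
        sc = call_states(hs, ls)
        assert sc.prev_hyper == pytest.approx(0.3, abs=0.1)
        assert sc.prev_hypo == 0

    def test_planted_dual_has_both_prevalences(self):
        hs, ls = _high_low(shift_frac=0.25, shift=0.3, dual_frac=0.25, seed=3)
        sc = call_states(hs, ls)
        assert sc.prev_hyper > 0 and sc.prev_hypo > 0


class TestPairTest:
    def _state(self, hs, ls):
        return call_states(hs, ls)

    def test_planted_negative_mode_hyper_detected(self, rng):
        hs, ls = _high_low(shift_frac=0.25, shift=0.3, seed=4)
        sc = self._state(hs, ls)
        hyper_idx = sc.states.index[sc.states == "hyper"]
        expr_high = pd.Series(rng.normal(100, 10, len(hs)), index=hs.index)
        expr_high[hyper_idx] = rng.normal(80, 10, len(hyper_idx))  # 2 SD below
        expr_low = pd.Series(rng.normal(100, 10, len(ls)), index=ls.index)
        ps = pair_test(sc, expr_high, expr_low, "negative")
        assert "hyper" in ps and ps["hyper"] < 0.01

    def test_null_expression_type_one_error_near_alpha(self):
        """One-sided rank-sum p-values are uniform under the null."""
        hs, ls = _high_low(shift_frac=0.25, shift=0.3, seed=5)
        sc = self._state(hs, ls)
        rejections = 0
        n_reps = 500
        for rep in range(n_reps):
            r = np.random.default_rng(rep)
            expr_high = pd.Series(r.normal(100, 10, len(hs)), index=hs.index)
            expr_low = pd.Series(r.normal(100, 10, len(ls)), index=ls.index)
            ps = pair_test(sc, expr_high, expr_low, "negative")
            if ps.get("hyper", 1.0) < 0.05:
                rejections += 1
        assert rejections / n_reps == pytest.approx(0.05, abs=0.025)

    def test_dual_pair_both_states_pass_positive_mode(self, rng):
        hs, ls = _high_low(shift_frac=0.3, shift=0.3, dual_frac=0.25, seed=6)
        sc = self._state(hs, ls)
        expr_high = pd.Series(rng.normal(100, 10, len(hs)), index=hs.index)
        hyper_idx = sc.states.index[sc.states == "hyper"]
        hypo_idx = sc.states.index[sc.states == "hypo"]
        expr_high[hyper_idx] = rng.normal(125, 10, len(hyper_idx))
        expr_high[hypo_idx] = rng.normal(75, 10, len(hypo_idx))
        expr_low = pd.Series(rng.normal(100, 10, len(ls)), index=ls.index)
        ps = pair_test(sc, expr_high, expr_low, "positive")
        assert ps["hyper"] < 0.01 and ps["hypo"] < 0.01

    def test_small_subset_not_tested(self, rng):
        hs, ls = _high_low(shift_frac=0.25, shift=0.3, seed=7)
        sc = self._state(hs, ls)
        expr_high = pd.Series(rng.normal(100, 10, len(hs)), index=hs.index)
        expr_low = pd.Series(rng.normal(100, 10, len(ls)), index=ls.index)
        ps = pair_test(sc, expr_high, expr_low, "negative", min_subset=10_000)
        assert ps == {}


class TestRunMode:
    def test_planted_pairs_recovered_with_mode_separation(self, celltype_data):
        meth, expr, groups, ann, truth = celltype_data
        states = assoc.compute_states(meth, groups)
        neg = run_mode(meth, expr, groups, ann, "negative", cell_type="ct",
                       states=states)
        pos = run_mode(meth, expr, groups, ann, "positive", cell_type="ct",
                       states=states)
        detected_neg = set(neg["cpg"])
        detected_pos = set(pos["cpg"])
        truth_neg = set(truth.loc[truth["mode"] == "negative", "cpg"])
        truth_pos = set(truth.loc[truth["mode"] == "positive", "cpg"])
        # sensitivity over all planted pairs
        n_tp = len(detected_neg & truth_neg) + len(detected_pos & truth_pos)
        assert n_tp >= 0.8 * len(truth)
        # a planted positive-mode pair never surfaces in negative mode
        assert not (detected_neg & truth_pos)
        assert not (detected_pos & truth_neg)

    def test_results_sorted_by_adjusted_p(self, celltype_data):
        meth, expr, groups, ann, truth = celltype_data
        neg = run_mode(meth, expr, groups, ann, "negative", cell_type="ct")
        assert (neg["p_adj"].diff().dropna() >= 0).all()

    def test_no_links_warns_and_returns_empty(self, rng, caplog):
        meth = pd.DataFrame(rng.uniform(0.3, 0.7, (5, 30)),
                            index=[f"cg{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(30)])
        expr = pd.DataFrame(rng.lognormal(3, 1, (5, 30)),
                            index=[f"X{i}" for i in range(5)],
                            columns=meth.columns)
        groups = pd.Series(["high"] * 15 + ["low"] * 15, index=meth.columns)
        ann = pd.DataFrame({"chrom": "chr1", "stratum": "typeII",
                            "gene": "", "blacklist": False}, index=meth.index)
        with caplog.at_level("WARNING", logger="alcyte"):
            out = run_mode(meth, expr, groups, ann, "negative")
        assert out.empty


class TestBenjaminiHochberg:
    def test_adjusted_monotone_and_bounded(self, rng):
        """BH-adjusted p-values are monotone in raw p and never exceed 1."""
        for _ in range(20):
            p = rng.uniform(0, 1, 50)
            adj = multipletests(p, method="fdr_bh")[1]
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()
            assert (adj <= 1.0).all()
            # manual step-up oracle
            m = len(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            expected = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1)
            assert np.allclose(adj[order], expected, atol=1e-12)


class TestCombineModes:
    def test_concatenation_and_unique_counts(self):
        def _frame(n, cpg_start, mode):
            return pd.DataFrame({
                "cpg": [f"cg{cpg_start + i}" for i in range(n)],
                "gene": [f"G{cpg_start + i}" for i in range(n)],
                "cell_type": "CD8T", "mode": mode, "state": "hyper",
                "prev_hypo": 0.0, "prev_hyper": 0.3,
                "p_raw": 0.001, "p_adj": 0.01,
            })

        # mirror the study arithmetic: 173 + 90 pairs; 163 + 87 disjoint CpGs
        neg = _frame(173, 0, "negative")
        neg.loc[163:, "cpg"] = [f"cg{i}" for i in range(10)]  # 163 unique
        pos = _frame(90, 1000, "positive")
        pos.loc[87:, "cpg"] = [f"cg{1000 + i}" for i in range(3)]  # 87 unique
        combined, summary = combine_modes(neg, pos)
        assert summary["n_pairs"] == 263
        assert summary["n_unique_cpgs"] == 250
        assert set(combined["mode"]) == {"negative", "positive"}

    def test_empty_positive_list_is_identity(self):
        neg = pd.DataFrame({
            "cpg": ["cg1"], "gene": ["G1"], "cell_type": ["A"],
            "mode": ["negative"], "state": ["hypo"], "prev_hypo": [0.2],
            "prev_hyper": [0.0], "p_raw": [0.001], "p_adj": [0.01],
        })
        empty = neg.iloc[0:0]
        combined, summary = combine_modes(neg, empty)
        pd.testing.assert_frame_equal(combined, neg)
        assert summary["n_pairs"] == 1
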