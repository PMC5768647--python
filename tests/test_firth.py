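import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndseq.firth import (
    Contrast,
    DEFAULT_CONTRASTS,
    batch_concordance,
    bh_adjust,
    de_contrast,
    firth_fit,
    firth_test,
    standardize_gene,
)


def two_by_two_design(a, b, c, d):
    """Binary-covariate dataset with cell counts (y=1,x=1)=a, (1,0)=b,
    (0,1)=c, (0,0)=d."""
    y = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    x = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    return y, np.column_stack([np.ones(len(y)), x])


def add_half_lor(a, b, c, d):
    return np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))


class TestStandardize:
    def test_hand_example(self):
        assert standardize_gene([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_idempotent(self):
        z = standardize_gene(np.random.default_rng(0).normal(size=30))
        assert standardize_gene(z) == pytest.approx(z, abs=1e-12)

    def test_output_moments(self):
        z = standardize_gene(np.random.default_rng(1).exponential(size=101))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize_gene([3.0, 3.0, 3.0])


class TestFirthFit:
    def test_balanced_table_zero_slope(self):
        y, X = two_by_two_design(1, 1, 1, 1)
        assert firth_fit(y, X).beta[1] == pytest.approx(0, abs=1e-9)

    def test_complete_separation_gives_log81(self):
        y, X = two_by_two_design(4, 0, 0, 4)
        fit = firth_fit(y, X)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(np.log(81), abs=1e-6)

    def test_separated_slope_matches_grid_search_oracle(self):
        """Independent check: brute-force maximization of the penalized
        likelihood over a fine slope grid (intercept profile by symmetry
        is -slope/2 for this symmetric table)."""
        y, X = two_by_two_design(4, 0, 0, 4)

        def pll(b1):
            beta = np.array([-b1 / 2, b1])
            eta = X @ beta
            p = 1 / (1 + np.exp(-eta))
            ll = y @ eta - np.logaddexp(0, eta).sum()
            w = p * (1 - p)
            return ll + 0.5 * np.linalg.slogdet((X * w[:, None]).T @ X)[1]

        grid = np.linspace(3.5, 5.5, 200001)
        best = grid[np.argmax([pll(b) for b in grid])]
        assert firth_fit(y, X).beta[1] == pytest.approx(best, abs=1e-4)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_slope_equals_add_half_corrected_lor(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return  # one-class outcome or constant covariate
        y, X = two_by_two_design(a, b, c, d)
        fit = firth_fit(y, X)
        assert fit.beta[1] == pytest.approx(add_half_lor(a, b, c, d), abs=1e-6)

    def test_penalized_loglik_not_below_start(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
            y = rng.integers(0, 2, 40).astype(float)
            if y.min() == y.max():
                continue
            from ndseq.firth import _penalized_loglik

            fit = firth_fit(y, X)
            assert fit.loglik >= _penalized_loglik(np.zeros(3), X, y) - 1e-9

    def test_rank_deficient_design_rejected(self):
        y = np.array([1.0, 0, 1, 0])
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            firth_fit(y, X)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            firth_fit(np.ones(4), np.ones((4, 1)))


class TestFirthTest:
    def test_balanced_table_p_near_one(self):
        y, X = two_by_two_design(1, 1, 1, 1)
        assert firth_test(y, X, 1) == pytest.approx(1.0, abs=1e-6)

    def test_separated_data_finite_p(self):
        y, X = two_by_two_design(4, 0, 0, 4)
        p = firth_test(y, X, 1)
        assert 0 < p < 0.05

    def test_null_type_one_error_calibrated(self):
        """Monte-Carlo: continuous null covariate, nominal 0.05 level."""
        rng = np.random.default_rng(5)
        n_reps, n = 400, 60
        rejections = 0
        for _ in range(n_reps):
            y = np.repeat([1.0, 0.0], n // 2)
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            rejections += firth_test(y, X, 1) < 0.05
        rate = rejections / n_reps
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < ci

    def test_wald_agrees_with_plrt_in_sign_of_evidence(self):
        y, X = two_by_two_design(8, 2, 2, 8)
        assert firth_test(y, X, 1, method="wald") < 0.05
        with pytest.raises(ValueError):
            firth_test(y, X, 1, method="bogus")


class TestBHAdjust:
    def test_step_up_hand_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_nan_propagates_and_shrinks_m(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2 successful tests, not 3
        assert q[0] == pytest.approx(0.02)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDEContrast:
    def test_planted_effects_recovered_with_correct_sign(self, small_cohort):
        de = de_contrast(
            small_cohort["norm"], small_cohort["samples"], DEFAULT_CONTRASTS[2]
        )
        truth = small_cohort["truth"].loc[de.index]
        shared = truth["label"] == "shared"
        assert de.loc[shared.to_numpy(), "de"].mean() >= 0.8
        called = shared.to_numpy() & de["de"].to_numpy()
        assert (
            np.sign(de.loc[called, "lor"])
            == np.sign(truth.loc[called, "lfc_hd"])
        ).all()

    def test_label_flip_negates_lor_keeps_p(self, small_cohort):
        norm, samples = small_cohort["norm"], small_cohort["samples"]
        sub = norm.iloc[:40]
        fwd = de_contrast(sub, samples, Contrast("f", frozenset({"HD"}), frozenset({"C"})))
        rev = de_contrast(sub, samples, Contrast("r", frozenset({"C"}), frozenset({"HD"})))
        assert rev["lor"].to_numpy() == pytest.approx(-fwd["lor"].to_numpy(), abs=1e-6)
        assert rev["p"].to_numpy() == pytest.approx(fwd["p"].to_numpy(), abs=1e-6)

    def test_count_scaling_invariance(self, small_cohort):
        norm, samples = small_cohort["norm"], small_cohort["samples"]
        sub = norm.iloc[:30]
        a = de_contrast(sub, samples, DEFAULT_CONTRASTS[0])
        b = de_contrast(sub * 7.5, samples, DEFAULT_CONTRASTS[0])
        assert b["lor"].to_numpy() == pytest.approx(a["lor"].to_numpy(), abs=1e-8)

    def test_sample_order_invariance(self, small_cohort):
        norm, samples = small_cohort["norm"], small_cohort["samples"]
        sub = norm.iloc[:30]
        perm = np.random.default_rng(7).permutation(norm.columns)
        a = de_contrast(sub, samples, DEFAULT_CONTRASTS[2])
        b = de_contrast(sub[perm], samples.loc[perm], DEFAULT_CONTRASTS[2])
        assert b["lor"].to_numpy() == pytest.approx(a["lor"].to_numpy(), abs=1e-9)

    def test_covariate_path_and_missing_covariate(self, small_cohort):
        norm, samples = small_cohort["norm"], small_cohort["samples"]
        sub = norm.iloc[:10]
        res = de_contrast(sub, samples, DEFAULT_CONTRASTS[0], covariates=("rin", "pmi"))
        assert res["converged"].all()
        with pytest.raises(KeyError):
            de_contrast(sub, samples, DEFAULT_CONTRASTS[0], covariates=("nope",))

    def test_q_never_below_p(self, small_cohort):
        de = de_contrast(
            small_cohort["norm"].iloc[:50],
            small_cohort["samples"],
            DEFAULT_CONTRASTS[1],
        )
        ok = de["p"].notna()
        assert (de.loc[ok, "q"] >= de.loc[ok, "p"] - 1e-12).all()


class TestBatchConcordance:
    def test_no_batch_effect_gives_high_rho(self, small_cohort):
        bc = batch_concordance(
            small_cohort["norm"], small_cohort["samples"], DEFAULT_CONTRASTS[0]
        )
        assert bc.rho > 0.95
        assert bc.pvalue < 0.001

    def test_single_batch_rejected(self, small_cohort):
        samples = small_cohort["samples"].copy()
        samples["batch"] = "batch_0"
        with pytest.raises(ValueError, match="two batches"):
            batch_concordance(small_cohort["norm"], samples, DEFAULT_CONTRASTS[0])

    def test_confounded_batch_rejected(self, small_cohort):
        samples = small_cohort["samples"].copy()
        samples["batch"] = np.where(samples["condition"] == "C", "b0", "b1")
        with pytest.raises(ValueError, match="confounded"):
            batch_concordance(
                small_cohort["norm"].iloc[:10], samples, DEFAULT_CONTRASTS[0]
            )
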