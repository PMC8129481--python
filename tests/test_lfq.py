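"""Unit and property tests for the label-free differential-enrichment engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn
from scipy import stats

from lipoproteome import (
    ModerationParams,
    bh_adjust,
    fit_moderation,
    impute_first_percentile,
    median_normalize,
    moderated_test,
    paired_ratio_test,
    quantifiability_filter,
    replicate_diff,
    run_lfq_pipeline,
)
from lipoproteome.datasets import load_enrichment_reference

from conftest import make_matrix


# ------------------------------------------------------------ normalization


class TestMedianNormalize:
    def test_equal_medians_is_identity(self):
        vals = np.tile([[1.0], [2.0], [3.0]], (1, 4))
        m = make_matrix(vals)
        out = median_normalize(m)
        np.testing.assert_allclose(out.intensities.to_numpy(), vals)

    def test_hand_computed_two_sample_case(self):
        # observed {1,2,3} and {2,4,6}: medians 2 and 4, reference median 3
        vals = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        m = make_matrix(vals, n_pairs=1)
        out = median_normalize(m)
        got = out.intensities.to_numpy()
        # second sample ends up divided by 2 relative to the first
        np.testing.assert_allclose(got[:, 1] / got[:, 0], np.ones(3))
        meds = np.median(got, axis=0)
        np.testing.assert_allclose(meds, [3.0, 3.0])

    def test_preserves_within_sample_ratios(self, small_matrix):
        out = median_normalize(small_matrix)
        before = small_matrix.intensities.to_numpy()
        after = out.intensities.to_numpy()
        np.testing.assert_allclose(after[0] / after[1], before[0] / before[1])

    def test_missing_mask_unchanged(self, small_matrix):
        m = small_matrix
        m.intensities.iloc[0, 0] = np.nan
        out = median_normalize(m)
        assert out.intensities.isna().equals(m.intensities.isna())

    def test_all_missing_sample_errors(self):
        vals = np.full((3, 4), np.nan)
        vals[:, 1:] = 5.0
        m = make_matrix(vals)
        with pytest.raises(ValueError, match="LPA_1"):
            median_normalize(m)


# ------------------------------------------------------------ imputation


class TestImputeFirstPercentile:
    def test_no_missing_identity(self, small_matrix):
        out = impute_first_percentile(small_matrix)
        np.testing.assert_allclose(out.intensities.to_numpy(), small_matrix.intensities.to_numpy())

    def test_value_matches_brute_force_percentile(self):
        # 100 observed values 1..100 plus one missing cell in that sample
        vals = np.ones((101, 2))
        vals[:100, 0] = np.arange(1, 101, dtype=float)
        vals[100, 0] = np.nan
        m = make_matrix(vals, n_pairs=1)
        out = impute_first_percentile(m)
        # brute-force linear interpolation between sorted order statistics
        srt = np.arange(1, 101, dtype=float)
        pos = 0.01 * (len(srt) - 1)
        lo, hi = int(math.floor(pos)), int(math.ceil(pos))
        expected = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
        assert out.intensities.iloc[100, 0] == pytest.approx(expected)
        assert expected == pytest.approx(1.99)

    def test_degenerate_single_observation(self):
        vals = np.full((5, 2), np.nan)
        vals[0, :] = 7.0
        m = make_matrix(vals, n_pairs=1)
        out = impute_first_percentile(m)
        np.testing.assert_allclose(out.intensities.to_numpy(), np.full((5, 2), 7.0))

    def test_output_has_no_missing_and_tracks_imputed(self, small_matrix):
        m = small_matrix
        m.intensities.iloc[2, 3] = np.nan
        out = impute_first_percentile(m)
        assert not out.intensities.isna().any().any()
        assert out.imputed.iloc[2, 3]
        assert out.imputed.to_numpy().sum() == 1

    def test_normalize_then_impute_idempotent(self):
        rng = np.random.default_rng(3)
        vals = 2.0 ** rng.normal(25, 2, size=(40, 12))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        m = make_matrix(vals)
        once = impute_first_percentile(median_normalize(m))
        twice = impute_first_percentile(median_normalize(once))
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)


# ------------------------------------------------------------ filtering


class TestQuantifiabilityFilter:
    def _matrix(self, lpa_obs, ldl_obs, peptides):
        vals = np.full((1, 12), np.nan)
        vals[0, :lpa_obs] = 10.0
        vals[0, 6:6 + ldl_obs] = 10.0
        return make_matrix(vals, peptide_counts=[peptides])

    def test_four_of_six_one_condition_quantifiable(self):
        m = self._matrix(lpa_obs=4, ldl_obs=0, peptides=2)
        assert quantifiability_filter(m).iloc[0]

    def test_three_of_six_both_conditions_not_quantifiable(self):
        m = self._matrix(lpa_obs=3, ldl_obs=3, peptides=2)
        assert not quantifiability_filter(m).iloc[0]

    def test_single_peptide_not_quantifiable(self):
        m = self._matrix(lpa_obs=6, ldl_obs=6, peptides=1)
        assert not quantifiability_filter(m).iloc[0]

    def test_bad_frac_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            quantifiability_filter(small_matrix, frac=0.0)


# ------------------------------------------------------------ paired test


class TestPairedRatioTest:
    def test_identical_conditions_ratio_one_p_one(self):
        vals = np.tile(np.array([[4.0, 8.0, 16.0]]).T, (1, 4))
        m = make_matrix(vals)
        res = paired_ratio_test(m)
        np.testing.assert_allclose(res["ratio"], 1.0)
        np.testing.assert_allclose(res["p_plain"], 1.0)
        assert res["zero_variance"].all()

    def test_constant_nonzero_difference(self):
        lpa = np.full((1, 6), 16.0)
        ldl = np.full((1, 6), 8.0)
        m = make_matrix(np.hstack([lpa, ldl]))
        res = paired_ratio_test(m)
        assert res["zero_variance"].iloc[0]
        assert 0 < res["p_plain"].iloc[0] < 1e-300
        assert res["ratio"].iloc[0] == pytest.approx(2.0)

    def test_closed_form_t_from_first_principles(self):
        diffs = np.array([2.1, 1.9, 2.0, 2.2, 1.8, 2.0])
        ldl = np.full(6, 1024.0)
        lpa = ldl * 2.0**diffs
        m = make_matrix(np.hstack([lpa, ldl]).reshape(1, 12))
        res = paired_ratio_test(m)
        t_expected = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(6))
        assert res["t_plain"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        p_expected = 2 * stats.t.sf(abs(t_expected), df=5)
        assert res["p_plain"].iloc[0] == pytest.approx(p_expected, rel=1e-12)

    def test_pairs_matched_by_pair_id_not_column_order(self):
        # scramble the LDL column order; pairing must follow pair_id
        rng = np.random.default_rng(1)
        vals = 2.0 ** rng.normal(20, 1, size=(5, 12))
        m = make_matrix(vals)
        perm = [3, 0, 1, 5, 4, 2]
        cols = list(m.samples_of("LPA")) + [m.samples_of("LDL")[j] for j in perm]
        m2 = type(m)(
            intensities=m.intensities[cols],
            condition=m.condition[cols],
            pair_id=m.pair_id[cols],
            peptide_counts=m.peptide_counts,
        )
        r1 = paired_ratio_test(m)
        r2 = paired_ratio_test(m2)
        np.testing.assert_allclose(r1["t_plain"], r2["t_plain"])

    def test_requires_two_pairs(self):
        m = make_matrix(np.array([[1.0, 2.0]]), n_pairs=1)
        with pytest.raises(ValueError):
            paired_ratio_test(m)

    def test_requires_complete_matrix(self, small_matrix):
        small_matrix.intensities.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            paired_ratio_test(small_matrix)


# ------------------------------------------------------------ moderation


class TestModeration:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        d0, s0, df = 4.0, 1.0, 5
        sigma2 = s0 * d0 / rng.chisquare(d0, size=20000)
        s2 = sigma2 * rng.chisquare(df, size=20000) / df
        params = fit_moderation(s2, df)
        assert params.d0 == pytest.approx(d0, rel=0.10)
        assert params.s0_sq == pytest.approx(s0, rel=0.05)

    def test_equal_variances_give_complete_shrinkage(self):
        params = fit_moderation(np.full(50, 2.0), 5)
        assert math.isinf(params.d0)
        assert params.s0_sq == pytest.approx(2.0)

    def test_posterior_equals_common_variance_under_shrinkage(self):
        base = pd.DataFrame({
            "mean_diff": [1.0, -0.5],
            "var_diff": [2.0, 2.0],
            "n_pairs": [6, 6],
        }, index=["a", "b"])
        params = ModerationParams(d0=math.inf, s0_sq=2.0, residual_df=5)
        out = moderated_test(base, params)
        np.testing.assert_allclose(out["s2_post"], 2.0)

    def test_no_prior_reduces_to_plain_t(self):
        diffs = np.array([0.3, 0.1, 0.5, -0.2, 0.4, 0.25])
        base = pd.DataFrame({
            "mean_diff": [diffs.mean()],
            "var_diff": [diffs.var(ddof=1)],
            "n_pairs": [6],
        })
        params = ModerationParams(d0=1e-300, s0_sq=1.0, residual_df=5)
        out = moderated_test(base, params)
        t_plain = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(6))
        assert out["t_mod"].iloc[0] == pytest.approx(t_plain, rel=1e-9)

    def test_hand_worked_posterior(self):
        # d0=4, s0_sq=1, df=5, s2=2, mean diff 1, n=6
        base = pd.DataFrame({"mean_diff": [1.0], "var_diff": [2.0], "n_pairs": [6]})
        params = ModerationParams(d0=4.0, s0_sq=1.0, residual_df=5)
        out = moderated_test(base, params)
        s2_post = (4.0 * 1.0 + 5.0 * 2.0) / (4.0 + 5.0)
        assert out["s2_post"].iloc[0] == pytest.approx(s2_post)
        t_expected = 1.0 / math.sqrt(s2_post / 6.0)
        assert out["t_mod"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        p_expected = 2 * stats.t.sf(t_expected, df=9)
        assert out["p_mod"].iloc[0] == pytest.approx(p_expected, rel=1e-12)

    def test_infinite_d0_limit_matches_pooled_z(self):
        base = pd.DataFrame({"mean_diff": [0.5], "var_diff": [1.0], "n_pairs": [6]})
        params = ModerationParams(d0=math.inf, s0_sq=1.0, residual_df=5)
        out = moderated_test(base, params)
        z = 0.5 / math.sqrt(1.0 / 6.0)
        assert out["p_mod"].iloc[0] == pytest.approx(2 * stats.norm.sf(z), rel=1e-9)

    def test_too_few_variances_rejected(self):
        with pytest.raises(ValueError):
            fit_moderation(np.ones(5), 5)


# ------------------------------------------------------------ BH


def bh_brute_force(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(7)), np.ones(7))

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(stn.lists(stn.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, p):
        q = bh_adjust(p)
        assert np.all((q >= 0) & (q <= 1))
        # monotone in p rank
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)
        np.testing.assert_allclose(q, bh_brute_force(p), rtol=1e-12)


# ------------------------------------------------------------ replication


class TestReplicateDiff:
    @staticmethod
    def _phases():
        ref = load_enrichment_reference()
        disc = pd.DataFrame({"ratio": ref["discovery_ratio"], "p": ref["discovery_p"]})
        repl = pd.DataFrame({"ratio": ref["replication_ratio"], "p": ref["replication_p"]})
        return disc, repl

    def test_reference_table_replays_fifteen_lpa_proteins(self):
        disc, repl = self._phases()
        out = replicate_diff(disc, repl, alpha=0.05, discovery_alpha=1e-4)
        assert len(out) == 15
        assert (out["direction"] == "LPA").all()

    def test_empty_discovery(self):
        disc, repl = self._phases()
        out = replicate_diff(disc.iloc[0:0], repl)
        assert out.empty

    def test_direction_disagreement_blocks_replication(self):
        disc = pd.DataFrame({"ratio": [5.0], "p": [1e-6]}, index=["X"])
        repl = pd.DataFrame({"ratio": [0.2], "p": [1e-4]}, index=["X"])
        assert replicate_diff(disc, repl).empty

    def test_nonsignificant_replication_blocks(self):
        disc = pd.DataFrame({"ratio": [5.0], "p": [1e-6]}, index=["X"])
        repl = pd.DataFrame({"ratio": [4.0], "p": [0.2]}, index=["X"])
        assert replicate_diff(disc, repl).empty


# ------------------------------------------------------------ pipeline-level


class TestPipeline:
    def test_null_matrix_zero_noise_zero_discoveries(self):
        from lipoproteome import LfqSimTruth, simulate_lfq

        truth = LfqSimTruth(n_proteins=50, n_pairs=6, enriched_ids=frozenset(), cv=0.0, seed=4)
        res = run_lfq_pipeline(simulate_lfq(truth))
        quant = res.loc[res["quantifiable"]]
        assert (quant["p_plain"] == 1.0).all()
        assert not (quant["q_mod"] < 0.999).any()

    def test_spiked_proteins_recovered(self):
        from lipoproteome import LfqSimTruth, simulate_lfq

        spiked = frozenset(range(10))
        truth = LfqSimTruth(n_proteins=400, n_pairs=6, enriched_ids=spiked,
                            log2_effect=3.0, cv=0.1, seed=5)
        res = run_lfq_pipeline(simulate_lfq(truth))
        ids = [f"P{i:05d}" for i in spiked]
        sub = res.loc[ids]
        assert ((sub["ratio"] > 6) & (sub["ratio"] < 10)).all()
        assert (sub["q_mod"] < 0.05).all()
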