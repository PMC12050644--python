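"""Differential analysis: exact Wilcoxon, Storey q-values, folds, quadrants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from scproteome import (ValidationError, analyze_study, arm_fold_change,
                        classify_quadrant, fold_change_ratio, generate_study,
                        scatter_summary, storey_qvalues,
                        subject_log_fold_changes, wilcoxon_signed_rank)
from scproteome import test_between_arm_changes as between_arm_changes
from scproteome.synthetic import Effect


# ---------------------------------------------------------------------------
# independent oracle: brute-force enumeration of all sign assignments
# ---------------------------------------------------------------------------

def enumeration_p(diffs) -> float:
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array([np.sum(ranks[list(signs)])
                      for signs in itertools.product([False, True], repeat=n)
                      ], dtype=float)
    total = w_all.size
    p_low = np.sum(w_all <= w_obs + 1e-9) / total
    p_high = np.sum(w_all >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_low, p_high))


class TestWilcoxon:
    def test_n8_all_positive_gives_two_in_256(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6, 7, 8])
        assert res.p_value == pytest.approx(0.0078125, abs=1e-15)
        assert res.method == "exact"

    def test_symmetry_under_negation(self):
        d = [0.3, -1.2, 2.5, 0.7, -0.1]
        assert wilcoxon_signed_rank(d).p_value == \
            wilcoxon_signed_rank([-x for x in d]).p_value

    def test_hand_vector_matches_enumeration(self):
        d = [1, -2, 3, 4, 5]
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(enumeration_p(d), abs=1e-12)

    def test_all_zero_vector_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_zeros_dropped_before_ranking(self):
        with_zeros = wilcoxon_signed_rank([0.0, 1.0, 2.0, -0.5, 0.0])
        without = wilcoxon_signed_rank([1.0, 2.0, -0.5])
        assert with_zeros.p_value == without.p_value
        assert with_zeros.n == 3

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-10, max_value=10,
                              allow_nan=False).filter(lambda x: abs(x) > 1e-6),
                    min_size=1, max_size=12))
    def test_exact_equals_enumeration(self, diffs):
        if np.unique(np.abs(diffs)).size < len(diffs):
            return  # exact path requires untied magnitudes
        res = wilcoxon_signed_rank(diffs)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(enumeration_p(diffs), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            d = rng.normal(size=rng.integers(3, 15))
            ours = wilcoxon_signed_rank(d).p_value
            theirs = stats.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_normal_approximation_with_ties(self):
        d = [1.0, 1.0, -1.0, 2.0, 3.0, 3.0, 4.0, -2.0] * 4
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal"
        theirs = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert res.p_value == pytest.approx(theirs, rel=1e-6)

    def test_large_n_uses_normal_path(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, 40)
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal"
        assert 0 < res.p_value <= 1


class TestStorey:
    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(5, 200))
            q, pi0 = storey_qvalues(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            assert pi0 == 1.0
            np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_all_ones_give_all_ones(self):
        q, pi0 = storey_qvalues(np.ones(30))
        assert (q == 1.0).all()

    def test_uniform_pvalues_pi0_near_one(self):
        rng = np.random.default_rng(7)
        estimates = [storey_qvalues(rng.uniform(size=10_000))[1]
                     for _ in range(20)]
        assert 0.9 <= np.mean(estimates) <= 1.0

    def test_q_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(11)
        p = np.concatenate([rng.uniform(size=80),
                            rng.uniform(0, 1e-4, size=20)])
        q, pi0 = storey_qvalues(p)
        assert 0 < pi0 <= 1
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q > 0) & (q <= 1)).all()

    def test_q_at_least_pi0_scaled_bh(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=100) ** 2
        q, pi0 = storey_qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, np.minimum(pi0 * bh, 1.0), atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            storey_qvalues([0.5, 1.2])
        with pytest.raises(ValidationError):
            storey_qvalues([0.5, -0.1])


class TestFoldChanges:
    def test_identical_timepoints_give_zero_delta(self, make_config):
        study = generate_study(make_config())
        from scproteome import quantify
        _, _, pai = quantify(study.peptides)
        for arm in ("lotion", "lotion_ff"):
            delta = subject_log_fold_changes(pai, study.design, arm)
            assert np.abs(delta.to_numpy()).max() < 1e-9

    def test_planted_effect_pass_through(self, noiseless_effect_study):
        study = noiseless_effect_study
        from scproteome import quantify
        _, _, pai = quantify(study.peptides)
        delta = subject_log_fold_changes(pai, study.design, "lotion_ff")
        np.testing.assert_allclose(delta.loc["SBSN"], np.log10(1.9),
                                   atol=1e-9)
        fc = arm_fold_change(delta)
        assert fc.loc["SBSN", "fc"] == pytest.approx(1.9, abs=1e-9)

    def test_unknown_arm_rejected(self, noiseless_effect_study):
        from scproteome import quantify
        _, _, pai = quantify(noiseless_effect_study.peptides)
        with pytest.raises(ValidationError, match="arm"):
            subject_log_fold_changes(pai, noiseless_effect_study.design, "placebo")

    def test_missing_day14_drops_only_that_subject(self, make_config):
        study = generate_study(make_config())
        gone = study.design.query(
            "subject_id == 'S01' and arm == 'lotion' and timepoint == 'day14'"
        )["sample_id"].iloc[0]
        peptides = study.peptides[study.peptides["sample_id"] != gone]
        from scproteome import quantify
        _, _, pai = quantify(peptides)
        delta = subject_log_fold_changes(pai, study.design, "lotion")
        assert "S01" not in delta.columns
        assert delta.shape[1] == 3

    def test_arm_fold_change_hand_means(self):
        delta = pd.DataFrame({"a": [0.0, np.log10(2)],
                              "b": [0.0, np.log10(8)],
                              "c": [0.0, np.nan]},
                             index=["Pzero", "Pmix"])
        fc = arm_fold_change(delta)
        assert fc.loc["Pzero", "lfc"] == 0.0
        assert fc.loc["Pzero", "fc"] == 1.0
        assert fc.loc["Pmix", "lfc"] == pytest.approx(2 * np.log10(2))
        assert fc.loc["Pmix", "fc"] == pytest.approx(4.0)
        assert fc.loc["Pmix", "n"] == 2


class TestBetweenArm:
    def test_identical_arms_flagged_degenerate(self, make_config):
        study = generate_study(make_config())
        from scproteome import quantify
        _, _, pai = quantify(study.peptides)
        dl = subject_log_fold_changes(pai, study.design, "lotion")
        df = subject_log_fold_changes(pai, study.design, "lotion_ff")
        res = between_arm_changes(dl, df)
        assert (res["p_value"] == 1.0).all()
        assert res["degenerate"].all()

    def test_planted_ff_effect_hits_exact_floor(self, make_config):
        config = make_config(
            n_subjects=8, n_proteins=20, noise_sd=0.005,
            sample_scale_sd=0.1,
            effects=(Effect("SBSN", "lotion_ff", float(np.log10(1.9))),),
            seed=2)
        study = generate_study(config)
        from scproteome import quantify
        _, _, pai = quantify(study.peptides)
        dl = subject_log_fold_changes(pai, study.design, "lotion")
        df = subject_log_fold_changes(pai, study.design, "lotion_ff")
        res = between_arm_changes(dl, df)
        assert res.loc["SBSN", "p_value"] == pytest.approx(0.0078125,
                                                           abs=1e-15)


class TestQuadrants:
    @pytest.mark.parametrize("lot,ff,expected", [
        (0.3, 0.2, "up_up"),
        (-0.3, -0.2, "down_down"),
        (-0.1, 0.4, "up_ff_down_lotion"),
        (0.1, -0.4, "up_lotion_down_ff"),
        (0.0, 0.5, "boundary"),
        (0.2, 0.0, "boundary"),
    ])
    def test_sign_rule(self, lot, ff, expected):
        assert classify_quadrant(lot, ff) == expected

    def test_partition_covers_all_records(self, make_config):
        config = make_config(n_subjects=6, n_proteins=30, noise_sd=0.05,
                             sample_scale_sd=0.1, seed=9)
        study = generate_study(config)
        res = analyze_study(study.peptides, study.design)
        quads = res["quadrants"]
        assert quads["n"].sum() == len(res["differential"])


class TestRatiosAndScatter:
    @pytest.mark.parametrize("ff,lot,expected", [
        (1.9, 0.5, 3.8), (2.0, 1.0, 2.0), (1.4, 1.4, 1.0)])
    def test_fold_change_ratio(self, ff, lot, expected):
        assert fold_change_ratio(ff, lot) == pytest.approx(expected)

    def test_ratio_rejects_nonpositive_denominator(self):
        with pytest.raises(ValidationError):
            fold_change_ratio(1.0, 0.0)

    def test_perfect_correlation(self):
        lfc = np.linspace(-0.4, 0.4, 10)
        rec = pd.DataFrame({"lfc_lotion": lfc, "lfc_ff": lfc})
        assert scatter_summary(rec).pearson_r == pytest.approx(1.0)
        rec2 = pd.DataFrame({"lfc_lotion": lfc, "lfc_ff": -lfc})
        assert scatter_summary(rec2).pearson_r == pytest.approx(-1.0)

    def test_five_point_hand_example(self):
        x = np.array([0.1, -0.2, 0.3, 0.05, -0.4])
        y = np.array([0.2, -0.1, 0.25, 0.1, -0.3])
        rec = pd.DataFrame({"lfc_lotion": x, "lfc_ff": y})
        l2x, l2y = x / np.log10(2), y / np.log10(2)
        # textbook Pearson formula, computed independently
        r = (np.sum((l2x - l2x.mean()) * (l2y - l2y.mean())) /
             np.sqrt(np.sum((l2x - l2x.mean()) ** 2) *
                     np.sum((l2y - l2y.mean()) ** 2)))
        assert scatter_summary(rec).pearson_r == pytest.approx(r, abs=1e-12)

    def test_histogram_counts_sum_to_records(self):
        rng = np.random.default_rng(2)
        rec = pd.DataFrame({"lfc_lotion": rng.normal(0, 0.2, 50),
                            "lfc_ff": rng.normal(0.1, 0.2, 50)})
        s = scatter_summary(rec)
        assert s.counts_lotion.sum() == 50
        assert s.counts_ff.sum() == 50

    def test_zero_variance_flagged(self):
        rec = pd.DataFrame({"lfc_lotion": [0.1, 0.1, 0.1],
                            "lfc_ff": [0.0, 0.1, 0.3]})
        s = scatter_summary(rec)
        assert s.degenerate
        assert np.isnan(s.pearson_r)
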