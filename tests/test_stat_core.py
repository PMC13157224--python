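"""Plaintext statistics: worked examples, invariants, and an external
cross-check of the meta-analysis against R's metafor."""

import json
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedcrypt import stat_core as sc


class TestStandardize:
    def test_direct_substitution(self):
        p = sc.StandardizationParams(3.0, 2.0)
        assert sc.standardize_scores([5.0], p)[0] == pytest.approx(1.0)

    def test_identity_params(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(
            sc.standardize_scores(x, sc.StandardizationParams(0.0, 1.0)), x
        )

    def test_control_scores_become_standard_normal_moments(self, rng):
        ctrl = rng.normal(3.0, 2.5, 500)
        p = sc.StandardizationParams(ctrl.mean(), ctrl.std(ddof=1))
        z = sc.standardize_scores(ctrl, p)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            sc.StandardizationParams(0.0, 0.0)


class TestQuintiles:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (list(range(10)), [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]),
            ([0.0] * 10, [1] * 10),
            ([3.0, 1.0, 4.0, 1.5, 5.0], [3, 1, 4, 2, 5]),
        ],
    )
    def test_examples(self, values, expected):
        assert sc.assign_quintiles(values).tolist() == expected

    def test_too_few_observations(self):
        with pytest.raises(sc.DegenerateDataError):
            sc.assign_quintiles([1.0, 2.0, 3.0, 4.0])

    @given(st.integers(5, 200), st.integers(0, 2**31))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_balanced_sizes_and_permutation_invariance(self, n, seed):
        g = np.random.default_rng(seed)
        x = g.normal(size=n)  # ties have probability zero
        q = sc.assign_quintiles(x)
        sizes = np.bincount(q, minlength=6)[1:]
        assert sizes.max() - sizes.min() <= 1
        perm = g.permutation(n)
        assert (sc.assign_quintiles(x[perm]) == q[perm]).all()

    def test_monotone_in_score(self, rng):
        x = rng.normal(size=100)
        q = sc.assign_quintiles(x)
        order = np.argsort(x)
        assert (np.diff(q[order]) >= 0).all()


class TestCaseControlRule:
    @pytest.mark.parametrize(
        "sbp,dbp,history,expected",
        [
            (120, 80, False, "control"),
            (135, 80, False, "case"),
            (120, 90, False, "case"),
            (120, 80, True, "case"),
            (130, 85, False, "case"),      # boundary is inclusive for cases
            (129.9, 84.9, False, "control"),
        ],
    )
    def test_rule(self, sbp, dbp, history, expected):
        assert sc.label_case_control(sbp, dbp, history) == expected

    def test_missing_field(self):
        with pytest.raises(ValueError, match="missing"):
            sc.label_case_control(float("nan"), 80, False)


class TestWelch:
    def test_identical_groups(self):
        r = sc.welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = sc.welch_ttest([1, 2, 3, 4], [2, 3, 4, 5])
        assert r.t_stat == pytest.approx(-1.0954451, abs=1e-6)
        assert r.df == pytest.approx(6.0)

    def test_equal_variance_equal_n_df(self, rng):
        x = rng.normal(size=12)
        r = sc.welch_ttest(x, x + 1.0)  # same sample variance, shifted
        assert r.df == pytest.approx(22.0)

    def test_df_bounds(self, rng):
        x1, x2 = rng.normal(size=9), rng.normal(0, 3, 15)
        r = sc.welch_ttest(x1, x2)
        assert min(9, 15) - 1 <= r.df <= 9 + 15 - 2

    def test_zero_variance_rejected(self):
        with pytest.raises(sc.DegenerateDataError):
            sc.welch_ttest([1.0, 1.0], [2.0, 2.0])


class TestAnova:
    def test_equal_means_give_zero_f(self):
        r = sc.one_way_anova([1, 2, 3] * 3, [1, 1, 1, 2, 2, 2, 3, 3, 3][:9])
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3], dtype=float)
        g = np.repeat([1, 2, 3], 3)
        r = sc.one_way_anova(x, g)
        assert r.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_two_group_example(self):
        r = sc.one_way_anova([1.0, 2.0, 3.0, 4.0], [1, 1, 2, 2])
        assert r.f_stat == pytest.approx(8.0)
        assert (r.df_between, r.df_within) == (1, 2)

    def test_f_equals_squared_pooled_t_two_groups(self):
        # brute-force identity check over many random equal-size datasets
        g = np.random.default_rng(5)
        for _ in range(1000):
            n = int(g.integers(3, 12))
            x1, x2 = g.normal(size=n), g.normal(g.normal(), 1.5, n)
            f = sc.one_way_anova(
                np.concatenate([x1, x2]), np.repeat([0, 1], n)
            ).f_stat
            from scipy import stats as sps

            t = sps.ttest_ind(x1, x2, equal_var=True).statistic
            assert f == pytest.approx(t * t, rel=1e-9, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(sc.DegenerateDataError):
            sc.one_way_anova([1.0, 2.0, 3.0], [1, 1, 1], n_groups=2)


class TestHedgesG:
    def test_zero_difference(self, rng):
        x = rng.normal(size=10)
        r = sc.smd_hedges(x, x)
        assert r.g == pytest.approx(0.0, abs=1e-12)
        assert r.var_g == pytest.approx(20.0 / 100.0)

    def test_hand_computed_example(self):
        # n1=n2=10, mean gap 1, sd 1: g = (68/71), var = 0.2 + g^2/36.06
        g = np.random.default_rng(3)
        base = g.normal(size=10)
        base = (base - base.mean()) / base.std(ddof=1)
        r = sc.smd_hedges(base + 1.0, base)
        expected_g = 68.0 / 71.0
        assert r.g == pytest.approx(expected_g, rel=1e-12)
        assert r.var_g == pytest.approx(0.2 + expected_g**2 / 36.06, rel=1e-12)

    def test_correction_shrinks_toward_cohens_d(self, rng):
        x1, x2 = rng.normal(1, 1, 8), rng.normal(0, 1, 9)
        r = sc.smd_hedges(x1, x2)
        d = (x1.mean() - x2.mean()) / r.s_pooled
        assert abs(r.g) <= abs(d)
        big = sc.smd_hedges(
            np.concatenate([x1] * 200) + rng.normal(0, 1e-6, 1600),
            np.concatenate([x2] * 200) + rng.normal(0, 1e-6, 1800),
        )
        assert abs(big.g / ((big.mean1 - big.mean2) / big.s_pooled)) > 0.999


class TestMeta:
    def test_identical_studies_collapse(self):
        r = sc.meta_analyze([(0.2, 0.04)] * 3)
        assert r.g_fixed == pytest.approx(0.2)
        assert r.tau2 == 0.0
        assert r.g_random == pytest.approx(0.2)
        assert r.ci_fixed == pytest.approx(r.ci_random)

    def test_symmetric_example(self):
        r = sc.meta_analyze([(0.2, 0.04), (0.2, 0.04)])
        half = 1.96 / np.sqrt(50.0)
        assert r.g_fixed == pytest.approx(0.2)
        assert r.q_stat == pytest.approx(0.0, abs=1e-12)
        assert r.ci_fixed[1] - r.ci_fixed[0] == pytest.approx(2 * half)

    def test_heterogeneous_hand_example(self):
        r = sc.meta_analyze([(0.2, 0.04), (0.6, 0.04)])
        assert r.q_stat == pytest.approx(2.0)
        assert r.tau2 == pytest.approx(0.04)
        assert r.g_fixed == pytest.approx(0.4)
        assert r.g_random == pytest.approx(0.4)
        assert sum(r.weights_random) == pytest.approx(1.0, abs=1e-12)

    def test_random_ci_never_narrower(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            studies = [
                (float(rng.normal(0, 0.5)), float(rng.uniform(0.01, 0.2)))
                for _ in range(k)
            ]
            r = sc.meta_analyze(studies)
            wf = r.ci_fixed[1] - r.ci_fixed[0]
            wr = r.ci_random[1] - r.ci_random[0]
            assert wr >= wf - 1e-12
            assert r.tau2 >= 0.0

    def test_too_few_studies(self):
        with pytest.raises(sc.DegenerateDataError):
            sc.meta_analyze([(0.1, 0.05)])


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_meta_matches_r_metafor(tmp_path):
    """Independent oracle: fixed-effect and DerSimonian-Laird pooling must
    match R's metafor on a small study set."""
    studies = [(0.31, 0.052), (0.58, 0.041), (0.12, 0.087), (0.44, 0.060)]
    ours = sc.meta_analyze(studies)
    script = tmp_path / "meta.R"
    script.write_text(
        """
        suppressMessages(library(metafor)); suppressMessages(library(jsonlite))
        yi <- c(0.31, 0.58, 0.12, 0.44); vi <- c(0.052, 0.041, 0.087, 0.060)
        fe <- rma(yi, vi, method="FE"); dl <- rma(yi, vi, method="DL")
        cat(toJSON(list(g_fixed=as.numeric(fe$beta), g_random=as.numeric(dl$beta),
                        tau2=dl$tau2, q=dl$QE,
                        se_f=fe$se, se_r=dl$se), digits=12))
        """
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
        timeout=120,
    )
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    assert ours.g_fixed == pytest.approx(ref["g_fixed"][0], rel=1e-9)
    assert ours.g_random == pytest.approx(ref["g_random"][0], rel=1e-9)
    assert ours.tau2 == pytest.approx(ref["tau2"][0], rel=1e-9)
    assert ours.q_stat == pytest.approx(ref["q"][0], rel=1e-9)
    # CI with the flat 1.96 normal multiplier on metafor's standard errors
    assert ours.ci_fixed[0] == pytest.approx(
        ref["g_fixed"][0] - 1.96 * ref["se_f"][0], rel=1e-9
    )
    assert ours.ci_random[1] == pytest.approx(
        ref["g_random"][0] + 1.96 * ref["se_r"][0], rel=1e-9
    )
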