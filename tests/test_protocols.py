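"""Federated protocols vs the plaintext oracle, revealed-output discipline,
and packing/partitioning invariances."""

import numpy as np
import pytest

from fedcrypt import stat_core as sc
from fedcrypt.he.engine import HEParams
from fedcrypt.mpc.engine import MpcSession
from fedcrypt.protocols import (
    FederatedSession,
    ProtocolAbort,
    SecureAttribute,
    secure_anova,
    secure_meta,
    secure_smd,
    secure_ttest,
)
from fedcrypt.transcript import audit_openings


def _dataset(seed=0, n=300, effect=3.0, mean=130.0, sd=12.0):
    rng = np.random.default_rng(seed)
    q = rng.integers(1, 6, n)
    x = mean + effect * (q - 3) + rng.normal(0, sd, n)
    return x, q


def _quintile_indicators(q):
    return np.stack([(q == k).astype(int) for k in range(1, 6)])


def _pair_indicators(q, hi=5, lo=1):
    return np.stack([(q == hi).astype(int), (q == lo).astype(int)])


@pytest.fixture(scope="module")
def cohort():
    x, q = _dataset(seed=11)
    sess = FederatedSession(seed=21, session_id="tp")
    attr = SecureAttribute.from_parts(sess, [x])
    return sess, attr, x, q


class TestSecureAnova:
    def test_matches_plaintext(self, cohort):
        sess, attr, x, q = cohort
        res = secure_anova(sess, _quintile_indicators(q), attr)
        plain = sc.one_way_anova(x, q)
        assert res.f_stat == pytest.approx(plain.f_stat, rel=1e-3)
        assert (res.df_between, res.df_within) == (plain.df_between, plain.df_within)

    def test_two_group_f_equals_pooled_t_squared(self):
        x, q = _dataset(seed=3, n=120)
        two = np.where(q >= 3, 1, 0)
        sess = FederatedSession(seed=4, session_id="tp2")
        ind = np.stack([(two == 0).astype(int), (two == 1).astype(int)])
        res = secure_anova(sess, ind, [x])
        from scipy import stats as sps

        t = sps.ttest_ind(x[two == 0], x[two == 1], equal_var=True).statistic
        assert res.f_stat == pytest.approx(t * t, rel=1e-3)

    def test_single_group_aborts(self):
        x, _ = _dataset(seed=5, n=40)
        sess = FederatedSession(seed=6, session_id="tp3")
        ind = np.ones((1, 40), dtype=int)
        with pytest.raises((ProtocolAbort, Exception)):
            secure_anova(sess, ind, [x])

    def test_degenerate_group_aborts(self):
        x, q = _dataset(seed=7, n=60)
        q[q == 2] = 1  # empty group 2
        sess = FederatedSession(seed=8, session_id="tp4")
        with pytest.raises(ProtocolAbort):
            secure_anova(sess, _quintile_indicators(q), [x])


class TestSecureTTest:
    def test_matches_plaintext_including_sign(self, cohort):
        sess, attr, x, q = cohort
        for hi, lo in ((5, 1), (1, 5), (5, 3)):
            res = secure_ttest(sess, _pair_indicators(q, hi, lo), attr)
            plain = sc.welch_ttest(x[q == hi], x[q == lo])
            assert res.t_stat == pytest.approx(plain.t_stat, rel=1e-3)
            assert res.df == round(plain.df)

    def test_identical_groups_p_at_top(self):
        rng = np.random.default_rng(9)
        base = rng.normal(130, 10, 40)
        x = np.concatenate([base, base])
        ind = np.stack(
            [np.r_[np.ones(40), np.zeros(40)], np.r_[np.zeros(40), np.ones(40)]]
        ).astype(int)
        sess = FederatedSession(seed=10, session_id="tp5")
        res = secure_ttest(sess, ind, [x])
        assert res.t_stat == pytest.approx(0.0, abs=1e-4)
        assert res.p_value == 1.0

    def test_equal_n_equal_s_gives_2n_minus_2(self):
        rng = np.random.default_rng(12)
        g1 = rng.normal(0, 1, 30)
        g1 = (g1 - g1.mean()) / g1.std(ddof=1) * 8 + 120
        g2 = g1 + 7.5  # same sample sd, shifted mean
        x = np.concatenate([g1, g2])
        ind = np.stack(
            [np.r_[np.ones(30), np.zeros(30)], np.r_[np.zeros(30), np.ones(30)]]
        ).astype(int)
        sess = FederatedSession(seed=13, session_id="tp6")
        res = secure_ttest(sess, ind, [x])
        assert res.df == 58


class TestSecureSMD:
    def test_matches_plaintext(self, cohort):
        sess, attr, x, q = cohort
        res = secure_smd(sess, _pair_indicators(q), attr)
        plain = sc.smd_hedges(x[q == 5], x[q == 1])
        assert res.g == pytest.approx(plain.g, rel=1e-3)
        assert res.var_g == pytest.approx(plain.var_g, rel=1e-3)
        # Hedges variance is bounded below by (n1+n2)/(n1 n2)
        n1, n2 = int((q == 5).sum()), int((q == 1).sum())
        assert res.var_g >= (n1 + n2) / (n1 * n2) - 1e-6

    def test_equal_means_give_zero(self):
        rng = np.random.default_rng(14)
        base = rng.normal(120, 9, 50)
        x = np.concatenate([base, base])
        ind = np.stack(
            [np.r_[np.ones(50), np.zeros(50)], np.r_[np.zeros(50), np.ones(50)]]
        ).astype(int)
        sess = FederatedSession(seed=15, session_id="tp7")
        res = secure_smd(sess, ind, [x])
        assert res.g == pytest.approx(0.0, abs=1e-5)

    def test_shared_mode_reveals_nothing(self):
        x, q = _dataset(seed=16, n=200)
        sess = FederatedSession(seed=17, session_id="tp8")
        g_sh, v_sh = secure_smd(sess, _pair_indicators(q), [x], mode="shared")
        assert sess.transcript.revealed() == []
        plain = sc.smd_hedges(x[q == 5], x[q == 1])
        # shares reconstruct to the oracle values (reconstruction happens
        # here in the test, not in the protocol)
        assert sess.mpc.reconstruct(g_sh) == pytest.approx(plain.g, rel=1e-3)
        assert sess.mpc.reconstruct(v_sh) == pytest.approx(plain.var_g, rel=1e-3)


class TestSecureMeta:
    def test_worked_example(self):
        mpc = MpcSession(FederatedSession(seed=18, session_id="tp9").mpc.params, seed=19)
        pairs = [(mpc.share(0.2), mpc.share(0.04)), (mpc.share(0.6), mpc.share(0.04))]
        res = secure_meta(pairs, session=mpc)
        assert res.q_stat == pytest.approx(2.0, abs=1e-3)
        assert res.tau2 == pytest.approx(0.04, abs=1e-3)
        assert res.g_fixed == pytest.approx(0.4, abs=1e-3)
        assert res.g_random == pytest.approx(0.4, abs=1e-3)
        wf = res.ci_fixed[1] - res.ci_fixed[0]
        wr = res.ci_random[1] - res.ci_random[0]
        assert wr > wf

    def test_identical_studies(self):
        mpc = MpcSession(FederatedSession(seed=20, session_id="tp10").mpc.params, seed=21)
        pairs = [(mpc.share(0.3), mpc.share(0.05)), (mpc.share(0.3), mpc.share(0.05))]
        res = secure_meta(pairs, session=mpc)
        assert res.g_fixed == pytest.approx(0.3, abs=1e-4)
        assert res.tau2 == 0.0
        assert res.g_random == pytest.approx(res.g_fixed, abs=1e-4)

    def test_random_pairs_match_plaintext(self):
        rng = np.random.default_rng(22)
        ring = FederatedSession(seed=23, session_id="tp11").mpc.params
        for trial in range(30):
            mpc = MpcSession(ring, seed=1000 + trial)
            studies = [
                (float(rng.normal(0.4, 0.3)), float(rng.uniform(0.02, 0.2)))
                for _ in range(int(rng.integers(2, 5)))
            ]
            res = secure_meta(
                [(mpc.share(g), mpc.share(v)) for g, v in studies], session=mpc
            )
            plain = sc.meta_analyze(studies)
            for got, want in (
                (res.g_fixed, plain.g_fixed),
                (res.g_random, plain.g_random),
                (res.q_stat, plain.q_stat),
                (res.tau2, plain.tau2),
                (res.ci_random[0], plain.ci_random[0]),
                (res.ci_random[1], plain.ci_random[1]),
            ):
                assert got == pytest.approx(want, rel=1e-3, abs=1e-5)

    def test_insufficient_studies(self):
        mpc = MpcSession(FederatedSession(seed=24, session_id="tp12").mpc.params, seed=25)
        with pytest.raises(ProtocolAbort):
            secure_meta([(mpc.share(0.2), mpc.share(0.04))], session=mpc)

    def test_weights_revealed_only_by_policy(self):
        ring = FederatedSession(seed=26, session_id="tp13").mpc.params
        studies = [(0.2, 0.05), (0.5, 0.08), (0.3, 0.04)]
        mpc = MpcSession(ring, seed=27)
        res = secure_meta(
            [(mpc.share(g), mpc.share(v)) for g, v in studies], session=mpc
        )
        assert res.weights_fixed == ()
        mpc2 = MpcSession(ring, seed=28)
        res2 = secure_meta(
            [(mpc2.share(g), mpc2.share(v)) for g, v in studies],
            session=mpc2, reveal_weights=True,
        )
        plain = sc.meta_analyze(studies)
        np.testing.assert_allclose(res2.weights_fixed, plain.weights_fixed, rtol=1e-3)
        assert sum(res2.weights_fixed) == pytest.approx(1.0, abs=1e-4)


class TestPartitioningAndPacking:
    def test_hybrid_phenotype_slices(self):
        """Two phenotype sites each encrypt their slice; results match the
        single-site run."""
        x, q = _dataset(seed=30, n=150)
        part1, part2 = np.zeros_like(x), np.zeros_like(x)
        part1[:80] = x[:80]
        part2[80:] = x[80:]
        s1 = FederatedSession(seed=31, session_id="hp1")
        s2 = FederatedSession(n_phenotype_sites=2, seed=31, session_id="hp2")
        r1 = secure_anova(s1, _quintile_indicators(q), [x])
        r2 = secure_anova(s2, _quintile_indicators(q), [part1, part2])
        assert r2.f_stat == pytest.approx(r1.f_stat, rel=1e-4)
        assert r2.p_value == r1.p_value

    def test_chunk_boundary_invariance(self):
        """Same data, slot counts straddling the vector length: results
        agree although one run needs 2 ciphertexts per vector."""
        x, q = _dataset(seed=32, n=600)
        plain = sc.one_way_anova(x, q)
        for ring_dim, expected_chunks in ((2048, 1), (512, 3)):
            sess = FederatedSession(
                seed=33, session_id=f"chunk{ring_dim}",
                he_params=HEParams(ring_dim=ring_dim, n_parties=2),
            )
            attr = SecureAttribute.from_parts(sess, [x])
            assert attr.ev_x.n_ciphertexts == expected_chunks
            res = secure_anova(sess, _quintile_indicators(q), attr)
            assert res.f_stat == pytest.approx(plain.f_stat, rel=1e-3)

    def test_attribute_bound_enforced(self):
        sess = FederatedSession(seed=34, session_id="ab")
        with pytest.raises(ValueError, match="bound"):
            SecureAttribute.from_parts(sess, [np.array([1e5, 2.0])])


class TestRevealedOutputDiscipline:
    def test_anova_transcript_reveals_only_declared_outputs(self):
        x, q = _dataset(seed=40, n=200)
        sess = FederatedSession(seed=41, session_id="audit")
        secure_anova(sess, _quintile_indicators(q), [x])
        tags = {e["tag"] for e in sess.transcript.revealed()}
        assert tags == {"reveal:p_value", "reveal:F"}
        # no masked opening collides with a sensitive intermediate
        sens = []
        for k in range(1, 6):
            xk = x[q == k]
            sens += [xk.sum(), (xk**2).sum(), xk.mean(), xk.var(ddof=1)]
        from fedcrypt.mpc.ring import decode

        violations = audit_openings(
            sess.transcript, sens,
            decoder=lambda v: decode(v, sess.mpc.params), atol=1e-9,
        )
        assert violations == []
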