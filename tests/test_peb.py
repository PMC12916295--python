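"""Parametric empirical Bayes: GLS oracle, BMR, model comparison, BMA."""
import numpy as np
import pandas as pd
import pytest

from nmda_dcm.densities import GaussianDensity
from nmda_dcm.errors import DesignError, InvalidParameterError, StructuralError
from nmda_dcm.peb import (
    PEBDesign, PEBSettings, all_combinations_bma, bayesian_model_average,
    bayesian_model_reduction, fit_peb, model_space_compare,
    softmax_probabilities,
)

FIELDS = ("p0", "p1", "p2")


def synthetic_posteriors(rng, n, prior, truths, like_sd=0.05):
    """First-level posteriors built from known truths and a Gaussian likelihood."""
    P = len(prior.names)
    P0 = np.linalg.inv(prior.cov)
    posts = []
    for i in range(n):
        L = np.eye(P) / like_sd ** 2
        d = truths[i] + rng.normal(0, like_sd, size=P)
        C = np.linalg.inv(L + P0)
        posts.append(GaussianDensity(prior.names, C @ (L @ d), C))
    return posts


@pytest.fixture()
def prior():
    return GaussianDensity(FIELDS, np.zeros(3), np.eye(3) * 0.5)


class TestDesign:
    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(DesignError):
            PEBDesign(X, ("constant", "dup"))

    def test_from_table_centres_and_standardises(self):
        tab = pd.DataFrame({"mmse": [20.0, 25.0, 30.0]})
        d = PEBDesign.from_table(tab, ["mmse"], standardize=["mmse"])
        assert d.X[:, 1] == pytest.approx([-np.sqrt(1.5), 0, np.sqrt(1.5)])
        assert d.regressor_names == ("constant", "mmse")

    def test_unknown_covariate_rejected(self):
        with pytest.raises(DesignError):
            PEBDesign.from_table(pd.DataFrame({"a": [1.0, 2.0]}), ["b"])


class TestFitPEB:
    def test_identical_subjects_constant_design(self, rng):
        """With a weak first-level prior the constant recovers the shared mean
        and a balanced group regressor carries no effect."""
        weak = GaussianDensity(FIELDS, np.zeros(3), np.eye(3) * 1e4)
        shared = np.array([0.4, -0.2, 0.1])
        posts = synthetic_posteriors(rng, 10, weak, [shared] * 10, like_sd=1e-3)
        X = np.column_stack([np.ones(10), np.tile([-0.5, 0.5], 5)])
        res = fit_peb(posts, PEBDesign(X, ("constant", "group")), FIELDS, weak,
                      PEBSettings(beta_var=100.0, optimize_between=False))
        const = res.beta.mean[res.beta.index([f"{f}:constant" for f in FIELDS])]
        grp = res.beta.mean[res.beta.index([f"{f}:group" for f in FIELDS])]
        assert np.allclose(const, shared, atol=5e-3)
        assert np.allclose(grp, 0.0, atol=5e-3)

    def test_matches_dense_joint_oracle(self, rng, prior):
        """The accumulated closed form equals one big joint-Gaussian solve."""
        n = 9
        truths = [rng.normal(0, 0.3, size=3) for _ in range(n)]
        posts = synthetic_posteriors(rng, n, prior, truths)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        s = PEBSettings(optimize_between=False)
        res = fit_peb(posts, PEBDesign(X, ("constant", "grp")), FIELDS, prior, s)

        P = 3
        P0 = np.linalg.inv(prior.cov)
        Sb = np.eye(P) * s.between_var
        Sbeta = np.eye(2 * P) * s.beta_var
        Kall = np.vstack([np.kron(x[None, :], np.eye(P)).reshape(P, 2 * P)
                          for x in X])
        mts, blocks = [], []
        for p in posts:
            Ci = np.linalg.inv(p.cov)
            Pi = Ci - P0
            mts.append(np.linalg.solve(Pi, Ci @ p.mean))
            blocks.append(np.linalg.inv(Pi) + Sb)
        mt = np.concatenate(mts)
        V = np.zeros((n * P, n * P))
        for i, B in enumerate(blocks):
            V[i * P:(i + 1) * P, i * P:(i + 1) * P] = B
        V = V + Kall @ Sbeta @ Kall.T
        beta_or = Sbeta @ Kall.T @ np.linalg.solve(V, mt)
        cov_or = Sbeta - Sbeta @ Kall.T @ np.linalg.solve(V, Kall @ Sbeta)
        assert np.allclose(res.beta.mean, beta_or, rtol=1e-6, atol=1e-8)
        assert np.allclose(res.beta.cov, cov_or, rtol=1e-6, atol=1e-8)

    def test_group_effect_recovery_with_probability(self, rng, prior):
        """A planted +0.4 group shift on p0 is recovered with P > 0.95."""
        n = 12
        truths = []
        for i in range(n):
            base = rng.normal(0, 0.125, size=3)
            for shift in (0.0, 0.4):
                truths.append(base + np.array([shift, 0.0, 0.0]))
        posts = synthetic_posteriors(rng, 2 * n, prior, truths)
        X = np.column_stack([np.ones(2 * n), np.tile([0, 1], n)])
        res = fit_peb(posts, PEBDesign(X, ("constant", "group")), FIELDS, prior)
        i = res.beta.names.index("p0:group")
        assert res.beta.mean[i] > 0.2
        assert res.posterior_probability("p0:group") > 0.95

    def test_row_mismatch_rejected(self, rng, prior):
        posts = synthetic_posteriors(rng, 3, prior, [np.zeros(3)] * 3)
        with pytest.raises(DesignError):
            fit_peb(posts, PEBDesign(np.ones((4, 1)), ("constant",)), FIELDS, prior)

    def test_missing_fields_rejected(self, rng, prior):
        posts = synthetic_posteriors(rng, 3, prior, [np.zeros(3)] * 3)
        with pytest.raises(StructuralError):
            fit_peb(posts, PEBDesign(np.ones((3, 1)), ("constant",)),
                    ("nope",), prior)


class TestBMR:
    def test_identity_under_unchanged_prior(self, rng, prior):
        posts = synthetic_posteriors(rng, 6, prior,
                                     [rng.normal(size=3) for _ in range(6)])
        res = fit_peb(posts, PEBDesign(np.ones((6, 1)), ("constant",)),
                      FIELDS, prior, PEBSettings(optimize_between=False))
        dF, reduced = bayesian_model_reduction(res.beta, res.beta_prior,
                                               res.beta_prior)
        assert abs(dF) < 1e-8
        assert np.allclose(reduced.mean, res.beta.mean, atol=1e-10)

    def test_matches_direct_refit_oracle(self, rng, prior):
        """Prior switching without refitting equals refitting with the
        reduced prior (free energies compared as differences)."""
        n = 8
        truths = [rng.normal(0, 0.3, size=3) for _ in range(n)]
        posts = synthetic_posteriors(rng, n, prior, truths)
        design = PEBDesign(np.column_stack([np.ones(n), rng.normal(size=n)]),
                           ("constant", "grp"))
        s = PEBSettings(optimize_between=False)
        res = fit_peb(posts, design, FIELDS, prior, s)
        rvar = res.beta_prior.variances.copy()
        off = [i for i, nm in enumerate(res.beta.names)
               if nm.endswith(":grp") and not nm.startswith("p0")]
        rvar[off] = s.reduced_var
        reduced_prior = GaussianDensity(res.beta.names, np.zeros(len(rvar)),
                                        np.diag(rvar))
        dF, post_r = bayesian_model_reduction(res.beta, res.beta_prior,
                                              reduced_prior)

        # oracle: dense-joint marginal likelihood under each prior
        P = 3
        P0 = np.linalg.inv(prior.cov)
        Sb = np.eye(P) * s.between_var
        Kall = np.vstack([np.kron(x[None, :], np.eye(P)).reshape(P, 2 * P)
                          for x in design.X])
        mts, blocks = [], []
        for p in posts:
            Ci = np.linalg.inv(p.cov)
            Pi = Ci - P0
            mts.append(np.linalg.solve(Pi, Ci @ p.mean))
            blocks.append(np.linalg.inv(Pi) + Sb)
        mt = np.concatenate(mts)
        Vb = np.zeros((n * P, n * P))
        for i, B in enumerate(blocks):
            Vb[i * P:(i + 1) * P, i * P:(i + 1) * P] = B

        def marginal(prior_var):
            V = Vb + Kall @ np.diag(prior_var) @ Kall.T
            sign, logdet = np.linalg.slogdet(V)
            return -0.5 * (mt @ np.linalg.solve(V, mt) + logdet
                           + len(mt) * np.log(2 * np.pi))

        assert dF == pytest.approx(
            marginal(rvar) - marginal(res.beta_prior.variances), abs=1e-6)


class TestModelComparison:
    def test_softmax_properties(self):
        p = softmax_probabilities([3.0, 3.0])
        assert p == pytest.approx([0.5, 0.5])
        a = softmax_probabilities([1.0, 2.0, 4.0])
        b = softmax_probabilities([101.0, 102.0, 104.0])
        assert np.allclose(a, b)
        assert a.sum() == pytest.approx(1.0)

    def test_planted_field_wins_model_space(self, rng, prior):
        n = 10
        truths = []
        for i in range(n):
            base = rng.normal(0, 0.1, size=3)
            for shift in (0.0, 0.5):
                truths.append(base + np.array([0.0, shift, 0.0]))
        posts = synthetic_posteriors(rng, 2 * n, prior, truths)
        X = np.column_stack([np.ones(2 * n), np.tile([0, 1], n)])
        res = fit_peb(posts, PEBDesign(X, ("constant", "group")), FIELDS, prior)
        mc = model_space_compare(res, {"m0": ["p0"], "m1": ["p1"], "m2": ["p2"],
                                       "all": list(FIELDS)})
        assert mc.table["probability"].sum() == pytest.approx(1.0)
        assert mc.best == "m1"

    def test_empty_hypothesis_rejected(self, rng, prior):
        posts = synthetic_posteriors(rng, 4, prior, [np.zeros(3)] * 4)
        res = fit_peb(posts, PEBDesign(np.ones((4, 1)), ("constant",)),
                      FIELDS, prior)
        with pytest.raises(InvalidParameterError):
            model_space_compare(res, {"bad": []})


class TestBMA:
    def test_single_model_unchanged(self):
        g = GaussianDensity(("a",), np.array([0.3]), np.array([[0.1]]))
        out = bayesian_model_average([g])
        assert np.allclose(out.mean, g.mean) and np.allclose(out.cov, g.cov)

    def test_two_equal_models_mixture_moments(self):
        a = 0.7
        g1 = GaussianDensity(("x",), np.array([+a]), np.array([[0.2]]))
        g2 = GaussianDensity(("x",), np.array([-a]), np.array([[0.2]]))
        out = bayesian_model_average([g1, g2], weights=[0.5, 0.5])
        assert out.mean[0] == pytest.approx(0.0)
        assert out.cov[0, 0] == pytest.approx(0.2 + a ** 2)

    def test_degenerate_weights_select_first_model(self):
        g1 = GaussianDensity(("x",), np.array([1.0]), np.array([[0.1]]))
        g2 = GaussianDensity(("x",), np.array([5.0]), np.array([[0.3]]))
        out = bayesian_model_average([g1, g2], weights=[1.0, 0.0])
        assert np.allclose(out.mean, g1.mean) and np.allclose(out.cov, g1.cov)


class TestCalibration:
    def test_null_effects_rarely_flagged(self):
        """Zero planted effects: the >0.95 flag fires in at most 10% of runs."""
        fields = ("blk_l", "blk_r")
        prior = GaussianDensity(fields, np.zeros(2), np.eye(2) / 64)
        flagged = 0
        n = 12
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            truths = []
            for i in range(n):
                base = r.normal(0, 0.125, size=2)
                truths.extend([base, base])
            posts = synthetic_posteriors(r, 2 * n, prior, truths, like_sd=0.02)
            X = np.column_stack([np.ones(2 * n), np.tile([0, 1], n)])
            res = fit_peb(posts, PEBDesign(X, ("constant", "group")),
                          fields, prior)
            flagged += any(res.posterior_probability(nm) > 0.95
                           for nm in res.beta.names if nm.endswith(":group"))
        assert flagged <= 2

    def test_session_shift_recovered_at_peb_level(self):
        """A -0.125 session shift on both fields, n = 30 pairs: sign recovered
        with high probability from first-level summaries alone."""
        fields = ("blk_l", "blk_r")
        prior = GaussianDensity(fields, np.zeros(2), np.eye(2) / 64)
        r = np.random.default_rng(7)
        truths = []
        n = 30
        for i in range(n):
            base = r.normal(0, 0.125, size=2)
            truths.extend([base, base - 0.125])
        posts = synthetic_posteriors(r, 2 * n, prior, truths, like_sd=0.02)
        X = np.column_stack([np.ones(2 * n), np.tile([0, 1], n)])
        res = fit_peb(posts, PEBDesign(X, ("constant", "group")), fields, prior)
        for nm in ("blk_l:group", "blk_r:group"):
            i = res.beta.names.index(nm)
            assert res.beta.mean[i] < 0
            assert res.posterior_probability(nm) > 0.9
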