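"""Variational Laplace: conjugate oracle equivalence, free energy, recovery."""
import numpy as np
import pytest

from nmda_dcm import (
    ERPDataset, GaussianDensity, MicrocircuitParameters, default_observation,
    default_priors, invert, invert_erp, predict_evoked,
)
from nmda_dcm.errors import InvalidParameterError
from nmda_dcm.vl import InversionResult, InversionSettings, free_energy

LINEAR_SETTINGS = InversionSettings(
    max_iter=60, tol=1e-12, tol_hits=3, damping_init=1e-8,
    update_noise=False, init_log_precision=None,
)


def conjugate_linear(X, y, mu0, S0, lam):
    """Closed-form Bayesian linear regression and its log evidence."""
    P0 = np.linalg.inv(S0)
    H = lam * X.T @ X + P0
    cov = np.linalg.inv(H)
    mean = cov @ (lam * X.T @ y + P0 @ mu0)
    V = np.eye(len(y)) / lam + X @ S0 @ X.T
    r = y - X @ mu0
    sign, logdet = np.linalg.slogdet(V)
    evidence = -0.5 * (r @ np.linalg.solve(V, r) + logdet
                       + len(y) * np.log(2 * np.pi))
    return mean, cov, evidence


def run_linear_instance(seed, n=40, p=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    theta_true = rng.normal(size=p)
    lam = 4.0
    y = X @ theta_true + rng.normal(scale=1 / np.sqrt(lam), size=n)
    mu0 = rng.normal(scale=0.3, size=p)
    S0 = np.diag(rng.uniform(0.2, 2.0, size=p))
    priors = GaussianDensity(tuple(f"w{i}" for i in range(p)), mu0, S0)
    settings = InversionSettings(**{**LINEAR_SETTINGS.__dict__,
                                    "init_log_precision": np.log(lam)})
    res = invert(y, lambda th: X @ th, priors, settings=settings)
    mean, cov, evidence = conjugate_linear(X, y, mu0, S0, lam)
    return res, mean, cov, evidence


class TestConjugateOracle:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_posterior_and_evidence_match_closed_form(self, seed):
        res, mean, cov, evidence = run_linear_instance(seed)
        assert np.allclose(res.posterior.mean, mean, rtol=1e-6, atol=1e-8)
        assert np.allclose(res.posterior.cov, cov, rtol=1e-6, atol=1e-9)
        assert res.free_energy == pytest.approx(evidence, rel=1e-6, abs=1e-5)

    def test_trace_non_decreasing(self):
        res, *_ = run_linear_instance(21)
        assert np.all(np.diff(res.f_trace) >= -1e-9)


class TestFreeEnergyFunction:
    def test_zero_complexity_when_posterior_equals_prior(self, rng):
        names = ("a", "b")
        prior = GaussianDensity(names, rng.normal(size=2), np.diag([0.5, 1.5]))
        y = rng.normal(size=10)
        parts = free_energy(y, np.zeros(10), None, prior, prior,
                            np.array([0.0]), np.zeros(10, dtype=int))
        assert parts.complexity == pytest.approx(0.0, abs=1e-12)

    def test_complexity_penalty_grows_as_prior_shrinks(self, rng):
        names = ("a",)
        post = GaussianDensity(names, np.array([0.8]), np.array([[0.01]]))
        y = rng.normal(size=6)
        pred = y.copy()
        kls = []
        for v in (1.0, 0.25, 0.05):
            prior = GaussianDensity(names, np.zeros(1), np.array([[v]]))
            parts = free_energy(y, pred, None, post, prior,
                                np.array([0.0]), np.zeros(6, dtype=int))
            kls.append(-parts.complexity)
        assert kls[0] < kls[1] < kls[2]

    def test_all_masked_priors_rejected(self):
        priors = GaussianDensity(("a",), np.zeros(1), np.zeros((1, 1)))
        with pytest.raises(InvalidParameterError):
            invert(np.zeros(4), lambda th: np.zeros(4), priors)


@pytest.fixture(scope="module")
def erp_fixture():
    config = __import__("nmda_dcm").ModelConfig()
    obs = default_observation()
    truth = {"blk_l": 0.5, "b_l": -0.4, "b_r": -0.4}
    clean = predict_evoked(MicrocircuitParameters(config, truth), obs)
    rng = np.random.default_rng(99)
    noisy = clean + 0.02 * rng.standard_normal(clean.shape)
    ds = ERPDataset("s01", "a", config.times(),
                    {"standard": noisy[:, :, 0], "deviant": noisy[:, :, 1]})
    return config, obs, truth, ds


class TestERPInversion:
    def test_blockade_recovery_single_subject(self, erp_fixture):
        """One region's blockade raised to +0.5: the posterior localises it."""
        config, obs, truth, ds = erp_fixture
        priors = default_priors(("blk_l", "blk_r", "b_l", "b_r"))
        res = invert_erp(ds, obs, config, priors, InversionSettings())
        i = res.posterior.names.index("blk_l")
        j = res.posterior.names.index("blk_r")
        assert abs(res.posterior.mean[i] - truth["blk_l"]) < 0.2
        assert abs(res.posterior.mean[j]) < 0.2
        assert np.all(np.diff(res.f_trace) >= -1e-9)
        assert np.all(np.linalg.eigvalsh(res.posterior.cov) > 0)
        # masked latents stay clamped and are reported as fixed
        assert "lgain" in res.fixed and "lgain" not in res.posterior.names

    def test_prediction_sensitive_to_single_region_blockade(self, config, obs):
        base = MicrocircuitParameters(config, {"b_l": -0.4, "b_r": -0.4})
        pert = MicrocircuitParameters(
            config, {"b_l": -0.4, "b_r": -0.4, "blk_l": 0.05})
        d = predict_evoked(pert, obs) - predict_evoked(base, obs)
        assert np.abs(d).max() > 1e-4

    def test_self_consistency_at_prior_mean_with_clean_data(self, config, obs):
        clean = predict_evoked(MicrocircuitParameters(config, {}), obs)
        ds = ERPDataset("s0", "a", config.times(),
                        {"standard": clean[:, :, 0], "deviant": clean[:, :, 1]})
        priors = default_priors(("blk_l", "blk_r"))
        res = invert_erp(ds, obs, config, priors, InversionSettings(max_iter=8))
        assert np.max(np.abs(res.posterior.mean)) < 1e-6
        assert res.converged

    def test_result_json_round_trip(self, tmp_path, erp_fixture):
        config, obs, _, ds = erp_fixture
        priors = default_priors(("blk_l", "blk_r"))
        res = invert_erp(ds, obs, config, priors, InversionSettings(max_iter=4))
        res.to_json(tmp_path / "r.json")
        back = InversionResult.from_json(tmp_path / "r.json")
        assert np.allclose(back.posterior.mean, res.posterior.mean)
        assert np.allclose(back.predicted, res.predicted)
        assert back.f_trace == [float(v) for v in res.f_trace]
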