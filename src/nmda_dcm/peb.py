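"""Parametric empirical Bayes over first-level posteriors.

Each subject/session contributes a Gaussian posterior over a chosen subset of
latents ("fields").  Removing the first-level prior from each posterior leaves
a Gaussian likelihood summary; a general linear model over rows (subjects or
sessions) with design matrix X then yields closed-form Gaussian inference on
the group effects beta, a second-level free energy for model comparison, and
empirical-Bayes re-estimates of every subject's parameters under the group
model.  Hypotheses about *which* fields carry an effect are scored by Bayesian
model reduction (switching priors without refitting) and combined by Bayesian
model averaging.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .densities import GaussianDensity
from .errors import DesignError, InvalidParameterError, StructuralError


@dataclass
class PEBSettings:
    beta_var: float = 1.0 / 16       # prior variance of each second-level effect
    between_var: float = 1.0 / 16    # between-row residual variance per field
    optimize_between: bool = True    # empirical-Bayes scale on the residual variance
    gamma_bounds: tuple = (-8.0, 8.0)
    precision_clip: float = 1e-8     # floor on likelihood-precision eigenvalues
    reduced_var: float = 1e-8        # "switched off" prior variance in BMR


@dataclass
class PEBDesign:
    """Second-level design: rows = subjects/sessions, columns = regressors."""

    X: np.ndarray
    regressor_names: tuple

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.regressor_names = tuple(self.regressor_names)
        if self.X.shape[1] != len(self.regressor_names):
            raise DesignError("one name per design column required")
        if not np.all(np.isfinite(self.X)):
            raise DesignError("design matrix must be finite")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("design matrix is rank deficient")

    @classmethod
    def from_table(cls, table: pd.DataFrame, regressors: Sequence[str],
                   mean_center: Sequence[str] = (), standardize: Sequence[str] = ()):
        """Build a design from a covariate table; first column is the constant.

        ``mean_center``/``standardize`` name covariates to centre (and scale to
        unit standard deviation) across rows, as for an MMSE or scan-interval
        regressor.
        """
        cols = [np.ones(len(table))]
        for name in regressors:
            if name not in table.columns:
                raise DesignError(f"covariate {name!r} not in table")
            col = table[name].to_numpy(dtype=float)
            if name in mean_center or name in standardize:
                col = col - col.mean()
            if name in standardize:
                sd = col.std(ddof=0)
                if sd == 0:
                    raise DesignError(f"covariate {name!r} has zero variance")
                col = col / sd
            cols.append(col)
        return cls(np.column_stack(cols), ("constant",) + tuple(regressors))


def _beta_names(fields, regressors) -> tuple:
    return tuple(f"{f}:{r}" for r in regressors for f in fields)


@dataclass
class PEBResult:
    """Posterior over group effects plus everything BMR/BMA need."""

    beta: GaussianDensity            # posterior over beta (field x regressor)
    beta_prior: GaussianDensity
    free_energy: float
    design: PEBDesign
    fields: tuple
    subject_expectations: pd.DataFrame   # empirical-Bayes re-estimates per row
    between_log_scale: float
    settings: PEBSettings

    def posterior_probability(self, name: str) -> float:
        """Probability that the named effect shares the sign of its mean."""
        i = self.beta.index([name])[0]
        mu, sd = self.beta.mean[i], np.sqrt(self.beta.cov[i, i])
        if sd == 0:
            return 1.0
        return float(norm.cdf(abs(mu) / sd))


def _likelihood_summaries(posteriors, fields, first_level_priors, clip):
    """Remove the first-level prior from each posterior: (h_i, Pi_i) pairs."""
    pr = first_level_priors.marginal(fields)
    P0 = np.linalg.inv(pr.cov)
    out = []
    for post in posteriors:
        m = post.marginal(fields)
        Ci = np.linalg.inv(m.cov)
        Pi = 0.5 * ((Ci - P0) + (Ci - P0).T)
        w, V = np.linalg.eigh(Pi)
        w = np.maximum(w, clip)
        Pi = (V * w) @ V.T
        h = Ci @ m.mean - P0 @ pr.mean
        out.append((h, Pi))
    return out


def _fit_closed_form(summaries, X, Sigma_b, Sigma_beta):
    """Exact Gaussian algebra for the two-level linear model.

    Returns (beta mean, beta covariance, free energy up to a constant shared
    by all second-level prior choices).
    """
    P = summaries[0][1].shape[0]
    R = X.shape[1]
    D = R * P
    Pb = np.linalg.inv(Sigma_beta)
    A = Pb.copy()
    b = np.zeros(D)
    const = 0.0
    resid_terms = []
    for (h, Pi), x in zip(summaries, X):
        mt = np.linalg.solve(Pi, h)
        W = np.linalg.inv(np.linalg.inv(Pi) + Sigma_b)   # marginal precision of m-tilde
        K = np.kron(x[None, :], np.eye(P)).reshape(P, D)
        A += K.T @ W @ K
        b += K.T @ (W @ mt)
        sgn, logdet = np.linalg.slogdet(W)
        const += 0.5 * logdet - 0.5 * P * np.log(2 * np.pi) - 0.5 * mt @ W @ mt
        resid_terms.append((mt, W, K))
    cov_beta = np.linalg.inv(A)
    cov_beta = 0.5 * (cov_beta + cov_beta.T)
    beta = cov_beta @ b
    sgn, logdet_cov = np.linalg.slogdet(cov_beta)
    sgn0, logdet_prior = np.linalg.slogdet(Sigma_beta)
    F = const + 0.5 * (b @ cov_beta @ b) + 0.5 * logdet_cov - 0.5 * logdet_prior
    return beta, cov_beta, float(F)


def fit_peb(posteriors: Sequence[GaussianDensity], design: PEBDesign,
            fields: Sequence[str], first_level_priors: GaussianDensity,
            settings: PEBSettings | None = None,
            row_index: pd.DataFrame | None = None) -> PEBResult:
    """Second-level empirical-Bayes GLM over subject posteriors.

    ``fields`` selects the latents taken to the second level; every posterior
    must contain them.  ``row_index`` (optional) carries subject/session labels
    for the returned expectation table.
    """
    s = settings or PEBSettings()
    fields = tuple(fields)
    if len(posteriors) != design.X.shape[0]:
        raise DesignError(
            f"{len(posteriors)} posteriors but {design.X.shape[0]} design rows"
        )
    if not fields:
        raise InvalidParameterError("fields must be non-empty")
    summaries = _likelihood_summaries(posteriors, fields, first_level_priors,
                                      s.precision_clip)
    P = len(fields)
    R = design.X.shape[1]
    Sigma_beta = np.eye(R * P) * s.beta_var
    Sb0 = np.eye(P) * s.between_var

    def F_of(gamma: float) -> tuple:
        return _fit_closed_form(summaries, design.X, np.exp(gamma) * Sb0, Sigma_beta)

    gamma = 0.0
    if s.optimize_between:
        res = minimize_scalar(lambda g: -F_of(g)[2], bounds=s.gamma_bounds,
                              method="bounded", options={"xatol": 1e-3})
        gamma = float(res.x)
    beta, cov_beta, F = F_of(gamma)
    Sigma_b = np.exp(gamma) * Sb0
    Pb_inv = np.linalg.inv(Sigma_b)

    # empirical-Bayes re-estimates of each row's parameters under the group model
    rows = []
    for (h, Pi), x in zip(summaries, design.X):
        K = np.kron(x[None, :], np.eye(P)).reshape(P, R * P)
        prior_mean = K @ beta
        Pp = Pi + Pb_inv
        mean = np.linalg.solve(Pp, h + Pb_inv @ prior_mean)
        var = np.diag(np.linalg.inv(Pp))
        rows.append(np.concatenate([mean, var]))
    cols = [f"{f}" for f in fields] + [f"{f}_var" for f in fields]
    expectations = pd.DataFrame(rows, columns=cols)
    if row_index is not None:
        expectations = pd.concat(
            [row_index.reset_index(drop=True), expectations], axis=1)

    names = _beta_names(fields, design.regressor_names)
    return PEBResult(
        beta=GaussianDensity(names, beta, cov_beta),
        beta_prior=GaussianDensity(names, np.zeros(len(names)), Sigma_beta),
        free_energy=F,
        design=design,
        fields=fields,
        subject_expectations=expectations,
        between_log_scale=gamma,
        settings=s,
    )


def bayesian_model_reduction(posterior: GaussianDensity, prior: GaussianDensity,
                             reduced_prior: GaussianDensity):
    """Re-score a Gaussian model under a switched prior without refitting.

    Returns (delta log-evidence, reduced posterior).  With an unchanged prior
    the delta is 0 and the posterior is returned unchanged.
    """
    if posterior.names != prior.names or prior.names != reduced_prior.names:
        raise StructuralError("posterior, prior and reduced prior must share names")
    Pq = np.linalg.inv(posterior.cov)
    P0 = np.linalg.inv(prior.cov)
    P0r = np.linalg.inv(reduced_prior.cov)
    Pr = Pq + P0r - P0
    w = np.linalg.eigvalsh(0.5 * (Pr + Pr.T))
    if np.min(w) <= 0:
        raise InvalidParameterError("reduced model is improper (non-PD precision)")
    hr = Pq @ posterior.mean + P0r @ reduced_prior.mean - P0 @ prior.mean
    cov_r = np.linalg.inv(Pr)
    cov_r = 0.5 * (cov_r + cov_r.T)
    mu_r = cov_r @ hr

    def _logdet(M):
        return np.linalg.slogdet(M)[1]

    dF = 0.5 * (_logdet(P0r) - _logdet(P0) + _logdet(Pq) - _logdet(Pr)) \
        + 0.5 * (mu_r @ Pr @ mu_r - posterior.mean @ Pq @ posterior.mean
                 - reduced_prior.mean @ P0r @ reduced_prior.mean
                 + prior.mean @ P0 @ prior.mean)
    return float(dF), GaussianDensity(posterior.names, mu_r, cov_r)


def softmax_probabilities(free_energies) -> np.ndarray:
    f = np.asarray(free_energies, dtype=float)
    f = f - f.max()
    w = np.exp(f)
    return w / w.sum()


@dataclass
class ModelComparison:
    table: pd.DataFrame                  # name, free_energy, delta_f, probability
    posteriors: list                     # reduced posterior per model

    @property
    def best(self) -> str:
        return str(self.table.loc[self.table["probability"].idxmax(), "model"])


def _reduced_prior_for(result: PEBResult, keep_fields, restrict_regressors,
                       reduced_var: float) -> GaussianDensity:
    keep = set(keep_fields)
    var = result.beta_prior.variances
    names = result.beta_prior.names
    out = var.copy()
    for i, name in enumerate(names):
        fld, reg = name.rsplit(":", 1)
        if reg in restrict_regressors and fld not in keep:
            out[i] = reduced_var
    return GaussianDensity(names, result.beta_prior.mean, np.diag(out))


def model_space_compare(result: PEBResult, hypotheses: dict,
                        restrict_regressors: Sequence[str] | None = None
                        ) -> ModelComparison:
    """Score named field-subset hypotheses by BMR + softmax.

    Each hypothesis allows the (non-constant) regressor effects only on its
    fields; constants are always free.  ``hypotheses`` maps model name -> list
    of field names.
    """
    if not hypotheses:
        raise InvalidParameterError("at least one hypothesis required")
    if restrict_regressors is None:
        restrict_regressors = tuple(r for r in result.design.regressor_names
                                    if r != "constant")
    rows = []
    posts = []
    for name, fields_kept in hypotheses.items():
        if not fields_kept:
            raise InvalidParameterError(f"hypothesis {name!r} is empty")
        unknown = set(fields_kept) - set(result.fields)
        if unknown:
            raise StructuralError(f"hypothesis {name!r} has unknown fields {unknown}")
        rp = _reduced_prior_for(result, fields_kept, restrict_regressors,
                                result.settings.reduced_var)
        dF, post = bayesian_model_reduction(result.beta, result.beta_prior, rp)
        rows.append((name, result.free_energy + dF, dF))
        posts.append(post)
    df = pd.DataFrame(rows, columns=["model", "free_energy", "delta_f"])
    df["probability"] = softmax_probabilities(df["free_energy"].to_numpy())
    return ModelComparison(df, posts)


def bayesian_model_average(posteriors: Sequence[GaussianDensity],
                           log_evidences=None, weights=None) -> GaussianDensity:
    """Moment-matched mixture of model posteriors.

    Weights come from ``softmax(log_evidences)`` unless given explicitly.  The
    mixture covariance includes the between-model spread of the means.
    """
    posteriors = list(posteriors)
    if not posteriors:
        raise InvalidParameterError("at least one model required")
    names = posteriors[0].names
    if any(p.names != names for p in posteriors):
        raise StructuralError("all model posteriors must share the parameter layout")
    if weights is None:
        if log_evidences is None:
            weights = np.full(len(posteriors), 1.0 / len(posteriors))
        else:
            weights = softmax_probabilities(log_evidences)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(posteriors) or abs(weights.sum() - 1.0) > 1e-8:
        raise InvalidParameterError("weights must match models and sum to 1")
    mean = sum(w * p.mean for w, p in zip(weights, posteriors))
    cov = sum(w * (p.cov + np.outer(p.mean - mean, p.mean - mean))
              for w, p in zip(weights, posteriors))
    return GaussianDensity(names, mean, cov)


def all_combinations_bma(result: PEBResult, parameter_sets: dict,
                         restrict_regressors: Sequence[str] | None = None
                         ) -> tuple[GaussianDensity, pd.DataFrame]:
    """BMA over the 2^k on/off combinations of named parameter sets.

    The all-off model keeps only the constants.  Returns the averaged posterior
    over beta and the per-combination evidence table.
    """
    if restrict_regressors is None:
        restrict_regressors = tuple(r for r in result.design.regressor_names
                                    if r != "constant")
    set_names = list(parameter_sets)
    rows = []
    posts = []
    for mask in range(2 ** len(set_names)):
        kept = []
        for j, sn in enumerate(set_names):
            if mask >> j & 1:
                kept.extend(parameter_sets[sn])
        rp = _reduced_prior_for(result, kept, restrict_regressors,
                                result.settings.reduced_var)
        dF, post = bayesian_model_reduction(result.beta, result.beta_prior, rp)
        label = "+".join(sn for j, sn in enumerate(set_names) if mask >> j & 1) or "null"
        rows.append((label, result.free_energy + dF))
        posts.append(post)
    df = pd.DataFrame(rows, columns=["model", "free_energy"])
    df["probability"] = softmax_probabilities(df["free_energy"].to_numpy())
    bma = bayesian_model_average(posts, log_evidences=df["free_energy"].to_numpy())
    return bma, df
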