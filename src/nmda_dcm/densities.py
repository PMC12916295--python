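"""Named multivariate Gaussian densities.

Priors and posteriors at both analysis levels share this shape: a mean and a
covariance over an ordered, named parameter vector.  Masked (fixed) parameters
are represented by zero prior variance, so positive definiteness is checked on
demand rather than at construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, StructuralError


@dataclass
class GaussianDensity:
    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            raise StructuralError("parameter names must be unique")
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim == 1:  # diagonal shorthand
            self.cov = np.diag(self.cov)
        p = len(self.names)
        if self.mean.shape != (p,) or self.cov.shape != (p, p):
            raise StructuralError(
                f"inconsistent shapes: {p} names, mean {self.mean.shape}, cov {self.cov.shape}"
            )
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.cov))):
            raise InvalidParameterError("non-finite mean or covariance")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise InvalidParameterError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)

    # -- access ---------------------------------------------------------
    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.cov).copy()

    def index(self, names) -> np.ndarray:
        try:
            return np.array([self.names.index(n) for n in names], dtype=int)
        except ValueError as err:
            raise StructuralError(f"unknown parameter name: {err}") from None

    def marginal(self, names) -> "GaussianDensity":
        idx = self.index(names)
        return GaussianDensity(tuple(names), self.mean[idx], self.cov[np.ix_(idx, idx)])

    def validate_pd(self) -> None:
        """Raise unless the covariance is symmetric positive definite."""
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError:
            raise InvalidParameterError("covariance is not positive definite") from None

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianDensity":
        return cls(tuple(d["names"]), np.array(d["mean"]), np.array(d["cov"]))
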