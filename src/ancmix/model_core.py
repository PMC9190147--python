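"""Probability model for the marginalized Poisson-Poisson (MPois-Pois) mixture.

The population is a two-component mixture of Poisson distributions: with
probability ``pi`` a subject belongs to component 1 with mean ``mu1``, and
with probability ``1 - pi`` to component 2 with mean ``mu2``.  The
*marginalized* parameterization regresses the population-wide (marginal)
mean ``mu = pi*mu1 + (1-pi)*mu2`` on covariates,

    log(mu_i)  = x_i' beta,
    log(mu1_i) = z_i' alpha,
    logit(pi)  = tau,

and recovers the second component's mean by substitution,
``mu2_i = (mu_i - pi*mu1_i) / (1 - pi)``, which must be positive for the
parameter set to be valid.  Coefficients ``beta`` then act directly on the
marginal mean, so ``exp(beta_j)`` is an incidence density ratio (IDR).

This module houses the mixture pmf, the marginal moments, the eta function
(the substituted ``mu2`` on its natural scale), and the marginalized
log-likelihood, all computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logsumexp

__all__ = [
    "DesignData",
    "MarginalizedParams",
    "MixtureMoments",
    "mixture_log_pmf",
    "mu2_from_marginal",
    "marginal_moments",
    "eta",
    "marginalized_loglik",
]

#: Base of the penalty returned for parameter sets with any eta_i <= 0.
PENALTY_BASE = -1.0e10


@dataclass
class DesignData:
    """Outcome vector with marginal-mean and component-mean design matrices.

    ``X`` (n x p1) carries the covariates of the marginal mean, ``Z``
    (n x p2) those of component 1's mean.  Both must include a leading
    intercept column of ones.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    row_ids: np.ndarray | None = None
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        n = self.y.shape[0]
        if self.X.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("X and Z must be 2-d design matrices")
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X and Z must have one row per outcome")
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("outcome must be non-negative integer counts")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Z).all()):
            raise ValueError("design matrices contain missing/non-finite entries")
        if not np.all(self.X[:, 0] == 1.0) or not np.all(self.Z[:, 0] == 1.0):
            raise ValueError("first column of X and Z must be an intercept of ones")
        if self.row_ids is None:
            self.row_ids = np.arange(n)
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]
        if not self.z_names:
            self.z_names = [f"z{j}" for j in range(self.Z.shape[1])]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p1(self) -> int:
        return self.X.shape[1]

    @property
    def p2(self) -> int:
        return self.Z.shape[1]


@dataclass
class MarginalizedParams:
    """Full parameter vector (beta, alpha, tau) of the marginalized model."""

    beta: np.ndarray
    alpha: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.tau = float(self.tau)
        if not (
            np.isfinite(self.beta).all()
            and np.isfinite(self.alpha).all()
            and np.isfinite(self.tau)
        ):
            raise ValueError("parameters must be finite")

    @property
    def pi(self) -> float:
        """Mixing proportion pi = e^tau / (1 + e^tau)."""
        return float(expit(self.tau))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha, [self.tau]])

    @classmethod
    def unpack(cls, theta: np.ndarray, p1: int, p2: int) -> "MarginalizedParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape[0] != p1 + p2 + 1:
            raise ValueError("parameter vector has wrong length")
        return cls(beta=theta[:p1], alpha=theta[p1 : p1 + p2], tau=theta[-1])


@dataclass(frozen=True)
class MixtureMoments:
    """Marginal mean/variance alongside the two component means."""

    mu: float
    mu1: float
    mu2: float
    var: float


def _check_count(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("y must be a non-negative integer count")
    return arr


def mixture_log_pmf(y, mu1, mu2, pi) -> np.ndarray | float:
    """Log of the two-component Poisson mixture pmf.

    ``log[ pi * Pois(y; mu1) + (1 - pi) * Pois(y; mu2) ]`` evaluated by
    log-sum-exp, so it is stable for counts and rates far beyond the data's
    range.  ``pi`` may be 1 (pure first component); ``pi = 0`` is handled by
    the symmetric degenerate branch.
    """
    yv = _check_count(y)
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    if np.any(mu1 <= 0) or np.any(mu2 <= 0):
        raise ValueError("component means must be positive")
    pi = float(pi)
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    log_f1 = -mu1 + yv * np.log(mu1) - gammaln(yv + 1.0)
    log_f2 = -mu2 + yv * np.log(mu2) - gammaln(yv + 1.0)
    if pi == 1.0:
        out = log_f1
    elif pi == 0.0:
        out = log_f2
    else:
        stacked = np.stack(
            [np.log(pi) + log_f1, np.log1p(-pi) + log_f2], axis=0
        )
        out = logsumexp(stacked, axis=0)
    return float(out) if np.isscalar(y) and out.ndim == 0 else out


def mu2_from_marginal(mu, mu1, pi):
    """Second-component mean implied by the marginal mean.

    Solves ``mu = pi*mu1 + (1-pi)*mu2`` for ``mu2``.  A non-positive result
    means the (mu, mu1, pi) combination lies outside the mixture's support
    and raises a ValueError.
    """
    pi = float(pi)
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must lie strictly inside (0, 1)")
    mu = np.asarray(mu, dtype=float)
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = (mu - pi * mu1) / (1.0 - pi)
    if np.any(mu2 <= 0):
        raise ValueError(
            "implied mu2 <= 0: marginal mean too small for this (mu1, pi)"
        )
    return float(mu2) if mu2.ndim == 0 else mu2


def marginal_moments(mu1: float, mu2: float, pi: float) -> MixtureMoments:
    """Closed-form marginal mean and variance of the mixture.

    ``E(Y) = pi*mu1 + (1-pi)*mu2`` and
    ``Var(Y) = E(Y) + pi*(1-pi)*(mu1-mu2)^2``; the second term is the
    (always non-negative) overdispersion contributed by the mixing.
    """
    mu1 = float(mu1)
    mu2 = float(mu2)
    pi = float(pi)
    if mu1 <= 0 or mu2 <= 0:
        raise ValueError("component means must be positive")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    mu = pi * mu1 + (1.0 - pi) * mu2
    var = mu + pi * (1.0 - pi) * (mu1 - mu2) ** 2
    return MixtureMoments(mu=mu, mu1=mu1, mu2=mu2, var=var)


def eta(params: MarginalizedParams, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """The eta function: e^{x'beta}(1 + e^tau) - e^tau e^{z'alpha}.

    Because (1 + e^tau)(1 - pi) = 1, eta_i equals the substituted second
    component mean mu2_i; validity of a parameter set is eta_i > 0 for all i.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    et = np.exp(params.tau)
    return np.exp(X @ params.beta) * (1.0 + et) - et * np.exp(Z @ params.alpha)


def marginalized_loglik(
    params: MarginalizedParams, data: DesignData, return_validity: bool = False
):
    """Observed-data log-likelihood of the marginalized mixture.

    For valid parameters (all ``eta_i > 0``) this equals the latent-class
    mixture log-likelihood evaluated at ``(pi, mu1_i, mu2_i = eta_i)``, with
    the inner bracket combined by log-sum-exp.  When any ``eta_i <= 0`` the
    parameter set lies outside the model's support and a large negative
    penalized value ``PENALTY_BASE - sum(max(0, -eta_i))`` is returned
    instead of raising, so an unconstrained quasi-Newton line search can
    retreat smoothly.

    With ``return_validity=True`` also returns the number of invalid rows.
    """
    eta_i = eta(params, data.X, data.Z)
    n_invalid = int(np.sum(eta_i <= 0))
    if n_invalid > 0:
        value = PENALTY_BASE - float(np.sum(np.maximum(0.0, -eta_i)))
        return (value, n_invalid) if return_validity else value
    tau = params.tau
    log_mu1 = data.Z @ params.alpha
    mu1 = np.exp(log_mu1)
    y = data.y
    # bracket terms of the likelihood display, in log space
    log_t1 = tau - mu1 + y * log_mu1
    log_t2 = -eta_i + y * np.log(eta_i)
    bracket = logsumexp(np.stack([log_t1, log_t2], axis=0), axis=0)
    # log(1 + e^tau) via logaddexp keeps large |tau| overflow-free
    ll = float(np.sum(bracket - np.logaddexp(0.0, tau) - gammaln(y + 1.0)))
    return (ll, 0) if return_validity else ll
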