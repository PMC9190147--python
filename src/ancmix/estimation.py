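"""Maximum-likelihood fitting of the marginalized mixture and baselines.

The marginalized likelihood is maximized jointly over (beta, alpha, tau) by
BFGS with numerical gradients; outside the valid region (any eta_i <= 0) the
objective returns a smooth penalty so the line search retreats.  Standard
errors come from the numerically differentiated observed information.
Poisson and NB2 negative-binomial regressions are fitted on the same data
for AIC comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .model_core import (
    PENALTY_BASE,
    DesignData,
    MarginalizedParams,
    marginalized_loglik,
)

__all__ = [
    "FitResult",
    "fit_mpoispois",
    "observed_information_se",
    "fit_poisson",
    "fit_negbin",
    "mixing_proportion",
]


@dataclass
class FitResult:
    """Estimates, SEs and fit statistics for one fitted model."""

    model_name: str
    params: np.ndarray
    se: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    param_names: list[str] = field(default_factory=list)
    validity_violations: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not self.param_names:
            self.param_names = [f"theta{j}" for j in range(self.params.size)]

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def to_frame(self) -> pd.DataFrame:
        """Flat per-parameter table with Wald z, p and 95% CI."""
        z = self.params / self.se
        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.params,
                "se": self.se,
                "z": z,
                "p": p,
                "ci_low": self.params - 1.96 * self.se,
                "ci_high": self.params + 1.96 * self.se,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_name,
                "estimates": dict(zip(self.param_names, self.params.tolist())),
                "se": dict(zip(self.param_names, self.se.tolist())),
                "loglik": self.loglik,
                "aic": self.aic,
                "n_params": self.n_params,
                "n_obs": self.n_obs,
                "converged": self.converged,
                "validity_violations": self.validity_violations,
                "message": self.message,
            },
            indent=2,
        )


def observed_information_se(loglik_fn, theta_hat: np.ndarray) -> np.ndarray:
    """SEs from the inverse negative numerical Hessian at the optimum.

    The Hessian is built from central second differences with per-coordinate
    step ``h_j = max(1e-5, 1e-5 * |theta_j|)``.  If the negative Hessian is
    not positive definite the affected components get NaN SEs and a warning
    is issued rather than failing the fit.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    k = theta_hat.size
    h = np.maximum(1e-5, 1e-5 * np.abs(theta_hat))
    H = np.empty((k, k))
    f0 = loglik_fn(theta_hat)

    def f_at(shift):
        return loglik_fn(theta_hat + shift)

    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f_at(ei) - 2.0 * f0 + f_at(-ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f_at(ei + ej) - f_at(ei - ej) - f_at(-ei + ej) + f_at(-ei - ej)
            ) / (4.0 * h[i] * h[j])

    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; SEs set to NaN")
        return np.full(k, np.nan)
    diag = np.diag(cov).copy()
    bad = diag <= 0
    if bad.any():
        warnings.warn(
            "observed information not positive definite; NaN SEs for "
            f"{int(bad.sum())} component(s)"
        )
        diag[bad] = np.nan
    return np.sqrt(diag)


def fit_mpoispois(
    data: DesignData,
    starts: MarginalizedParams,
    gtol: float = 1e-6,
    max_iter: int = 1000,
    compute_se: bool = True,
) -> FitResult:
    """Quasi-Newton maximization of the marginalized mixture likelihood.

    Starting values must be valid (all eta_i > 0); the optimum is checked to
    be in the valid region and to not degrade the starting log-likelihood.
    """
    p1, p2 = data.p1, data.p2
    ll_start, n_bad = marginalized_loglik(starts, data, return_validity=True)
    if n_bad > 0:
        raise ValueError(
            f"starting values invalid: {n_bad} rows with eta <= 0; re-initialize"
        )

    def negll(theta):
        return -marginalized_loglik(
            MarginalizedParams.unpack(theta, p1, p2), data
        )

    res = minimize(
        negll,
        starts.pack(),
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    theta_hat = res.x
    params_hat = MarginalizedParams.unpack(theta_hat, p1, p2)
    ll_hat, n_bad = marginalized_loglik(params_hat, data, return_validity=True)
    if ll_hat <= PENALTY_BASE / 2:
        raise ValueError(
            "optimum lies in the penalized (eta <= 0) region; re-initialize "
            "from different starting values"
        )
    # with numerical gradients BFGS can stop on "precision loss" at a point
    # whose gradient is already negligible; accept that as convergence
    grad_ok = bool(np.max(np.abs(res.jac)) < 1e-2)
    converged = (bool(res.success) or grad_ok) and n_bad == 0
    if ll_hat < ll_start - 1e-6:
        converged = False
    se = (
        observed_information_se(lambda t: -negll(t), theta_hat)
        if compute_se
        else np.full(theta_hat.size, np.nan)
    )
    names = (
        [f"beta[{nm}]" for nm in data.x_names]
        + [f"alpha[{nm}]" for nm in data.z_names]
        + ["tau"]
    )
    return FitResult(
        model_name="MPois-Pois",
        params=theta_hat,
        se=se,
        loglik=ll_hat,
        n_params=p1 + p2 + 1,
        n_obs=data.n,
        converged=converged,
        param_names=names,
        validity_violations=n_bad,
        message=str(res.message),
    )


def fit_poisson(data: DesignData) -> FitResult:
    """Log-linear Poisson regression baseline."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(data.y, data.X, family=sm.families.Poisson()).fit()
    params = np.asarray(res.params)
    return FitResult(
        model_name="Poisson",
        params=params,
        se=np.asarray(res.bse),
        loglik=float(res.llf),
        n_params=data.p1,
        n_obs=data.n,
        converged=True,
        param_names=[f"beta[{nm}]" for nm in data.x_names],
    )


def fit_negbin(data: DesignData) -> FitResult:
    """NB2 negative-binomial regression baseline (log link).

    If the estimated dispersion collapses to equidispersion the model is not
    distinguishable from Poisson and the Poisson fit is returned with a
    warning (parameter count still p1, as the NB reduced).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(data.y, data.X, loglike_method="nb2")
            res = model.fit(disp=False, maxiter=200)
            alpha_hat = float(res.params[-1])
        except Exception:
            alpha_hat = 0.0
            res = None
    if res is None or alpha_hat < 1e-6:
        warnings.warn("NB dispersion ~ 0 (equidispersion); falling back to Poisson")
        pois = fit_poisson(data)
        pois.model_name = "NegBin(->Poisson)"
        return pois
    names = [f"beta[{nm}]" for nm in data.x_names] + ["alpha_dispersion"]
    return FitResult(
        model_name="NegBin",
        params=np.asarray(res.params),
        se=np.asarray(res.bse),
        loglik=float(res.llf),
        n_params=data.p1 + 1,
        n_obs=data.n,
        converged=bool(res.mle_retvals.get("converged", True)),
        param_names=names,
    )


def mixing_proportion(tau_hat: float, se_tau: float):
    """Mixing proportion on the probability scale with delta-method SE.

    ``pi = expit(tau)``, ``se(pi) = pi (1 - pi) se(tau)``; the z statistic
    reported for the table is pi / se(pi) with a two-sided normal p-value.
    """
    if se_tau <= 0:
        raise ValueError("se_tau must be positive")
    pi_hat = float(expit(tau_hat))
    se_pi = pi_hat * (1.0 - pi_hat) * float(se_tau)
    z = pi_hat / se_pi
    p = 2.0 * float(norm.sf(abs(z)))
    return pi_hat, se_pi, z, p
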