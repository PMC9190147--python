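"""Starting values for the marginalized mixture fit.

Two separate devices, as in standard practice for this model family:

* ``em_poisson_mixture`` fits the plain (latent-class) two-component Poisson
  regression mixture by EM and exports component 1's coefficients as the
  start for ``alpha`` and logit of the fitted mixing weight as the start for
  ``tau``.
* ``fit_mzip`` fits a marginalized zero-inflated Poisson — a ZIP whose
  regression acts on the overall mean ``nu = (1 - psi) * lambda`` — and
  exports its mean coefficients as the start for ``beta``; because both
  models parameterize the *marginal* mean, the MZIP slope coefficients are
  consistent starting points even though the mixture is not zero-inflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .model_core import DesignData

__all__ = ["EmTrace", "em_poisson_mixture", "fit_mzip", "starting_values"]

PI_CLAMP = (0.01, 0.99)  # starting values only; the final fit is unclamped


@dataclass
class EmTrace:
    loglik_path: list[float] = field(default_factory=list)
    responsibilities: np.ndarray | None = None
    iterations: int = 0
    converged: bool = False
    #: fitted (component1, component2) coefficient vectors, label rule applied
    component_coefs: tuple[np.ndarray, np.ndarray] | None = None
    mixing_weight: float = float("nan")


def _weighted_poisson_fit(y, Z, w, start=None):
    """Responsibility-weighted Poisson regression (log link)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Z, family=sm.families.Poisson(), freq_weights=w)
        res = model.fit(start_params=start, maxiter=200)
    return np.asarray(res.params)


def _mixture_obs_loglik(y, Z, coefs, pi):
    """Observed-data log-likelihood of the latent-class mixture, plus the
    per-component complete log-densities used for the E-step."""
    log_dens = np.empty((2, y.shape[0]))
    for k in range(2):
        log_mu = Z @ coefs[k]
        log_dens[k] = -np.exp(log_mu) + y * log_mu - gammaln(y + 1.0)
    log_w = np.log([pi, 1.0 - pi])[:, None]
    ll = float(np.sum(logsumexp(log_dens + log_w, axis=0)))
    return ll, log_dens


def em_poisson_mixture(
    data: DesignData,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    random_start: bool = False,
):
    """EM fit of the two-component Poisson regression mixture.

    Both component means are regressed on ``Z`` (log link); the mixing
    weight is free.  Initial responsibilities split subjects at the outcome
    median (deterministic); ``random_start=True`` perturbs that split using
    ``seed``.  Component labels are fixed by the rule "component 1 has the
    smaller fitted intercept", so the exported ``(alpha, tau)`` are
    deterministic.  The returned ``tau`` is logit of the fitted mixing
    weight, clamped to keep it finite if the fit collapses on one component.

    Returns ``(alpha_start, tau_start, trace)``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    y, Z = data.y, data.Z
    n = data.n

    median = np.median(y)
    resp1 = np.where(y <= median, 0.75, 0.25)
    if random_start:
        rng = np.random.default_rng(seed)
        resp1 = np.clip(resp1 + rng.uniform(-0.2, 0.2, size=n), 0.05, 0.95)
    resp = np.column_stack([resp1, 1.0 - resp1])

    coefs = [None, None]
    trace = EmTrace()
    prev_ll = -np.inf
    pi = float(resp[:, 0].mean())
    for it in range(1, max_iter + 1):
        # M-step: weighted Poisson regressions + mixing weight
        for k in range(2):
            coefs[k] = _weighted_poisson_fit(y, Z, resp[:, k], start=coefs[k])
        pi = float(resp[:, 0].mean())
        # E-step at the new parameters; loglik is recorded here so the path
        # is the observed-data likelihood after each full EM sweep
        ll, log_dens = _mixture_obs_loglik(y, Z, coefs, pi)
        log_post = log_dens + np.log([pi, 1.0 - pi])[:, None]
        log_post -= logsumexp(log_post, axis=0, keepdims=True)
        resp = np.exp(log_post).T
        trace.loglik_path.append(ll)
        trace.iterations = it
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            trace.converged = True
            break
        prev_ll = ll
    if not trace.converged:
        warnings.warn("EM did not converge within max_iter; returning best iterate")
    trace.responsibilities = resp

    # label rule: component 1 has the smaller fitted intercept
    if coefs[0][0] > coefs[1][0]:
        coefs = coefs[::-1]
        pi = 1.0 - pi
        trace.responsibilities = resp[:, ::-1]
    trace.component_coefs = (np.asarray(coefs[0]), np.asarray(coefs[1]))
    trace.mixing_weight = pi
    lo, hi = PI_CLAMP
    if not lo <= pi <= hi:
        warnings.warn(f"degenerate mixing weight {pi:.4f} clamped to [{lo}, {hi}]")
        pi = float(np.clip(pi, lo, hi))
    tau_start = float(np.log(pi / (1.0 - pi)))
    return np.asarray(coefs[0]), tau_start, trace


def _mzip_negloglik(theta, y, X, is_zero):
    """Negative log-likelihood of the marginalized ZIP in (gamma0, beta).

    psi = expit(gamma0) is the structural-zero probability (intercept only);
    the marginal mean nu_i = exp(x_i'beta) ties to the Poisson rate through
    lambda_i = nu_i / (1 - psi).
    """
    gamma0, beta = theta[0], theta[1:]
    log_psi = -np.logaddexp(0.0, -gamma0)
    log_1mpsi = -np.logaddexp(0.0, gamma0)
    lam = np.exp(X @ beta - log_1mpsi)
    ll_zero = np.logaddexp(log_psi, log_1mpsi - lam)
    ll_pos = log_1mpsi - lam + y * np.log(lam) - gammaln(y + 1.0)
    return -float(np.sum(np.where(is_zero, ll_zero, ll_pos)))


def fit_mzip(data: DesignData, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Marginalized-ZIP starting values for the marginal-mean coefficients.

    Quasi-Newton (BFGS) maximization of the ZIP likelihood reparameterized in
    ``(gamma0, beta)`` with ``log(nu_i) = x_i'beta`` the marginal mean.  If
    the data contain no zero counts the ZIP reduces to Poisson and plain
    Poisson regression coefficients are returned with a warning.
    """
    y, X = data.y, data.X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    beta_pois = np.asarray(pois.params)
    is_zero = y == 0
    if not is_zero.any():
        warnings.warn("no zero counts: MZIP reduces to Poisson regression")
        return beta_pois
    # start psi at half the observed zero share, kept off the boundary
    psi0 = float(np.clip(is_zero.mean() / 2.0, 0.02, 0.5))
    theta0 = np.concatenate([[np.log(psi0 / (1 - psi0))], beta_pois])
    res = minimize(
        _mzip_negloglik,
        theta0,
        args=(y, X, is_zero),
        method="BFGS",
        options={"gtol": 1e-6, "maxiter": max_iter},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-2:
        warnings.warn(f"MZIP optimizer did not fully converge: {res.message}")
    return np.asarray(res.x[1:])


def starting_values(data: DesignData, **em_kwargs):
    """Convenience wrapper: (beta, alpha, tau) starts for the full fit."""
    alpha0, tau0, trace = em_poisson_mixture(data, **em_kwargs)
    beta0 = fit_mzip(data)
    return beta0, alpha0, tau0, trace
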