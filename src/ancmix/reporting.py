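"""Regression-table reporting and dataset I/O.

Turns a fitted marginalized mixture into the published table layout: per
covariate level the coefficient on the marginal-mean (log) scale with its
Wald SE, z, p and 95% CI, the incidence density ratio IDR = exp(beta), plus
a final mixing-proportion row on the probability scale.  Reference levels
are interleaved as "(ref)" rows.  Also houses the CSV reader that applies
the complete-case rule and dummy-codes declared covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .descriptives import significance_stars
from .estimation import FitResult, mixing_proportion
from .model_core import DesignData

__all__ = [
    "IdrRow",
    "RunConfig",
    "idr",
    "wald_ci",
    "percent_change",
    "render_percent_change",
    "build_table2",
    "read_dataset",
]

Z95 = 1.96


@dataclass
class RunConfig:
    """Covariate roles for reading an analysis dataset.

    ``covariates`` maps column name -> ordered level list with the reference
    level first (the coding the fitted coefficients are reported against).
    """

    outcome: str
    covariates: dict[str, list[str]]
    seed: int = 0
    output_dir: str = "results"


@dataclass
class IdrRow:
    variable: str
    level: str
    beta: float | None
    se: float | None
    z: float | None
    p: float | None
    ci_low: float | None
    ci_high: float | None
    idr: float | None
    stars: str = ""
    is_reference: bool = False


def idr(beta: float) -> float:
    """Incidence density ratio exp(beta), displayed to 3 dp."""
    return round(float(np.exp(beta)), 3)


def wald_ci(est: float, se: float, level: float = 0.95):
    """Normal Wald interval est +/- z * se (z = 1.96 at 95%), 3-dp display."""
    if se < 0:
        raise ValueError("se must be non-negative")
    z = Z95 if level == 0.95 else float(norm.ppf(0.5 + level / 2.0))
    return round(est - z * se, 3), round(est + z * se, 3)


def percent_change(beta: float) -> float:
    """Signed percent change of the marginal mean, (exp(beta) - 1) * 100."""
    return round((float(np.exp(beta)) - 1.0) * 100.0, 1)


def render_percent_change(beta: float) -> str:
    pc = percent_change(beta)
    if pc < 0:
        return f"{-pc:g}% lower"
    if pc > 0:
        return f"{pc:g}% higher"
    return "no change"


def _split_param_name(name: str):
    # "beta[study_continuity[drop_outed]]" -> ("study_continuity", "drop_outed")
    inner = name[name.index("[") + 1 : -1]
    if "[" in inner:
        var, lev = inner.split("[", 1)
        return var, lev[:-1]
    return inner, ""


def build_table2(
    fit: FitResult,
    variable_levels: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Published-style coefficient table for the marginalized mixture fit.

    Rows are grouped by variable with "(ref)" rows interleaved in declared
    level order; only the marginal-mean (beta) block is tabulated, followed
    by the mixing-proportion row computed from (tau, se_tau) by the delta
    method.  Refuses to render a non-converged fit.
    """
    if not fit.converged:
        raise ValueError(
            f"fit did not converge (message: {fit.message}); refusing to render"
        )
    frame = fit.to_frame()
    beta_rows = frame[frame["parameter"].str.startswith("beta[")]
    rows: list[IdrRow] = []
    by_key = {}
    for _, r in beta_rows.iterrows():
        var, lev = _split_param_name(r["parameter"])
        by_key[(var, lev)] = r

    def numeric_row(var, lev, r):
        return IdrRow(
            variable=var,
            level=lev,
            beta=round(r["estimate"], 3),
            se=round(r["se"], 3),
            z=round(r["z"], 3),
            p=round(r["p"], 3),
            ci_low=round(r["ci_low"], 3),
            ci_high=round(r["ci_high"], 3),
            idr=idr(r["estimate"]) if var != "intercept" else None,
            stars=significance_stars(min(max(r["p"], 0.0), 1.0)),
        )

    r0 = by_key.pop(("intercept", ""))
    rows.append(numeric_row("intercept", "", r0))
    if variable_levels:
        for var, levels in variable_levels.items():
            for j, lev in enumerate(levels):
                if j == 0:
                    rows.append(
                        IdrRow(var, f"{lev} (ref)", None, None, None, None, None,
                               None, None, is_reference=True)
                    )
                else:
                    rows.append(numeric_row(var, lev, by_key[(var, lev)]))
    else:
        for (var, lev), r in by_key.items():
            rows.append(numeric_row(var, lev, r))

    tau_idx = fit.param_names.index("tau")
    pi_hat, se_pi, z_pi, p_pi = mixing_proportion(
        fit.params[tau_idx], fit.se[tau_idx]
    )
    rows.append(
        IdrRow(
            variable="mixing_proportion",
            level="pi",
            beta=round(pi_hat, 3),
            se=round(se_pi, 3),
            z=round(z_pi, 3),
            p=round(p_pi, 3),
            ci_low=None,
            ci_high=None,
            idr=None,
            stars=significance_stars(min(max(p_pi, 0.0), 1.0)),
        )
    )
    return pd.DataFrame([r.__dict__ for r in rows])


def format_p(p: float) -> str:
    """Display convention: 3 dp with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def read_dataset(path, config: RunConfig) -> tuple[DesignData, int]:
    """Read an analysis CSV into a DesignData, applying complete-case rules.

    Rows with any missing declared field are dropped and counted (the
    exclusion count is returned alongside).  Covariates are dummy-coded
    against the declared reference level (first in each level list); an
    observed level not declared in the config is an error.

    Returns ``(design, n_excluded)``.
    """
    table = pd.read_csv(path)
    if config.outcome not in table.columns:
        raise ValueError(f"outcome column {config.outcome!r} not in file")
    needed = [config.outcome] + list(config.covariates)
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    sub = table[needed]
    keep = sub.notna().all(axis=1)
    n_excluded = int((~keep).sum())
    sub = sub[keep]

    y = sub[config.outcome].to_numpy()
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for cov, levels in config.covariates.items():
        observed = sub[cov].astype(str).to_numpy()
        undeclared = sorted(set(observed) - set(levels))
        if undeclared:
            raise ValueError(
                f"covariate {cov!r} has undeclared levels: {undeclared}"
            )
        for lev in levels[1:]:
            cols.append((observed == lev).astype(float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    design = DesignData(
        y=y, X=X, Z=X.copy(), row_ids=sub.index.to_numpy(),
        x_names=names, z_names=list(names),
    )
    return design, n_excluded
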