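"""Synthetic BDHS-like cohorts for the antenatal-care (ANC) visit analysis.

The study population (ever-married Bangladeshi women reporting ANC visits for
their most recent birth) is access-restricted, so this module emulates its
structure: categorical socioeconomic/demographic covariates sampled with the
published marginal proportions, and visit counts drawn from the two-component
Poisson mixture whose marginal mean follows the log-linear model of
:mod:`ancmix.model_core`.  It also implements the study's derived-variable
rules (study-continuity classification and wealth tertiles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model_core import DesignData, MarginalizedParams, eta

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "classify_study_continuity",
    "assign_wealth_tertile",
    "generate_covariates",
    "simulate_counts",
    "simulate_dataset",
    "default_covariate_specs",
    "default_true_params",
    "default_config",
    "OUTCOME_COLUMN",
    "LATENT_COLUMN",
]

OUTCOME_COLUMN = "anc_visits"
LATENT_COLUMN = "latent_class"


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical covariate: ordered levels (first = reference) and
    per-level sampling proportions."""

    name: str
    levels: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"covariate {self.name!r} needs at least 2 levels")
        if len(self.levels) != len(self.probabilities):
            raise ValueError(f"covariate {self.name!r}: levels/probabilities mismatch")
        probs = np.asarray(self.probabilities, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError(f"covariate {self.name!r}: probabilities outside [0,1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"covariate {self.name!r}: probabilities sum to {probs.sum()}, not 1"
            )

    @property
    def reference(self) -> str:
        return self.levels[0]


@dataclass
class SimulationConfig:
    """Everything needed to draw one synthetic cohort reproducibly."""

    n: int
    covariate_specs: list[CovariateSpec]
    true_params: MarginalizedParams
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")
        self.seed = int(self.seed)


@dataclass
class SimulatedDataset:
    """Simulated cohort table plus the design matrices it was drawn from.

    ``latent_class`` (in {1, 2}) records the mixture component of each draw
    for diagnostics only; the fitting pipeline never sees it.
    """

    table: pd.DataFrame
    design: DesignData
    latent_class: np.ndarray
    config: SimulationConfig | None = None

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def classify_study_continuity(
    years_schooling: int,
    attended_school_before_marriage: bool,
    continued_after_marriage: bool,
) -> str:
    """Assign the study-continuity exposure category.

    Women with fewer than 10 years of schooling are classed as school
    dropouts regardless of the marriage-timing flags; among those with >= 10
    years, continuing study after marriage distinguishes ``continued`` from
    ``not_continued_ge10``.
    """
    years = int(years_schooling)
    if years < 0:
        raise ValueError("years_schooling must be non-negative")
    if years < 10:
        return "drop_outed"
    if continued_after_marriage:
        return "continued"
    return "not_continued_ge10"


def assign_wealth_tertile(scores) -> np.ndarray:
    """Split subjects into poor/middle/rich thirds by ranked wealth score.

    Subjects are ranked ascending by score (ties broken by stable order of
    appearance) and partitioned into three groups with sizes as equal as
    possible; the lowest third is labelled ``poor``.  The labels depend only
    on the ranks, so any strictly increasing transform of the scores leaves
    them unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    n = scores.size
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    # group sizes differ by at most one, extras go to the lowest groups
    base, extra = divmod(n, 3)
    sizes = [base + (1 if g < extra else 0) for g in range(3)]
    cut1, cut2 = sizes[0], sizes[0] + sizes[1]
    labels = np.where(ranks < cut1, "poor", np.where(ranks < cut2, "middle", "rich"))
    return labels


def default_covariate_specs() -> list[CovariateSpec]:
    """Covariates of the published cohort with their observed marginal
    proportions (reference level first, matching the fitted model)."""
    return [
        CovariateSpec(
            "study_continuity",
            ("continued", "not_continued_ge10", "drop_outed"),
            (0.112, 0.123, 0.765),
        ),
        CovariateSpec("residence", ("rural", "urban"), (0.657, 0.343)),
        CovariateSpec("media_exposure", ("no", "yes"), (0.458, 0.542)),
        CovariateSpec(
            "age_at_birth", ("20-29", "<20", ">=30"), (0.570, 0.279, 0.151)
        ),
        CovariateSpec(
            "spousal_age_diff",
            ("1-5", "non_positive", "6-10", ">10"),
            (0.324, 0.011, 0.425, 0.240),
        ),
        CovariateSpec(
            "decision_participation", ("none", "1-2", "all_3"), (0.151, 0.302, 0.547)
        ),
        CovariateSpec(
            "beating_justified", ("not_at_all", "1-2", "3-5"), (0.821, 0.143, 0.036)
        ),
        CovariateSpec("wealth_index", ("poor", "middle", "rich"), (0.369, 0.321, 0.310)),
        CovariateSpec("birth_order", ("1", "2", "3", ">=4"), (0.379, 0.328, 0.172, 0.121)),
    ]


# marginal-mean coefficients of the published fit, in the dummy order produced
# by default_covariate_specs (intercept first)
_DEFAULT_BETA = np.array(
    [
        1.359,  # intercept
        -0.112, -0.225,  # study continuity: not_continued_ge10, drop_outed
        0.113,  # urban
        0.218,  # media yes
        -0.080, 0.052,  # age <20, >=30
        0.228, -0.002, 0.011,  # spousal age diff: non_positive, 6-10, >10
        0.002, 0.021,  # decisions 1-2, all 3
        -0.126, -0.128,  # beating justified 1-2, 3-5
        0.129, 0.216,  # wealth middle, rich
        -0.075, -0.116, -0.369,  # birth order 2, 3, >=4
    ]
)

#: Component-1 mean as a fraction of the marginal mean in the default cohort.
#: mu1 = 0.6*mu with pi = 0.61 keeps mu2 = (1 - 0.6*pi)/(1 - pi) * mu > 0 on
#: every row and yields marginal SD approx 2.8 at mean approx 3.9, close to the
#: dispersion of the real cohort (mean 3.93, SD 2.88).
_MU1_RATIO = 0.6
_DEFAULT_PI = 0.61


def default_true_params() -> MarginalizedParams:
    """Data-generating parameters of the default synthetic cohort."""
    alpha = _DEFAULT_BETA.copy()
    alpha[0] += np.log(_MU1_RATIO)
    tau = float(np.log(_DEFAULT_PI / (1.0 - _DEFAULT_PI)))
    return MarginalizedParams(beta=_DEFAULT_BETA.copy(), alpha=alpha, tau=tau)


def default_config(n: int = 4941, seed: int = 0) -> SimulationConfig:
    """Default cohort: published sample size, proportions and coefficients."""
    return SimulationConfig(
        n=n,
        covariate_specs=default_covariate_specs(),
        true_params=default_true_params(),
        seed=seed,
    )


def _dummy_design(
    table: pd.DataFrame, specs: list[CovariateSpec]
) -> tuple[np.ndarray, list[str]]:
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for spec in specs:
        values = table[spec.name].to_numpy()
        unknown = set(values) - set(spec.levels)
        if unknown:
            raise ValueError(
                f"covariate {spec.name!r}: undeclared levels {sorted(unknown)}"
            )
        for level in spec.levels[1:]:
            cols.append((values == level).astype(float))
            names.append(f"{spec.name}[{level}]")
    return np.column_stack(cols), names


def generate_covariates(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Sample the covariate table and build the dummy-coded design matrix.

    Covariates are sampled independently per their spec proportions; the
    design has an intercept column followed by indicator columns for every
    non-reference level, in declared order.  Identical seeds give identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    data = {}
    for spec in config.covariate_specs:
        data[spec.name] = rng.choice(
            spec.levels, size=config.n, p=np.asarray(spec.probabilities)
        )
    table = pd.DataFrame(data)
    X, names = _dummy_design(table, config.covariate_specs)
    return table, X, names


def simulate_counts(
    X: np.ndarray,
    Z: np.ndarray,
    params: MarginalizedParams,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw counts from the marginalized mixture at the given designs.

    Per subject: latent class 1 with probability ``pi``, then a Poisson draw
    with mean ``mu1_i = exp(z_i' alpha)`` (class 1) or the substituted
    ``mu2_i`` (class 2).  Raises if any implied ``mu2_i`` is non-positive,
    naming the first offending row.

    Returns ``(counts, latent_class)`` with classes coded 1/2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    mu2 = eta(params, X, Z)  # eta equals the substituted mu2
    if np.any(mu2 <= 0):
        bad = int(np.argmax(mu2 <= 0))
        raise ValueError(
            f"invalid parameter set: implied mu2 <= 0 at row {bad} (mu2={mu2[bad]:.4g})"
        )
    mu1 = np.exp(Z @ params.alpha)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    in_class1 = rng.random(n) < params.pi
    means = np.where(in_class1, mu1, mu2)
    y = rng.poisson(means)
    latent = np.where(in_class1, 1, 2)
    return y, latent


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full cohort draw: covariates, designs, counts and latent classes.

    The component-mean design ``Z`` reuses the marginal design ``X`` (the
    fitted model uses the same covariates for both parts).
    """
    table, X, names = generate_covariates(config)
    # independent stream for the counts so covariates match across params
    y, latent = simulate_counts(X, X, config.true_params, seed=config.seed + 1)
    table = table.copy()
    table[OUTCOME_COLUMN] = y
    table[LATENT_COLUMN] = latent
    design = DesignData(y=y, X=X, Z=X.copy(), x_names=names, z_names=list(names))
    return SimulatedDataset(table=table, design=design, latent_class=latent, config=config)


def _specs_from_mapping(raw: list[dict]) -> list[CovariateSpec]:
    return [
        CovariateSpec(
            name=item["name"],
            levels=tuple(item["levels"]),
            probabilities=tuple(float(p) for p in item["probabilities"]),
        )
        for item in raw
    ]


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from YAML or JSON; the seed is mandatory."""
    text = open(path).read()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "seed" not in raw:
        raise ValueError("simulation config must declare a seed")
    params = raw.get("true_params")
    if params is None:
        true_params = default_true_params()
    else:
        true_params = MarginalizedParams(
            beta=np.asarray(params["beta"], dtype=float),
            alpha=np.asarray(params["alpha"], dtype=float),
            tau=float(params["tau"]),
        )
    specs = (
        _specs_from_mapping(raw["covariates"])
        if "covariates" in raw
        else default_covariate_specs()
    )
    return SimulationConfig(
        n=int(raw["n"]), covariate_specs=specs, true_params=true_params, seed=raw["seed"]
    )
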