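"""Derived-variable rules and the synthetic-cohort generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ancmix.model_core import MarginalizedParams
from ancmix.synthetic_data import (
    OUTCOME_COLUMN,
    CovariateSpec,
    SimulationConfig,
    assign_wealth_tertile,
    classify_study_continuity,
    default_config,
    default_covariate_specs,
    default_true_params,
    generate_covariates,
    simulate_counts,
    simulate_dataset,
)


class TestStudyContinuity:
    @pytest.mark.parametrize(
        "years, before, after, expected",
        [
            (12, True, True, "continued"),
            (10, True, False, "not_continued_ge10"),  # boundary: exactly 10
            (10, True, True, "continued"),
            (8, True, True, "drop_outed"),  # <10 years dominates the flags
            (0, False, False, "drop_outed"),
            (9, False, True, "drop_outed"),
        ],
    )
    def test_categories(self, years, before, after, expected):
        assert classify_study_continuity(years, before, after) == expected

    def test_negative_years_rejected(self):
        with pytest.raises(ValueError):
            classify_study_continuity(-1, True, True)

    @given(
        years=st.integers(0, 25),
        before=st.booleans(),
        after=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_totality(self, years, before, after):
        """Every input falls in exactly one of the three categories."""
        out = classify_study_continuity(years, before, after)
        assert out in {"continued", "not_continued_ge10", "drop_outed"}


class TestWealthTertile:
    def test_nine_distinct_scores_split_evenly(self):
        labels = assign_wealth_tertile(np.arange(9, 0, -1))
        counts = {lab: int((labels == lab).sum()) for lab in ("poor", "middle", "rich")}
        assert counts == {"poor": 3, "middle": 3, "rich": 3}

    def test_sorted_scores_order(self):
        labels = assign_wealth_tertile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert list(labels) == ["poor", "poor", "middle", "middle", "rich", "rich"]

    def test_large_uniform_sample_balanced(self):
        rng = np.random.default_rng(5)
        labels = assign_wealth_tertile(rng.uniform(size=3000))
        for lab in ("poor", "middle", "rich"):
            assert abs(int((labels == lab).sum()) - 1000) <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_wealth_tertile([])

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=40, unique=True))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_transform_invariance(self, scores):
        """Labels depend only on ranks: a strictly increasing transform of
        the scores (here cubing, exact on integers) changes nothing."""
        base = assign_wealth_tertile(np.asarray(scores, dtype=float))
        transformed = assign_wealth_tertile(np.asarray(scores, dtype=float) ** 3)
        assert list(base) == list(transformed)


class TestCovariateSpecs:
    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            CovariateSpec("bad", ("only",), (1.0,))

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CovariateSpec("bad", ("a", "b"), (0.5, 0.6))

    def test_default_specs_are_valid_and_sum_to_one(self):
        specs = default_covariate_specs()
        assert len(specs) == 9
        for spec in specs:
            assert abs(sum(spec.probabilities) - 1.0) < 1e-9


class TestGenerateCovariates:
    def test_empirical_proportions_match_spec(self):
        cfg = default_config(n=50_000, seed=12)
        table, X, names = generate_covariates(cfg)
        sc = table["study_continuity"]
        for level, p in zip(
            ("continued", "not_continued_ge10", "drop_outed"), (0.112, 0.123, 0.765)
        ):
            assert abs((sc == level).mean() - p) < 0.01

    def test_determinism(self):
        cfg = default_config(n=500, seed=33)
        t1, X1, _ = generate_covariates(cfg)
        t2, X2, _ = generate_covariates(cfg)
        assert t1.equals(t2)
        assert np.array_equal(X1, X2)

    def test_design_matches_reference_coding(self):
        cfg = default_config(n=200, seed=2)
        table, X, names = generate_covariates(cfg)
        assert names[0] == "intercept"
        assert np.all(X[:, 0] == 1.0)
        # one indicator per non-reference level
        expected_cols = 1 + sum(len(s.levels) - 1 for s in cfg.covariate_specs)
        assert X.shape == (200, expected_cols)
        j = names.index("residence[urban]")
        assert np.array_equal(X[:, j], (table["residence"] == "urban").astype(float))


class TestSimulateCounts:
    def test_near_degenerate_mixture_is_single_poisson(self):
        p = MarginalizedParams(beta=[np.log(4.0)], alpha=[0.0], tau=-30.0)
        X = np.ones((100_000, 1))
        y, latent = simulate_counts(X, X, p, seed=8)
        mc_se = np.sqrt(4.0 / y.size)
        assert abs(y.mean() - 4.0) < 3 * mc_se
        assert (latent == 2).all()

    def test_class2_mean_is_substituted_mu2(self):
        # beta0=log 2, alpha0=0, tau=0 -> mu2 = 2*2 - 1 = 3
        p = MarginalizedParams(beta=[np.log(2.0)], alpha=[0.0], tau=0.0)
        X = np.ones((200_000, 1))
        y, latent = simulate_counts(X, X, p, seed=21)
        class2 = y[latent == 2]
        mc_se = np.sqrt(3.0 / class2.size)
        assert abs(class2.mean() - 3.0) < 3 * mc_se

    def test_invalid_params_raise_naming_row(self):
        p = MarginalizedParams(beta=[0.0], alpha=[2.0], tau=0.0)
        with pytest.raises(ValueError, match="row 0"):
            simulate_counts(np.ones((3, 1)), np.ones((3, 1)), p, seed=1)

    def test_latent_proportion_converges_to_pi(self):
        p = MarginalizedParams(beta=[np.log(3.0)], alpha=[0.3], tau=0.4)
        X = np.ones((100_000, 1))
        _, latent = simulate_counts(X, X, p, seed=4)
        pi = p.pi
        assert abs((latent == 1).mean() - pi) < 3 * np.sqrt(pi * (1 - pi) / X.shape[0])


class TestSimulateDataset:
    def test_cohort_round_trip_and_columns(self, tmp_path):
        ds = simulate_dataset(default_config(n=400, seed=10))
        assert OUTCOME_COLUMN in ds.table.columns
        assert set(ds.table["latent_class"].unique()) <= {1, 2}
        path = tmp_path / "cohort.csv"
        ds.write_csv(path)
        import pandas as pd

        back = pd.read_csv(path, dtype=str)
        for col in ("study_continuity", "residence", "wealth_index"):
            assert list(back[col]) == list(ds.table[col].astype(str))

    def test_default_params_valid_on_every_row(self):
        """The default data-generating parameters keep mu2 > 0 on every
        possible covariate combination by construction (mu1 = 0.6 mu)."""
        ds = simulate_dataset(default_config(n=2000, seed=3))
        from ancmix.model_core import eta

        e = eta(default_true_params(), ds.design.X, ds.design.Z)
        assert (e > 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                n=0,
                covariate_specs=default_covariate_specs(),
                true_params=default_true_params(),
                seed=1,
            )
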