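"""Trait statistics: moments, correlation, BLUE, heritability, expression."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soyqtl.genome import PlantedQtl
from soyqtl.simulate import simulate_phenotypes
from soyqtl.traits import (compute_blue, describe, heritability,
                           heritability_from_components, pearson,
                           relative_expression, trait_summary_table)


def _pheno(values_by_line, years=1, reps=None, trait="T"):
    """Build a long phenotype table from {line: [values...]}."""
    rows = []
    for line, vals in values_by_line.items():
        for i, v in enumerate(vals):
            year = i // (len(vals) // years) + 1 if years > 1 else 1
            rows.append((line, year, i + 1, trait, float(v)))
    return pd.DataFrame(rows, columns=["line_id", "year", "replicate",
                                       "trait", "value"])


class TestDescribe:
    def test_small_sample_exact_values(self):
        s = describe([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)
        assert s.min == 1.0 and s.max == 3.0

    def test_symmetric_sample_has_zero_skewness(self):
        assert describe([1, 2, 2, 3]).skewness == pytest.approx(0.0)

    def test_gaussian_excess_kurtosis_near_zero(self):
        x = np.random.default_rng(0).normal(size=100_000)
        assert describe(x).kurtosis == pytest.approx(0.0, abs=0.1)

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40))
    def test_moments_match_definitions(self, xs):
        x = np.asarray(xs)
        s = describe(x)
        n, m = len(x), x.mean()
        m2 = ((x - m) ** 2).mean()
        if m2 < 1e-30:  # (near-)degenerate: higher moments ill-conditioned
            return
        m3 = ((x - m) ** 3).mean()
        m4 = ((x - m) ** 4).mean()
        assert s.mean == pytest.approx(m, abs=1e-12)
        assert s.sd == pytest.approx(
            np.sqrt(((x - m) ** 2).sum() / (n - 1)), rel=1e-12)
        assert s.skewness == pytest.approx(m3 / m2 ** 1.5, rel=1e-9,
                                           abs=1e-9)
        assert s.kurtosis == pytest.approx(m4 / m2 ** 2 - 3.0, rel=1e-9,
                                           abs=1e-9)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            describe([1.0])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestBlue:
    def test_balanced_zero_year_variance_equals_line_means(
            self, small_population):
        ph = simulate_phenotypes(
            small_population, [PlantedQtl("Gm01", 9_000_000, 2.0, "T")],
            years=3, reps=3, year_sd=0.0, resid_sd=2.0, grand_mean=10.0,
            seed=21)
        res = compute_blue(ph, "T")
        means = ph.groupby("line_id")["value"].mean().reindex(res.blue.index)
        np.testing.assert_allclose(res.blue, means, atol=1e-9)

    def test_recovers_line_effects_from_noisy_design(self, small_population):
        # 3 years x 3 reps, year_sd=2, resid_sd=1: RMSE of centred effects
        pop = small_population
        q = PlantedQtl("Gm01", 9_000_000, 3.0, "T")
        ph = simulate_phenotypes(pop, [q], years=3, reps=3, year_sd=2.0,
                                 resid_sd=1.0, grand_mean=10.0, seed=22)
        res = compute_blue(ph, "T")
        true = np.array([10.0 + 6.0 * pop.dosage(l, q.chrom, q.pos)
                         for l in res.blue.index])
        b = res.blue.to_numpy()
        rmse = np.sqrt(np.mean(((b - b.mean()) - (true - true.mean())) ** 2))
        assert rmse < 0.5
        # residual variance is well identified (year variance has only
        # 2 df here and is realization-dependent)
        assert res.sigma_e2 == pytest.approx(1.0, abs=0.3)
        assert res.sigma_year2 >= 0.0

    def test_matches_mixedlm_reml_oracle(self, small_population):
        # independent route: statsmodels MixedLM on the same design
        import statsmodels.api as sm

        ph = simulate_phenotypes(
            small_population, [PlantedQtl("Gm02", 9_000_000, 1.5, "T")],
            years=4, reps=2, year_sd=1.5, resid_sd=1.0, grand_mean=5.0,
            seed=23)
        res = compute_blue(ph, "T")
        exog = pd.get_dummies(ph["line_id"], dtype=float)[
            list(res.blue.index)]
        model = sm.MixedLM(ph["value"].to_numpy(), exog.to_numpy(),
                           groups=ph["year"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = model.fit(reml=True, method="cg")
        np.testing.assert_allclose(res.blue.to_numpy(),
                                   np.asarray(ref.fe_params), atol=1e-5)
        assert res.sigma_e2 == pytest.approx(float(ref.scale), rel=1e-3)

    def test_constant_phenotype_gives_constant_blue(self):
        ph = _pheno({"A": [4.0] * 6, "B": [4.0] * 6}, years=2)
        res = compute_blue(ph, "T")
        assert set(res.blue) == {4.0}
        assert res.sigma_year2 == 0.0 and res.sigma_e2 == 0.0

    def test_single_year_falls_back_to_means_with_warning(self):
        ph = _pheno({"A": [1.0, 2.0], "B": [3.0, 5.0]})
        with pytest.warns(UserWarning):
            res = compute_blue(ph, "T")
        assert res.blue["A"] == pytest.approx(1.5)
        assert res.blue["B"] == pytest.approx(4.0)


class TestHeritability:
    def test_component_plugins_evaluate_exactly(self):
        assert heritability_from_components(1.0, 0.0, 3) == 1.0
        assert heritability_from_components(1.0, 3.0, 3) == 0.5

    def test_clamped_to_zero_when_within_exceeds_between(self):
        # group means equal, all variance within: MSg < MSe
        ph = _pheno({"A": [0.0, 4.0], "B": [1.0, 3.0]})
        assert heritability(ph, "T", r=2) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        ph = _pheno({f"L{i}": rng.normal(i % 7, 1.0, 3) for i in range(30)})
        h = heritability(ph, "T", r=3)
        ph2 = ph.assign(value=ph["value"] * 3.7 - 11.0)
        assert heritability(ph2, "T", r=3) == pytest.approx(h, rel=1e-9)

    def test_estimator_consistency_over_simulated_populations(self):
        # mean estimate over 200 populations within +-0.05 of the
        # variance-component value (sigma_g2=1, sigma_e2=1, r=3 -> 0.75)
        rng = np.random.default_rng(42)
        n_lines, r = 200, 3
        estimates = []
        for _ in range(200):
            g = rng.normal(0.0, 1.0, n_lines)
            vals = g[:, None] + rng.normal(0.0, 1.0, (n_lines, r))
            ph = _pheno({f"L{i}": vals[i] for i in range(n_lines)})
            estimates.append(heritability(ph, "T", r=r))
        expected = heritability_from_components(1.0, 1.0, r)
        assert np.mean(estimates) == pytest.approx(expected, abs=0.05)

    def test_recovers_planted_components_via_simulator(self,
                                                       small_population):
        # single-population check against the realized genetic variance
        pop = small_population
        q = PlantedQtl("Gm03", 9_000_000, 2.0, "T")
        ph = simulate_phenotypes(pop, [q], years=1, reps=3, year_sd=0.0,
                                 resid_sd=1.0, grand_mean=0.0, seed=31)
        g = np.array([4.0 * pop.dosage(l, q.chrom, q.pos)
                      for l in pop.line_ids])
        expected = heritability_from_components(g.var(ddof=1), 1.0, 3)
        assert heritability(ph, "T", r=3) == pytest.approx(expected,
                                                           abs=0.15)

    def test_r_below_two_rejected(self):
        with pytest.raises(ValueError):
            heritability_from_components(1.0, 1.0, 1)


class TestRelativeExpression:
    @pytest.mark.parametrize("ref,target,expected", [
        (20.0, 20.0, 1.0),
        (20.0, 18.0, 4.0),
        (18.0, 20.0, 0.25),
    ])
    def test_two_power_delta_ct(self, ref, target, expected):
        assert relative_expression(ref, target) == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(float("nan"), 20.0)


def test_trait_summary_table_layout(small_population):
    ph = simulate_phenotypes(
        small_population, [PlantedQtl("Gm01", 9_000_000, 2.0, "T")],
        years=2, reps=3, year_sd=1.0, resid_sd=2.0, grand_mean=10.0, seed=41)
    tab = trait_summary_table(ph, "T", r=3)
    assert list(tab["year"]) == ["1", "2", "BLUE"]
    assert ((tab["h2"].dropna() >= 0) & (tab["h2"].dropna() <= 1)).all()
    assert (tab["min"] <= tab["mean"]).all() and \
        (tab["mean"] <= tab["max"]).all()
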