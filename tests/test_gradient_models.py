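import math

import numpy as np
import pytest
from scipy import stats

from traitflux.gradient_models import (
    env_gradient_check,
    fit_categorical_trait_glm,
    fit_itv_lmm,
    lmm_eligible_frame,
)
from traitflux.synthetic_community import SyntheticConfig, generate_study

from conftest import make_individual, make_plot, make_species, make_study


# ----------------------------------------------------------------------
# Environment vs age
# ----------------------------------------------------------------------


def _plots_with_env(values_by_var, ages=(10.0, 20.0, 30.0, 40.0)):
    plots = []
    for i, age in enumerate(ages):
        env = {k: v[i] for k, v in values_by_var.items()}
        plots.append(make_plot(f"P{i}", age=age, **env))
    return plots


def _study_with_plots(plots):
    species = [make_species("A")]
    individuals = [make_individual(plots[0].plot_id, "A", y=1.0)]
    return make_study(plots, species, individuals)


def test_env_noiseless_line():
    ages = (10.0, 20.0, 30.0, 40.0)
    plots = _plots_with_env({"openness": [-0.5 * a for a in ages]}, ages)
    res = env_gradient_check(_study_with_plots(plots), "MIX")
    assert res.loc["openness", "slope"] == pytest.approx(-0.5)
    assert res.loc["openness", "p"] < 1e-10
    assert res.loc["openness", "band"] == "p<0.05"


def test_env_constant_flagged():
    plots = _plots_with_env({"ph": [6.0, 6.0, 6.0, 6.0]})
    res = env_gradient_check(_study_with_plots(plots), "MIX")
    assert bool(res.loc["ph", "constant"])
    assert math.isnan(res.loc["ph", "p"])


def test_env_null_p_uniform():
    """p-values of an age-independent variable are uniform on (0,1)."""
    rng = np.random.default_rng(0)
    ages = tuple(float(a) for a in (12, 19, 27, 33, 48, 61))
    pvals = []
    for _ in range(400):
        plots = _plots_with_env({"v": list(rng.normal(size=6))}, ages)
        res = env_gradient_check(_study_with_plots(plots), "MIX")
        pvals.append(res.loc["v", "p"])
    d, p_ks = stats.kstest(pvals, "uniform")
    assert p_ks > 0.01


def test_env_synthetic_openness_decreases():
    study, _ = generate_study(SyntheticConfig(seed=2, n_species=10, n_plots_per_type=6))
    for ft in ("MIX", "OAK"):
        res = env_gradient_check(study, ft)
        assert res.loc["canopy_openness_dry", "slope"] < 0
        assert res.loc["canopy_openness_wet", "slope"] < 0


# ----------------------------------------------------------------------
# Quasi-binomial GLM
# ----------------------------------------------------------------------


def _glm_toy_study(counts=(8, 6, 4, 2), totals=(10, 10, 10, 10)):
    """Per-plot deciduous/total counts realized through two species."""
    ages = (10.0, 20.0, 30.0, 40.0)
    plots = [make_plot(f"P{i}", age=a) for i, a in enumerate(ages)]
    species = [
        make_species("D", phenology="deciduous"),
        make_species("E", phenology="evergreen"),
    ]
    individuals = []
    for i, (k, n) in enumerate(zip(counts, totals)):
        individuals += [make_individual(f"P{i}", "D", y=1.0)] * k
        individuals += [make_individual(f"P{i}", "E", y=1.0)] * (n - k)
    return make_study(plots, species, individuals)


def _irls_oracle(counts, totals, ages, tol=1e-10):
    """From-scratch IRLS for the binomial logit model with intercept + age."""
    y = np.asarray(counts, float)
    n = np.asarray(totals, float)
    X = np.column_stack([np.ones(len(ages)), np.asarray(ages, float)])
    beta = np.zeros(2)
    for _ in range(200):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = n * mu * (1.0 - mu)
        z = eta + (y / n - mu) / (mu * (1.0 - mu))
        new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def test_glm_matches_irls_oracle():
    study = _glm_toy_study()
    res = fit_categorical_trait_glm(study, "phenology", "deciduous")
    assert res.retained_terms == ["age"]
    expected = _irls_oracle((8, 6, 4, 2), (10, 10, 10, 10), (10, 20, 30, 40))
    assert res.coefficients["intercept"] == pytest.approx(expected[0], abs=1e-8)
    assert res.coefficients["age"] == pytest.approx(expected[1], abs=1e-8)
    assert res.coefficients["age"] < 0
    assert res.dispersion > 0
    assert 0 <= res.pseudo_r2 <= 1


def test_glm_score_equations():
    study = _glm_toy_study()
    res = fit_categorical_trait_glm(study, "phenology", "deciduous")
    b0, b1 = res.coefficients["intercept"], res.coefficients["age"]
    ages = np.array([10.0, 20.0, 30.0, 40.0])
    mu = 1 / (1 + np.exp(-(b0 + b1 * ages)))
    y = np.array([8.0, 6.0, 4.0, 2.0])
    n = np.full(4, 10.0)
    score = np.array([np.sum(y - n * mu), np.sum(ages * (y - n * mu))])
    assert np.max(np.abs(score)) < 1e-6


def test_glm_no_signal_drops_age():
    study = _glm_toy_study(counts=(5, 5, 5, 5))
    res = fit_categorical_trait_glm(study, "phenology", "deciduous")
    assert "age" not in res.retained_terms
    assert res.retained_terms == []


def test_glm_separation_flag():
    study = _glm_toy_study(counts=(10, 10, 10, 10))
    res = fit_categorical_trait_glm(study, "phenology", "deciduous")
    assert res.separation


def test_glm_plot_relabeling_invariance():
    study = _glm_toy_study()
    res1 = fit_categorical_trait_glm(study, "phenology", "deciduous")
    # rebuild with shuffled plot ids (same ages/counts)
    relabeled = _glm_toy_study()
    for p, new in zip(relabeled.plots, ["Z3", "Z1", "Z4", "Z2"]):
        old = p.plot_id
        p.plot_id = new
        for ind in relabeled.individuals:
            if ind.plot_id == old:
                ind.plot_id = new
    relabeled = make_study(relabeled.plots, relabeled.species, relabeled.individuals)
    res2 = fit_categorical_trait_glm(relabeled, "phenology", "deciduous")
    assert res1.coefficients["age"] == pytest.approx(res2.coefficients["age"], abs=1e-10)


def test_glm_two_forest_types_backward_selection():
    """With a shared age trend across forest types the interaction and the
    forest main effect are dropped."""
    ages = (10.0, 16.0, 22.0, 28.0, 34.0, 40.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0)
    fts = ("MIX",) * 6 + ("OAK",) * 6
    plots = [make_plot(f"P{i:02d}", forest_type=ft, age=a) for i, (a, ft) in enumerate(zip(ages, fts))]
    species = [
        make_species("D", phenology="deciduous"),
        make_species("E", phenology="evergreen"),
    ]
    individuals = []
    rng = np.random.default_rng(0)
    for i, a in enumerate(ages):
        p = 1 / (1 + math.exp(-(2.0 - 0.08 * a)))
        k = int(rng.binomial(40, p))  # binomial noise keeps dispersion ~ 1
        individuals += [make_individual(f"P{i:02d}", "D", y=1.0)] * k
        individuals += [make_individual(f"P{i:02d}", "E", y=1.0)] * (40 - k)
    study = make_study(plots, species, individuals)
    res = fit_categorical_trait_glm(study, "phenology", "deciduous")
    assert "age" in res.retained_terms
    assert "age:forest" not in res.retained_terms
    assert res.coefficients["age"] < 0


# ----------------------------------------------------------------------
# Linear mixed models
# ----------------------------------------------------------------------


def _lmm_study(seed=0, **kw):
    base = dict(
        seed=seed, n_species=20, n_plots_per_type=6, species_mean_sd=0.3,
        ontogeny_slope=-0.9, cii_slope=0.05, noise_sd=0.2, mean_abundance=1.5,
        niche_width=50.0, traits=("SLA",),
    )
    base.update(kw)
    study, truth = generate_study(SyntheticConfig(**base))
    for ind in study.individuals:
        # values were generated on the linear scale; exponentiate so the
        # log response of the mixed model recovers the planted coefficients
        ind.trait_values = {t: math.exp(v - 8.0) for t, v in ind.trait_values.items()}
    return study, truth


def test_lmm_eligibility_filter():
    plots = [make_plot("P1"), make_plot("P2", age=30.0)]
    species = [make_species("A"), make_species("B")]
    individuals = [
        make_individual("P1", "A", height=1.25, y=1.0),
        make_individual("P2", "A", height=2.75, y=2.0),
        make_individual("P1", "B", height=1.25, y=1.0),  # single height class
        make_individual("P2", "B", height=1.25, y=2.0),
    ]
    study = make_study(plots, species, individuals)
    df = lmm_eligible_frame(study, "y")
    assert set(df["species_id"]) == {"A"}


def test_lmm_nonpositive_values_error():
    plots = [make_plot("P1")]
    species = [make_species("A")]
    individuals = [
        make_individual("P1", "A", height=1.25, y=-1.0),
        make_individual("P1", "A", height=2.75, y=2.0),
    ]
    study = make_study(plots, species, individuals)
    with pytest.raises(ValueError, match="non-positive"):
        lmm_eligible_frame(study, "y")


def test_lmm_degenerate_hierarchy_matches_ols():
    """Zero species-level variance: intercept-only structure with ~0 variance
    and fixed estimates matching ordinary least squares."""
    study, _ = _lmm_study(seed=1, species_mean_sd=1e-8, cii_slope=0.0)
    res = fit_itv_lmm(study, "SLA")
    assert res.random_structure == "intercept"
    # the REML variance estimate absorbs a little noise but stays negligible
    assert res.var_random < 0.05 * res.var_residual
    df = lmm_eligible_frame(study, "SLA")
    # OLS with the same retained fixed terms
    from traitflux.gradient_models import _lmm_design

    X, names = _lmm_design(df, res.fixed_terms)
    beta = np.linalg.lstsq(X, df["log_value"].to_numpy(), rcond=None)[0]
    for name, b in zip(names, beta):
        assert res.coefficients[name] == pytest.approx(b, abs=0.1)


def test_lmm_r2_ordering_and_variances():
    study, _ = _lmm_study(seed=2)
    res = fit_itv_lmm(study, "SLA")
    assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0
    assert res.var_fixed >= 0 and res.var_random >= 0 and res.var_residual > 0


def test_lmm_recovers_planted_slope_single_fit():
    study, _ = _lmm_study(seed=3, noise_sd=0.05)
    res = fit_itv_lmm(study, "SLA")
    assert "h_rel" in res.fixed_terms
    assert res.coefficients["h_rel"] == pytest.approx(-0.9, abs=0.25)


def test_lmm_random_slope_detected_when_planted():
    """Species-varying ontogeny slopes favour the intercept+slope structure."""
    study, _ = _lmm_study(seed=4, noise_sd=0.05, ontogeny_slope=0.0)
    rng = np.random.default_rng(99)
    slope_of = {s.species_id: rng.normal(-0.9, 1.2) for s in study.species}
    for ind in study.individuals:
        h_rel = study.h_rel(ind)
        ind.trait_values = {
            t: v * math.exp(slope_of[ind.species_id] * h_rel)
            for t, v in ind.trait_values.items()
        }
    res = fit_itv_lmm(study, "SLA")
    assert res.random_structure == "intercept_slope"
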