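"""Regression layer: environment-vs-age checks, quasi-binomial logit models
for community proportions of species-level categorical traits, and linear
mixed models for individual-scale trait variation vs ontogeny and light.

The mixed model treats the natural log of each individual's trait value as
a function of relative height (H/Hmax), forest type, crown illumination and
the height × forest interaction, with species as a random factor on the
intercept and optionally on the H/Hmax slope.  Random structure and fixed
terms are selected by AIC (restricted likelihood for the random part with a
common fixed part, full likelihood for fixed-term comparisons), and the
final model is refitted by restricted likelihood.  Marginal R² is the share
of variance from fixed effects only, conditional R² from fixed plus random
effects; with a random slope the random-effect variance is averaged over
the observed H/Hmax design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .core_data import Study
from .cwm_partition import _ols

__all__ = [
    "GLMResult",
    "LMMResult",
    "env_gradient_check",
    "fit_categorical_trait_glm",
    "fit_itv_lmm",
    "lmm_eligible_frame",
]


# ----------------------------------------------------------------------
# Environment vs successional age
# ----------------------------------------------------------------------


def env_gradient_check(study: Study, forest_type: str) -> pd.DataFrame:
    """OLS slope and two-sided p of each environment variable on age."""
    plots = study.plots_of(forest_type)
    if len(plots) < 3:
        raise ValueError(f"need >=3 plots in forest type {forest_type!r}")
    ages = np.asarray([p.successional_age for p in plots])
    rows = []
    for var in study.env_variables:
        y = np.asarray([p.env.get(var, math.nan) for p in plots])
        if np.any(~np.isfinite(y)):
            rows.append({"variable": var, "slope": math.nan, "p": math.nan,
                         "band": "missing", "constant": False})
            continue
        if np.ptp(y) == 0:
            rows.append({"variable": var, "slope": 0.0, "p": math.nan,
                         "band": "constant", "constant": True})
            continue
        slope, p, _ = _ols(ages, y)
        band = "p<0.05" if p < 0.05 else ("p<0.1" if p < 0.1 else "ns")
        rows.append({"variable": var, "slope": slope, "p": p,
                     "band": band, "constant": False})
    return pd.DataFrame(rows).set_index("variable")


# ----------------------------------------------------------------------
# Quasi-binomial GLM with backward selection
# ----------------------------------------------------------------------


@dataclass
class GLMResult:
    trait: str
    level: str
    retained_terms: list[str]
    coefficients: dict[str, float]
    dispersion: float
    term_pvalues: dict[str, float]  # drop-one F-test p for each retained term
    pseudo_r2: float
    separation: bool = False
    selection_trace: list[str] = field(default_factory=list)


_TERM_ORDER = ["age:forest", "age", "forest"]  # interaction dropped first


def _glm_design(ages: np.ndarray, forest: np.ndarray, terms: list[str]) -> np.ndarray:
    cols = [np.ones_like(ages)]
    for t in terms:
        if t == "age":
            cols.append(ages)
        elif t == "forest":
            cols.append(forest)
        elif t == "age:forest":
            cols.append(ages * forest)
    return np.column_stack(cols)


def _fit_quasibinomial(endog: np.ndarray, exog: np.ndarray):
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def fit_categorical_trait_glm(
    study: Study, trait: str, level: str, threshold: float = 0.05
) -> GLMResult:
    """Quasi-binomial logit model of per-plot proportions of saplings whose
    species carries ``level`` of the species-level categorical ``trait``,
    with backward selection over age, forest type and their interaction.

    Term significance uses F-tests on quasi-deviance differences with the
    Pearson-based dispersion of the fuller model; the least significant term
    above ``threshold`` is dropped first, the interaction before main
    effects, until all retained terms are significant.
    """
    plots = sorted(study.plots, key=lambda p: p.plot_id)
    counts, totals = [], []
    for p in plots:
        inds = study.individuals_in_plot(p.plot_id)
        totals.append(len(inds))
        counts.append(
            sum(
                study.species_info(i.species_id).categorical_value(trait) == level
                for i in inds
            )
        )
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if np.any(totals == 0):
        raise ValueError("plot with zero individuals")
    props = counts / totals
    separation = bool(np.all(props == 0) or np.all(props == 1))
    ages = np.asarray([p.successional_age for p in plots])
    forest = np.asarray([1.0 if p.forest_type == "OAK" else 0.0 for p in plots])
    two_types = len(set(forest)) > 1
    terms = [t for t in _TERM_ORDER if two_types or t == "age"]
    endog = np.column_stack([counts, totals - counts])
    trace: list[str] = []

    def droppable(current: list[str]) -> list[str]:
        out = []
        for t in current:
            if t in ("age", "forest") and "age:forest" in current:
                continue  # marginality: mains stay while the interaction stays
            out.append(t)
        return [t for t in _TERM_ORDER if t in out]  # interaction first

    while True:
        full = _fit_quasibinomial(endog, _glm_design(ages, forest, terms))
        df_full = full.df_resid
        if df_full <= 0:
            break
        phi = float(full.pearson_chi2 / df_full)
        pvals: dict[str, float] = {}
        for t in droppable(terms):
            reduced_terms = [x for x in terms if x != t]
            red = _fit_quasibinomial(endog, _glm_design(ages, forest, reduced_terms))
            num = (red.deviance - full.deviance) / 1.0
            if num <= 1e-12:
                pvals[t] = 1.0  # dropping the term changes nothing
            elif phi <= 0:
                pvals[t] = 0.0  # exact fit elsewhere: any change is decisive
            else:
                pvals[t] = float(stats.f.sf(num / phi, 1, df_full))
        worst = None
        for t in _TERM_ORDER:  # deterministic: higher-order terms first on ties
            if t in pvals and pvals[t] > threshold:
                if worst is None or pvals[t] > pvals[worst]:
                    worst = t
        if worst is None or not terms:
            break
        terms = [x for x in terms if x != worst]
        trace.append(f"dropped {worst} (p={pvals[worst]:.4f})")
        if not terms:
            break

    final = _fit_quasibinomial(endog, _glm_design(ages, forest, terms))
    df_final = max(final.df_resid, 1)
    phi = float(final.pearson_chi2 / df_final)
    null = _fit_quasibinomial(endog, np.ones((len(plots), 1)))
    pseudo_r2 = float(1.0 - final.deviance / null.deviance) if null.deviance > 0 else 0.0
    names = ["intercept"] + terms
    coefficients = dict(zip(names, map(float, final.params)))
    # drop-one p-values for the retained terms, for reporting
    term_p: dict[str, float] = {}
    for t in terms:
        red = _fit_quasibinomial(endog, _glm_design(ages, forest, [x for x in terms if x != t]))
        f = (red.deviance - final.deviance) / phi if phi > 0 else math.inf
        term_p[t] = float(stats.f.sf(f, 1, final.df_resid)) if final.df_resid > 0 else math.nan
    return GLMResult(
        trait=trait,
        level=level,
        retained_terms=terms,
        coefficients=coefficients,
        dispersion=phi,
        term_pvalues=term_p,
        pseudo_r2=pseudo_r2,
        separation=separation,
        selection_trace=trace,
    )


# ----------------------------------------------------------------------
# Linear mixed models for individual-scale ITV
# ----------------------------------------------------------------------


@dataclass
class LMMResult:
    trait: str
    random_structure: str  # "intercept" | "intercept_slope"
    fixed_terms: list[str]
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    var_fixed: float
    var_random: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_species: int
    flags: list[str] = field(default_factory=list)
    aic_trace: list[str] = field(default_factory=list)


def lmm_eligible_frame(study: Study, trait: str) -> pd.DataFrame:
    """Rows entering the individual-scale model for ``trait``.

    Kept: individuals with a CII score and a measured/imputed trait value
    whose species has a known Hmax and at least one individual in two
    different height classes of the same forest type.
    """
    ft_of = {p.plot_id: p.forest_type for p in study.plots}
    classes: dict[tuple[str, str], set[float]] = {}
    for ind in study.individuals:
        key = (ind.species_id, ft_of[ind.plot_id])
        classes.setdefault(key, set()).add(ind.height_class_midpoint)
    eligible_keys = {k for k, v in classes.items() if len(v) >= 2}
    rows = []
    bad_rows = []
    for ind in study.individuals:
        ft = ft_of[ind.plot_id]
        if (ind.species_id, ft) not in eligible_keys:
            continue
        sp = study.species_info(ind.species_id)
        if not (sp.hmax > 0) or math.isnan(sp.hmax):
            continue
        if ind.cii is None or trait not in ind.trait_values:
            continue
        v = ind.trait_values[trait]
        if v <= 0:
            bad_rows.append(ind.individual_id)
            continue
        rows.append(
            {
                "individual_id": ind.individual_id,
                "species_id": ind.species_id,
                "plot_id": ind.plot_id,
                "forest_type": ft,
                "h_rel": ind.height_class_midpoint / sp.hmax,
                "cii": float(ind.cii),
                "log_value": math.log(v),
            }
        )
    if bad_rows:
        raise ValueError(
            f"non-positive {trait!r} values under log transform for individuals "
            f"{bad_rows[:10]} ({len(bad_rows)} total)"
        )
    return pd.DataFrame(rows)


_LMM_TERM_ORDER = ["h_rel:forest", "h_rel", "forest", "cii"]


def _lmm_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(df))], ["intercept"]
    forest = (df["forest_type"] == "OAK").to_numpy(dtype=float)
    for t in terms:
        if t == "h_rel":
            cols.append(df["h_rel"].to_numpy())
        elif t == "forest":
            cols.append(forest)
        elif t == "cii":
            cols.append(df["cii"].to_numpy())
        elif t == "h_rel:forest":
            cols.append(df["h_rel"].to_numpy() * forest)
        names.append(t)
    return np.column_stack(cols), names


def _fit_mixed(df, terms, random_slope, reml):
    X, names = _lmm_design(df, terms)
    exog_re = (
        np.column_stack([np.ones(len(df)), df["h_rel"].to_numpy()])
        if random_slope
        else np.ones((len(df), 1))
    )
    model = sm.MixedLM(
        df["log_value"].to_numpy(), X, groups=df["species_id"].to_numpy(),
        exog_re=exog_re,
    )
    last_exc: Exception | None = None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method, maxiter=1000)
            return res, names
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc  # near-singular random structure; try another optimizer
    raise last_exc


def _n_cov_params(random_slope: bool) -> int:
    return 3 if random_slope else 1  # var(int) [+ var(slope) + cov]


def _aic(res, n_fixed: int, random_slope: bool) -> float:
    if not math.isfinite(res.llf):  # boundary/degenerate optimum
        return math.inf
    k = n_fixed + _n_cov_params(random_slope) + 1  # + residual variance
    return float(-2.0 * res.llf + 2.0 * k)


def fit_itv_lmm(study: Study, trait: str) -> LMMResult:
    """Fit and select the individual-scale mixed model for one trait."""
    df = lmm_eligible_frame(study, trait)
    if df.empty or df["species_id"].nunique() < 2:
        raise ValueError(f"not enough eligible data for trait {trait!r}")
    two_types = df["forest_type"].nunique() > 1
    full_terms = [t for t in _LMM_TERM_ORDER if two_types or t in ("h_rel", "cii")]
    full_terms = [t for t in ["h_rel", "forest", "cii", "h_rel:forest"] if t in full_terms]
    flags: list[str] = []
    trace: list[str] = []

    # -- random structure by REML AIC with the full fixed part ---------
    aics = {}
    for slope in (False, True):
        try:
            res, _ = _fit_mixed(df, full_terms, slope, reml=True)
            aics[slope] = _aic(res, len(full_terms) + 1, slope)
        except Exception as exc:  # singular fits on degenerate data
            aics[slope] = math.inf
            flags.append(f"random structure {'I+S' if slope else 'I'} failed: {exc}")
    random_slope = bool(aics.get(True, math.inf) < aics.get(False, math.inf))
    trace.append(
        f"random AIC: intercept={aics.get(False):.2f} "
        f"intercept+slope={aics.get(True):.2f} -> "
        f"{'I+S' if random_slope else 'I'}"
    )

    # -- fixed terms by ML AIC, backward with marginality --------------
    terms = list(full_terms)
    while True:
        cur, _ = _fit_mixed(df, terms, random_slope, reml=False)
        cur_aic = _aic(cur, len(terms) + 1, random_slope)
        candidates = [
            t
            for t in _LMM_TERM_ORDER  # interaction considered first
            if t in terms
            and not (t in ("h_rel", "forest") and "h_rel:forest" in terms)
        ]
        best_t, best_aic = None, cur_aic
        for t in candidates:
            red, _ = _fit_mixed(df, [x for x in terms if x != t], random_slope, reml=False)
            a = _aic(red, len(terms), random_slope)
            if a < best_aic - 1e-9:
                best_t, best_aic = t, a
        if best_t is None:
            break
        terms = [x for x in terms if x != best_t]
        trace.append(f"dropped {best_t} (AIC {cur_aic:.2f} -> {best_aic:.2f})")

    # -- final REML refit ---------------------------------------------
    res, names = _fit_mixed(df, terms, random_slope, reml=True)
    beta = np.asarray(res.fe_params, dtype=float)
    X, _ = _lmm_design(df, terms)
    y = df["log_value"].to_numpy()
    G = np.asarray(res.cov_re, dtype=float)
    if random_slope:
        Z = np.column_stack([np.ones(len(df)), df["h_rel"].to_numpy()])
        var_r = float(np.mean(np.einsum("ij,jk,ik->i", Z, G, Z)))
    else:
        var_r = float(G[0, 0])
    var_r = max(var_r, 0.0)
    var_e = float(res.scale)
    se = np.asarray(res.bse_fe, dtype=float)
    singular = var_r < 1e-8 * float(np.var(y)) or not np.all(np.isfinite(beta))
    if singular:
        # zero random variance: the model degenerates to ordinary least
        # squares on the fixed design, which is better conditioned
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        var_e = float(resid @ resid / dof)
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(xtx_inv) * var_e)
        var_r = 0.0
        flags.append("singular fit: random-effect variance ~ 0 (fixed-only model)")
    var_f = float(np.var(X @ beta))
    denom = var_f + var_r + var_e
    r2m = var_f / denom if denom > 0 else math.nan
    r2c = (var_f + var_r) / denom if denom > 0 else math.nan

    n, p = len(df), len(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(n - p, 1))
    return LMMResult(
        trait=trait,
        random_structure="intercept_slope" if random_slope else "intercept",
        fixed_terms=terms,
        coefficients=dict(zip(names, map(float, beta))),
        pvalues=dict(zip(names, map(float, pvals))),
        var_fixed=var_f,
        var_random=var_r,
        var_residual=var_e,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=n,
        n_species=int(df["species_id"].nunique()),
        flags=flags,
        aic_trace=trace,
    )
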