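"""Specific/fixed community-weighted means and the turnover/ITV/covariation
sum-of-squares partition, overall and against successional age.

Two flavours of community-weighted mean (CWM) per plot and quantitative
trait are compared:

* *specific* — abundance-weighted mean using each species' mean trait value
  in that plot (reflects species turnover **and** within-species shifts);
* *fixed* — abundance-weighted mean using each species' mean computed over
  all plots of the same forest type (reflects turnover only).

Their difference (specific − fixed) isolates the intraspecific (ITV)
component.  Among-plot sums of squares of the three series partition the
total variation; in gradient mode the explained sums of squares of
ordinary least-squares regressions on successional age are partitioned
instead, with the covariation term obtained by subtraction (it may be
negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Study

__all__ = [
    "CWMTable",
    "DecompositionResult",
    "compute_cwm",
    "cwm_table",
    "decompose_total",
    "decompose_vs_gradient",
]


@dataclass
class DecompositionResult:
    trait: str
    forest_type: str
    mode: str  # "total" | "gradient"
    ss_total: float
    ss_turnover: float
    ss_itv: float
    ss_cov: float
    pct_turnover: float
    pct_itv: float
    pct_cov: float
    slope_total: float | None = None
    p_total: float | None = None
    slope_turnover: float | None = None
    p_turnover: float | None = None
    slope_itv: float | None = None
    p_itv: float | None = None
    degenerate: bool = False  # SS_total == 0: contributions undefined

    def as_row(self) -> dict:
        return {
            "forest_type": self.forest_type,
            "trait": self.trait,
            "mode": self.mode,
            "ss_total": self.ss_total,
            "ss_turnover": self.ss_turnover,
            "ss_itv": self.ss_itv,
            "ss_cov": self.ss_cov,
            "pct_turnover": self.pct_turnover,
            "pct_itv": self.pct_itv,
            "pct_cov": self.pct_cov,
            "slope_turnover": self.slope_turnover,
            "p_turnover": self.p_turnover,
            "slope_itv": self.slope_itv,
            "p_itv": self.p_itv,
            "slope_total": self.slope_total,
            "p_total": self.p_total,
        }


@dataclass
class CWMTable:
    """Plots × traits community-weighted means in the three flavours."""

    specific: pd.DataFrame
    fixed: pd.DataFrame
    itv: pd.DataFrame
    weights: pd.DataFrame = field(repr=False)  # plots × species relative abundance


def _abundance_weights(study: Study) -> pd.DataFrame:
    """Relative abundance (individual counts) of species per plot."""
    counts: dict[str, dict[str, int]] = {p.plot_id: {} for p in study.plots}
    for ind in study.individuals:
        counts[ind.plot_id][ind.species_id] = (
            counts[ind.plot_id].get(ind.species_id, 0) + 1
        )
    w = pd.DataFrame(counts).T.fillna(0.0).sort_index()
    empty = w.index[w.sum(axis=1) == 0]
    if len(empty):
        raise ValueError(f"plot(s) with zero individuals: {list(empty)}")
    return w.div(w.sum(axis=1), axis=0)


def _species_plot_means(study: Study, trait: str) -> dict[tuple[str, str], float]:
    acc: dict[tuple[str, str], list[float]] = {}
    for ind in study.individuals:
        if trait in ind.trait_values:
            acc.setdefault((ind.species_id, ind.plot_id), []).append(
                ind.trait_values[trait]
            )
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _species_forest_means(study: Study, trait: str) -> dict[tuple[str, str], float]:
    """Fixed species mean: individual-weighted mean over all plots of the
    forest type (not the mean of per-plot means)."""
    ft_of = {p.plot_id: p.forest_type for p in study.plots}
    acc: dict[tuple[str, str], list[float]] = {}
    for ind in study.individuals:
        if trait in ind.trait_values:
            acc.setdefault((ind.species_id, ft_of[ind.plot_id]), []).append(
                ind.trait_values[trait]
            )
    return {k: float(np.mean(v)) for k, v in acc.items()}


def compute_cwm(study: Study, trait: str, mode: str) -> pd.Series:
    """Per-plot community-weighted mean of ``trait`` (``specific`` or ``fixed``)."""
    if study.trait(trait).kind != "quantitative":
        raise ValueError(f"trait {trait!r} is not quantitative")
    if mode not in ("specific", "fixed"):
        raise ValueError(f"unknown CWM mode {mode!r}")
    weights = _abundance_weights(study)
    ft_of = {p.plot_id: p.forest_type for p in study.plots}
    means = (
        _species_plot_means(study, trait)
        if mode == "specific"
        else _species_forest_means(study, trait)
    )
    out = {}
    for plot_id, row in weights.iterrows():
        total = 0.0
        for species_id, w in row.items():
            if w == 0:
                continue
            key = (
                (species_id, plot_id)
                if mode == "specific"
                else (species_id, ft_of[plot_id])
            )
            if key not in means:
                raise ValueError(
                    f"species {species_id!r} has no measured {trait!r} value in "
                    f"scope of plot {plot_id!r}; run imputation first"
                )
            total += w * means[key]
        out[plot_id] = total
    return pd.Series(out, name=f"{trait}_{mode}").sort_index()


def cwm_table(study: Study, traits: list[str] | None = None) -> CWMTable:
    names = traits or [t.name for t in study.quantitative_traits]
    spec = pd.DataFrame({t: compute_cwm(study, t, "specific") for t in names})
    fixed = pd.DataFrame({t: compute_cwm(study, t, "fixed") for t in names})
    return CWMTable(
        specific=spec, fixed=fixed, itv=spec - fixed, weights=_abundance_weights(study)
    )


def _series_for(study: Study, trait: str, forest_type: str):
    plot_ids = sorted(p.plot_id for p in study.plots_of(forest_type))
    if len(plot_ids) < 3:
        raise ValueError(f"need >=3 plots in forest type {forest_type!r}")
    sub = Study(
        study.traits,
        study.species,
        study.plots_of(forest_type),
        study.individuals_of(forest_type),
    )
    spec = compute_cwm(sub, trait, "specific").loc[plot_ids]
    fixed = compute_cwm(sub, trait, "fixed").loc[plot_ids]
    ages = np.asarray([study.plot(pid).successional_age for pid in plot_ids])
    return spec.to_numpy(), fixed.to_numpy(), ages


def decompose_total(study: Study, trait: str, forest_type: str) -> DecompositionResult:
    """Partition among-plot total variation of the specific CWM."""
    spec, fixed, _ = _series_for(study, trait, forest_type)
    itv = spec - fixed
    ss_total = float(np.sum((spec - spec.mean()) ** 2))
    ss_turn = float(np.sum((fixed - fixed.mean()) ** 2))
    ss_itv = float(np.sum((itv - itv.mean()) ** 2))
    return _finalize(trait, forest_type, "total", ss_total, ss_turn, ss_itv)


def decompose_vs_gradient(
    study: Study, trait: str, forest_type: str
) -> DecompositionResult:
    """Partition the explained variation of the specific CWM vs successional age."""
    spec, fixed, ages = _series_for(study, trait, forest_type)
    if np.ptp(ages) == 0:
        raise ValueError("successional age is constant; gradient mode undefined")
    itv = spec - fixed
    (b_t, p_t, ss_t) = _ols(ages, spec)
    (b_f, p_f, ss_f) = _ols(ages, fixed)
    (b_i, p_i, ss_i) = _ols(ages, itv)
    res = _finalize(trait, forest_type, "gradient", ss_t, ss_f, ss_i)
    res.slope_total, res.p_total = b_t, p_t
    res.slope_turnover, res.p_turnover = b_f, p_f
    res.slope_itv, res.p_itv = b_i, p_i
    return res


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, two-sided t-test p-value and explained SS of y ~ x."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.sum(xc**2))
    slope = float(np.sum(xc * yc) / sxx)
    ss_explained = slope * slope * sxx
    ss_resid = float(np.sum((yc - slope * xc) ** 2))
    df = n - 2
    if df <= 0 or ss_resid <= 0:
        p = 0.0 if ss_explained > 0 else 1.0
    else:
        se = math.sqrt(ss_resid / df / sxx)
        t = slope / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return slope, p, ss_explained


def _finalize(
    trait: str,
    forest_type: str,
    mode: str,
    ss_total: float,
    ss_turn: float,
    ss_itv: float,
) -> DecompositionResult:
    ss_cov = ss_total - ss_turn - ss_itv
    if ss_total <= 0:
        return DecompositionResult(
            trait, forest_type, mode, ss_total, ss_turn, ss_itv, ss_cov,
            math.nan, math.nan, math.nan, degenerate=True,
        )
    return DecompositionResult(
        trait, forest_type, mode, ss_total, ss_turn, ss_itv, ss_cov,
        pct_turnover=100.0 * ss_turn / ss_total,
        pct_itv=100.0 * ss_itv / ss_total,
        pct_cov=100.0 * ss_cov / ss_total,
    )
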