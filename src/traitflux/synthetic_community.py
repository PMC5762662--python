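"""Synthetic sapling communities with known ground truth.

Generates studies with the statistical structure the analysis pipeline
assumes: correlated species-mean leaf traits (a leaf-economics axis),
Gaussian niche turnover of composition along a successional-age gradient,
within-species trait shifts along the same gradient, ontogenetic and
light (crown illumination) effects at the individual level, and plot
environment variables that are monotone functions of age plus noise.

The generator stores a :class:`SyntheticTruth` sufficient to predict the
expected turnover/ITV decomposition by direct evaluation of the generating
model, independently of the analysis code, for parameter-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .core_data import (
    HEIGHT_CLASS_MIDPOINTS,
    IndividualRecord,
    PlotEnvironment,
    SpeciesInfo,
    Study,
    TraitDefinition,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_study",
    "truth_expected_decomposition",
    "DEFAULT_TRAITS",
]

#: Quantitative traits generated by default, with their leaf-economics
#: loadings (sign of association with the acquisitive end of the axis).
DEFAULT_TRAITS: dict[str, float] = {
    "SLA": +1.0,
    "LNC": +1.0,
    "LPC": +1.0,
    "thickness": -1.0,
    "LDMC": -1.0,
    "density": -1.0,
}

_DEFAULT_AGE_RANGES = {"MIX": (19.0, 67.0), "OAK": (12.0, 37.0)}


class ConfigError(ValueError):
    """Invalid synthetic-community configuration."""


def _per_trait(value, traits: tuple[str, ...], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {t: float(value.get(t, 0.0)) for t in traits}
    return {t: float(value) for t in traits}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_plots_per_type: int = 6
    forest_types: tuple[str, ...] = ("MIX", "OAK")
    age_ranges: dict = field(default_factory=lambda: dict(_DEFAULT_AGE_RANGES))
    n_species: int = 50
    traits: tuple[str, ...] = tuple(DEFAULT_TRAITS)
    trait_correlation: float = 0.7
    species_mean_sd: float = 1.0
    turnover_strength: float | Mapping = 0.0
    itv_strength: float | Mapping = 0.0
    ontogeny_slope: float | Mapping = 0.0
    cii_slope: float | Mapping = 0.0
    noise_sd: float | Mapping = 0.1
    mean_abundance: float = 3.0
    niche_width: float = 25.0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if not 0.0 <= self.trait_correlation < 1.0:
            raise ConfigError(
                "trait_correlation must be in [0, 1) for a positive-definite "
                "species-mean covariance"
            )
        noise = _per_trait(self.noise_sd, self.traits, "noise_sd")
        if any(v <= 0 for v in noise.values()):
            raise ConfigError("noise_sd must be > 0 for every trait")
        for ft in self.forest_types:
            lo, hi = self.age_ranges[ft]
            if not 0 < lo < hi:
                raise ConfigError(f"invalid age range for {ft}: ({lo}, {hi})")

    def resolved(self, name: str) -> dict[str, float]:
        return _per_trait(getattr(self, name), self.traits, name)


@dataclass
class SyntheticTruth:
    """Generating-model parameters needed to predict expected outcomes."""

    config: SyntheticConfig
    species_means: dict[str, dict[str, float]]  # species -> trait -> mean
    niche_optima: dict[str, float]
    mean_age: dict[str, float]  # per forest type
    turnover_slope: dict[str, float]
    itv_slope: dict[str, float]
    ontogeny_slope: dict[str, float]
    cii_slope: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["config"]["traits"] = list(self.config.traits)
        payload["config"]["forest_types"] = list(self.config.forest_types)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_study(config: SyntheticConfig) -> tuple[Study, SyntheticTruth]:
    """Generate a study and its ground truth from ``config`` (deterministic)."""
    rng = np.random.default_rng(config.seed)
    traits = config.traits
    turnover = config.resolved("turnover_strength")
    itv = config.resolved("itv_strength")
    onto = config.resolved("ontogeny_slope")
    cii_sl = config.resolved("cii_slope")
    noise = config.resolved("noise_sd")
    rho = config.trait_correlation

    # -- plots ---------------------------------------------------------
    plots: list[PlotEnvironment] = []
    ages_all: list[float] = []
    for ft in config.forest_types:
        lo, hi = config.age_ranges[ft]
        ages = np.linspace(lo, hi, config.n_plots_per_type)
        for k, age in enumerate(ages):
            env = {
                "canopy_openness_dry": 45.0 - 0.40 * age + rng.normal(0, 1.5),
                "canopy_openness_wet": 35.0 - 0.30 * age + rng.normal(0, 1.5),
                "air_temp_dry": 32.0 - 0.06 * age + rng.normal(0, 0.4),
                "air_temp_wet": 28.0 - 0.04 * age + rng.normal(0, 0.4),
                "soil_moisture_dry": 8.0 + 0.10 * age + rng.normal(0, 0.8),
                "soil_moisture_wet": 20.0 + 0.12 * age + rng.normal(0, 0.8),
                "adult_basal_area": 4.0 + 0.35 * age + rng.normal(0, 1.2),
                "soil_ph": (5.4 if ft == "OAK" else 6.3) + rng.normal(0, 0.15),
                "soil_clay": (12.0 if ft == "OAK" else 30.0) + rng.normal(0, 2.0),
            }
            plots.append(
                PlotEnvironment(
                    plot_id=f"{ft}{k + 1:02d}",
                    forest_type=ft,
                    successional_age=float(age),
                    env={k2: float(v) for k2, v in env.items()},
                )
            )
            ages_all.append(float(age))
    mean_age = {
        ft: float(np.mean([p.successional_age for p in plots if p.forest_type == ft]))
        for ft in config.forest_types
    }
    age_mid = float(np.mean(ages_all))
    age_span = max(ages_all) - min(ages_all)

    # -- species means on a latent leaf-economics axis -----------------
    axis = rng.normal(size=config.n_species)
    optima = rng.uniform(min(ages_all), max(ages_all), size=config.n_species)
    species_ids = [f"S{j + 1:03d}" for j in range(config.n_species)]
    hmax = rng.uniform(8.0, 25.0, size=config.n_species)
    species_means: dict[str, dict[str, float]] = {}
    species_list: list[SpeciesInfo] = []
    for j, sid in enumerate(species_ids):
        row: dict[str, float] = {}
        for t in traits:
            loading = DEFAULT_TRAITS.get(t, 0.0) * math.sqrt(rho)
            indep = math.sqrt(max(0.0, 1.0 - rho))
            base = 10.0
            row[t] = base + config.species_mean_sd * (
                loading * axis[j] + indep * rng.normal()
            ) + turnover[t] * (optima[j] - age_mid)
        species_means[sid] = row
        # Categorical traits carry signal along the niche optimum so the
        # GLM stage has something to recover: deciduousness declines and
        # legume frequency rises with later-succession optima.
        z = 4.0 * (optima[j] - age_mid) / max(age_span, 1e-9)
        p_dec = _sigmoid(-z)
        u = rng.uniform()
        if u < p_dec:
            phen = "deciduous"
        elif u < p_dec + 0.7 * (1 - p_dec):
            phen = "evergreen"
        else:
            phen = "intermediate"
        legume = bool(rng.uniform() < _sigmoid(z - 1.0))
        species_list.append(
            SpeciesInfo(
                species_id=sid,
                hmax=float(hmax[j]),
                legume=legume,
                phenology=phen,
                compoundness="bipinnate" if legume else str(
                    rng.choice(["simple", "compound"])
                ),
                pubescence=str(rng.choice(["glabrous", "pubescent"], p=[0.7, 0.3])),
            )
        )

    # -- individuals: Gaussian-niche Poisson abundances ----------------
    individuals: list[IndividualRecord] = []
    counter = 0
    for p in plots:
        lam = config.mean_abundance * np.exp(
            -((p.successional_age - optima) ** 2) / (2.0 * config.niche_width**2)
        )
        counts = rng.poisson(lam)
        if counts.sum() == 0:
            counts[int(np.argmax(lam))] = 1  # every plot keeps >=1 individual
        openness = p.env["canopy_openness_dry"]
        p_cii = min(0.95, max(0.05, 0.35 + 0.012 * (openness - 30.0)))
        for j, sid in enumerate(species_ids):
            for _ in range(int(counts[j])):
                counter += 1
                height = float(rng.choice(HEIGHT_CLASS_MIDPOINTS))
                cii = 1 + int(rng.binomial(4, p_cii))
                h_rel = height / hmax[j]
                values = {}
                for t in traits:
                    values[t] = float(
                        species_means[sid][t]
                        + itv[t] * (p.successional_age - mean_age[p.forest_type])
                        + onto[t] * h_rel
                        + cii_sl[t] * (cii - 3)
                        + rng.normal(0, noise[t])
                    )
                individuals.append(
                    IndividualRecord(
                        individual_id=f"I{counter:05d}",
                        plot_id=p.plot_id,
                        species_id=sid,
                        height_class_midpoint=height,
                        cii=cii,
                        trait_values=values,
                    )
                )

    trait_defs = [
        TraitDefinition(name=t, kind="quantitative", log_transform_for_lmm=False)
        for t in traits
    ] + [
        TraitDefinition("phenology", "categorical", levels=("deciduous", "evergreen", "intermediate")),
        TraitDefinition("compoundness", "categorical", levels=("simple", "compound", "bipinnate")),
        TraitDefinition("pubescence", "binary", levels=("glabrous", "pubescent")),
        TraitDefinition("legume", "binary", levels=("non_legume", "legume")),
    ]
    study = Study(trait_defs, species_list, plots, individuals)
    truth = SyntheticTruth(
        config=config,
        species_means=species_means,
        niche_optima={sid: float(optima[j]) for j, sid in enumerate(species_ids)},
        mean_age=mean_age,
        turnover_slope=turnover,
        itv_slope=itv,
        ontogeny_slope=onto,
        cii_slope=cii_sl,
    )
    return study, truth


# ----------------------------------------------------------------------
# Independent oracle for expected decomposition shares
# ----------------------------------------------------------------------


def truth_expected_decomposition(
    truth: SyntheticTruth,
    study: Study,
    trait: str,
    forest_type: str,
    mode: str = "total",
) -> dict[str, float]:
    """Expected turnover/ITV/covariation shares from the generating model.

    Evaluates the noise-free expectation of every individual's trait value on
    the realized plots and individuals, builds the expected specific/fixed
    community means with explicit loops, and partitions sums of squares from
    first principles.  This does not call the analysis pipeline and serves as
    its recovery oracle.
    """
    if trait not in truth.config.traits:
        raise ValueError(f"trait {trait!r} not generated by this truth")
    plots = [p for p in study.plots if p.forest_type == forest_type]
    if not plots:
        raise ValueError(f"no plots of forest type {forest_type!r}")
    mean_age = truth.mean_age[forest_type]
    itv = truth.itv_slope[trait]
    onto = truth.ontogeny_slope[trait]
    cii_sl = truth.cii_slope[trait]

    def mu(ind) -> float:
        sp = study.species_info(ind.species_id)
        h_rel = ind.height_class_midpoint / sp.hmax
        age = study.plot(ind.plot_id).successional_age
        return (
            truth.species_means[ind.species_id][trait]
            + itv * (age - mean_age)
            + onto * h_rel
            + cii_sl * (ind.cii - 3)
        )

    inds = study.individuals_of(forest_type)
    # Expected fixed species mean: count-weighted mean of expectations over
    # the species' individuals in the forest type.
    by_species: dict[str, list[float]] = {}
    for ind in inds:
        by_species.setdefault(ind.species_id, []).append(mu(ind))
    fixed_mean = {s: sum(v) / len(v) for s, v in by_species.items()}

    specific, fixed = [], []
    for p in plots:
        here = [i for i in inds if i.plot_id == p.plot_id]
        specific.append(sum(mu(i) for i in here) / len(here))
        fixed.append(sum(fixed_mean[i.species_id] for i in here) / len(here))
    specific = np.asarray(specific)
    fixed = np.asarray(fixed)
    itv_series = specific - fixed

    if mode == "total":
        ss_total = float(np.sum((specific - specific.mean()) ** 2))
        ss_turn = float(np.sum((fixed - fixed.mean()) ** 2))
        ss_itv = float(np.sum((itv_series - itv_series.mean()) ** 2))
    elif mode == "gradient":
        ages = np.asarray([p.successional_age for p in plots])
        xc = ages - ages.mean()
        sxx = float(np.sum(xc**2))

        def explained(y: np.ndarray) -> float:
            b = float(np.sum(xc * (y - y.mean())) / sxx)
            return b * b * sxx

        ss_total = explained(specific)
        ss_turn = explained(fixed)
        ss_itv = explained(itv_series)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if ss_total <= 0:
        return {"turnover_pct": math.nan, "itv_pct": math.nan, "cov_pct": math.nan}
    return {
        "turnover_pct": 100.0 * ss_turn / ss_total,
        "itv_pct": 100.0 * ss_itv / ss_total,
        "cov_pct": 100.0 * (ss_total - ss_turn - ss_itv) / ss_total,
    }
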