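"""Domain types, delimited-text I/O, imputation and small community metrics.

The study data model has four tables: trait definitions, species attributes,
plot environments and individual saplings.  All downstream stages (CWM
partitioning, ordination, RLQ, regression models) operate on a fully
cross-referenced :class:`Study`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitDefinition",
    "SpeciesInfo",
    "IndividualRecord",
    "PlotEnvironment",
    "Study",
    "SchemaError",
    "ReferentialIntegrityError",
    "ImputationError",
    "read_study",
    "write_study",
    "impute_missing_traits",
    "sorensen_similarity",
    "kendall_tau",
]

FOREST_TYPES = ("MIX", "OAK")
PHENOLOGY_LEVELS = ("deciduous", "evergreen", "intermediate")
COMPOUNDNESS_LEVELS = ("simple", "compound", "bipinnate")
PUBESCENCE_LEVELS = ("glabrous", "pubescent")

#: 50-cm height classes on [1.0, 4.0] m and their midpoints.
HEIGHT_CLASS_MIDPOINTS = (1.25, 1.75, 2.25, 2.75, 3.25, 3.75)

MISSING_SENTINELS = {"", "NA", "NaN", "nan"}


class SchemaError(ValueError):
    """A table is missing a required column or holds an unparsable value."""


class ReferentialIntegrityError(ValueError):
    """A row references a plot or species that does not exist."""


class ImputationError(ValueError):
    """A quantitative trait cannot be imputed (no measured value in scope)."""


@dataclass(frozen=True)
class TraitDefinition:
    name: str
    kind: str  # "quantitative" | "binary" | "categorical"
    units: str = ""
    log_transform_for_lmm: bool = False
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary", "categorical"):
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and self.levels and len(self.levels) < 2:
            raise ValueError(f"categorical trait {self.name!r} needs >=2 levels")


@dataclass(frozen=True)
class SpeciesInfo:
    species_id: str
    hmax: float
    legume: bool
    phenology: str
    compoundness: str
    pubescence: str

    def __post_init__(self) -> None:
        if not (self.hmax > 0 or math.isnan(self.hmax)):
            raise ValueError(f"hmax must be > 0 for species {self.species_id!r}")

    def categorical_value(self, trait_name: str) -> str:
        if trait_name == "legume":
            return "legume" if self.legume else "non_legume"
        if trait_name in ("phenology", "compoundness", "pubescence"):
            return getattr(self, trait_name)
        raise KeyError(trait_name)


@dataclass
class IndividualRecord:
    individual_id: str
    plot_id: str
    species_id: str
    height_class_midpoint: float
    cii: int | None
    trait_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1.0 <= self.height_class_midpoint <= 4.0:
            raise ValueError(
                f"height_class_midpoint {self.height_class_midpoint} of "
                f"{self.individual_id!r} outside [1.0, 4.0]"
            )


@dataclass
class PlotEnvironment:
    plot_id: str
    forest_type: str
    successional_age: float
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.forest_type not in FOREST_TYPES:
            raise ValueError(f"unknown forest type {self.forest_type!r}")
        if not self.successional_age > 0:
            raise ValueError(f"successional_age of {self.plot_id!r} must be > 0")


@dataclass
class Study:
    """A cross-referenced study: traits, species, plots and individuals."""

    traits: list[TraitDefinition]
    species: list[SpeciesInfo]
    plots: list[PlotEnvironment]
    individuals: list[IndividualRecord]

    def __post_init__(self) -> None:
        self._trait_by_name = {t.name: t for t in self.traits}
        self._species_by_id = {s.species_id: s for s in self.species}
        self._plot_by_id = {p.plot_id: p for p in self.plots}
        if len(self._trait_by_name) != len(self.traits):
            raise ValueError("duplicate trait names")
        if len(self._species_by_id) != len(self.species):
            raise ValueError("duplicate species ids")
        if len(self._plot_by_id) != len(self.plots):
            raise ValueError("duplicate plot ids")
        bad = [
            (i, ind)
            for i, ind in enumerate(self.individuals)
            if ind.plot_id not in self._plot_by_id
            or ind.species_id not in self._species_by_id
        ]
        if bad:
            rows = ", ".join(f"row {i}: {ind.individual_id}" for i, ind in bad[:10])
            raise ReferentialIntegrityError(
                f"{len(bad)} individuals reference unknown plots/species ({rows})"
            )
        for ind in self.individuals:
            unknown = set(ind.trait_values) - set(self._trait_by_name)
            if unknown:
                raise ReferentialIntegrityError(
                    f"individual {ind.individual_id!r} carries undeclared "
                    f"traits {sorted(unknown)}"
                )

    # -- lookups -------------------------------------------------------
    def trait(self, name: str) -> TraitDefinition:
        return self._trait_by_name[name]

    def species_info(self, species_id: str) -> SpeciesInfo:
        return self._species_by_id[species_id]

    def plot(self, plot_id: str) -> PlotEnvironment:
        return self._plot_by_id[plot_id]

    @property
    def quantitative_traits(self) -> list[TraitDefinition]:
        return [t for t in self.traits if t.kind == "quantitative"]

    @property
    def categorical_traits(self) -> list[TraitDefinition]:
        return [t for t in self.traits if t.kind in ("binary", "categorical")]

    @property
    def env_variables(self) -> list[str]:
        keys: list[str] = []
        for p in self.plots:
            for k in p.env:
                if k not in keys:
                    keys.append(k)
        return keys

    def h_rel(self, individual: IndividualRecord) -> float:
        """Height-class midpoint relative to the species' maximum height."""
        hmax = self.species_info(individual.species_id).hmax
        return individual.height_class_midpoint / hmax

    def individuals_in_plot(self, plot_id: str) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.plot_id == plot_id]

    def plots_of(self, forest_type: str) -> list[PlotEnvironment]:
        return [p for p in self.plots if p.forest_type == forest_type]

    def individuals_of(self, forest_type: str) -> list[IndividualRecord]:
        plot_ids = {p.plot_id for p in self.plots_of(forest_type)}
        return [i for i in self.individuals if i.plot_id in plot_ids]

    def species_sets(self) -> dict[str, set[str]]:
        """Species present per plot (from the individual survey)."""
        out: dict[str, set[str]] = {p.plot_id: set() for p in self.plots}
        for ind in self.individuals:
            out[ind.plot_id].add(ind.species_id)
        return out

    def counts(self) -> tuple[int, int, int]:
        return len(self.plots), len(self.species), len(self.individuals)


# ----------------------------------------------------------------------
# Delimited-text I/O
# ----------------------------------------------------------------------

_TRAIT_COLUMNS = ["name", "kind", "units", "log_transform_for_lmm"]
_SPECIES_COLUMNS = [
    "species_id", "hmax", "legume", "phenology", "compoundness", "pubescence",
]
_PLOT_COLUMNS = ["plot_id", "forest_type", "successional_age"]
_INDIVIDUAL_COLUMNS = [
    "individual_id", "plot_id", "species_id", "height_class_midpoint", "cii",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[], skipinitialspace=True
    )


def _parse_float(raw: str, table: str, row: int, column: str) -> float:
    if raw in MISSING_SENTINELS:
        return math.nan
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(
            f"{table}: non-numeric value {raw!r} at row {row}, column {column!r}"
        ) from None


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in ("1", "true", "yes", "y", "t")


def read_study(
    traits: str | Path,
    species: str | Path,
    plots: str | Path,
    individuals: str | Path,
) -> Study:
    """Read the four study tables and return a cross-referenced :class:`Study`.

    Raises :class:`SchemaError` on missing columns or unparsable numeric
    fields and :class:`ReferentialIntegrityError` (listing row numbers) when
    individuals reference unknown plots or species.
    """
    tdf = _read_csv(traits)
    _require_columns(tdf, _TRAIT_COLUMNS, "traits")
    trait_defs = [
        TraitDefinition(
            name=r["name"],
            kind=r["kind"],
            units=r["units"],
            log_transform_for_lmm=_parse_bool(r["log_transform_for_lmm"]),
        )
        for _, r in tdf.iterrows()
    ]

    sdf = _read_csv(species)
    _require_columns(sdf, _SPECIES_COLUMNS, "species")
    species_list = [
        SpeciesInfo(
            species_id=r["species_id"],
            hmax=_parse_float(r["hmax"], "species", i, "hmax"),
            legume=_parse_bool(r["legume"]),
            phenology=r["phenology"],
            compoundness=r["compoundness"],
            pubescence=r["pubescence"],
        )
        for i, r in sdf.iterrows()
    ]

    pdf = _read_csv(plots)
    _require_columns(pdf, _PLOT_COLUMNS, "plots")
    env_cols = [c for c in pdf.columns if c not in _PLOT_COLUMNS]
    plot_list = [
        PlotEnvironment(
            plot_id=r["plot_id"],
            forest_type=r["forest_type"],
            successional_age=_parse_float(
                r["successional_age"], "plots", i, "successional_age"
            ),
            env={
                c: _parse_float(r[c], "plots", i, c) for c in env_cols
            },
        )
        for i, r in pdf.iterrows()
    ]

    idf = _read_csv(individuals)
    _require_columns(idf, _INDIVIDUAL_COLUMNS, "individuals")
    quant_names = [t.name for t in trait_defs if t.kind == "quantitative"]
    trait_cols = [c for c in idf.columns if c in quant_names]
    known_plots = {p.plot_id for p in plot_list}
    known_species = {s.species_id for s in species_list}
    bad_rows: list[tuple[int, str]] = []
    individual_list: list[IndividualRecord] = []
    for i, r in idf.iterrows():
        if r["plot_id"] not in known_plots:
            bad_rows.append((i + 2, f"unknown plot {r['plot_id']!r}"))
            continue
        if r["species_id"] not in known_species:
            bad_rows.append((i + 2, f"unknown species {r['species_id']!r}"))
            continue
        cii_raw = r["cii"]
        values = {}
        for c in trait_cols:
            v = _parse_float(r[c], "individuals", i, c)
            if not math.isnan(v):
                values[c] = v
        individual_list.append(
            IndividualRecord(
                individual_id=r["individual_id"],
                plot_id=r["plot_id"],
                species_id=r["species_id"],
                height_class_midpoint=_parse_float(
                    r["height_class_midpoint"], "individuals", i,
                    "height_class_midpoint",
                ),
                cii=None if cii_raw in MISSING_SENTINELS else int(float(cii_raw)),
                trait_values=values,
            )
        )
    if bad_rows:
        listing = "; ".join(f"line {n}: {msg}" for n, msg in bad_rows[:20])
        raise ReferentialIntegrityError(
            f"individuals: {len(bad_rows)} row(s) with unknown references ({listing})"
        )
    return Study(trait_defs, species_list, plot_list, individual_list)


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write a study back to the four CSV tables (missing values as empty)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": out / "traits.csv",
        "species": out / "species.csv",
        "plots": out / "plots.csv",
        "individuals": out / "individuals.csv",
    }
    pd.DataFrame(
        [
            {
                "name": t.name,
                "kind": t.kind,
                "units": t.units,
                "log_transform_for_lmm": t.log_transform_for_lmm,
            }
            for t in study.traits
        ]
    ).to_csv(paths["traits"], index=False)
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "hmax": s.hmax,
                "legume": s.legume,
                "phenology": s.phenology,
                "compoundness": s.compoundness,
                "pubescence": s.pubescence,
            }
            for s in study.species
        ]
    ).to_csv(paths["species"], index=False)
    env_cols = study.env_variables
    pd.DataFrame(
        [
            {
                "plot_id": p.plot_id,
                "forest_type": p.forest_type,
                "successional_age": p.successional_age,
                **{c: p.env.get(c, math.nan) for c in env_cols},
            }
            for p in study.plots
        ]
    ).to_csv(paths["plots"], index=False)
    quant = [t.name for t in study.quantitative_traits]
    pd.DataFrame(
        [
            {
                "individual_id": i.individual_id,
                "plot_id": i.plot_id,
                "species_id": i.species_id,
                "height_class_midpoint": i.height_class_midpoint,
                "cii": "" if i.cii is None else i.cii,
                **{t: i.trait_values.get(t, math.nan) for t in quant},
            }
            for i in study.individuals
        ]
    ).to_csv(paths["individuals"], index=False)
    return paths


# ----------------------------------------------------------------------
# Missing-value imputation
# ----------------------------------------------------------------------


def impute_missing_traits(study: Study) -> tuple[Study, list[dict]]:
    """Fill missing quantitative trait values by hierarchical means.

    Order of fallbacks per missing cell: mean over the same species in the
    same plot, else over the same species in the same forest type, else over
    all individuals of the forest type.  Measured values are never altered.

    Returns the imputed study (a new object) and a log with one entry per
    filled cell: ``{individual_id, trait, rule, value}``.

    Raises :class:`ImputationError` if a trait has no measured value at all
    in some forest type that contains individuals.
    """
    quant = [t.name for t in study.quantitative_traits]
    ft_of_plot = {p.plot_id: p.forest_type for p in study.plots}

    # Accumulate measured values per (trait, species, plot), (trait, species,
    # forest type) and (trait, forest type).
    sp_plot: dict[tuple[str, str, str], list[float]] = {}
    sp_ft: dict[tuple[str, str, str], list[float]] = {}
    ft_all: dict[tuple[str, str], list[float]] = {}
    for ind in study.individuals:
        ft = ft_of_plot[ind.plot_id]
        for tr, v in ind.trait_values.items():
            sp_plot.setdefault((tr, ind.species_id, ind.plot_id), []).append(v)
            sp_ft.setdefault((tr, ind.species_id, ft), []).append(v)
            ft_all.setdefault((tr, ft), []).append(v)

    forest_types_present = {ft_of_plot[i.plot_id] for i in study.individuals}
    for tr in quant:
        for ft in sorted(forest_types_present):
            if (tr, ft) not in ft_all:
                raise ImputationError(
                    f"trait {tr!r} has no measured value in forest type {ft!r}"
                )

    log: list[dict] = []
    new_individuals = []
    for ind in study.individuals:
        ft = ft_of_plot[ind.plot_id]
        values = dict(ind.trait_values)
        for tr in quant:
            if tr in values:
                continue
            if (tr, ind.species_id, ind.plot_id) in sp_plot:
                pool = sp_plot[(tr, ind.species_id, ind.plot_id)]
                rule = "species_plot_mean"
            elif (tr, ind.species_id, ft) in sp_ft:
                pool = sp_ft[(tr, ind.species_id, ft)]
                rule = "species_forest_type_mean"
            else:
                pool = ft_all[(tr, ft)]
                rule = "forest_type_mean"
            value = float(np.mean(pool))
            values[tr] = value
            log.append(
                {
                    "individual_id": ind.individual_id,
                    "trait": tr,
                    "rule": rule,
                    "value": value,
                }
            )
        new_individuals.append(replace(ind, trait_values=values))
    imputed = Study(study.traits, study.species, study.plots, new_individuals)
    return imputed, log


# ----------------------------------------------------------------------
# Small community metrics
# ----------------------------------------------------------------------


def sorensen_similarity(plot_a: Iterable[str], plot_b: Iterable[str]) -> float:
    """Sørensen similarity 2|A∩B| / (|A|+|B|) of two species sets."""
    a, b = set(plot_a), set(plot_b)
    if not a or not b:
        raise ValueError("Sørensen similarity undefined for an empty species set")
    return 2.0 * len(a & b) / (len(a) + len(b))


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided normal-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall tau undefined for a constant vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
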