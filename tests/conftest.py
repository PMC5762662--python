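"""Shared builders and fixtures for the test suite."""

from __future__ import annotations

import itertools

import pytest

from traitflux.core_data import (
    IndividualRecord,
    PlotEnvironment,
    SpeciesInfo,
    Study,
    TraitDefinition,
)

_counter = itertools.count(1)


def make_species(species_id, hmax=15.0, legume=False, phenology="deciduous",
                 compoundness="simple", pubescence="glabrous"):
    return SpeciesInfo(species_id, hmax, legume, phenology, compoundness, pubescence)


def make_plot(plot_id, forest_type="MIX", age=20.0, **env):
    return PlotEnvironment(plot_id, forest_type, age, env=dict(env))


def make_individual(plot_id, species_id, height=1.75, cii=3, **trait_values):
    return IndividualRecord(
        individual_id=f"ind{next(_counter):05d}",
        plot_id=plot_id,
        species_id=species_id,
        height_class_midpoint=height,
        cii=cii,
        trait_values=dict(trait_values),
    )


def make_study(plots, species, individuals, trait_names=("y",)):
    traits = [TraitDefinition(n, "quantitative") for n in trait_names]
    return Study(traits, species, plots, individuals)


@pytest.fixture
def toy_three_plots():
    """The worked 3-plot example: P1 A={10,12}; P2 A={14}, B={20}; P3 B={22,24}.

    Fixed means A=12, B=22; specific CWM (11, 17, 23), fixed (12, 17, 22),
    ITV (-1, 0, +1); ages (10, 20, 30).
    """
    plots = [
        make_plot("P1", age=10.0),
        make_plot("P2", age=20.0),
        make_plot("P3", age=30.0),
    ]
    species = [make_species("A"), make_species("B")]
    individuals = [
        make_individual("P1", "A", y=10.0),
        make_individual("P1", "A", y=12.0),
        make_individual("P2", "A", y=14.0),
        make_individual("P2", "B", y=20.0),
        make_individual("P3", "B", y=22.0),
        make_individual("P3", "B", y=24.0),
    ]
    return make_study(plots, species, individuals)
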