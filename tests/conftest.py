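"""Shared fixtures: toy models, media, expression profiles, oracles."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phasegem as pg

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Default toy model (two designed auxotrophies, one isoenzyme pair)."""
    model, truth = pg.generate_core_model(pg.ToySpec())
    return model, truth


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def prototroph():
    """Toy model with no deleted branches (no designed auxotrophies)."""
    model, truth = pg.generate_core_model(
        pg.ToySpec(deleted_branches=frozenset(),
                   isoenzyme_steps=frozenset(),
                   complex_steps=frozenset())
    )
    return model, truth


@pytest.fixture(scope="session")
def minimal_medium(toy_model):
    return pg.generate_media(toy_model, "minimal")


@pytest.fixture(scope="session")
def rich_medium(toy_model):
    return pg.generate_media(toy_model, "rich")


@pytest.fixture(scope="session")
def phase_reductions(toy, minimal_medium, rich_medium):
    """AP and GP condition models for the default toy."""
    model, truth = toy
    ap = pg.reduce_from_profile(
        model, pg.generate_expression(model, "AP", seed=1, truth=truth),
        minimal_medium, objective_id="ATPM",
    )
    gp = pg.reduce_from_profile(
        model, pg.generate_expression(model, "GP", seed=1, truth=truth),
        rich_medium, objective_id="BIOMASS",
    )
    return ap, gp


@pytest.fixture(scope="session")
def interval_model():
    """A model whose feasible set is a single free interval [0, 10]."""
    m = pg.Model(id="interval", compartments={"e"})
    m.add_metabolite(pg.Metabolite("a_e", compartment="e"))
    m.add_reaction(pg.Reaction("EX_a_e", stoichiometry={"a_e": -1.0},
                               lower_bound=-10.0, upper_bound=0.0))
    m.add_reaction(pg.Reaction("SINK_a", stoichiometry={"a_e": -1.0},
                               lower_bound=0.0, upper_bound=1000.0))
    return m
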