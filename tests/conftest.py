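import logging

import pytest

from rhizoscope.netbuild import MetabolicNetwork, Reaction, ReactionBank

logging.getLogger("rhizoscope").setLevel(logging.ERROR)


def make_reaction(rid, subs, prods, ec=None, reversible=False, pathways=()):
    return Reaction(
        rid,
        frozenset({ec or f"1.1.1.{rid.lstrip('R') or 1}"}),
        frozenset(subs),
        frozenset(prods),
        reversible=reversible,
        pathways=frozenset(pathways),
    )


def make_network(*reactions: Reaction) -> MetabolicNetwork:
    rxns = {r.reaction_id: r for r in reactions}
    enzymes = frozenset(ec for r in reactions for ec in r.ec_set)
    return MetabolicNetwork(rxns, enzymes)


def make_bank(*reactions: Reaction, compound_pathways=None, ec_pathways=None) -> ReactionBank:
    return ReactionBank(
        {r.reaction_id: r for r in reactions},
        {k: frozenset(v) for k, v in (compound_pathways or {}).items()},
        {k: frozenset(v) for k, v in (ec_pathways or {}).items()},
    )


@pytest.fixture
def chain_network():
    """A -> B -> C."""
    return make_network(
        make_reaction("R1", ["A"], ["B"], ec="1.1.1.1"),
        make_reaction("R2", ["B"], ["C"], ec="1.1.1.2"),
    )


@pytest.fixture
def fixture_study():
    """One default synthetic study shared by perturbation/pipeline tests."""
    from rhizoscope import catalog as cat
    from rhizoscope import dominance as dom
    from rhizoscope import seeds as seedmod
    from rhizoscope.netbuild import build_network
    from rhizoscope.synth import SynthSpec, make_fixture

    fx = make_fixture(SynthSpec(rng_seed=7))
    profile = cat.build_enzyme_profile(fx.catalog, fx.ko2ec)
    table = dom.call_dominance(profile, fx.catalog.design)
    meta_net = build_network(fx.bank.enzymes, fx.bank)
    meta_seeds = seedmod.detect_seeds(meta_net)
    return fx, profile, table, meta_seeds
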