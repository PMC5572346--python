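"""The network-expansion (scope) algorithm.

Starting from a set of source metabolites, the algorithm repeatedly scans the
reaction set for feasible reactions — those whose substrates are ALL already
available — fires them, and adds their products to the available pool.  It
stops when no new feasible reaction is found.  The fixpoint ("scope")
describes the metabolites a community could in principle produce given its
enzyme repertoire and the environment's inputs.

The fixpoint is unique and independent of iteration order (feasibility is
monotone in the available set), so the implementation is a simple worklist
over rounds; the per-round trace is recorded for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rhizoscope._errors import ValidationError
from rhizoscope.netbuild import DirectedReaction, MetabolicNetwork, ReactionBank, build_network
from rhizoscope.seeds import SeedSet

logger = logging.getLogger(__name__)


@dataclass
class ExpansionScope:
    """The fixpoint of a network expansion run."""

    seeds: frozenset[str]
    supplements: frozenset[str]
    reachable: frozenset[str]
    active_reactions: frozenset[str]
    trace: list[frozenset[str]]
    environment: str | None = None

    def __len__(self) -> int:
        return len(self.reachable)


def expand(
    seeds: Iterable[str],
    reactions: Sequence[DirectedReaction] | MetabolicNetwork,
    supplements: Iterable[str] = (),
    environment: str | None = None,
    known_compounds: Iterable[str] | None = None,
) -> ExpansionScope:
    """Compute the scope of ``seeds`` over a directed reaction set.

    ``supplements`` (e.g. currency metabolites) join the seed pool but are
    flagged separately in the result; default empty — the literal algorithm
    with no cofactor bootstrapping.  Seed compounds absent from the known
    compound universe are kept with a warning (they may still appear as
    reaction substrates elsewhere).
    """
    if isinstance(reactions, MetabolicNetwork):
        if known_compounds is None:
            known_compounds = reactions.compounds
        reactions = reactions.directed_reactions()
    seeds = frozenset(seeds)
    supplements = frozenset(supplements)
    if known_compounds is not None:
        unknown = (seeds | supplements) - frozenset(known_compounds)
        if unknown:
            logger.warning(
                "expand: %d seed compound(s) absent from the compound universe: %s",
                len(unknown),
                sorted(unknown)[:5],
            )

    available: set[str] = set(seeds | supplements)
    trace: list[frozenset[str]] = [frozenset(available)]
    active: set[str] = set()
    pending = [dr for dr in reactions if dr.directed_id not in active]
    while True:
        new_round: set[str] = set()
        still_pending: list[DirectedReaction] = []
        for dr in pending:
            if dr.substrates <= available:
                active.add(dr.directed_id)
                new_round |= dr.products - available
            else:
                still_pending.append(dr)
        # products of this round only become substrates in the next round
        new_round -= available
        if not new_round and len(still_pending) == len(pending):
            break
        available |= new_round
        pending = still_pending
        if new_round:
            trace.append(frozenset(new_round))
        if not pending and not new_round:
            break

    # fixpoint certificate: no unfired reaction is feasible
    for dr in pending:
        assert not dr.substrates <= available, (
            f"fixpoint violated: {dr.directed_id} feasible but inactive"
        )
    return ExpansionScope(
        seeds=seeds,
        supplements=supplements,
        reachable=frozenset(available),
        active_reactions=frozenset(active),
        trace=trace,
        environment=environment,
    )


def expand_environment(
    bank: ReactionBank,
    meta_enzymes: Iterable[str],
    env_seeds: SeedSet | Iterable[str],
    environment: str | None = None,
    supplements: Iterable[str] = (),
) -> ExpansionScope:
    """Expand the full meta-network with one environment's seed set.

    The reaction repertoire is shared across environments (nearly all enzymes
    are detected in all samples); environments differ only through their
    filtered source-metabolite sets.
    """
    seed_compounds = env_seeds.flat if isinstance(env_seeds, SeedSet) else frozenset(env_seeds)
    if not seed_compounds:
        logger.warning("expand_environment(%s): empty seed set", environment)
        return ExpansionScope(
            seeds=frozenset(),
            supplements=frozenset(supplements),
            reachable=frozenset(supplements),
            active_reactions=frozenset(),
            trace=[frozenset(supplements)],
            environment=environment,
        )
    network = build_network(meta_enzymes, bank)
    return expand(
        seed_compounds,
        network,
        supplements=supplements,
        environment=environment,
        known_compounds=bank.compounds,
    )


def scope_diff(
    reference: ExpansionScope, other: ExpansionScope
) -> tuple[frozenset[str], float]:
    """Compounds in the reference scope missing from ``other``, and the
    missing fraction of the reference.  Extra compounds in ``other`` are
    ignored: only reference-side loss is counted."""
    if not reference.reachable:
        raise ValidationError("scope_diff: reference scope is empty")
    missing = reference.reachable - other.reachable
    return missing, len(missing) / len(reference.reachable)
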