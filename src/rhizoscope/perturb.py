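"""In-silico taxon removal and synergistic metabolic complementation.

Both simulations rest on differential network expansion over the shared
meta-network reaction repertoire with an environment's filtered seed set.

Removal: the reference scope is expanded from the full enzyme set; then, per
key taxonomic group (or all at once), the enzymes that group dominates are
deleted and the scope re-expanded.  The metabolites lost, mapped to pathways,
yield a per-pathway removal effect — reported both as the fraction of the
pathway's reference metabolites remaining and as the fraction missing.

Complementation: the reverse. A "core" of enzymes dominated by NO key group
is expanded alone with each combination member's dominated enzymes, and with
all of them jointly; compounds produced by the joint network but by none of
the single-member networks are the complementary metabolites — functions no
member could realise alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from rhizoscope._errors import ValidationError
from rhizoscope.dominance import rank_key_groups
from rhizoscope.expansion import ExpansionScope, expand_environment, scope_diff
from rhizoscope.netbuild import ReactionBank
from rhizoscope.seeds import SeedSet

logger = logging.getLogger(__name__)

#: sentinel target meaning "remove every key group's dominated enzymes at once"
ALL_GROUPS = "all"


@dataclass
class PathwayEffect:
    n_reference: int
    n_missing: int

    @property
    def fraction_remaining(self) -> float:
        return 1.0 - self.n_missing / self.n_reference

    @property
    def fraction_missing(self) -> float:
        return self.n_missing / self.n_reference


@dataclass
class RemovalResult:
    environment: str
    target: str  # taxon name or "all"
    removed_enzymes: frozenset[str]
    missing_metabolites: frozenset[str]
    reduction_fraction: float
    pathway_effects: dict[str, PathwayEffect] = field(default_factory=dict)
    reference: ExpansionScope | None = None
    truncated: ExpansionScope | None = None

    def effect_table(self) -> pd.DataFrame:
        """Per-pathway effect scores; ``effect_score`` is fraction_remaining."""
        rows = [
            (
                pw,
                e.n_reference,
                e.n_missing,
                e.fraction_remaining,
                e.fraction_missing,
                e.fraction_remaining,
            )
            for pw, e in sorted(self.pathway_effects.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "pathway_id",
                "n_reference",
                "n_missing",
                "fraction_remaining",
                "fraction_missing",
                "effect_score",
            ],
        )


@dataclass
class ComplementationResult:
    environment: str
    combination: frozenset[str]
    complementary_metabolites: frozenset[str]
    pathway_counts: dict[str, int] = field(default_factory=dict)
    joint: ExpansionScope | None = None
    singles: dict[str, ExpansionScope] = field(default_factory=dict)


def dominated_enzymes(
    table: pd.DataFrame,
    environment: str,
    taxon: str,
    n_key: int = 5,
) -> frozenset[str]:
    """Enzymes dominated by ``taxon`` (a key group, or the ``"all"`` sentinel
    for the union over every key group) in an environment."""
    ranking = rank_key_groups(table, environment, n=n_key)
    key = ranking.key_groups
    if taxon == ALL_GROUPS:
        out: set[str] = set()
        for t in key:
            out |= dominated_enzymes(table, environment, t, n_key=n_key)
        return frozenset(out)
    if taxon not in key:
        raise ValidationError(
            f"{taxon!r} is not a key group in {environment!r}; key groups: {key}"
        )
    sub = table[
        (table["environment"] == environment)
        & table["dominated"]
        & (table["consensus_taxon"] == taxon)
    ]
    enzymes = frozenset(sub["enzyme"])
    if not enzymes:
        logger.warning("%s dominates no enzyme in %s", taxon, environment)
    return enzymes


def _pathway_membership(
    compounds: Iterable[str], bank: ReactionBank
) -> dict[str, frozenset[str]]:
    groups: dict[str, set[str]] = {}
    for c in compounds:
        for pw in bank.compound_pathways.get(c, frozenset()):
            groups.setdefault(pw, set()).add(c)
    return {pw: frozenset(s) for pw, s in groups.items()}


def simulate_removal(
    bank: ReactionBank,
    meta_enzymes: Iterable[str],
    env_seeds: SeedSet | Iterable[str],
    table: pd.DataFrame,
    environment: str,
    target: str,
    n_key: int = 5,
) -> RemovalResult:
    """Expand with and without a key group's dominated enzymes and report the
    metabolites lost, overall and per pathway."""
    meta_enzymes = frozenset(meta_enzymes)
    reference = expand_environment(bank, meta_enzymes, env_seeds, environment)
    if not reference.reachable:
        raise ValidationError("simulate_removal: reference scope is empty")
    removed = dominated_enzymes(table, environment, target, n_key=n_key)
    truncated_set = meta_enzymes - removed
    if truncated_set:
        truncated = expand_environment(bank, truncated_set, env_seeds, environment)
    else:  # every enzyme dominated: nothing can fire beyond the seeds
        truncated = ExpansionScope(
            seeds=reference.seeds,
            supplements=frozenset(),
            reachable=reference.seeds,
            active_reactions=frozenset(),
            trace=[reference.seeds],
            environment=environment,
        )
    missing, fraction = scope_diff(reference, truncated)
    assert truncated.reachable <= reference.reachable, (
        "removal enlarged the scope — expansion monotonicity violated"
    )

    ref_groups = _pathway_membership(reference.reachable, bank)
    miss_groups = _pathway_membership(missing, bank)
    effects = {
        pw: PathwayEffect(len(ref_groups[pw]), len(miss_groups.get(pw, frozenset())))
        for pw in ref_groups
    }
    return RemovalResult(
        environment=environment,
        target=target,
        removed_enzymes=removed,
        missing_metabolites=missing,
        reduction_fraction=fraction,
        pathway_effects=effects,
        reference=reference,
        truncated=truncated,
    )


def core_enzymes(
    table: pd.DataFrame,
    environment: str,
    meta_enzymes: Iterable[str],
    n_key: int = 5,
) -> frozenset[str]:
    """Enzymes not dominated by ANY key taxonomic group in the environment.

    Enzymes dominated by non-key groups stay in the core: the key groups are
    the perturbation units, everything else is common background."""
    removed = dominated_enzymes(table, environment, ALL_GROUPS, n_key=n_key)
    return frozenset(meta_enzymes) - removed


def simulate_complementation(
    bank: ReactionBank,
    meta_enzymes: Iterable[str],
    env_seeds: SeedSet | Iterable[str],
    table: pd.DataFrame,
    environment: str,
    combo: Iterable[str],
    n_key: int = 5,
) -> ComplementationResult:
    """Three-network (for a pair; generally len(combo)+1) complementation test.

    Expands core+A, core+B, ... and core+all; metabolites produced in the
    joint network but in no single-member network are complementary.
    """
    combo = frozenset(combo)
    if len(combo) < 2:
        raise ValidationError("simulate_complementation: need >= 2 taxa in the combination")
    meta_enzymes = frozenset(meta_enzymes)
    core = core_enzymes(table, environment, meta_enzymes, n_key=n_key)

    singles: dict[str, ExpansionScope] = {}
    union_single: set[str] = set()
    joint_enzymes = set(core)
    for taxon in sorted(combo):
        enz = dominated_enzymes(table, environment, taxon, n_key=n_key)
        joint_enzymes |= enz
        scope = expand_environment(bank, core | enz, env_seeds, environment)
        singles[taxon] = scope
        union_single |= scope.reachable
    joint = expand_environment(bank, frozenset(joint_enzymes), env_seeds, environment)
    assert union_single <= joint.reachable, (
        "joint scope must contain every single-member scope (monotonicity)"
    )
    complementary = joint.reachable - union_single

    pathway_counts = {
        pw: len(members)
        for pw, members in _pathway_membership(complementary, bank).items()
    }
    return ComplementationResult(
        environment=environment,
        combination=combo,
        complementary_metabolites=frozenset(complementary),
        pathway_counts=pathway_counts,
        joint=joint,
        singles=singles,
    )
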