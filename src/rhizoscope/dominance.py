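"""Taxonomic dominance of enzymatic functions via the Simpson index.

Ecologists use the Simpson index D = sum(p_i^2) to measure species dominance
in a habitat.  Here each enzyme plays the role of the habitat and the p_i are
the fractions of its reads assigned to each order-level taxon: D is the
probability that two randomly drawn reads of the enzyme share a taxon.  A low
score marks a function carried by many groups; a high score a function
carried by a single or few groups.

An enzyme is "dominated" in an environment when (i) the environmental
Simpson index — the mean of the per-sample indices across that environment's
replicates — exceeds a threshold (default 0.4), and (ii) the same taxon holds
the per-sample read-fraction argmax in every replicate.  Per environment the
five taxa dominating the most enzymes are the "key" taxonomic groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from rhizoscope._errors import ConfigError, ValidationError
from rhizoscope.catalog import UNASSIGNED

logger = logging.getLogger(__name__)

DOMINANCE_COLUMNS = ("enzyme", "environment", "simpson_mean", "consensus_taxon", "dominated")


@dataclass
class KeyGroupRanking:
    """Taxa of one environment ranked by dominated-enzyme count."""

    environment: str
    ranking: list[tuple[str, int]]  # (taxon, count), counts non-increasing

    @property
    def key_groups(self) -> list[str]:
        return [t for t, _ in self.ranking]


def simpson_index(
    taxon_counts: Mapping[str, int | float], unassigned: str = UNASSIGNED
) -> float | None:
    """Simpson dominance index D = sum(p_i^2) over taxon read fractions.

    Reads under the ``unassigned`` sentinel are excluded: the index is over
    taxonomic groups, which presupposes a taxonomic label.  Returns None (a
    not-available marker, never 0) when no assignable reads remain.
    """
    counts = [c for t, c in taxon_counts.items() if t != unassigned and c > 0]
    total = float(sum(counts))
    if total <= 0:
        return None
    return sum((c / total) ** 2 for c in counts)


def _dominant_taxon(
    taxon_counts: Mapping[str, int | float], unassigned: str = UNASSIGNED
) -> str | None:
    """Argmax taxon by read fraction; a tie yields None (a tied sample can
    never satisfy the all-replicates consensus rule)."""
    counts = {t: c for t, c in taxon_counts.items() if t != unassigned and c > 0}
    if not counts:
        return None
    best = max(counts.values())
    winners = [t for t, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else None


def call_dominance(
    profile: pd.DataFrame,
    design: pd.DataFrame,
    threshold: float | str = 0.4,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Score every (enzyme, environment) pair for taxonomic dominance.

    ``threshold`` is either a number in (0, 1) or ``"auto"`` — the mean
    environmental Simpson index over all enzymes in the dataset at hand.
    ``min_reads`` (assignable reads per sample) guards near-empty
    distributions; samples below it contribute no index and break consensus.
    An (enzyme, environment) pair with no qualifying sample is skipped.

    Returns a tidy table: enzyme, environment, simpson_mean, consensus_taxon,
    dominated.
    """
    if not isinstance(threshold, str) and not (0 < float(threshold) < 1):
        raise ConfigError(f"dominance threshold must be in (0, 1), got {threshold}")
    if profile.empty:
        raise ValidationError("call_dominance: empty enzyme profile")

    env_samples = {
        env: sorted(g["sample_id"]) for env, g in design.groupby("environment")
    }
    # per (enzyme, sample): taxon count dict
    grouped = profile.groupby(["enzyme", "sample_id"])

    rows = []
    for enzyme, env_group in profile.groupby("enzyme"):
        samples_with_data = set(env_group["sample_id"])
        for env, samples in env_samples.items():
            indices: list[float] = []
            dominants: list[str | None] = []
            complete = True  # every sample of the env has assignable reads
            for s in samples:
                if s not in samples_with_data:
                    complete = False
                    continue
                counts = dict(
                    grouped.get_group((enzyme, s))[["taxon", "read_count"]].values
                )
                assignable = sum(
                    c for t, c in counts.items() if t != UNASSIGNED
                )
                if assignable < min_reads:
                    complete = False
                    continue
                d = simpson_index(counts)
                if d is None:
                    complete = False
                    continue
                indices.append(d)
                dominants.append(_dominant_taxon(counts))
            if not indices:
                continue  # enzyme absent from this environment
            mean_d = sum(indices) / len(indices)
            consensus = None
            if (
                complete
                and dominants
                and dominants[0] is not None
                and all(t == dominants[0] for t in dominants)
            ):
                consensus = dominants[0]
            rows.append((enzyme, env, mean_d, consensus))

    table = pd.DataFrame(rows, columns=["enzyme", "environment", "simpson_mean", "consensus_taxon"])
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ConfigError(f"unknown threshold {threshold!r} (number or 'auto')")
        threshold = float(table["simpson_mean"].mean())
        logger.info("call_dominance: auto threshold = %.4f", threshold)
    table["dominated"] = (table["simpson_mean"] > threshold) & table[
        "consensus_taxon"
    ].notna()
    return table.sort_values(["environment", "enzyme"], ignore_index=True)


def rank_key_groups(
    table: pd.DataFrame, environment: str, n: int = 5
) -> KeyGroupRanking:
    """Rank taxa by the number of enzymes they dominate in an environment.

    Counts non-increasing; ties broken lexicographically (smaller taxon name
    first).  The top ``n`` (default five) are the key taxonomic groups.
    """
    sub = table[(table["environment"] == environment) & table["dominated"]]
    if table[table["environment"] == environment].empty:
        raise ValidationError(f"rank_key_groups: no rows for environment {environment!r}")
    counts = sub.groupby("consensus_taxon")["enzyme"].nunique()
    ranking = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return KeyGroupRanking(environment, [(t, int(c)) for t, c in ranking])
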