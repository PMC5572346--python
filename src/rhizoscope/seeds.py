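"""Source-metabolite (seed) prediction from network topology.

A seed compound is one the community must take up from its environment
because the network cannot produce it internally.  Topologically these are
the members of source strongly connected components (SCCs) of the
compound-level digraph: components with no incoming edge from outside
themselves.  Every member of a source SCC of size k is reported with
confidence 1/k (any one of them, if supplied externally, renders the others
producible).

Environment-specific networks built from differentially abundant enzymes
only are highly fragmented and predict artificial seeds; those seed sets
are therefore intersected with the meta-network's seed set before use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from rhizoscope._errors import ValidationError
from rhizoscope.netbuild import MetabolicNetwork

logger = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Seed components with per-compound confidence 1/|component|."""

    components: list[frozenset[str]]
    provenance: str = ""
    confidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.confidence:
            self.confidence = {
                c: 1.0 / len(comp) for comp in self.components for c in comp
            }

    @property
    def flat(self) -> frozenset[str]:
        """All seed compounds, flattened across components."""
        return frozenset(c for comp in self.components for c in comp)

    def __len__(self) -> int:
        return len(self.flat)


def detect_seeds(
    network: MetabolicNetwork, min_confidence: float = 0.0
) -> SeedSet:
    """Predict seed compounds of a network.

    Condenses the compound digraph into its SCC DAG; SCCs with in-degree 0
    are seed components.  ``min_confidence`` optionally drops components
    larger than 1/min_confidence (default 0 keeps all).
    """
    compounds = network.compounds
    if not compounds:
        raise ValidationError("detect_seeds: network has no compounds")
    g = network.compound_graph()
    cond = nx.condensation(g)
    components: list[frozenset[str]] = []
    for node in cond.nodes:
        if cond.in_degree(node) == 0:
            comp = frozenset(cond.nodes[node]["members"])
            if min_confidence > 0 and 1.0 / len(comp) < min_confidence:
                continue
            components.append(comp)
    components.sort(key=lambda c: sorted(c)[0])
    return SeedSet(components, provenance="detected")


def filter_seeds(env_seeds: SeedSet, meta_seeds: SeedSet) -> SeedSet:
    """Keep only environment seeds also predicted as seeds of the meta-network.

    Fragmentation filter: environment networks are built from differential
    enzymes only, so many of their topological sources are artifacts of the
    missing reactions rather than genuine external inputs.  Confidences are
    inherited from ``env_seeds``.
    """
    keep = env_seeds.flat & meta_seeds.flat
    if not keep:
        logger.warning("filter_seeds: no environment seed survives the meta filter")
    components = [
        comp & keep for comp in env_seeds.components if comp & keep
    ]
    confidence = {c: env_seeds.confidence[c] for c in keep}
    return SeedSet(components, provenance="filtered", confidence=confidence)
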