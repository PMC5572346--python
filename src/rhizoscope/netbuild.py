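"""Reaction bank parsing and metabolic-network construction.

A reaction bank is a KEGG-like flat table of enzymatic reactions: each row
carries a reaction id, the EC numbers catalysing it, substrate and product
compound ids, a reversibility flag and pathway annotations.  A metabolic
network is the subset of bank reactions whose EC set intersects a given
enzyme set — the communal repertoire detected in a metagenome.  Reversible
reactions are treated topologically as two directed reactions.

Stoichiometric coefficients are ignored throughout: this is a topological
(reachability) framework, not a flux model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from rhizoscope._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Syntactic check for a four-field EC number, allowing trailing dashes
#: ("1.14.12.10", "1.2.3.-").
EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

_BANK_COLUMNS = ("reaction_id", "ec", "substrates", "products")


@dataclass(frozen=True)
class Reaction:
    """One bank reaction (undirected record; direction lives in views)."""

    reaction_id: str
    ec_set: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: substrate and product lists "
                "must be non-empty"
            )
        if not self.ec_set:
            raise ValidationError(f"reaction {self.reaction_id!r}: no EC number")
        overlap = self.substrates & self.products
        if overlap:
            logger.warning(
                "reaction %s: compounds %s appear on both sides (autocatalytic form)",
                self.reaction_id,
                sorted(overlap),
            )


@dataclass(frozen=True)
class DirectedReaction:
    """A single firing direction of a bank reaction."""

    directed_id: str
    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]


def _directions(rxn: Reaction) -> list[DirectedReaction]:
    fwd = DirectedReaction(
        directed_id=f"{rxn.reaction_id}_fwd",
        reaction_id=rxn.reaction_id,
        substrates=rxn.substrates,
        products=rxn.products,
    )
    if not rxn.reversible:
        return [fwd]
    rev = DirectedReaction(
        directed_id=f"{rxn.reaction_id}_rev",
        reaction_id=rxn.reaction_id,
        substrates=rxn.products,
        products=rxn.substrates,
    )
    return [fwd, rev]


@dataclass
class ReactionBank:
    """All known reactions, indexed by id and by EC, plus pathway maps."""

    reactions: dict[str, Reaction]
    compound_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    ec_pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ec_index: dict[str, frozenset[str]] = {}
        idx: dict[str, set[str]] = {}
        for rid, rxn in self.reactions.items():
            for ec in rxn.ec_set:
                idx.setdefault(ec, set()).add(rid)
        self.ec_index = {ec: frozenset(rids) for ec, rids in idx.items()}

    @property
    def compounds(self) -> frozenset[str]:
        """The compound universe: every substrate or product of any reaction."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.substrates | rxn.products
        return frozenset(out)

    @property
    def enzymes(self) -> frozenset[str]:
        return frozenset(self.ec_index)

    def reactions_for(self, ec: str) -> frozenset[str]:
        return self.ec_index.get(ec, frozenset())


@dataclass
class MetabolicNetwork:
    """The bank subset whose EC sets intersect a given enzyme set.

    A reaction is included if ANY of its ECs is present in the enzyme set
    (presence-based logic: metagenomic enzyme sets carry no complex/subunit
    information).
    """

    reactions: dict[str, Reaction]
    enzymes: frozenset[str]
    bank: ReactionBank | None = None

    @property
    def compounds(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.substrates | rxn.products
        return frozenset(out)

    def directed_reactions(self) -> list[DirectedReaction]:
        """Directed view: each reversible reaction contributes two directions."""
        out: list[DirectedReaction] = []
        for rid in sorted(self.reactions):
            out.extend(_directions(self.reactions[rid]))
        return out

    def compound_graph(self) -> nx.DiGraph:
        """Compound-level digraph: u -> v iff some directed reaction consumes
        u and produces v.  Every network compound is a node even if isolated."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.compounds))
        for dr in self.directed_reactions():
            for u in dr.substrates:
                for v in dr.products:
                    g.add_edge(u, v)
        return g

    def bipartite_graph(self) -> nx.DiGraph:
        """Bipartite compound <-> directed-reaction digraph, node attr
        ``kind`` in {"compound", "reaction"}."""
        g = nx.DiGraph()
        for c in sorted(self.compounds):
            g.add_node(c, kind="compound")
        for dr in self.directed_reactions():
            g.add_node(dr.directed_id, kind="reaction")
            for u in sorted(dr.substrates):
                g.add_edge(u, dr.directed_id)
            for v in sorted(dr.products):
                g.add_edge(dr.directed_id, v)
        return g


def _split_list(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    return frozenset(p.strip() for p in str(cell).split(";") if p.strip())


def read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    """Read a UTF-8 TSV with a header row; ``#`` comment lines ignored."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise FormatError(f"file not found: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_reaction_bank(
    path: str | Path,
    compound_pathway_path: str | Path | None = None,
    ec_pathway_path: str | Path | None = None,
) -> ReactionBank:
    """Load a reaction bank TSV (and optional pathway-map TSVs).

    Columns: ``reaction_id, ec, substrates, products`` plus optional
    ``reversible`` (0/1, default 0) and ``pathways``; the list columns are
    semicolon-separated.
    """
    df = read_tsv(path, _BANK_COLUMNS)
    reactions: dict[str, Reaction] = {}
    for i, row in df.iterrows():
        rid = row["reaction_id"].strip()
        if rid in reactions:
            raise ValidationError(f"{path}: duplicate reaction_id {rid!r}")
        ecs = _split_list(row["ec"])
        for ec in ecs:
            if not EC_RE.match(ec):
                raise ValidationError(f"{path} row {i}: malformed EC string {ec!r}")
        substrates = _split_list(row["substrates"])
        products = _split_list(row["products"])
        if not substrates or not products:
            raise ValidationError(
                f"{path}: reaction {rid!r} has an empty substrate or product list"
            )
        reversible = False
        if "reversible" in df.columns:
            reversible = str(row["reversible"]).strip() in {"1", "true", "True"}
        pathways = (
            _split_list(row["pathways"]) if "pathways" in df.columns else frozenset()
        )
        reactions[rid] = Reaction(rid, ecs, substrates, products, reversible, pathways)

    compound_pathways: dict[str, frozenset[str]] = {}
    if compound_pathway_path is not None:
        cp = read_tsv(compound_pathway_path, ("compound_id", "pathway_id"))
        grouped = cp.groupby("compound_id")["pathway_id"].apply(frozenset)
        compound_pathways = grouped.to_dict()
    ec_pathways: dict[str, frozenset[str]] = {}
    if ec_pathway_path is not None:
        ep = read_tsv(ec_pathway_path, ("ec", "pathway_id"))
        ec_pathways = ep.groupby("ec")["pathway_id"].apply(frozenset).to_dict()

    return ReactionBank(reactions, compound_pathways, ec_pathways)


def build_network(enzymes: Iterable[str], bank: ReactionBank) -> MetabolicNetwork:
    """Select the bank reactions catalysed by any enzyme in ``enzymes``.

    Passing the bank's full EC set yields the meta-network.  An empty enzyme
    set is a precondition violation; an enzyme set matching no reaction
    returns an empty network with a warning (the fragmented-network case).
    """
    enzymes = frozenset(enzymes)
    if not enzymes:
        raise ValidationError("build_network: enzyme set must be non-empty")
    selected: dict[str, Reaction] = {}
    for ec in enzymes:
        for rid in bank.reactions_for(ec):
            selected[rid] = bank.reactions[rid]
    if not selected:
        logger.warning("build_network: no bank reaction matched %d enzymes", len(enzymes))
    return MetabolicNetwork(dict(sorted(selected.items())), enzymes, bank)


def export_network(network: MetabolicNetwork, fmt: str, path: str | Path) -> None:
    """Write the bipartite digraph as Cytoscape-compatible SIF or GraphML."""
    path = Path(path)
    g = network.bipartite_graph()
    if fmt == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for u, v in sorted(g.edges()):
                rel = "consumes" if g.nodes[u].get("kind") == "compound" else "produces"
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown export format {fmt!r} (use 'sif' or 'graphml')")
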