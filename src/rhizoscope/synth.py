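"""Seeded synthetic fixtures with planted ground truth.

Generates the full input file set the framework consumes — reaction bank,
pathway maps, gene catalog with replicate structure, study design, KO->EC
mapping — from small topological motifs, so that every analysis stage can be
tested without KEGG or a real metagenome.  All generation is a pure function
of a :class:`SynthSpec` (seeded RNG): identical specs give identical outputs.

Planted structure and the exact expectations it induces:

* motifs (chains, branches, cycles, two-substrate joins) are built on fresh,
  disjoint compound ids, so the ground-truth seed components are known by
  construction (the in-degree-0 compounds, or whole cycle components);
* taxonomic dominance is planted per motif: a planted taxon contributes a
  fraction ``f`` of every sample's reads for ALL enzymes of its motifs, the
  remainder spread over the other taxa; non-planted motifs get near-uniform
  taxa (expected Simpson ~ 1/n_taxa, below the 0.4 call threshold for
  n_taxa >= 3).  Because one taxon owns a whole motif and motifs are
  disjoint, removing that taxon's enzymes makes exactly the motif's
  non-seed compounds unreachable — an exact removal expectation;
* complementation chains realise the three-network scenario: a core reaction
  S -> M, a taxon-A step M -> I and a taxon-B step I -> T on fresh compounds;
  T is producible only by the joint network, so the expected complementary
  set is exactly the chain targets.  A negative-control chain adds a
  core-only bypass M -> T, making its target reachable without either taxon
  (expected complementary contribution: none);
* per-environment differential abundance is planted by boosting the read
  depth of a few enzymes in one environment's samples.

Negative controls (near-uniform motifs, core-reachable targets) are always
emitted alongside positives so specificity is tested, not only sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from rhizoscope._errors import ConfigError, ValidationError
from rhizoscope.catalog import GeneCatalog, UNASSIGNED
from rhizoscope.netbuild import Reaction, ReactionBank

_DEFAULT_TAXA = (
    "Rhizobiales",
    "Pseudomonadales",
    "Sphingomonadales",
    "Burkholderiales",
    "Actinomycetales",
)


@dataclass
class SynthSpec:
    """Parameters of one synthetic study.

    Defaults emulate the study conditions the framework targets: five
    order-level taxa, a root environment in triplicate and a soil environment
    in duplicate, dominance fraction 0.9 for planted functions, read depths
    log-uniform in [50, 500] per (enzyme, sample).
    """

    rng_seed: int = 0
    n_reactions: int = 40
    motif_mix: dict[str, float] = field(
        default_factory=lambda: {"chain": 0.4, "branch": 0.2, "cycle": 0.2, "join": 0.2}
    )
    chain_length: int = 4  # compounds per chain motif
    cycle_size: int = 3
    taxa: tuple[str, ...] = _DEFAULT_TAXA
    environments: dict[str, int] = field(
        default_factory=lambda: {"root": 3, "soil": 2}
    )
    dominance_fraction: float = 0.9  # planted majority-taxon read fraction
    planted_taxa: tuple[str, ...] = _DEFAULT_TAXA[:3]
    motifs_per_taxon: int = 2
    complementation_pair: tuple[str, str] = _DEFAULT_TAXA[:2]
    n_complementation_chains: int = 1
    negative_control_chain: bool = True
    n_differential_per_env: int = 3
    differential_boost: float = 8.0
    depth_range: tuple[int, int] = (50, 500)
    unassigned_fraction: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.motif_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("motif_mix proportions must sum to 1")
        unknown = set(self.motif_mix) - {"chain", "branch", "cycle", "join"}
        if unknown:
            raise ConfigError(f"unknown motif kind(s): {sorted(unknown)}")
        if not 0.5 < self.dominance_fraction <= 1.0:
            raise ConfigError(
                "dominance_fraction must be in (0.5, 1] to guarantee the "
                "argmax consensus of planted taxa"
            )
        if self.n_reactions < 1:
            raise ConfigError("n_reactions must be >= 1")
        bad = set(self.planted_taxa) - set(self.taxa)
        if bad:
            raise ConfigError(f"planted taxa not in taxa list: {sorted(bad)}")
        if set(self.complementation_pair) - set(self.taxa):
            raise ConfigError("complementation pair must be drawn from taxa")
        for env, reps in self.environments.items():
            if reps < 1:
                raise ConfigError(f"environment {env!r} needs >= 1 replicate")


@dataclass
class Motif:
    kind: str
    reactions: list[str]  # reaction ids
    ecs: list[str]
    compounds: list[str]
    seed_compounds: frozenset[str]  # the motif's ground-truth seeds
    pathway: str

    @property
    def downstream(self) -> frozenset[str]:
        """Compounds reachable only through the motif's own reactions."""
        return frozenset(self.compounds) - self.seed_compounds


@dataclass
class SynthFixture:
    """A complete synthetic study: inputs plus planted ground truth."""

    spec: SynthSpec
    bank: ReactionBank
    motifs: list[Motif]
    catalog: GeneCatalog
    ko2ec: pd.DataFrame
    assignments: dict[str, frozenset[str]]  # taxon -> planted ECs
    truth: dict


class _Namer:
    """Deterministic fresh-id source for compounds/reactions/ECs/pathways."""

    def __init__(self) -> None:
        self.counts = {"C": 0, "R": 0, "ec": 0, "P": 0, "K": 0, "g": 0}

    def compound(self) -> str:
        self.counts["C"] += 1
        return f"C{self.counts['C']:05d}"

    def reaction(self) -> str:
        self.counts["R"] += 1
        return f"R{self.counts['R']:05d}"

    def ec(self) -> str:
        self.counts["ec"] += 1
        n = self.counts["ec"]
        return f"{1 + n % 6}.{1 + n % 13}.{1 + n % 21}.{n}"

    def pathway(self) -> str:
        self.counts["P"] += 1
        return f"map{self.counts['P']:04d}"


def _build_motif(kind: str, namer: _Namer, spec: SynthSpec) -> tuple[Motif, list[Reaction]]:
    pw = namer.pathway()
    reactions: list[Reaction] = []

    def add(subs: list[str], prods: list[str]) -> str:
        rid, ec = namer.reaction(), namer.ec()
        reactions.append(
            Reaction(rid, frozenset({ec}), frozenset(subs), frozenset(prods),
                     reversible=False, pathways=frozenset({pw}))
        )
        return ec

    if kind == "chain":
        comps = [namer.compound() for _ in range(spec.chain_length)]
        ecs = [add([a], [b]) for a, b in zip(comps, comps[1:])]
        seeds = frozenset({comps[0]})
    elif kind == "branch":
        comps = [namer.compound() for _ in range(3)]
        ecs = [add([comps[0]], [comps[1]]), add([comps[0]], [comps[2]])]
        seeds = frozenset({comps[0]})
    elif kind == "cycle":
        cyc = [namer.compound() for _ in range(spec.cycle_size)]
        exit_c = namer.compound()
        ecs = [add([a], [b]) for a, b in zip(cyc, cyc[1:] + cyc[:1])]
        ecs.append(add([cyc[-1]], [exit_c]))
        comps = cyc + [exit_c]
        seeds = frozenset(cyc)  # the whole cycle is one source SCC
    elif kind == "join":
        comps = [namer.compound() for _ in range(3)]
        ecs = [add([comps[0], comps[1]], [comps[2]])]
        seeds = frozenset(comps[:2])
    else:  # pragma: no cover - guarded by SynthSpec validation
        raise ConfigError(f"unknown motif kind {kind!r}")

    motif = Motif(kind, [r.reaction_id for r in reactions], ecs, comps, seeds, pw)
    return motif, reactions


def make_reaction_bank(spec: SynthSpec) -> tuple[ReactionBank, list[Motif]]:
    """Assemble a reaction bank from randomly mixed motifs.

    Motifs are sampled by the spec's proportions until the reaction budget is
    met; the final motif is a chain trimmed to land exactly on
    ``n_reactions``.  Ground-truth seed components are the per-motif seed
    sets (motifs share no compounds).
    """
    rng = np.random.default_rng(spec.rng_seed)
    namer = _Namer()
    kinds = sorted(spec.motif_mix)
    probs = np.array([spec.motif_mix[k] for k in kinds])
    motif_sizes = {
        "chain": spec.chain_length - 1,
        "branch": 2,
        "cycle": spec.cycle_size + 1,
        "join": 1,
    }
    if spec.n_reactions < 1 or spec.chain_length < 2 or spec.cycle_size < 2:
        raise ConfigError("infeasible spec: motif capacity exceeds the reaction budget")

    motifs: list[Motif] = []
    all_reactions: list[Reaction] = []
    n_left = spec.n_reactions
    while n_left > 0:
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        if motif_sizes[kind] > n_left:
            # trim: finish with a chain of exactly n_left reactions
            comps = [namer.compound() for _ in range(n_left + 1)]
            pw = namer.pathway()
            chain_rxns = []
            ecs = []
            for a, b in zip(comps, comps[1:]):
                rid, ec = namer.reaction(), namer.ec()
                chain_rxns.append(
                    Reaction(rid, frozenset({ec}), frozenset({a}), frozenset({b}),
                             False, frozenset({pw}))
                )
                ecs.append(ec)
            motifs.append(
                Motif("chain", [r.reaction_id for r in chain_rxns], ecs, comps,
                      frozenset({comps[0]}), pw)
            )
            all_reactions.extend(chain_rxns)
            n_left = 0
            break
        motif, rxns = _build_motif(kind, namer, spec)
        motifs.append(motif)
        all_reactions.extend(rxns)
        n_left -= motif_sizes[kind]

    bank = _bank_from(all_reactions, motifs)
    return bank, motifs


def _bank_from(reactions: list[Reaction], motifs: list[Motif]) -> ReactionBank:
    compound_pathways: dict[str, set[str]] = {}
    ec_pathways: dict[str, set[str]] = {}
    for m in motifs:
        for c in m.compounds:
            compound_pathways.setdefault(c, set()).add(m.pathway)
        for ec in m.ecs:
            ec_pathways.setdefault(ec, set()).add(m.pathway)
    return ReactionBank(
        {r.reaction_id: r for r in reactions},
        {c: frozenset(p) for c, p in compound_pathways.items()},
        {e: frozenset(p) for e, p in ec_pathways.items()},
    )


def ground_truth_seeds(motifs: list[Motif]) -> list[frozenset[str]]:
    """The constructed seed components, one or two per motif."""
    out: list[frozenset[str]] = []
    for m in motifs:
        if m.kind == "join":  # two independent single-compound sources
            out.extend(frozenset({c}) for c in sorted(m.seed_compounds))
        else:
            out.append(m.seed_compounds)
    return out


def plant_complementation(
    spec: SynthSpec, bank: ReactionBank, motifs: list[Motif]
) -> tuple[ReactionBank, list[Motif], dict[str, frozenset[str]], dict]:
    """Add complementation chains (and one negative control) to the bank.

    Returns the rebuilt bank, the extended motif list, the chain-enzyme
    dominance assignments {taxon A: ECs, taxon B: ECs} and a truth dict with
    the expected complementary targets and the per-chain removal losses.
    Raises if a chain target would collide with an existing route.
    """
    if spec.n_complementation_chains < 1:
        raise ValidationError("plant_complementation: spec includes no chain")
    namer = _Namer()
    # continue numbering past the existing bank
    existing = bank.compounds
    namer.counts["C"] = len(existing)
    namer.counts["R"] = len(bank.reactions)
    namer.counts["ec"] = len(bank.enzymes)
    namer.counts["P"] = len(
        {pw for m in motifs for pw in [m.pathway]}
    )

    taxon_a, taxon_b = spec.complementation_pair
    new_reactions: list[Reaction] = []
    new_motifs: list[Motif] = []
    a_ecs: set[str] = set()
    b_ecs: set[str] = set()
    expected: set[str] = set()
    removal_a: set[str] = set()
    removal_b: set[str] = set()

    def build_chain(negative: bool) -> None:
        pw = namer.pathway()
        s, m_, i, t = (namer.compound() for _ in range(4))
        for c in (s, m_, i, t):
            if c in existing:
                raise ValidationError(
                    f"plant_complementation: compound {c} collides with an "
                    "existing route; ground truth would break"
                )
        specs = [([s], [m_], "core"), ([m_], [i], "A"), ([i], [t], "B")]
        if negative:
            specs.append(([m_], [t], "core"))  # core-only bypass to the target
        ecs = []
        rids = []
        for subs, prods, owner in specs:
            rid, ec = namer.reaction(), namer.ec()
            new_reactions.append(
                Reaction(rid, frozenset({ec}), frozenset(subs), frozenset(prods),
                         False, frozenset({pw}))
            )
            rids.append(rid)
            ecs.append(ec)
            if owner == "A":
                a_ecs.add(ec)
            elif owner == "B":
                b_ecs.add(ec)
        new_motifs.append(
            Motif("complementation" + ("_negative" if negative else ""),
                  rids, ecs, [s, m_, i, t], frozenset({s}), pw)
        )
        # expectations: I needs A; T needs A then B unless the bypass exists
        removal_a.update({i, t} if not negative else {i})
        if not negative:
            removal_b.add(t)
            expected.add(t)

    for _ in range(spec.n_complementation_chains):
        build_chain(negative=False)
    if spec.negative_control_chain:
        build_chain(negative=True)

    all_motifs = motifs + new_motifs
    merged = list(bank.reactions.values()) + new_reactions
    new_bank = _bank_from(merged, all_motifs)
    assignments = {taxon_a: frozenset(a_ecs), taxon_b: frozenset(b_ecs)}
    truth = {
        "pair": [taxon_a, taxon_b],
        "expected_complementary": sorted(expected),
        "chain_removal_missing": {
            taxon_a: sorted(removal_a),
            taxon_b: sorted(removal_b),
        },
    }
    return new_bank, all_motifs, assignments, truth


def plant_dominance(
    spec: SynthSpec,
    motifs: list[Motif],
    rng: np.random.Generator,
    reserved_ecs: frozenset[str] = frozenset(),
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Assign whole motifs to planted taxa (``motifs_per_taxon`` each).

    Whole-motif assignment keeps the removal expectation exact: a taxon's
    removal severs complete motifs, losing exactly their non-seed compounds.
    Returns (taxon -> planted ECs, taxon -> expected missing compounds).
    """
    candidates = [
        m for m in motifs
        if not m.kind.startswith("complementation")
        and not (set(m.ecs) & reserved_ecs)
    ]
    need = spec.motifs_per_taxon * len(spec.planted_taxa)
    if need > len(candidates):
        raise ConfigError(
            f"infeasible spec: {need} motifs to plant but only "
            f"{len(candidates)} available"
        )
    order = rng.permutation(len(candidates))
    assignments: dict[str, set[str]] = {t: set() for t in spec.planted_taxa}
    missing: dict[str, set[str]] = {t: set() for t in spec.planted_taxa}
    it = iter(order)
    for taxon in spec.planted_taxa:
        for _ in range(spec.motifs_per_taxon):
            m = candidates[int(next(it))]
            assignments[taxon].update(m.ecs)
            missing[taxon].update(m.downstream)
    return (
        {t: frozenset(e) for t, e in assignments.items()},
        {t: frozenset(c) for t, c in missing.items()},
    )


def make_catalog(
    spec: SynthSpec,
    bank: ReactionBank,
    assignments: Mapping[str, frozenset[str]],
    rng: np.random.Generator,
) -> tuple[GeneCatalog, pd.DataFrame, dict]:
    """Simulate the gene catalog: reads per (enzyme, sample, taxon).

    Planted enzymes give fraction ``f`` of each sample's reads to their taxon
    and spread the remainder (multinomial) over the others; non-planted
    enzymes draw near-uniform taxa.  A small extra fraction of reads is
    emitted under the ``unassigned`` sentinel.  Returns the catalog, the
    KO->EC table and the dominance ground truth.
    """
    f = spec.dominance_fraction
    if f <= 0.5:
        raise ConfigError("dominance fraction must exceed 0.5")
    ec_owner: dict[str, str] = {}
    for taxon, ecs in assignments.items():
        for ec in ecs:
            if ec in ec_owner:
                raise ValidationError(f"EC {ec} planted for two taxa")
            ec_owner[ec] = taxon

    design_rows = []
    for env, reps in sorted(spec.environments.items()):
        for r in range(1, reps + 1):
            design_rows.append((f"{env}_r{r}", env, r))
    design = pd.DataFrame(design_rows, columns=["sample_id", "environment", "replicate"])

    enzymes = sorted(bank.enzymes)
    ko_of = {ec: f"K{10000 + i:05d}" for i, ec in enumerate(enzymes)}
    ko2ec = pd.DataFrame({"ko_id": [ko_of[e] for e in enzymes], "ec": enzymes})
    labels = list(spec.taxa) + [UNASSIGNED]
    gene_of = {
        (ec, taxon): f"g{i * len(labels) + j:06d}"
        for i, ec in enumerate(enzymes)
        for j, taxon in enumerate(labels)
    }

    lo, hi = spec.depth_range
    taxa = list(spec.taxa)
    boosted = _plant_differential(spec, enzymes, ec_owner, rng)

    rows = []
    for ec in enzymes:
        for sample_id, env, _rep in design_rows:
            depth = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            if ec in boosted.get(env, frozenset()):
                depth = int(round(depth * spec.differential_boost))
            owner = ec_owner.get(ec)
            if owner is not None:
                n_major = int(round(f * depth))
                rest = depth - n_major
                others = [t for t in taxa if t != owner]
                alloc = rng.multinomial(rest, [1 / len(others)] * len(others))
                counts = dict(zip(others, alloc))
                counts[owner] = n_major
            else:
                alloc = rng.multinomial(depth, [1 / len(taxa)] * len(taxa))
                counts = dict(zip(taxa, alloc))
            n_unassigned = rng.binomial(depth, spec.unassigned_fraction)
            if n_unassigned:
                counts[UNASSIGNED] = n_unassigned
            for taxon, count in counts.items():
                if count > 0:
                    rows.append(
                        (gene_of[(ec, taxon)], sample_id, int(count), ko_of[ec], taxon)
                    )
    records = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "read_count", "ko_id", "taxon"]
    ).sort_values(["gene_id", "sample_id"], ignore_index=True)

    truth = {
        "dominated_pairs": sorted(
            [ec, taxon] for ec, taxon in ec_owner.items()
        ),
        "negative_enzymes": sorted(set(enzymes) - set(ec_owner)),
        "differential": {env: sorted(ecs) for env, ecs in boosted.items()},
    }
    return GeneCatalog(records, design), ko2ec, truth


def _plant_differential(
    spec: SynthSpec,
    enzymes: list[str],
    ec_owner: Mapping[str, str],
    rng: np.random.Generator,
) -> dict[str, frozenset[str]]:
    """Pick per-environment enzymes whose read depth is boosted there."""
    if spec.n_differential_per_env <= 0:
        return {}
    pool = [e for e in enzymes if e not in ec_owner]
    need = spec.n_differential_per_env * len(spec.environments)
    if need > len(pool):
        raise ConfigError("infeasible spec: not enough enzymes for differential planting")
    picks = rng.permutation(len(pool))
    out: dict[str, frozenset[str]] = {}
    i = 0
    for env in sorted(spec.environments):
        chosen = frozenset(pool[int(p)] for p in picks[i : i + spec.n_differential_per_env])
        out[env] = chosen
        i += spec.n_differential_per_env
    return out


def make_fixture(spec: SynthSpec) -> SynthFixture:
    """Build the complete synthetic study for one spec."""
    rng = np.random.default_rng(spec.rng_seed)
    bank, motifs = make_reaction_bank(spec)
    comp_truth: dict = {}
    chain_assignments: dict[str, frozenset[str]] = {}
    if spec.n_complementation_chains > 0:
        bank, motifs, chain_assignments, comp_truth = plant_complementation(
            spec, bank, motifs
        )
    reserved = frozenset().union(*chain_assignments.values()) if chain_assignments else frozenset()
    motif_assignments, motif_missing = plant_dominance(spec, motifs, rng, reserved)
    assignments: dict[str, frozenset[str]] = dict(motif_assignments)
    for taxon, ecs in chain_assignments.items():
        assignments[taxon] = assignments.get(taxon, frozenset()) | ecs

    catalog, ko2ec, dom_truth = make_catalog(spec, bank, assignments, rng)

    # exact removal expectations: whole-motif losses plus chain contributions
    chain_missing = (
        comp_truth.get("chain_removal_missing", {}) if comp_truth else {}
    )
    removal: dict[str, list[str]] = {}
    for taxon in assignments:
        lost = set(motif_missing.get(taxon, frozenset()))
        lost |= set(chain_missing.get(taxon, []))
        removal[taxon] = sorted(lost)
    removal["all"] = sorted(set().union(*(set(v) for v in removal.values())))

    truth = {
        "rng_seed": spec.rng_seed,
        "seed_components": sorted(
            sorted(c) for c in ground_truth_seeds(motifs)
        ),
        "assignments": {t: sorted(e) for t, e in sorted(assignments.items())},
        "removal_missing": removal,
        "complementation": comp_truth,
        **dom_truth,
    }
    return SynthFixture(spec, bank, motifs, catalog, ko2ec, assignments, truth)


def write_fixture(fixture: SynthFixture, outdir: str | Path) -> dict[str, Path]:
    """Emit the fixture as the TSV input set plus ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bank_rows = []
    for rid in sorted(fixture.bank.reactions):
        r = fixture.bank.reactions[rid]
        bank_rows.append(
            (
                rid,
                ";".join(sorted(r.ec_set)),
                ";".join(sorted(r.substrates)),
                ";".join(sorted(r.products)),
                int(r.reversible),
                ";".join(sorted(r.pathways)),
            )
        )
    frames = {
        "reaction_bank": pd.DataFrame(
            bank_rows,
            columns=["reaction_id", "ec", "substrates", "products", "reversible", "pathways"],
        ),
        "compound_pathways": pd.DataFrame(
            sorted(
                (c, pw)
                for c, pws in fixture.bank.compound_pathways.items()
                for pw in pws
            ),
            columns=["compound_id", "pathway_id"],
        ),
        "ec_pathways": pd.DataFrame(
            sorted(
                (e, pw) for e, pws in fixture.bank.ec_pathways.items() for pw in pws
            ),
            columns=["ec", "pathway_id"],
        ),
        "catalog": fixture.catalog.records,
        "design": fixture.catalog.design,
        "ko2ec": fixture.ko2ec,
    }
    for name, df in frames.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    gt = outdir / "ground_truth.json"
    gt.write_text(json.dumps(fixture.truth, indent=2, sort_keys=True))
    paths["ground_truth"] = gt
    return paths
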