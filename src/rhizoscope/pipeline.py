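"""End-to-end pipeline: gene catalog -> networks -> seeds -> expansion ->
dominance -> removal -> complementation -> enrichment.

The pipeline is a pure function of its inputs and configuration: rerunning
the same config gives bitwise-identical outputs.  Every output file carries
the SHA-256 hash of the resolved configuration so results can be traced to
the exact parameter set that produced them.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from rhizoscope import __version__
from rhizoscope._errors import ConfigError, RhizoscopeError
from rhizoscope import catalog as cat
from rhizoscope import dominance as dom
from rhizoscope import enrich
from rhizoscope import netbuild
from rhizoscope import perturb
from rhizoscope import seeds as seedmod
from rhizoscope.expansion import expand_environment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    catalog: str
    design: str
    ko2ec: str
    bank: str
    compound_pathways: str | None = None
    ec_pathways: str | None = None
    da_table: str | None = None
    comparisons: list[list[str]] = field(default_factory=list)  # [[env_a, env_b], ...]
    fold_threshold: float = 2.0
    fdr_threshold: float = 0.01
    simpson_threshold: float | str = 0.4
    alpha: float = 0.05
    n_key_groups: int = 5
    min_reads: int = 1
    seed_mode: str = "filtered"  # "filtered" (study procedure) or "meta"
    rng_seed: int = 0
    outdir: str = "rhizoscope_out"

    def validate(self) -> None:
        for name in ("catalog", "design", "ko2ec", "bank"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"config: {name} file does not exist: {p}")
        for name in ("compound_pathways", "ec_pathways", "da_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config: {name} file does not exist: {p}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.seed_mode not in {"filtered", "meta"}:
            raise ConfigError("seed_mode must be 'filtered' or 'meta'")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (outdir excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash}\trhizoscope={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_json(obj: dict, path: Path, config_hash: str) -> None:
    obj = {"config_hash": config_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name and code."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RhizoscopeError(
                    f"stage={name} code=E_{name.upper()}: {exc}"
                ) from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the five-step framework; returns the run directory.

    Steps: differential selection -> network construction -> seed detection
    with the meta-network intersection filter -> per-environment expansion ->
    Simpson dominance -> key-group removal (one by one and all at once) ->
    pairwise complementation -> pathway enrichment.
    """
    config.validate()
    chash = config.config_hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("ingest"):
        gc = cat.read_gene_catalog(config.catalog, config.design)
        ko2ec = cat.read_ko2ec(config.ko2ec)
        bank = netbuild.read_reaction_bank(
            config.bank, config.compound_pathways, config.ec_pathways
        )
        profile = cat.build_enzyme_profile(gc, ko2ec)
        logger.info(
            "ingest: %d gene records, %d enzymes, %d bank reactions",
            len(gc.records), profile["enzyme"].nunique(), len(bank.reactions),
        )

    environments = gc.environments()
    comparisons = [tuple(c) for c in config.comparisons]
    if not comparisons and len(environments) == 2:
        comparisons = [tuple(environments)]

    with _stage("differential"):
        diff_sets: dict[str, frozenset[str]] = {e: frozenset() for e in environments}
        provenance = "none"
        for env_a, env_b in comparisons:
            da, db = cat.select_differential(
                profile, gc.design, env_a, env_b,
                fold_threshold=config.fold_threshold,
                fdr_threshold=config.fdr_threshold,
                external_table=config.da_table,
            )
            diff_sets[env_a] = diff_sets[env_a] | da.enzymes
            diff_sets[env_b] = diff_sets[env_b] | db.enzymes
            provenance = da.provenance
        diff_df = pd.DataFrame(
            sorted(
                (env, e, provenance) for env, es in diff_sets.items() for e in es
            ),
            columns=["environment", "enzyme", "provenance"],
        )
        _write_tsv(diff_df, outdir / "differential_enzymes.tsv", chash)

    with _stage("networks"):
        meta_enzymes = frozenset(profile["enzyme"]) & bank.enzymes
        if not meta_enzymes:
            raise ConfigError("no catalog enzyme matches the reaction bank")
        meta_net = netbuild.build_network(meta_enzymes, bank)
        netbuild.export_network(meta_net, "sif", outdir / "meta_network.sif")
        logger.info("networks: meta-network with %d reactions", len(meta_net.reactions))

    with _stage("seeds"):
        meta_seeds = seedmod.detect_seeds(meta_net)
        env_seed_sets: dict[str, seedmod.SeedSet] = {}
        for env in environments:
            if config.seed_mode == "meta":
                env_seed_sets[env] = meta_seeds
                continue
            enzymes = diff_sets[env] & bank.enzymes
            if not enzymes:
                logger.warning("seeds: no differential enzymes for %s", env)
                env_seed_sets[env] = seedmod.SeedSet([], provenance="empty")
                continue
            env_net = netbuild.build_network(enzymes, bank)
            if not env_net.compounds:
                env_seed_sets[env] = seedmod.SeedSet([], provenance="empty")
                continue
            env_seed_sets[env] = seedmod.filter_seeds(
                seedmod.detect_seeds(env_net), meta_seeds
            )
        seed_rows = []
        for env, ss in sorted(env_seed_sets.items()):
            for i, comp in enumerate(ss.components):
                for c in sorted(comp):
                    seed_rows.append((env, c, i, ss.confidence[c]))
        _write_tsv(
            pd.DataFrame(seed_rows, columns=["environment", "compound_id", "component_id", "confidence"]),
            outdir / "source_metabolites.tsv", chash,
        )

    with _stage("expansion"):
        scopes = {
            env: expand_environment(bank, meta_enzymes, ss, environment=env)
            for env, ss in env_seed_sets.items()
        }
        _write_json(
            {
                "scopes": {
                    env: {
                        "seeds": sorted(s.seeds),
                        "reachable": sorted(s.reachable),
                        "n_active_reactions": len(s.active_reactions),
                        "rounds": len(s.trace),
                    }
                    for env, s in sorted(scopes.items())
                }
            },
            outdir / "expansion.json", chash,
        )

    with _stage("dominance"):
        table = dom.call_dominance(
            profile, gc.design,
            threshold=config.simpson_threshold, min_reads=config.min_reads,
        )
        _write_tsv(table, outdir / "dominance.tsv", chash)
        key_groups = {}
        for env in environments:
            try:
                key_groups[env] = dom.rank_key_groups(
                    table, env, n=config.n_key_groups
                ).key_groups
            except RhizoscopeError:
                key_groups[env] = []
        _write_json({"key_groups": key_groups}, outdir / "key_groups.json", chash)

    with _stage("removal"):
        removal_rows = []
        removal_json: dict = {}
        for env in environments:
            if not scopes[env].reachable or not key_groups[env]:
                logger.warning("removal: skipping %s (empty scope or no key group)", env)
                continue
            targets = key_groups[env] + [perturb.ALL_GROUPS]
            removal_json[env] = {}
            for target in targets:
                res = perturb.simulate_removal(
                    bank, meta_enzymes, env_seed_sets[env], table, env, target,
                    n_key=config.n_key_groups,
                )
                removal_json[env][target] = {
                    "missing": sorted(res.missing_metabolites),
                    "reduction_fraction": res.reduction_fraction,
                }
                eff = res.effect_table()
                eff.insert(0, "target", target)
                eff.insert(0, "environment", env)
                removal_rows.append(eff)
        if removal_rows:
            _write_tsv(pd.concat(removal_rows, ignore_index=True),
                       outdir / "removal_effects.tsv", chash)
        _write_json({"removal": removal_json}, outdir / "removal.json", chash)

    with _stage("complementation"):
        comp_json: dict = {}
        for env in environments:
            if not scopes[env].reachable or len(key_groups[env]) < 2:
                continue
            comp_json[env] = {}
            for a, b in itertools.combinations(sorted(key_groups[env]), 2):
                res = perturb.simulate_complementation(
                    bank, meta_enzymes, env_seed_sets[env], table, env, {a, b},
                    n_key=config.n_key_groups,
                )
                comp_json[env][f"{a}+{b}"] = {
                    "complementary": sorted(res.complementary_metabolites),
                    "pathway_counts": dict(sorted(res.pathway_counts.items())),
                }
        _write_json({"complementation": comp_json}, outdir / "complementation.json", chash)

    with _stage("enrichment"):
        enr_rows = []
        if bank.ec_pathways:
            for env in environments:
                subset = diff_sets[env] & meta_enzymes
                if not subset:
                    continue
                for r in enrich.enriched_pathways(
                    subset, meta_enzymes, bank.ec_pathways, alpha=config.alpha
                ):
                    enr_rows.append(("enzyme", env, r.pathway_id, r.k, r.n, r.K, r.N,
                                     r.p_hyper, r.p_chisq, r.enriched))
        if bank.compound_pathways:
            for env, targets in removal_json.items():
                ref = scopes[env].reachable
                for target, info in targets.items():
                    missing = frozenset(info["missing"])
                    if not missing:
                        continue
                    for r in enrich.enriched_pathways(
                        missing, ref, bank.compound_pathways, alpha=config.alpha
                    ):
                        enr_rows.append(
                            (f"removal:{target}", env, r.pathway_id, r.k, r.n, r.K,
                             r.N, r.p_hyper, r.p_chisq, r.enriched)
                        )
        enr_df = pd.DataFrame(
            enr_rows,
            columns=["subset", "environment", "pathway_id", "k", "n", "K", "N",
                     "p_hyper", "p_chisq", "enriched"],
        )
        _write_tsv(enr_df, outdir / "enrichment.tsv", chash)

    recorded = asdict(config)
    recorded.pop("outdir")  # outputs are a pure function of the analysis config
    _write_json(
        {"version": __version__, "config": recorded},
        outdir / "run_config.json", chash,
    )
    logger.info("pipeline complete: %s", outdir)
    return outdir
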