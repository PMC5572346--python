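# rhizoscope

Metabolic-network interpretation of taxonomically annotated metagenomes.

Shotgun metagenomes of complex microbial communities — rhizosphere and bulk
soil, gut, biofilms — yield gene catalogs that are two-dimensional: every
read carries a functional annotation (a KEGG ortholog, mapped to an EC
number) and a taxonomic one (here, order level). `rhizoscope` turns such a
catalog into a communal metabolic network and asks the ecological questions
the flat gene list cannot answer:

* **What does the environment feed the community?** Source (seed)
  metabolites are predicted from network topology: the members of source
  strongly connected components of the compound graph — compounds the
  network consumes but cannot produce internally (each member of a size-*k*
  source component is reported with confidence 1/*k*).
* **What can the community make?** The scope-expansion algorithm grows the
  set of producible metabolites from the seed set by iteratively firing
  every reaction whose substrates are all available, until no feasible
  reaction remains.
* **Who controls which function?** Each enzyme's reads are scored with the
  Simpson dominance index `D = Σᵢ pᵢ²` over the read fractions `pᵢ` of the
  taxa carrying it. An enzyme is *dominated* in an environment when its mean
  `D` across replicates exceeds 0.4 and the same taxon holds the read-count
  argmax in every replicate; the five taxa dominating the most enzymes are
  that environment's *key groups*.
* **What happens if a taxon disappears?** In-silico knockout: re-expand the
  network without the enzymes a key group dominates and measure the
  metabolites lost, overall and per pathway (removal effect score = fraction
  of a pathway's metabolites remaining).
* **What can taxa only do together?** Complementation: expand a shared core
  (enzymes dominated by no key group) plus each member of a taxon pair, and
  plus both; metabolites produced only by the joint network are
  *complementary* — candidate metabolic explanations for co-occurrence.
* **Which pathways stand out?** Dual enrichment test: a pathway is enriched
  when it passes both an exact upper-tail hypergeometric test and a Pearson
  chi-square goodness-of-fit test at p < 0.05.

Differential abundance between environments is consumed from an external
table (e.g. an edgeR analysis: enzyme, log2fc, FDR) at thresholds |fold| > 2
and FDR < 0.01 with replicate consistency; a clearly labelled exact-binomial
stand-in is included so the pipeline runs end-to-end without R.

A fully synthetic study generator (`rhizoscope.synth`) emulates every input
— reaction bank, pathway maps, gene catalog with a 3-replicate root /
2-replicate soil design — with planted dominance, removal and
complementation ground truth, so the whole framework is testable without
KEGG or a real metagenome.

## Worked example

```python
from rhizoscope.catalog import build_enzyme_profile
from rhizoscope.dominance import call_dominance
from rhizoscope.netbuild import build_network
from rhizoscope.perturb import simulate_removal
from rhizoscope.seeds import detect_seeds
from rhizoscope.synth import SynthSpec, make_fixture

fixture = make_fixture(SynthSpec(rng_seed=7))          # synthetic study
profile = build_enzyme_profile(fixture.catalog, fixture.ko2ec)
table = call_dominance(profile, fixture.catalog.design)  # Simpson scoring
seeds = detect_seeds(build_network(fixture.bank.enzymes, fixture.bank))

for target in list(fixture.assignments) + ["all"]:
    res = simulate_removal(fixture.bank, fixture.bank.enzymes, seeds,
                           table, "root", target)
    print(f"remove {target}: {len(res.missing_metabolites)} metabolites lost "
          f"({100 * res.reduction_fraction:.1f}%)")
```

prints

```
remove Rhizobiales: 9 metabolites lost (14.3%)
remove Pseudomonadales: 4 metabolites lost (6.3%)
remove Sphingomonadales: 4 metabolites lost (6.3%)
remove all: 16 metabolites lost (25.4%)
```

Each line is one knockout experiment: the planted *Rhizobiales* enzymes sit
on more upstream bridges in this fixture, so their removal cuts off the most
downstream metabolites; removing all key groups at once loses a quarter of
the reachable network. The `examples/` directory holds one narrative script
per capability (expansion, dominance, perturbation, full pipeline).

## Command line

```bash
rhizoscope simulate --seed 7 --outdir study/          # synthetic inputs
rhizoscope run --config config.yaml                   # full five-step pipeline
rhizoscope seeds --bank study/reaction_bank.tsv --enzymes ecs.txt --out seeds.tsv
rhizoscope dominance --catalog study/catalog.tsv --design study/design.tsv \
    --ko2ec study/ko2ec.tsv --out dominance.tsv
```

All inputs are plain TSV (see `docs/methods.md` for the column contracts);
networks export as Cytoscape-compatible SIF or GraphML. Pipeline outputs
carry the SHA-256 hash of their configuration and rerunning an identical
config reproduces them bitwise.

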