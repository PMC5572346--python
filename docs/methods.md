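# Methods

This note documents the models and procedures implemented in `rhizoscope`,
the parameters that matter, the numerical and design choices made where the
procedure was genuinely open, what the synthetic-data generator does and does
not emulate, and known limitations.

## Inputs and data contracts

All inputs are UTF-8 TSV files with a header row; `#` lines are comments.

| file | columns |
|---|---|
| gene catalog | `gene_id, sample_id, read_count, ko_id, taxon` |
| study design | `sample_id, environment, replicate` |
| KO→EC map | `ko_id, ec` |
| reaction bank | `reaction_id, ec, substrates, products[, reversible, pathways]` (lists `;`-separated) |
| compound pathways | `compound_id, pathway_id` |
| EC pathways | `ec, pathway_id` |
| external DA table | `enzyme, log2fc, fdr` (log2fc > 0 = enriched in the first environment) |

Validation is strict where silent corruption would propagate: unknown sample
ids, negative counts, duplicate reaction ids and malformed EC strings are
errors; duplicate `(gene_id, sample_id)` rows are summed with a warning, and
empty taxon fields become the `unassigned` sentinel.

A KO mapping to *k* EC numbers contributes its full read count to each EC
(duplication, not splitting). The mapping is genuinely ambiguous at the read
level and dominance is computed per EC over that EC's own reads, so
duplication does not bias taxon fractions; it does mean per-EC totals are not
additive across ECs sharing KOs.

## Differential enzyme selection

The framework consumes differential abundance; it does not own it. In
external mode the supplied table is thresholded at fold > 2 (|log2fc| >
1) and FDR < 0.01. The built-in stand-in — provenance-labelled `"standin"`,
with no claim of equivalence to dedicated count-model tools such as edgeR —
tests each enzyme's pooled counts with an exact binomial test against the two
environments' library-size proportions, corrects with Benjamini–Hochberg
across enzymes, and additionally requires (i) pooled fold change above the
threshold, computed on library-normalised proportions with pseudocount 1,
and (ii) replicate consistency: the same direction of change in every
cross-environment replicate pair. The two returned sets are disjoint by the
sign of the change, and swapping the environments swaps the sets exactly.

## Network construction

A reaction joins a network when ANY of its EC numbers is in the enzyme set:
metagenomic enzyme sets are presence-based and carry no complex/subunit
logic. Reversible reactions become two directed reactions (`*_fwd`,
`*_rev`); reversibility is taken from the bank file, defaulting to
irreversible, never inferred. Stoichiometric coefficients are ignored —
this is a topological reachability framework, not a flux model. The
meta-network is the special case where the enzyme set is everything detected
across all samples.

Two graph views serve different consumers: a bipartite compound↔reaction
digraph (exported as SIF or GraphML for Cytoscape) and a compound-level
digraph with an edge u→v whenever some directed reaction consumes u and
produces v (used for seed detection).

## Seed (source-metabolite) detection

Seeds are computed from the condensation of the compound digraph: every
strongly connected component with no incoming edge from outside itself is a
seed component, all its members are reported, and each carries confidence
1/|component| (supplying any one member externally renders the rest
producible). No confidence threshold is applied by default
(`min_confidence = 0`); a threshold is available but opt-in, since any
particular cut-off is a modelling decision the data do not force.

Environment-specific networks are built from differential enzymes only and
are therefore highly fragmented; fragmentation manufactures artificial
sources. The filter `filter_seeds` keeps only environment seeds that are
also seeds of the meta-network, inheriting the environment-side confidences.

## Scope expansion

`expand(seeds, reactions)` computes the fixpoint of: fire every reaction
whose substrates are ALL currently available; add the products; repeat.
Feasibility is monotone in the available set, so the fixpoint is unique and
independent of iteration order; the implementation is a worklist over
rounds, and products of a round only become substrates in the next round, so
the recorded per-round trace is meaningful (round 0 is the seed pool). After
every run a fixpoint certificate is asserted: no unfired reaction is
feasible. Currency-metabolite supplementation (cofactor bootstrapping) is
available but OFF by default — the literal algorithm is the default
behaviour — and supplements are flagged separately from seeds in the output.

Environment simulations expand the FULL meta-network reaction set with each
environment's filtered seed set: the repertoire is shared (nearly all
enzymes are detected everywhere), environments differ through their inputs.

## Dominance

For each enzyme and sample, the Simpson index `D = Σ pᵢ²` is computed over
the read fractions of the taxa carrying the enzyme; `unassigned` reads are
excluded (the index presupposes taxonomic labels), and when nothing
assignable remains the result is a not-available marker, never 0. The
per-sample dominant taxon is the read-fraction argmax; ties yield none
(conservative: a tied sample can never satisfy consensus). The environmental
index is the arithmetic mean over the environment's samples, computed over
samples with at least `min_reads` (default 1) assignable reads.

An enzyme is dominated in an environment iff mean `D` > threshold AND the
same taxon is dominant in every replicate, including that every replicate
actually observes the enzyme — a missing replicate breaks consensus. The
threshold default is the literal 0.4; `"auto"` uses the dataset's own mean
environmental Simpson instead, for datasets whose overall dominance level
differs. Taxa are ranked per environment by the number of enzymes they
dominate (ties broken lexicographically) and the top five are the key
groups.

## Removal and complementation

Removal: the reference scope is expanded from the full enzyme set; the
truncated scope from the full set minus the enzymes the target key group
dominates (target `"all"` removes the union over every key group). The
missing set is reference − truncated (monotonicity guarantees truncated ⊆
reference, asserted on every run). Missing and reference compounds are
mapped to pathways; each pathway gets both `fraction_remaining` and
`fraction_missing` (they sum to 1). The default `effect_score` column is
`fraction_remaining` — the per-pathway survival of the function — with the
complementary column emitted alongside for consumers who prefer loss.

Complementation: the core is the set of enzymes dominated by NO key group in
the environment (enzymes dominated by non-key taxa stay in the core — the
key groups are the perturbation units, everything else is common
background). For a combination of ≥ 2 taxa, the core plus each member's
dominated enzymes is expanded separately and jointly; complementary
metabolites are the joint scope minus the union of single scopes. The result
is independent of member order, and arbitrary combination sizes are
supported with pairs as the documented default. Dominance is scoped strictly
per environment: an enzyme dominated elsewhere but not here stays in the
core here.

## Enrichment

Per pathway, with a subset of size *n* drawn from a background of size *N*
(both counted over pathway-mapped entities only; unmapped entities are
reported separately and excluded), *K* background members in the pathway and
*k* subset hits: the hypergeometric p-value is the exact upper tail
P(X ≥ k), and the chi-square p-value is a goodness-of-fit of the observed
(k, n−k) split against expected proportions (K/N, 1−K/N), df = 1; expected
cells below 5 trigger a logged warning. A pathway is enriched iff both
p < α (default 0.05). Backgrounds: all pathway-mapped enzymes of the meta
set for enzyme enrichment, all pathway-mapped compounds of the reference
scope for metabolite enrichment. No multiple-testing correction is applied
to the dual call by default; a Benjamini–Hochberg option on the
hypergeometric p-values exists but is OFF, matching the stated α-level
procedure. The dual AND rule is empirically conservative — the measured
per-pathway type-I error on uniform random subsets is ≈ 1%, well under α.

## Synthetic studies

The generator is a pure function of a `SynthSpec` (seeded with numpy's
`default_rng`); identical specs give byte-identical files. Defaults encode
the study conditions the framework targets: five order-level taxa, a
three-replicate root and two-replicate soil environment, dominance fraction
f = 0.9, read depths log-uniform in [50, 500] per (enzyme, sample), a 5%
`unassigned` read fraction, and a 40-reaction bank mixed from four motif
types (linear chains, branches, cycles with an exit, two-substrate joins) on
disjoint fresh compounds, one pathway id per motif.

Disjointness is what makes ground truth exact:

* seed components are known by construction (motif heads; whole cycles);
* dominance is planted per whole motif — a planted taxon contributes
  fraction f of every sample's reads for all of its motifs' enzymes, the
  remainder multinomial over the other taxa, so removing that taxon severs
  complete motifs and loses exactly their non-seed compounds. With f = 0.9
  the planted per-sample Simpson is ≥ 0.81 and the argmax is deterministic,
  so planted calls are essentially certain; non-planted enzymes draw
  near-uniform taxa (expected D ≈ 1/5), far below the 0.4 threshold;
* complementation chains (core S→M, taxon-A M→I, taxon-B I→T on fresh
  compounds) make T producible only jointly; a negative-control chain adds a
  core bypass M→T so its target must NOT be reported. The generator refuses
  chain placements that would collide with an existing route;
* per-environment differential structure is planted by boosting a few
  enzymes' read depth 8× in one environment's samples.

What the generator does **not** emulate: read-level sequence error,
taxonomic misassignment, compositional coupling between enzymes (depths are
independent), shared compounds between pathways, and realistic KEGG-scale
topology. Passing tests therefore demonstrate algorithmic correctness and
planted-structure recovery under controlled noise, not performance on real
metagenomes. One interaction worth knowing: the independent log-uniform
depth noise spans a 10× range while the differential boost is 8×, so the
replicate-consistency rule occasionally (by design) vetoes a planted
differential enzyme — sensitivity of the stand-in DA under heavy depth noise
is deliberately not a guaranteed property.

## Pipeline, determinism, problem sizes

`run_pipeline` chains the stages (differential → networks → seeds + filter →
expansion → dominance → removal → pairwise complementation → enrichment);
any stage failure aborts with the stage name and a machine-readable code.
All serialisation is sorted; outputs carry the SHA-256 hash of the
analysis-relevant configuration (the output directory is excluded from the
hash, so identical analyses in different locations are recognisably the
same run) and reruns are bitwise identical. `seed_mode` selects the
environment seed sets: `"filtered"` (environment-network seeds intersected
with meta seeds — the standard procedure) or `"meta"` (all environments use
the meta-network seeds), the latter useful when differential sets are small
and fragmentation extreme, as in compact synthetic studies.

Verification problem sizes, chosen to exercise every code path at desk
scale: 1000 random networks of ≤ 15 compounds / ≤ 20 reactions for the
expansion and seed oracles; 100 synthetic studies (40 reactions, 47
enzymes, 5 samples) for planted recovery; exhaustive hypergeometric
enumeration to N = 25; 1000 uniform subsets for the type-I measurement.

## Known limitations

* Reachability is qualitative: no stoichiometry, thermodynamics or flux.
* The binomial DA stand-in ignores overdispersion between replicates; real
  analyses should supply an external table from a count-model tool.
* Dominance at a single taxonomic rank (the rank is just a label, so other
  ranks work, but cross-rank aggregation is out of scope).
* The dual enrichment test applies no multiplicity control by default, by
  design; interpret α literally per pathway.
* Removal is all-or-nothing per taxon; abundance-weighted partial removal is
  not modelled.
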