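"""Scope expansion: which metabolites can a community make from a seed set?

Builds a five-reaction toy network by hand, detects its source (seed)
metabolites from topology, and expands the network from them.
"""

from rhizoscope.expansion import expand
from rhizoscope.netbuild import MetabolicNetwork, Reaction
from rhizoscope.seeds import detect_seeds

# glucose -> pyruvate -> acetyl-CoA, a TCA-like cycle entry, and a
# two-substrate condensation that needs BOTH inputs to fire
reactions = [
    Reaction("R1", frozenset({"2.7.1.1"}), frozenset({"glc"}), frozenset({"pyr"})),
    Reaction("R2", frozenset({"1.2.4.1"}), frozenset({"pyr"}), frozenset({"accoa"})),
    Reaction("R3", frozenset({"2.3.3.1"}), frozenset({"accoa", "oaa"}), frozenset({"cit"})),
    Reaction("R4", frozenset({"4.2.1.3"}), frozenset({"cit"}), frozenset({"icit"}), reversible=True),
    Reaction("R5", frozenset({"1.1.1.42"}), frozenset({"icit"}), frozenset({"akg"})),
]
network = MetabolicNetwork(
    {r.reaction_id: r for r in reactions},
    frozenset(ec for r in reactions for ec in r.ec_set),
)

seed_set = detect_seeds(network)
print("predicted source metabolites:", sorted(seed_set.flat))
# 'glc' and 'oaa' are consumed but never produced -> external inputs

scope = expand(seed_set.flat, network)
print("reachable metabolites:", sorted(scope.reachable))
print("reactions fired:", len(scope.active_reactions), "of", len(network.directed_reactions()))

# without oxaloacetate the condensation R3 cannot fire and the cycle is cut off
partial = expand({"glc"}, network)
print("reachable from glucose alone:", sorted(partial.reachable))
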