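"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own algorithms: expansion is recomputed
from scratch every round over the full reaction list; seed detection uses a
pairwise reachability matrix; the hypergeometric tail is an explicit binomial
sum.  They are only meant for tiny instances.
"""

from __future__ import annotations

from math import comb

import numpy as np

from rhizoscope.netbuild import DirectedReaction, MetabolicNetwork, Reaction


def brute_force_expand(
    seeds: set[str], reactions: list[DirectedReaction]
) -> tuple[set[str], set[str]]:
    """Round-by-round closure, recomputed from scratch each round."""
    available = set(seeds)
    while True:
        feasible = {dr.directed_id for dr in reactions if set(dr.substrates) <= available}
        produced = set()
        for dr in reactions:
            if dr.directed_id in feasible:
                produced |= set(dr.products)
        if produced <= available:
            return available, feasible
        available |= produced


def reachability(nodes: list[str], edges: set[tuple[str, str]]) -> dict[str, set[str]]:
    """reach[u] = all nodes reachable from u (including u), by iteration."""
    reach = {u: {u} for u in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            new = reach[b] - reach[a]
            if new:
                reach[a] |= new
                changed = True
    return reach


def brute_force_seed_members(network: MetabolicNetwork) -> set[str]:
    """A compound belongs to a seed component iff no compound outside its SCC
    reaches it."""
    nodes = sorted(network.compounds)
    edges = set()
    for dr in network.directed_reactions():
        for u in dr.substrates:
            for v in dr.products:
                edges.add((u, v))
    reach = reachability(nodes, edges)
    same_scc = {
        u: {v for v in nodes if v in reach[u] and u in reach[v]} for u in nodes
    }
    out = set()
    for u in nodes:
        outside_reachers = [v for v in nodes if u in reach[v] and v not in same_scc[u]]
        if not outside_reachers:
            out.add(u)
    return out


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by explicit summation."""
    total = comb(N, n)
    s = 0
    for x in range(k, min(n, K) + 1):
        s += comb(K, x) * comb(N - K, n - x)
    return s / total


def random_network(
    seed: int, max_compounds: int = 15, max_reactions: int = 20
) -> tuple[MetabolicNetwork, set[str]]:
    """A small random reaction network plus a random seed-compound set."""
    rng = np.random.default_rng(seed)
    n_c = int(rng.integers(2, max_compounds + 1))
    n_r = int(rng.integers(1, max_reactions + 1))
    compounds = [f"C{i:03d}" for i in range(n_c)]
    reactions = {}
    for i in range(n_r):
        subs = rng.choice(n_c, size=int(rng.integers(1, min(3, n_c) + 1)), replace=False)
        prods = rng.choice(n_c, size=int(rng.integers(1, min(3, n_c) + 1)), replace=False)
        reactions[f"R{i:03d}"] = Reaction(
            f"R{i:03d}",
            frozenset({f"1.1.1.{i + 1}"}),
            frozenset(compounds[s] for s in subs),
            frozenset(compounds[p] for p in prods),
            reversible=bool(rng.random() < 0.3),
        )
    net = MetabolicNetwork(reactions, frozenset(f"1.1.1.{i + 1}" for i in range(n_r)))
    n_seeds = int(rng.integers(0, n_c + 1))
    seed_set = set(rng.choice(compounds, size=n_seeds, replace=False))
    return net, seed_set
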