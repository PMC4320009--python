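"""Haplotype networks under a statistical-parsimony connection limit.

Haplotypes are connected in a minimum-spanning network (MSN): candidate
edges are all haplotype pairs weighted by their mutational steps (site
mismatches); Kruskal-style rounds over increasing step counts add every
equal-weight edge that joins components which were still separate at the
start of the round, so alternative equally-short connections are kept.
Edges requiring more steps than the connection limit j* are discarded,
and the resulting connected components — independent subnetworks — are
the unconfirmed candidate species of the classic statistical-parsimony
argument.

The connection limit is the largest number of steps for which a
connection is judged homoplasy-free with the requested confidence.  Here
that probability is computed from a finite-sites site-collision model:
j mutations thrown uniformly on L sites are all parsimonious exactly
when they hit j distinct sites,

    P_par(j) = prod_{i=0}^{j-1} (1 - i / L),

a birthday-problem bound in the spirit of the 95% statistical-parsimony
criterion.  A fixed override is always accepted for studies that want a
published limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigError, LabelingError
from .haplotypes import HaplotypeSet
from .seqio import AMBIGUITY_SETS


def step_matrix(haps: HaplotypeSet) -> np.ndarray:
    """Pairwise mutational steps between haplotypes (site mismatches).

    Two site states mismatch when their IUPAC base sets are disjoint:
    ambiguity codes therefore only count against incompatible bases,
    while gaps mismatch every base (and match other gaps).
    """
    k = haps.k
    S = np.zeros((k, k), dtype=int)
    seqs = haps.haplotypes
    for i in range(k):
        for j in range(i + 1, k):
            steps = sum(
                1
                for a, b in zip(seqs[i], seqs[j])
                if not (AMBIGUITY_SETS[a] & AMBIGUITY_SETS[b])
            )
            S[i, j] = S[j, i] = steps
    return S


def parsimony_probability(j: int, L: int) -> float:
    """Probability that j uniform mutations over L sites are homoplasy-free
    (all land on distinct sites)."""
    if j <= 0:
        return 1.0
    p = 1.0
    for i in range(j):
        p *= 1.0 - i / L
    return max(p, 0.0)


def parsimony_limit(L: int, p: float = 0.95, override: int | None = None) -> int:
    """Connection limit j*: the largest j with P_par(j) >= p (minimum 1).

    ``override`` short-circuits the computation, e.g. to reproduce a
    published limit.  At L=573 sites and p=0.95 the limit is 8 steps.
    """
    if override is not None:
        if override < 1:
            raise ConfigError("connection limit override must be >= 1")
        return int(override)
    if L <= 0:
        raise ConfigError("L must be positive")
    if not 0.0 < p < 1.0:
        raise ConfigError("confidence p must be in (0, 1)")
    j = 1
    while j + 1 <= L and parsimony_probability(j + 1, L) >= p:
        j += 1
    return j


@dataclass
class HaplotypeNetwork:
    """MSN over haplotypes with a step limit; components are candidate units."""

    node_ids: list[str]
    freqs: list[int]
    edges: list[tuple[str, str, int]]     # (hap_i, hap_j, steps), steps <= limit
    connection_limit: int
    components: list[frozenset]           # partition of node_ids

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_of(self) -> dict[str, int]:
        return {
            node: ci for ci, comp in enumerate(self.components) for node in comp
        }

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        for node, f in zip(self.node_ids, self.freqs):
            G.add_node(node, freq=int(f))
        for a, b, w in self.edges:
            G.add_edge(a, b, steps=int(w))
        return G

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)

    def write_edges_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hap_i\thap_j\tsteps\n")
            for a, b, w in self.edges:
                fh.write(f"{a}\t{b}\t{w}\n")

    def write_components_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("component\thaplotypes\n")
            for ci, comp in enumerate(self.components):
                fh.write(f"{ci + 1}\t{','.join(sorted(comp))}\n")


def build_network(haps: HaplotypeSet, jstar: int) -> HaplotypeNetwork:
    """Minimum-spanning network with all equal-weight ties, cut at j*.

    Kruskal rounds over ascending step counts; within a round every edge
    joining components that were separate *at the start of the round* is
    kept (this is what preserves alternative equally-parsimonious
    connections).  Edges above the limit are never added, so haplotype
    groups farther than j* steps apart end in different components.
    """
    if jstar < 1:
        raise ConfigError("connection limit must be >= 1")
    k = haps.k
    S = step_matrix(haps)
    labels = haps.ids

    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[str, str, int]] = []
    pair_w = sorted(
        {int(S[i, j]) for i in range(k) for j in range(i + 1, k) if S[i, j] <= jstar}
    )
    for w in pair_w:
        snapshot = [find(a) for a in range(k)]
        round_joins = []
        for i in range(k):
            for j in range(i + 1, k):
                if S[i, j] == w and snapshot[i] != snapshot[j]:
                    edges.append((labels[i], labels[j], w))
                    round_joins.append((i, j))
        for i, j in round_joins:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    comp_map: dict[int, set] = {}
    for a in range(k):
        comp_map.setdefault(find(a), set()).add(labels[a])
    components = sorted(
        (frozenset(c) for c in comp_map.values()), key=lambda c: min(c)
    )
    return HaplotypeNetwork(
        node_ids=list(labels),
        freqs=list(haps.freqs),
        edges=edges,
        connection_limit=int(jstar),
        components=components,
    )


def candidate_units(
    net: HaplotypeNetwork, labels: Mapping[str, str]
) -> dict[str, int]:
    """Per species, the number of network components holding >=1 of its
    haplotypes.  More than one independent subnetwork flags hidden
    diversity (unconfirmed candidate species)."""
    missing = [h for h in net.node_ids if h not in labels]
    if missing:
        raise LabelingError(f"haplotypes without species labels: {missing}")
    comp = net.component_of()
    out: dict[str, set] = {}
    for h in net.node_ids:
        out.setdefault(labels[h], set()).add(comp[h])
    return {sp: len(cs) for sp, cs in out.items()}
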