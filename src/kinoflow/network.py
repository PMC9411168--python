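"""Seed-node expansion of activated kinases into an interaction sub-network.

Activated kinases are seed nodes on a literature-style protein interaction
graph.  Each seed starts its own sub-network; expansion iteratively admits
the outside node with the most edges to current members (ties broken by
edges to the seed nodes, then lexicographic id), merging sub-networks as
they come to share members.  Expansion halts when all sub-networks have
merged into one ("intersected"), when admitting another node would bring
membership up to ``max_nodes`` ("size_limit"; the bound is exclusive, the
network stays below it), or when no candidate touches a member
("exhausted").  The result is named by its most interconnected member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

__all__ = ["SeedNetwork", "expand_network", "name_network"]

log = logging.getLogger(__name__)

DEFAULT_MAX_NODES = 50


@dataclass
class SeedNetwork:
    """Expanded sub-network with provenance."""

    members: dict[str, str]  # node -> role in {"seed", "expansion"}
    admission_order: list[str]
    halt_reason: str  # intersected | size_limit | exhausted
    subgraph: nx.Graph
    name: str = ""

    @property
    def seeds(self) -> list[str]:
        return [n for n, r in self.members.items() if r == "seed"]

    def membership_table(self):
        import pandas as pd

        deg = dict(self.subgraph.degree())
        return pd.DataFrame(
            {
                "node": list(self.members),
                "role": [self.members[n] for n in self.members],
                "degree_in_network": [deg.get(n, 0) for n in self.members],
            }
        ).sort_values(["role", "node"], kind="stable").reset_index(drop=True)


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def add(self, x):
        self.parent.setdefault(x, x)

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def expand_network(
    seeds,
    graph: nx.Graph,
    max_nodes: int = DEFAULT_MAX_NODES,
    tiebreak: str = "members",
) -> SeedNetwork:
    """Grow the seed sub-networks on ``graph`` by connectivity preference.

    ``tiebreak="members"`` (default) ranks candidates by edges to current
    members, breaking ties by edges to seeds; ``"seeds"`` swaps the two
    keys.  Remaining ties go to the lexicographically smallest id.
    """
    if tiebreak not in ("members", "seeds"):
        raise ValueError(f"tiebreak must be 'members' or 'seeds', got {tiebreak!r}")
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("seed list is empty")
    present = [s for s in seeds if s in graph]
    dropped = sorted(set(seeds) - set(present))
    if dropped:
        log.warning("%d seed(s) not in the graph, dropped: %s", len(dropped), dropped)
    if not present:
        raise ValueError("no seed node is present in the interaction graph")
    if max_nodes < 2:
        raise ValueError(f"max_nodes must be >= 2, got {max_nodes}")

    members: dict[str, str] = {s: "seed" for s in present}
    uf = _UnionFind()
    for s in present:
        uf.add(s)
    # seeds already joined by an edge intersect immediately
    for a in present:
        for b in graph.neighbors(a):
            if b in members:
                uf.union(a, b)

    def intersected() -> bool:
        # a lone seed is one sub-network by construction; "intersected"
        # only makes sense once there are >= 2 sub-networks to merge
        return len(present) > 1 and len({uf.find(s) for s in present}) == 1

    admission_order: list[str] = []
    halt = None
    while True:
        if intersected():
            halt = "intersected"
            break
        candidates = {}
        for m in members:
            for nb in graph.neighbors(m):
                if nb not in members:
                    candidates.setdefault(nb, None)
        if not candidates:
            halt = "exhausted"
            break
        if len(members) + 1 >= max_nodes:
            halt = "size_limit"
            break
        scored = []
        for c in candidates:
            e_members = sum(1 for nb in graph.neighbors(c) if nb in members)
            e_seeds = sum(1 for nb in graph.neighbors(c) if members.get(nb) == "seed")
            primary, secondary = (
                (e_members, e_seeds) if tiebreak == "members" else (e_seeds, e_members)
            )
            scored.append((-primary, -secondary, c))
        _, _, chosen = min(scored)
        members[chosen] = "expansion"
        admission_order.append(chosen)
        uf.add(chosen)
        for nb in graph.neighbors(chosen):
            if nb in members:
                uf.union(chosen, nb)

    assert len(members) < max_nodes, "admission rule overshot the size bound"
    sub = graph.subgraph(members).copy()
    net = SeedNetwork(
        members=members,
        admission_order=admission_order,
        halt_reason=halt,
        subgraph=sub,
    )
    net.name = name_network(net)
    return net


def name_network(network: SeedNetwork) -> str:
    """Most centric (interconnected) member: maximal degree in the induced
    sub-network; ties prefer seeds, then the lexicographically smallest id."""
    if not network.members:
        raise ValueError("network has no members")
    deg = dict(network.subgraph.degree())
    return min(
        network.members,
        key=lambda n: (-deg.get(n, 0), 0 if network.members[n] == "seed" else 1, n),
    )
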