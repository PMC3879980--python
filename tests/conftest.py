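"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's search code: parsimony
minima are recomputed by plain enumeration of loss subsets in increasing
size (which proves minimality), and reachability is a fresh BFS written
against the raw edge list.
"""

from __future__ import annotations

import itertools
import random

import pytest

from ringroot import datasets
from ringroot.ring_model import ROOT_SITE, FlowGraph, Taxon, build_flow_graph


# ---------------------------------------------------------------------------
# packaged-data fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def ring_six() -> FlowGraph:
    return datasets.inner_ring_six()


@pytest.fixture(scope="session")
def ring_five() -> FlowGraph:
    return datasets.inner_ring_five()


@pytest.fixture(scope="session")
def cherry_tree():
    return datasets.three_cherry_tree()


@pytest.fixture(scope="session")
def paralog_matrix():
    return datasets.paralog_character_matrix()


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bfs_leaves(edges: list[tuple[str, str]], leaves: dict[str, str], start: str,
               blocked: frozenset = frozenset()) -> set[str]:
    """Taxa reachable from ``start`` without crossing a blocked edge."""
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        if (u, v) not in blocked:
            adj.setdefault(u, []).append(v)
    seen, queue = {start}, [start]
    while queue:
        node = queue.pop()
        for child in adj.get(node, []):
            if child not in seen:
                seen.add(child)
                queue.append(child)
    return {leaves[n] for n in seen if n in leaves}


def oracle_min_loss(graph: FlowGraph, character: dict[str, int]):
    """Exhaustive minimum over (gain site, loss subset) pairs.

    Enumerates loss subsets in increasing size, so the first feasible size
    per site is the proven per-site minimum.  Returns (min_losses, set of
    optimal gain-site ids) or None when no placement exists.
    """
    edges = graph.edges
    leaves = {n: t.id for n, t in graph.leaf_map.items()}
    present = frozenset(t for t, v in character.items() if v)
    best = None
    best_sites: set[str] = set()
    for site in graph.sites():
        start = graph.root if site == ROOT_SITE else site[1]
        if not present <= bfs_leaves(edges, leaves, start):
            continue
        limit = best if best is not None else len(edges)
        found = None
        for k in range(0, limit + 1):
            for combo in itertools.combinations(edges, k):
                if bfs_leaves(edges, leaves, start, frozenset(combo)) == present:
                    found = k
                    break
            if found is not None:
                break
        if found is None:
            continue
        if best is None or found < best:
            best, best_sites = found, {FlowGraph.site_id(site)}
        elif found == best:
            best_sites.add(FlowGraph.site_id(site))
    return (best, best_sites) if best is not None else None


def random_flow_graph(rng: random.Random, max_extra_edges: int = 4) -> FlowGraph:
    """A random small rooted DAG (possibly with merge nodes), <= 12 edges."""
    n_nodes = rng.randint(3, 8)
    names = [f"n{i}" for i in range(n_nodes)]  # topological order by index
    edges = {(names[rng.randrange(i)], names[i]) for i in range(1, n_nodes)}
    for _ in range(rng.randint(0, max_extra_edges)):
        if len(edges) >= 12:
            break
        j = rng.randrange(1, n_nodes)
        i = rng.randrange(j)
        edges.add((names[i], names[j]))
    leaves = [n for n in names if all(u != n for u, _ in edges)]
    leaf_map = {n: Taxon(id=n.upper()) for n in leaves}
    return build_flow_graph(sorted(edges), leaf_map)


def random_character(rng: random.Random, graph: FlowGraph) -> dict[str, int]:
    taxa = sorted(graph.taxon_ids())
    while True:
        char = {t: rng.randint(0, 1) for t in taxa}
        if any(char.values()):
            return char
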