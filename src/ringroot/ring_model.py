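"""Rooted flow graphs: trees and rings.

A *flow graph* is a rooted directed acyclic graph whose leaves are taxa.
Gene families originate at *gain sites* (an edge, or the root itself) and
flow along directed edges toward the leaves; a graph with one or more
*merge* nodes (in-degree >= 2) is a ring, one with none is an ordinary
rooted tree.  Rings arise when two lineages converge through symbiosis or
endosymbiosis, so a single character can reach a leaf along more than one
path.

The module also handles unrooted binary trees and the enumeration of all
their rootings (one per edge), which is how tree hypotheses are compared
against a ring on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Phylo
from io import StringIO

__all__ = [
    "Taxon",
    "FlowGraph",
    "UnrootedTree",
    "GraphError",
    "ROOT_SITE",
    "build_flow_graph",
    "enumerate_rootings",
    "reachable_leaves",
    "read_edge_list",
    "write_edge_list",
    "read_taxon_table",
    "read_newick_unrooted",
    "tree_to_newick",
]

#: Sentinel naming the root as a gain site (the root is a legal gain site
#: in addition to every edge).  Sorts before every edge identifier, which
#: fixes the deterministic tie-break order used downstream.
ROOT_SITE = "ROOT"


class GraphError(ValueError):
    """Raised when an edge list does not describe a valid flow graph."""


@dataclass(frozen=True)
class Taxon:
    """A terminal taxon with its super-group assignment.

    ``supergroup`` is one of a user-declared label set, e.g. the six-way
    A, D, B, C, E, H or the five-way A, D, F, H, E groupings of the
    prokaryotic super-taxa.
    """

    id: str
    name: str = ""
    supergroup: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("taxon id must be a non-empty string")


class FlowGraph:
    """A validated rooted DAG with taxon-mapped leaves.

    Use :func:`build_flow_graph` to construct one; the constructor assumes
    the edge list has already been validated.
    """

    def __init__(self, graph: nx.DiGraph, leaf_map: Mapping[str, Taxon]):
        self._g = graph
        self.leaf_map: dict[str, Taxon] = dict(leaf_map)
        roots = [n for n in graph.nodes if graph.in_degree(n) == 0]
        self.root: str = roots[0]

    # -- basic views ------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Edges sorted by (parent, child); the canonical edge order."""
        return sorted(self._g.edges)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_map)

    @property
    def merge_nodes(self) -> list[str]:
        return sorted(n for n in self._g.nodes if self._g.in_degree(n) >= 2)

    @property
    def is_tree(self) -> bool:
        return not self.merge_nodes

    def taxa(self) -> list[Taxon]:
        return [self.leaf_map[l] for l in self.leaves]

    def taxon_ids(self) -> set[str]:
        return {t.id for t in self.leaf_map.values()}

    def role(self, node: str) -> str:
        if node == self.root:
            return "root"
        if node in self.leaf_map:
            return "leaf"
        if self._g.in_degree(node) >= 2:
            return "merge"
        return "internal"

    def successors(self, node: str) -> list[str]:
        return sorted(self._g.successors(node))

    def has_edge(self, parent: str, child: str) -> bool:
        return self._g.has_edge(parent, child)

    def nx_graph(self) -> nx.DiGraph:
        """A copy of the underlying directed graph."""
        return self._g.copy()

    # -- sites ------------------------------------------------------------
    def sites(self) -> list[object]:
        """All legal gain sites: the root sentinel, then edges in order."""
        return [ROOT_SITE, *self.edges]

    @staticmethod
    def site_id(site: object) -> str:
        """Printable identifier for a site; root sorts first."""
        if site == ROOT_SITE:
            return ROOT_SITE
        parent, child = site  # type: ignore[misc]
        return f"{parent}->{child}"

    @staticmethod
    def site_sort_key(site: object) -> tuple:
        if site == ROOT_SITE:
            return ("",)
        return tuple(site)  # type: ignore[arg-type]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "tree" if self.is_tree else "ring"
        return (
            f"<FlowGraph ({kind}) root={self.root!r} "
            f"{len(self.leaf_map)} leaves, {self._g.number_of_edges()} edges>"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlowGraph):
            return NotImplemented
        return self.edges == other.edges and self.leaf_map == other.leaf_map

    def __hash__(self) -> int:
        return hash(tuple(self.edges))


@dataclass
class UnrootedTree:
    """An unrooted binary tree: internal nodes of degree 3, leaves degree 1.

    A binary tree on L leaves has 2L - 3 edges, hence 2L - 3 rootings.
    """

    graph: nx.Graph
    leaf_map: dict[str, Taxon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() < 2:
            raise GraphError("unrooted tree needs at least two nodes")
        if not nx.is_connected(g):
            raise GraphError("unrooted tree must be connected")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise GraphError("unrooted tree must be acyclic")
        leaves = {n for n in g.nodes if g.degree(n) == 1}
        internal = set(g.nodes) - leaves
        if g.number_of_nodes() > 2:
            bad = [n for n in internal if g.degree(n) != 3]
            if bad:
                raise GraphError(f"non-binary internal nodes: {sorted(bad)}")
        missing = leaves - set(self.leaf_map)
        if missing:
            raise GraphError(f"unmapped leaves: {sorted(missing)}")
        extra = set(self.leaf_map) - leaves
        if extra:
            raise GraphError(f"leaf_map entries that are not leaves: {sorted(extra)}")

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_map)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


# ---------------------------------------------------------------------------
# construction & validation
# ---------------------------------------------------------------------------

def build_flow_graph(
    edge_list: Iterable[tuple[str, str]],
    leaf_map: Mapping[str, Taxon | str],
) -> FlowGraph:
    """Validate an edge list and return a :class:`FlowGraph`.

    Parameters
    ----------
    edge_list:
        ``(parent, child)`` pairs.  Must describe a DAG with exactly one
        root (in-degree 0) from which every node is reachable.
    leaf_map:
        Mapping from every out-degree-0 node to its :class:`Taxon` (a bare
        string is promoted to a Taxon with that id).

    Raises
    ------
    GraphError
        On a cycle, multiple roots, an unmapped leaf, a mapped node that
        has out-edges, or an empty edge list.
    """
    edges = [tuple(e) for e in edge_list]
    if not edges:
        raise GraphError("empty edge list")
    g = nx.DiGraph()
    for parent, child in edges:
        if parent == child:
            raise GraphError(f"self-loop on node {parent!r}")
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        raise GraphError("cycle detected")
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    if len(roots) != 1:
        raise GraphError(f"expected exactly one root, found {sorted(roots)}")
    root = roots[0]
    reachable = set(nx.descendants(g, root)) | {root}
    if reachable != set(g.nodes):
        raise GraphError(
            f"nodes unreachable from root: {sorted(set(g.nodes) - reachable)}"
        )
    leaves = {n for n in g.nodes if g.out_degree(n) == 0}
    lmap: dict[str, Taxon] = {}
    for node, taxon in leaf_map.items():
        lmap[node] = taxon if isinstance(taxon, Taxon) else Taxon(id=str(taxon))
    missing = leaves - set(lmap)
    if missing:
        raise GraphError(f"unmapped leaves: {sorted(missing)}")
    nonleaf = set(lmap) - leaves
    if nonleaf:
        raise GraphError(f"mapped nodes with out-edges: {sorted(nonleaf)}")
    return FlowGraph(g, lmap)


def reachable_leaves(graph: FlowGraph, site: object) -> set[str]:
    """Taxon ids of all leaves on a directed path from ``site``.

    ``site`` is either :data:`ROOT_SITE`, a node name, or an edge tuple
    ``(parent, child)``; for an edge the flow starts at the child end, so
    the edge itself is part of every path counted.  From the root this is
    the full taxon set.
    """
    g = graph._g
    if site == ROOT_SITE:
        start = graph.root
    elif isinstance(site, tuple):
        if not g.has_edge(*site):
            raise GraphError(f"unknown edge {site!r}")
        start = site[1]
    else:
        if site not in g.nodes:
            raise GraphError(f"unknown node {site!r}")
        start = site
    nodes = set(nx.descendants(g, start)) | {start}
    return {graph.leaf_map[n].id for n in nodes if n in graph.leaf_map}


def enumerate_rootings(tree: UnrootedTree) -> list[FlowGraph]:
    """All rootings of an unrooted binary tree, one per edge.

    Each rooting subdivides one edge with a new node named ``root`` and
    orients every edge away from it; a tree with L leaves yields 2L - 3
    rooted trees.  Output order follows the canonical sorted edge order.
    """
    out: list[FlowGraph] = []
    for u, v in tree.edges:
        g = tree.graph.copy()
        g.remove_edge(u, v)
        root = "root"
        while root in g.nodes:  # avoid a clash with user node names
            root = "_" + root
        g.add_edge(root, u)
        g.add_edge(root, v)
        directed = nx.bfs_tree(g, root)
        out.append(build_flow_graph(directed.edges, tree.leaf_map))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_edge_list(graph: FlowGraph, path) -> None:
    """Write ``parent<TAB>child`` lines (the plain-text graph format)."""
    with open(path, "w") as fh:
        fh.write("# flow graph edge list: parent<TAB>child\n")
        for parent, child in graph.edges:
            fh.write(f"{parent}\t{child}\n")


def read_edge_list(path, leaf_map: Mapping[str, Taxon | str]) -> FlowGraph:
    """Read a TSV edge list (``#`` comments and blank lines ignored)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphError(f"malformed edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    return build_flow_graph(edges, leaf_map)


def read_taxon_table(path) -> dict[str, Taxon]:
    """Read a taxon TSV with columns id, name, supergroup."""
    taxa: dict[str, Taxon] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "id":  # header
                continue
            tid, name, group = (parts + ["", ""])[:3]
            if tid in taxa:
                raise GraphError(f"duplicate taxon id {tid!r}")
            taxa[tid] = Taxon(id=tid, name=name, supergroup=group)
    return taxa


def read_newick_unrooted(source: str, taxa: Mapping[str, Taxon] | None = None) -> UnrootedTree:
    """Parse a Newick string (or path) into an :class:`UnrootedTree`.

    The tree is taken as unrooted: a basal trifurcation is expected and a
    basal bifurcation is suppressed (its two edges fused), as is usual when
    an unrooted tree was serialized with an arbitrary root.  Newick cannot
    express merge nodes, so ring-shaped graphs have no Newick form.
    """
    try:
        handle = StringIO(source) if "(" in str(source) else open(source)
    except OSError:
        handle = StringIO(str(source))
    tree = Phylo.read(handle, "newick")
    g = nx.Graph()
    counter = [0]
    leaf_map: dict[str, Taxon] = {}

    def name_of(clade) -> str:
        if clade.name:
            return clade.name
        counter[0] += 1
        return f"n{counter[0]}"

    def walk(clade, parent_name):
        nm = name_of(clade)
        if parent_name is not None:
            g.add_edge(parent_name, nm)
        if not clade.clades:
            leaf_map[nm] = (taxa or {}).get(nm, Taxon(id=nm))
        for ch in clade.clades:
            walk(ch, nm)
        return nm

    root_name = walk(tree.root, None)
    # suppress an artificial degree-2 root left by rooted serialization
    if g.degree(root_name) == 2:
        a, b = list(g.neighbors(root_name))
        g.remove_node(root_name)
        g.add_edge(a, b)
    return UnrootedTree(g, leaf_map)


def tree_to_newick(graph: FlowGraph) -> str:
    """Serialize a tree-shaped FlowGraph to Newick (rings are rejected)."""
    if not graph.is_tree:
        raise GraphError("Newick cannot express merge nodes; use an edge list")

    def render(node: str) -> str:
        children = graph.successors(node)
        if not children:
            return graph.leaf_map[node].id
        return "(" + ",".join(render(c) for c in children) + ")"

    return render(graph.root) + ";"
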