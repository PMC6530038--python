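"""Module-level 3-uniform hypergraph construction and extraction.

Selected gene triplets are lifted to module labels (a gene belonging to
several modules duplicates its triplets, once per label combination) and
identical module multisets are aggregated into weighted hyperedges.  An
edge joining modules {a, b, c} is type 3 when all labels differ, type 2
when exactly two differ, and type 1 (a self-loop) when all three genes fall
in one module.  Raw counts are converted to fold changes over the expected
count under random placement of the lifted triplets across modules, and the
graph is sparsified by thresholding the fold change.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .grouping import ModuleAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleHyperedge",
    "Hypergraph3",
    "lift_triplets",
    "classify_edge_type",
    "multiset_probability",
    "expected_count",
    "build_hypergraph",
    "threshold_edges",
    "suggest_threshold",
    "vertex_degrees",
    "median_degree",
    "ego_subhypergraph",
    "top_k_subhypergraph",
    "gene_level_subhypergraph",
    "clique_expansion",
    "write_hyperedges_tsv",
    "write_graphml",
]

ModuleTriple = tuple[str, str, str]


@dataclass(frozen=True)
class ModuleHyperedge:
    """A weighted hyperedge over an unordered multiset of 3 module labels."""

    modules: ModuleTriple  # sorted
    count: int
    expected: float
    fold_change: float
    edge_type: int

    def __post_init__(self) -> None:
        if len(self.modules) != 3:
            raise ValueError("a hyperedge joins exactly 3 module labels")
        if tuple(sorted(self.modules)) != tuple(self.modules):
            raise ValueError("module labels must be stored sorted")
        if self.count < 1:
            raise ValueError("materialized edges require count >= 1")
        if self.expected <= 0:
            raise ValueError("expected count must be positive")
        if self.edge_type != len(set(self.modules)):
            raise ValueError("edge_type must equal the number of distinct modules")


@dataclass
class Hypergraph3:
    """A 3-uniform hypergraph over modules, with gene counts as vertex sizes."""

    vertices: dict[str, int]  # module label -> gene count
    edges: list[ModuleHyperedge]
    total_lifted: int
    median_degree: float | None = field(default=None)

    def __post_init__(self) -> None:
        for e in self.edges:
            for mod in set(e.modules):
                if mod not in self.vertices:
                    raise ValueError(f"edge references unknown module {mod!r}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_lookup(self) -> dict[ModuleTriple, ModuleHyperedge]:
        return {e.modules: e for e in self.edges}


def lift_triplets(
    triplets: list[tuple[str, str, str]],
    assignment: ModuleAssignment,
) -> tuple[list[ModuleTriple], int]:
    """Replace genes by module labels, duplicating for multi-membership.

    Each gene triplet whose three genes all carry at least one module label
    expands to the Cartesian product of the three membership lists; a
    triplet containing any unassigned gene is discarded (and counted).

    Returns the lifted multiset (list of sorted label triples) and the
    number of discarded gene triplets.
    """
    lifted: list[ModuleTriple] = []
    discarded = 0
    membership = assignment.membership
    for genes in triplets:
        mems = [membership.get(g) for g in genes]
        if any(not m for m in mems):
            discarded += 1
            continue
        for combo in itertools.product(*mems):
            lifted.append(tuple(sorted(combo)))  # type: ignore[arg-type]
    if discarded:
        logger.info("lift: discarded %d triplets containing unassigned genes", discarded)
    return lifted, discarded


def classify_edge_type(modules: tuple[str, str, str]) -> int:
    """1, 2 or 3 = number of distinct module labels among the three."""
    if len(modules) != 3:
        raise ValueError("exactly 3 module labels required")
    return len(set(modules))


def multiset_probability(
    modules: tuple[str, str, str],
    module_sizes: dict[str, int],
    with_replacement: bool = False,
) -> float:
    """Probability of drawing the module multiset for a random gene triplet.

    Three genes are drawn from the pooled membership list of size
    N = sum of module sizes (a multi-member gene contributes once per
    module).  Without replacement (default) the three slots are distinct
    draws; the ``with_replacement`` variant is provided for comparison.
    """
    mods = tuple(modules)
    if len(mods) != 3:
        raise ValueError("exactly 3 module labels required")
    counts = Counter(mods)
    for mod in counts:
        if module_sizes.get(mod, 0) < 1:
            raise ValueError(f"module {mod!r} has size 0 or is unknown")
    N = sum(module_sizes.values())
    if N < 3:
        raise ValueError("total membership N must be >= 3")
    # number of ordered slot arrangements of the multiset: 6, 3 or 1
    arrangements = {1: 1, 2: 3, 3: 6}[len(counts)]
    num = 1.0
    den = 1.0
    if with_replacement:
        for mod, r in counts.items():
            num *= float(module_sizes[mod]) ** r
        den = float(N) ** 3
    else:
        for mod, r in counts.items():
            n_mod = module_sizes[mod]
            for t in range(r):
                num *= n_mod - t
        den = float(N) * (N - 1) * (N - 2)
    return arrangements * num / den


def expected_count(
    modules: tuple[str, str, str],
    module_sizes: dict[str, int],
    total_lifted: int,
    with_replacement: bool = False,
) -> float:
    """Expected hyperedge count if lifted triplets were placed at random."""
    if total_lifted < 1:
        raise ValueError("total_lifted must be >= 1")
    return total_lifted * multiset_probability(modules, module_sizes, with_replacement)


def build_hypergraph(
    lifted: list[ModuleTriple],
    assignment: ModuleAssignment,
    with_replacement: bool = False,
) -> Hypergraph3:
    """Aggregate identical module multisets into weighted hyperedges.

    Edge count conservation holds by construction: the edge counts sum to
    the number of lifted triples.
    """
    if not lifted:
        raise ValueError("no lifted triplets to aggregate")
    sizes = assignment.module_sizes()
    counter = Counter(tuple(sorted(t)) for t in lifted)
    total = len(lifted)
    edges = []
    for mods in sorted(counter):
        cnt = counter[mods]
        exp = expected_count(mods, sizes, total, with_replacement)
        edges.append(
            ModuleHyperedge(
                modules=mods,
                count=cnt,
                expected=exp,
                fold_change=cnt / exp,
                edge_type=classify_edge_type(mods),
            )
        )
    return Hypergraph3(vertices=dict(sizes), edges=edges, total_lifted=total)


def vertex_degrees(graph: Hypergraph3) -> dict[str, int]:
    """Number of incident hyperedges per vertex.

    An edge touching a vertex more than once (self-loop labels) still
    contributes one to that vertex's degree.
    """
    deg = {v: 0 for v in graph.vertices}
    for e in graph.edges:
        for mod in set(e.modules):
            deg[mod] += 1
    return deg


def median_degree(graph: Hypergraph3) -> float | None:
    """Median degree over vertices incident to at least one edge."""
    deg = [d for d in vertex_degrees(graph).values() if d > 0]
    if not deg:
        return None
    return float(np.median(deg))


def threshold_edges(graph: Hypergraph3, min_fold_change: float) -> Hypergraph3:
    """Keep edges with fold change >= threshold; drop isolated vertices.

    The result records the median vertex degree of the sparsified graph.
    """
    if min_fold_change < 0:
        raise ValueError("min_fold_change must be >= 0")
    edges = [e for e in graph.edges if e.fold_change >= min_fold_change]
    involved: set[str] = set()
    for e in edges:
        involved.update(e.modules)
    vertices = {v: s for v, s in graph.vertices.items() if v in involved}
    out = Hypergraph3(vertices=vertices, edges=edges, total_lifted=graph.total_lifted)
    out.median_degree = median_degree(out)
    return out


def suggest_threshold(graph: Hypergraph3, target_median_degree: float) -> float | None:
    """Smallest fold-change threshold whose median degree is <= target.

    Scans the sorted distinct fold-change values (plus 0); returns None if
    no candidate brings the median degree down to the target.
    """
    candidates = sorted({0.0, *(e.fold_change for e in graph.edges)})
    for t in candidates:
        med = threshold_edges(graph, t).median_degree
        if med is not None and med <= target_median_degree:
            return t
    return None


def ego_subhypergraph(graph: Hypergraph3, vertex: str) -> Hypergraph3:
    """Edges incident to a vertex, together with their member vertices."""
    if vertex not in graph.vertices:
        raise KeyError(f"unknown vertex {vertex!r}")
    edges = [e for e in graph.edges if vertex in e.modules]
    involved = {vertex}
    for e in edges:
        involved.update(e.modules)
    vertices = {v: graph.vertices[v] for v in sorted(involved)}
    return Hypergraph3(vertices=vertices, edges=edges, total_lifted=graph.total_lifted)


def top_k_subhypergraph(graph: Hypergraph3, k: int) -> Hypergraph3:
    """Sub-hypergraph induced by the k most-connected vertices.

    Ties are broken by label order; an edge is kept when all of its member
    vertices lie in the top-k set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    deg = vertex_degrees(graph)
    ranked = sorted(deg, key=lambda v: (-deg[v], v))
    top = set(ranked[:k])
    edges = [e for e in graph.edges if set(e.modules) <= top]
    vertices = {v: graph.vertices[v] for v in sorted(top)}
    return Hypergraph3(vertices=vertices, edges=edges, total_lifted=graph.total_lifted)


def gene_level_subhypergraph(
    triplets: list[tuple[str, str, str]],
    assignment: ModuleAssignment,
    module_triple: ModuleTriple,
) -> tuple[dict[str, int], list[tuple[str, str, str]]]:
    """Gene-level view of one module hyperedge.

    Returns the selected gene triplets that lift to exactly the given module
    multiset (one entry per lifted occurrence, so the edge list length
    matches the parent hyperedge's count) and the genes involved with their
    incident-edge counts as vertex sizes.
    """
    target = tuple(sorted(module_triple))
    membership = assignment.membership
    edges: list[tuple[str, str, str]] = []
    for genes in triplets:
        mems = [membership.get(g) for g in genes]
        if any(not m for m in mems):
            continue
        for combo in itertools.product(*mems):
            if tuple(sorted(combo)) == target:
                edges.append(tuple(genes))  # type: ignore[arg-type]
    if not edges:
        raise KeyError(f"module triple {target} is not an edge of the lifted graph")
    sizes: dict[str, int] = {}
    for genes in edges:
        for g in set(genes):
            sizes[g] = sizes.get(g, 0) + 1
    return sizes, edges


def clique_expansion(graph: Hypergraph3) -> nx.Graph:
    """Reduce hyperedges to binary edges for generic graph viewers.

    Each hyperedge contributes the pairwise edges among its distinct
    modules (a type-1 edge becomes a self-loop).  Parallel contributions
    are merged, keeping the maximum fold change as the edge weight and the
    summed triplet count.  Vertices carry module size and hyperedge degree.
    """
    G = nx.Graph()
    deg = vertex_degrees(graph)
    for v, size in sorted(graph.vertices.items()):
        G.add_node(v, size=int(size), degree=int(deg[v]))
    for e in graph.edges:
        distinct = sorted(set(e.modules))
        pairs = [(distinct[0], distinct[0])] if len(distinct) == 1 else list(
            itertools.combinations(distinct, 2)
        )
        for a, b in pairs:
            if G.has_edge(a, b):
                G[a][b]["weight"] = max(G[a][b]["weight"], float(e.fold_change))
                G[a][b]["count"] += int(e.count)
            else:
                G.add_edge(a, b, weight=float(e.fold_change), count=int(e.count))
    return G


def write_hyperedges_tsv(graph: Hypergraph3, path: str | Path) -> None:
    """Write edges as TSV: sorted module labels, count, expected, fold change, type."""
    with open(path, "w") as fh:
        fh.write("module_a\tmodule_b\tmodule_c\tcount\texpected\tfold_change\tedge_type\n")
        for e in sorted(graph.edges, key=lambda e: e.modules):
            a, b, c = e.modules
            fh.write(
                f"{a}\t{b}\t{c}\t{e.count}\t{e.expected:.10g}\t{e.fold_change:.10g}\t{e.edge_type}\n"
            )


def write_graphml(graph: Hypergraph3, path: str | Path) -> None:
    """Write the clique expansion as GraphML."""
    nx.write_graphml(clique_expansion(graph), str(path))
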