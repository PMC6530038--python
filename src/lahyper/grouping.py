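"""Gene-to-module assignment: supervised (gene sets) or unsupervised.

The supervised route intersects a user-supplied gene-set collection (GMT)
with the data's genes and keeps sets within a size window; a gene may carry
several module labels.  The unsupervised route clusters genes on their
triplet co-involvement profiles: a pair-count matrix A tallies, for every
gene pair, the number of selected triplets containing both genes; the
correlation matrix C of A's rows measures similarity of involvement, and
average-linkage hierarchical clustering of the distance 1 - C, cut by an
adaptive minimum-size branch decomposition, yields the modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "ModuleAssignment",
    "PairCountMatrix",
    "read_gmt",
    "assign_supervised",
    "build_pair_count_matrix",
    "pair_profile_distance",
    "cluster_unsupervised",
]


@dataclass
class GeneSetCollection:
    """Named gene sets; genes may belong to several sets."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(g) for name, g in self.sets.items()}


@dataclass
class ModuleAssignment:
    """Mapping gene -> module labels plus the genes left unassigned.

    Supervised assignments may map a gene to several modules; unsupervised
    assignments map every clustered gene to exactly one.
    """

    mode: str  # "supervised" | "unsupervised"
    membership: dict[str, list[str]]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("supervised", "unsupervised"):
            raise ValueError("mode must be 'supervised' or 'unsupervised'")
        for gene, mods in self.membership.items():
            if not mods:
                raise ValueError(f"gene {gene!r} has an empty module list")
            if self.mode == "unsupervised" and len(mods) != 1:
                raise ValueError(f"unsupervised gene {gene!r} must have exactly one module")

    def modules(self) -> list[str]:
        out: set[str] = set()
        for mods in self.membership.values():
            out.update(mods)
        return sorted(out)

    def module_sizes(self) -> dict[str, int]:
        """Gene count per module (a multi-member gene counts once per module)."""
        sizes: dict[str, int] = {}
        for mods in self.membership.values():
            for mod in mods:
                sizes[mod] = sizes.get(mod, 0) + 1
        return sizes


@dataclass
class PairCountMatrix:
    """Symmetric gene-pair co-involvement counts with zero diagonal."""

    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("A must be symmetric")
        if self.A.diagonal().any():
            raise ValueError("A must have a zero diagonal")
        if (self.A < 0).any():
            raise ValueError("A must be non-negative")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {line_no}: expected name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"GMT line {line_no}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError("GMT file contains no gene sets")
    return GeneSetCollection(sets=sets)


def assign_supervised(
    genes: list[str],
    collection: GeneSetCollection,
    min_set_size: int = 5,
    max_set_size: int = 500,
) -> ModuleAssignment:
    """Map genes to the gene sets containing them, after a size filter.

    Set sizes are measured after intersecting each set with the data's
    genes; sets outside ``[min_set_size, max_set_size]`` are discarded.
    Genes contained in no surviving set are dropped (they carry no
    module-level information); genes in several sets keep every label.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe = set(genes)
    surviving: dict[str, set[str]] = {}
    for name, members in collection.sets.items():
        present = set(members) & universe
        if min_set_size <= len(present) <= max_set_size:
            surviving[name] = present
    if not surviving:
        raise ValueError(
            f"no gene set within size window [{min_set_size}, {max_set_size}] "
            "after intersecting with the data"
        )
    membership: dict[str, list[str]] = {}
    dropped: list[str] = []
    for g in genes:
        mods = sorted(name for name, present in surviving.items() if g in present)
        if mods:
            membership[g] = mods
        else:
            dropped.append(g)
    logger.info(
        "supervised grouping: %d/%d sets survive, %d genes assigned, %d dropped",
        len(surviving), len(collection), len(membership), len(dropped),
    )
    return ModuleAssignment(mode="supervised", membership=membership, dropped=dropped)


def build_pair_count_matrix(triplets: list[tuple[int, int, int]], n: int) -> PairCountMatrix:
    """Tally, for each ordered gene pair, its co-occurrences in triplets.

    Every triplet (i, j, k) increments the six ordered cells (i,j), (j,i),
    (i,k), (k,i), (j,k), (k,j) by one, so the grand total is six times the
    number of triplets.
    """
    A = np.zeros((n, n), dtype=np.int64)
    for t in triplets:
        i, j, k = (int(v) for v in t)
        if not (0 <= i < n and 0 <= j < n and 0 <= k < n):
            raise IndexError(f"triplet {t} out of range for n={n}")
        if len({i, j, k}) != 3:
            raise ValueError(f"triplet {t} has repeated gene indices")
        for a, b in ((i, j), (i, k), (j, k)):
            A[a, b] += 1
            A[b, a] += 1
    np.fill_diagonal(A, 0)
    return PairCountMatrix(A=A)


def pair_profile_distance(counts: PairCountMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance 1 - C between gene co-involvement profiles.

    C is the Pearson correlation between rows of A.  Rows without variation
    (genes in no triplet, or with a flat profile) have undefined
    correlations and are excluded from clustering.

    Returns
    -------
    D : ndarray
        Square distance matrix over the clusterable genes.
    kept : ndarray
        Indices (into A) of the clusterable genes.
    excluded : ndarray
        Indices of the excluded genes.
    """
    A = counts.A.astype(float)
    variable = A.std(axis=1) > 0
    kept = np.flatnonzero(variable)
    excluded = np.flatnonzero(~variable)
    if kept.size < 2:
        raise ValueError("need at least 2 genes with variable triplet profiles")
    C = np.corrcoef(A[kept])
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry
    return D, kept, excluded


def _cut_components(node: hierarchy.ClusterNode, height: float) -> list[hierarchy.ClusterNode]:
    """Maximal subtrees of ``node`` whose merge height lies below ``height``."""
    if node.is_leaf() or node.dist < height:
        return [node]
    out: list[hierarchy.ClusterNode] = []
    out.extend(_cut_components(node.get_left(), height))
    out.extend(_cut_components(node.get_right(), height))
    return out


def _branch_decompose(
    node: hierarchy.ClusterNode,
    min_size: int,
    clusters: list[list[int]],
    dropped: list[int],
) -> None:
    """Adaptive top-down branch cut honoring a minimum cluster size.

    A branch is cut at 0.99 times its own top merge height; when this
    separates at least two components of minimum size, the refinement is
    accepted (sub-minimum side components are dropped, not force-merged)
    and each large component is decomposed recursively.  Otherwise the
    branch has no substructure that can stand on its own and is emitted
    whole.
    """
    if node.is_leaf() or node.dist <= 0:
        clusters.append(sorted(node.pre_order(lambda x: x.id)))
        return
    comps = _cut_components(node, 0.99 * node.dist)
    big = [c for c in comps if c.get_count() >= min_size]
    if len(big) >= 2:
        for c in comps:
            if c.get_count() >= min_size:
                _branch_decompose(c, min_size, clusters, dropped)
            else:
                dropped.extend(c.pre_order(lambda x: x.id))
    else:
        clusters.append(sorted(node.pre_order(lambda x: x.id)))


def cluster_unsupervised(
    D: np.ndarray,
    min_cluster_size: int,
    gene_ids: list[str] | None = None,
    linkage_method: str = "average",
) -> ModuleAssignment:
    """Cluster genes by average-linkage hierarchical clustering of D.

    The dendrogram is cut by an adaptive branch decomposition: starting at
    the root, a branch is split as long as both children hold at least
    ``min_cluster_size`` leaves; side branches below the minimum are dropped.
    Deterministic given D.  Cluster labels are ``M001, M002, ...`` in order
    of each cluster's smallest member index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if min_cluster_size > n:
        raise ValueError(f"min_cluster_size {min_cluster_size} exceeds {n} clusterable genes")
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    root = hierarchy.to_tree(Z)
    clusters: list[list[int]] = []
    dropped_idx: list[int] = []
    _branch_decompose(root, min_cluster_size, clusters, dropped_idx)
    clusters.sort(key=lambda c: c[0])
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(n)]
    width = max(3, len(str(len(clusters))))
    membership: dict[str, list[str]] = {}
    for rank, members in enumerate(clusters, start=1):
        label = f"M{rank:0{width}d}"
        for idx in members:
            membership[ids[idx]] = [label]
    dropped = sorted(ids[i] for i in dropped_idx)
    logger.info(
        "unsupervised grouping: %d clusters (min size %d), %d genes dropped",
        len(clusters), min_cluster_size, len(dropped),
    )
    return ModuleAssignment(mode="unsupervised", membership=membership, dropped=dropped)
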