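"""Single-cell microglia morphometrics.

Morphology is measured on the medial-axis skeleton of a cell mask, following
the 3DMorph-style convention: the mask is thinned to a one-voxel-wide
skeleton, a graph is built over skeleton voxels with physically correct
(anisotropic) edge lengths, short terminal spurs are pruned, and branches are
the maximal paths between nodes of degree != 2.  Territorial volume is the
convex hull of the cell mask, and the ramification index is cell volume (or
area in 2D) divided by hull volume -- the solidity of the cell, which
decreases as the cell becomes more ramified.

The hull is computed over voxel *extents* (voxel centers offset by half a
voxel in every direction) rather than bare centers, so that a filled convex
solid scores a ramification index of exactly 1 and the index can never
exceed 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import generate_binary_structure, label as ndi_label
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import skeletonize

from gliavasc.exceptions import InconsistencyError

__all__ = [
    "SkeletonGraph",
    "BranchStats",
    "MorphFeatures",
    "FEATURE_NAMES",
    "skeletonize_cell",
    "branch_stats",
    "hull_and_ramification",
    "compute_features",
]

#: Canonical ordering of the 8-feature morphology vector.
FEATURE_NAMES = (
    "soma_size",
    "n_endpoints",
    "n_branchpoints",
    "max_branch_length",
    "total_branch_length",
    "cell_size",
    "hull_size",
    "ramification_index",
)


@dataclass
class SkeletonGraph:
    """Voxel-level skeleton graph of one cell.

    Nodes are voxel index tuples; each node stores its physical position in
    um (``pos_um``).  Edges connect neighbouring skeleton voxels (full
    8/26-connectivity) and carry the Euclidean distance between voxel
    centers in um (``length``), so lengths are correct for anisotropic
    voxels.
    """

    graph: nx.Graph
    voxel_size: tuple[float, ...]

    @property
    def endpoints(self) -> list[tuple[int, ...]]:
        """Degree-1 nodes."""
        return [n for n, d in self.graph.degree() if d == 1]

    def to_edge_list(self):
        """SWC-like export: node table (um coordinates) + edge table.

        Returns ``(nodes, edges)`` DataFrames; node ids are stable integers,
        edges carry their physical length in um.
        """
        import pandas as pd

        ids = {n: i for i, n in enumerate(sorted(self.graph.nodes))}
        nodes = pd.DataFrame(
            [
                {"node_id": ids[n], **{f"{ax}_um": c for ax, c in
                                        zip("zyx"[-len(n):], self.graph.nodes[n]["pos_um"])},
                 "degree": self.graph.degree(n)}
                for n in sorted(self.graph.nodes)
            ]
        )
        edges = pd.DataFrame(
            [
                {"node_a": ids[u], "node_b": ids[v], "length_um": d["length"]}
                for u, v, d in self.graph.edges(data=True)
            ]
        )
        return nodes, edges

    @property
    def branchpoint_clusters(self) -> list[set]:
        """Connected clusters of degree->=3 voxels, each one branch point.

        Thinning can produce several mutually adjacent junction voxels at a
        single anatomical branch point; counting clusters instead of voxels
        avoids inflating the branch-point count.
        """
        junction = [n for n, d in self.graph.degree() if d >= 3]
        if not junction:
            return []
        sub = self.graph.subgraph(junction)
        return [set(c) for c in nx.connected_components(sub)]


@dataclass
class BranchStats:
    n_endpoints: int
    n_branchpoints: int
    branch_lengths: list[float] = field(default_factory=list)

    @property
    def max_branch_length(self) -> float:
        return max(self.branch_lengths) if self.branch_lengths else 0.0

    @property
    def total_branch_length(self) -> float:
        return float(sum(self.branch_lengths))


@dataclass
class MorphFeatures:
    """The 8-feature morphology vector of one cell.

    Sizes are um^2 in 2D mode and um^3 in 3D mode; lengths are um.  The
    ramification index is ``cell_size / hull_size`` (dimensionless, in
    (0, 1]); lower values indicate more ramified cells.
    """

    soma_size: float
    n_endpoints: int
    n_branchpoints: int
    max_branch_length: float
    total_branch_length: float
    cell_size: float
    hull_size: float
    ramification_index: float

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    offs = [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]
    # keep one of each +-pair; edges are undirected
    return [o for o in offs if o > tuple(-x for x in o)]


def _build_graph(skel: np.ndarray, voxel_size: tuple[float, ...]) -> nx.Graph:
    coords = np.argwhere(skel)
    voxels = set(map(tuple, coords))
    vs = np.asarray(voxel_size, dtype=float)
    g = nx.Graph()
    for c in voxels:
        g.add_node(c, pos_um=tuple(np.asarray(c) * vs))
    for off in _neighbor_offsets(skel.ndim):
        step = float(np.sqrt(np.sum((np.asarray(off) * vs) ** 2)))
        for c in voxels:
            nb = tuple(np.asarray(c) + np.asarray(off))
            if nb in voxels:
                g.add_edge(c, nb, length=step)
    return g


def _prune_spurs(g: nx.Graph, prune_um: float) -> nx.Graph:
    """Iteratively remove terminal chains shorter than ``prune_um``.

    Only spurs attached to a junction are removed; a free-standing path
    (the whole skeleton) is never deleted.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for tip in [n for n, d in g.degree() if d == 1]:
            if tip not in g:
                continue
            chain = [tip]
            length = 0.0
            node = tip
            prev = None
            while True:
                nbrs = [x for x in g.neighbors(node) if x != prev]
                if g.degree(node) >= 3 or not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[node, nxt]["length"]
                prev, node = node, nxt
                if g.degree(node) != 2:
                    break
                chain.append(node)
            # node is the anchor (junction or opposite endpoint)
            if g.degree(node) >= 3 and length < prune_um:
                g.remove_nodes_from(chain)
                changed = True
    return g


def skeletonize_cell(
    mask: np.ndarray,
    voxel_size: tuple[float, ...],
    prune_um: float = 1.0,
) -> SkeletonGraph:
    """Thin a cell mask to its skeleton graph.

    Parameters
    ----------
    mask : bool array (2D or 3D)
        Cell mask; must be a single connected component.
    voxel_size : tuple of float
        Physical voxel size in um per axis, same order as the mask axes.
    prune_um : float
        Terminal spurs attached to a junction and shorter than this length
        (um) are removed; they are thinning artifacts, not processes.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != len(voxel_size):
        raise ValueError("voxel_size must have one entry per mask axis")
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    structure = generate_binary_structure(mask.ndim, mask.ndim)
    _, n_comp = ndi_label(mask, structure=structure)
    if n_comp > 1:
        raise ValueError(f"cell mask has {n_comp} connected components; expected 1")
    skel = skeletonize(mask)
    if not skel.any():  # tiny masks can thin away entirely; keep the centroid voxel
        c = tuple(np.round(np.mean(np.argwhere(mask), axis=0)).astype(int))
        skel = np.zeros_like(mask)
        skel[c] = True
    g = _build_graph(skel, tuple(voxel_size))
    if prune_um > 0:
        g = _prune_spurs(g, prune_um)
    return SkeletonGraph(graph=g, voxel_size=tuple(voxel_size))


def _marker_ids(g: nx.Graph, roots: set) -> dict:
    """Map each node to a marker id; degree-2 non-root nodes get None.

    Junction voxels that touch each other share one marker id (cluster),
    so a thinning-induced junction clique counts as a single branch point.
    """
    markers = {}
    junction = [n for n, d in g.degree() if d >= 3]
    sub = g.subgraph(junction)
    next_id = 0
    for comp in nx.connected_components(sub):
        for n in comp:
            markers[n] = next_id
        next_id += 1
    for n, d in g.degree():
        if n in markers:
            continue
        if d != 2 or n in roots:
            markers[n] = next_id
            next_id += 1
    return markers


def branch_stats(sk: SkeletonGraph, roots: set | None = None) -> BranchStats:
    """Branch statistics of a skeleton graph.

    Branches are maximal paths between nodes of degree != 2 (with adjacent
    junction voxels merged into one branch point).  ``roots`` marks nodes
    that terminate branches but are *not* endpoints -- used when branches
    emanate from a soma whose internal skeleton has been removed.
    """
    g = sk.graph
    roots = roots or set()
    n_endpoints = sum(1 for n, d in g.degree() if d == 1 and n not in roots)
    clusters = sk.branchpoint_clusters
    n_branchpoints = len(clusters)
    if g.number_of_edges() == 0:
        return BranchStats(n_endpoints, n_branchpoints, [])

    markers = _marker_ids(g, roots)
    lengths: list[float] = []
    seen_edges = set()
    for start in markers:
        for nb in g.neighbors(start):
            ekey = frozenset((start, nb))
            if ekey in seen_edges:
                continue
            # intra-cluster junction edges are part of the branch point, not a branch
            if nb in markers and markers[nb] == markers[start]:
                seen_edges.add(ekey)
                continue
            length = g.edges[start, nb]["length"]
            seen_edges.add(ekey)
            prev, node = start, nb
            while node not in markers:
                nbrs = [x for x in g.neighbors(node) if x != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[node, nxt]["length"]
                seen_edges.add(frozenset((node, nxt)))
                prev, node = node, nxt
            lengths.append(length)
    # pure cycles (every node degree 2) have no markers; count each as one branch
    if not markers and g.number_of_edges() > 0:
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            lengths.append(sum(d["length"] for _, _, d in sub.edges(data=True)))
    return BranchStats(n_endpoints, n_branchpoints, lengths)


def hull_and_ramification(
    mask: np.ndarray, voxel_size: tuple[float, ...]
) -> tuple[float, float, float]:
    """Cell size, convex-hull size, and ramification index.

    Returns ``(cell, hull, cell / hull)`` in um^2 (2D) or um^3 (3D).  The
    hull is taken over the corner points of every voxel, so the hull always
    contains the cell and the index lies in (0, 1].
    """
    mask = np.asarray(mask, dtype=bool)
    vs = np.asarray(voxel_size, dtype=float)
    coords = np.argwhere(mask).astype(float) * vs
    if coords.shape[0] == 0:
        raise ValueError("empty mask has no hull")
    corners = []
    for off in itertools.product((-0.5, 0.5), repeat=mask.ndim):
        corners.append(coords + np.asarray(off) * vs)
    points = np.concatenate(corners, axis=0)
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError(f"degenerate cell geometry: {exc}") from exc
    hull_size = float(hull.volume)  # area in 2D, volume in 3D
    cell_size = float(mask.sum() * np.prod(vs))
    return cell_size, hull_size, cell_size / hull_size


def compute_features(
    cell,
    voxel_size: tuple[float, ...],
    prune_um: float = 1.0,
) -> MorphFeatures:
    """Assemble the 8-feature morphology vector for one segmented cell.

    Skeleton voxels inside the soma are excluded before counting endpoints
    and measuring branches: the soma core of a thinning skeleton is not a
    process, and a soma-only cell must score zero endpoints and zero branch
    length.  Nodes where a branch leaves the soma become branch roots, which
    terminate branches without counting as endpoints.
    """
    mask = np.asarray(cell.mask, dtype=bool)
    soma = np.asarray(cell.soma_mask, dtype=bool)
    if not (soma & mask).sum() == soma.sum():
        raise InconsistencyError(f"cell {cell.cell_id}: soma mask not inside cell mask")

    sk = skeletonize_cell(mask, voxel_size, prune_um=prune_um)
    g = sk.graph
    inside = {n for n in g.nodes if soma[n]}
    outside_g = g.subgraph([n for n in g.nodes if n not in inside]).copy()
    roots = {
        n for n in outside_g.nodes if any(nb in inside for nb in g.neighbors(n))
    }
    arbor = SkeletonGraph(graph=outside_g, voxel_size=sk.voxel_size)
    stats = branch_stats(arbor, roots=roots)

    cell_size, hull_size, ri = hull_and_ramification(mask, voxel_size)
    return MorphFeatures(
        soma_size=float(cell.soma_size),
        n_endpoints=stats.n_endpoints,
        n_branchpoints=stats.n_branchpoints,
        max_branch_length=stats.max_branch_length,
        total_branch_length=stats.total_branch_length,
        cell_size=cell_size,
        hull_size=hull_size,
        ramification_index=ri,
    )
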