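"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive algorithms (exhaustive search, BFS flood
fill, path enumeration) so they share no code path with the package.
"""

import numpy as np
import networkx as nx


def otsu3_bruteforce(values, bins=256):
    """Exhaustive search over all histogram bin pairs for three-class Otsu.

    Returns (low_edge, high_edge) maximizing between-class variance, with
    the first (lexicographically smallest) pair kept on ties.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    total_w = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = float((counts * centers).sum() / total_w)

    def between_class_var(i, j):
        var = 0.0
        for sel in (slice(0, i + 1), slice(i + 1, j + 1), slice(j + 1, bins)):
            w = counts[sel].sum()
            if w > 0:
                m = (counts[sel] * centers[sel]).sum() / w
                var += w * (m - mu) ** 2
        return var

    best = -np.inf
    for i in range(bins - 2):
        for j in range(i + 1, bins - 1):
            best = max(best, between_class_var(i, j))
    # ties (within float noise) resolve to the smallest (i, j)
    for i in range(bins - 2):
        for j in range(i + 1, bins - 1):
            if between_class_var(i, j) >= best - abs(best) * 1e-12:
                return float(edges[i + 1]), float(edges[j + 1])


def hysteresis_floodfill(vesselness, low, high):
    """BFS flood fill from strong seeds through the weak region.

    Full (8/26) connectivity, matching the package default.
    """
    v = np.asarray(vesselness)
    weak = v > low
    strong = v >= high
    out = np.zeros_like(weak)
    offsets = [
        tuple(o - 1 for o in off)
        for off in np.ndindex(*([3] * v.ndim))
        if any(o - 1 for o in off)
    ]
    stack = [tuple(idx) for idx in np.argwhere(strong & weak)]
    for s in stack:
        out[s] = True
    while stack:
        cur = stack.pop()
        for off in offsets:
            nb = tuple(c + o for c, o in zip(cur, off))
            if any(n < 0 or n >= s for n, s in zip(nb, v.shape)):
                continue
            if weak[nb] and not out[nb]:
                out[nb] = True
                stack.append(nb)
    return out


def branch_lengths_by_path_enumeration(graph):
    """All branch lengths of a tree-shaped skeleton graph.

    A branch is a simple path between two nodes of degree != 2 whose
    interior nodes all have degree 2.  Assumes no two junction nodes are
    adjacent (the generator inserts spacers).
    """
    markers = [n for n, d in graph.degree() if d != 2]
    lengths = []
    for i, a in enumerate(markers):
        for b in markers[i:]:
            if a == b:
                # self-loop branches do not occur in trees
                continue
            for path in nx.all_simple_paths(graph, a, b):
                if all(graph.degree(n) == 2 for n in path[1:-1]):
                    lengths.append(
                        sum(
                            graph.edges[u, w]["length"]
                            for u, w in zip(path[:-1], path[1:])
                        )
                    )
    return sorted(lengths)


def random_skeleton_tree(rng, n_branches=6, max_chain=5):
    """A random tree with degree-2 chains and positive edge lengths.

    Junction nodes are always separated by at least one degree-2 node, so
    the branch semantics of path enumeration and chain walking coincide.
    """
    g = nx.Graph()
    g.add_node(0)
    next_node = 1
    attach_points = [0]
    for _ in range(n_branches):
        a = attach_points[rng.integers(len(attach_points))]
        # chains of >= 2 keep junction nodes non-adjacent (spacer guarantee)
        chain = int(rng.integers(2, max_chain + 1))
        prev = a
        for _ in range(chain):
            g.add_edge(prev, next_node, length=float(rng.uniform(0.5, 3.0)))
            prev = next_node
            next_node += 1
        attach_points.append(prev)
    return g


def welch_p_closed_form(x, y):
    """Two-tailed Welch p from the textbook formulas (no scipy.stats.ttest)."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx_, ny = x.size, y.size
    se2 = vx / nx_ + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df), float(2 * tdist.sf(abs(t), df))
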