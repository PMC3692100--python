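"""Phylogeny container, ML two-state distances and neighbor joining.

When the user supplies no tree, one is estimated from the phyletic pattern
itself: pairwise distances between genomes are obtained by maximum likelihood
under a reversible two-state (presence/absence) model whose stationary
frequencies are estimated by counting, and the distance matrix is fed to the
Saitou–Nei neighbor-joining algorithm.  The unrooted NJ tree is rooted at the
midpoint of its longest leaf-to-leaf path; under the reversible model the
likelihood is root-invariant, so rooting only fixes the coordinate system in
which per-branch events are later reported.

Branch lengths are in expected events per character: the two-state rate
matrix used for distances is scaled so that one unit of branch length equals
one expected gain-or-loss event per character at stationarity.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "two_state_frequencies",
    "ml_pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
]

DEFAULT_DISTANCE_CAP = 10.0


class TreeError(ValueError):
    """Raised for malformed trees or distance matrices."""


class Phylogeny:
    """Rooted tree with branch lengths, stored as flat parent/length arrays.

    Nodes are integers ``0..n_nodes-1``.  Leaves carry labels; internal nodes
    are auto-named ``N<k>`` in preorder so that branch identifiers are stable
    across runs.  A branch is identified with its child node.
    """

    def __init__(self, parent, lengths, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        n = self.parent.size
        if self.lengths.size != n or len(labels) != n:
            raise TreeError("parent, lengths and labels must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.lengths = self.lengths.copy()
        self.lengths[self.root] = 0.0
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise TreeError("branch lengths must be finite and >= 0")

        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                self.children[p].append(i)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        if not self.is_leaf.any():
            raise TreeError("tree has no leaves")

        # preorder / postorder via explicit stack
        pre: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            pre.append(v)
            stack.extend(reversed(self.children[v]))
        if len(pre) != n:
            raise TreeError("tree is not connected or contains a cycle")
        self.preorder = np.array(pre, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()

        self.labels = list(labels)
        self.leaves = [int(i) for i in self.preorder if self.is_leaf[i]]
        leaf_labels = [self.labels[i] for i in self.leaves]
        if any(not lb for lb in leaf_labels):
            raise TreeError("every leaf must carry a non-empty label")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise TreeError("leaf labels must be unique")
        self.leaf_labels = leaf_labels

        # stable node names: leaf label, or N<k> in preorder for internal nodes
        self.node_names = [""] * n
        k = 0
        for v in self.preorder:
            if self.is_leaf[v]:
                self.node_names[v] = self.labels[v]
            else:
                self.node_names[v] = f"N{k}"
                k += 1
        # branches = non-root nodes in preorder (fixed reporting order)
        self.branch_nodes = np.array([v for v in self.preorder if v != self.root],
                                     dtype=np.int64)
        self.branch_names = [self.node_names[v] for v in self.branch_nodes]

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
        except Exception as exc:
            raise TreeError(f"could not parse newick (leaf labels unique?): {exc}")
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.is_leaf():
                labels[i] = nd.label
        return cls(parent, lengths, labels)

    @classmethod
    def read_newick(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        buf = io.StringIO()

        def visit(v: int) -> None:
            if self.is_leaf[v]:
                buf.write(self.labels[v])
            else:
                buf.write("(")
                for j, c in enumerate(self.children[v]):
                    if j:
                        buf.write(",")
                    visit(c)
                buf.write(")")
            if v != self.root:
                buf.write(f":{self.lengths[v]:.10g}")

        visit(self.root)
        buf.write(";")
        return buf.getvalue()

    def write_newick(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- utilities
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def total_length(self) -> float:
        return float(self.lengths[self.branch_nodes].sum())

    def scaled(self, factor: float) -> "Phylogeny":
        """Copy with every branch length multiplied by ``factor``."""
        if factor <= 0 or not np.isfinite(factor):
            raise TreeError("scale factor must be positive and finite")
        return Phylogeny(self.parent, self.lengths * factor, self.labels)

    def relabeled(self, mapping) -> "Phylogeny":
        labels = [mapping.get(lb, lb) if lb else lb for lb in self.labels]
        return Phylogeny(self.parent, self.lengths, labels)

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    def leaf_distance_matrix(self) -> "DistanceMatrix":
        """Pairwise path lengths between leaves (patristic distances)."""
        depth = self.depths()
        anc: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for v in self.preorder:
            if v == self.root:
                anc[v] = {v}
            else:
                anc[v] = anc[self.parent[v]] | {v}
        m = self.n_leaves
        d = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                u, v = self.leaves[a], self.leaves[b]
                common = anc[u] & anc[v]
                lca_depth = max(depth[w] for w in common)
                d[a, b] = d[b, a] = depth[u] + depth[v] - 2.0 * lca_depth
        return DistanceMatrix(labels=list(self.leaf_labels), d=d,
                              cap=float(max(d.max(), 1.0)))

    def bipartitions(self) -> set[frozenset]:
        """Unrooted splits as {sideA, sideB} pairs of leaf-label frozensets.

        Trivial splits (singleton vs rest) are excluded; the two edges
        incident to a bifurcating root induce the same split and are
        deduplicated, so topologies can be compared root-invariantly.
        """
        below: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for v in self.postorder:
            if self.is_leaf[v]:
                below[v] = {self.labels[v]}
            else:
                for c in self.children[v]:
                    below[v] |= below[c]
        all_leaves = frozenset(self.leaf_labels)
        out = set()
        for v in self.branch_nodes:
            side = frozenset(below[v])
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset({side, other}))
        return out


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with a saturation cap."""

    labels: list
    d: np.ndarray
    cap: float = DEFAULT_DISTANCE_CAP

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise TreeError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise TreeError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise TreeError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > self.cap + 1e-9):
            raise TreeError("distances must lie in [0, cap]")


def two_state_frequencies(pattern, allow_degenerate: bool = False):
    """Stationary (pi0, pi1) estimated by counting matrix cells.

    An all-constant matrix gives pi1 in {0, 1}, under which the two-state
    model degenerates; this raises unless ``allow_degenerate`` requests the
    uninformative (0.5, 0.5) fallback.
    """
    m = np.asarray(pattern.matrix)
    if m.size == 0:
        raise TreeError("empty pattern")
    pi1 = float(m.mean())
    if pi1 in (0.0, 1.0):
        if allow_degenerate:
            return (0.5, 0.5)
        raise TreeError("degenerate frequencies: matrix is all-0 or all-1")
    return (1.0 - pi1, pi1)


def _pair_log_likelihood(t, counts, pi0, pi1):
    """Log-likelihood of one sequence pair at separation t.

    Under reversibility the joint probability of tip states (a, b) is
    pi_a * P_ab(t), with the chain scaled to one expected event per unit t
    at stationarity (rate s = 1 / (2 pi0 pi1))."""
    n00, n01, n10, n11 = counts
    s = 1.0 / (2.0 * pi0 * pi1)
    e = np.exp(-s * t)
    p00 = pi0 + pi1 * e
    p01 = pi1 * (1.0 - e)
    p10 = pi0 * (1.0 - e)
    p11 = pi1 + pi0 * e
    tiny = 1e-300
    return (n00 * np.log(max(pi0 * p00, tiny))
            + n01 * np.log(max(pi0 * p01, tiny))
            + n10 * np.log(max(pi1 * p10, tiny))
            + n11 * np.log(max(pi1 * p11, tiny)))


def ml_pairwise_distance(x, y, freqs, cap: float = DEFAULT_DISTANCE_CAP,
                         tol: float = 1e-6) -> float:
    """ML distance (expected events per character) between two 0/1 rows.

    Maximizes the two-sequence likelihood over the separation time t in
    [0, cap] by bounded scalar optimization; t is split evenly over the two
    pendant branches, which the reversible chain makes immaterial.
    """
    x = np.asarray(x, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if x.size == 0 or x.size != y.size:
        raise TreeError("sequences must be non-empty and of equal length")
    pi0, pi1 = freqs
    counts = np.bincount(2 * x + y, minlength=4).astype(float)
    n_diff = counts[1] + counts[2]
    if n_diff == 0:
        return 0.0
    res = minimize_scalar(lambda t: -_pair_log_likelihood(t, counts, pi0, pi1),
                          bounds=(0.0, cap), method="bounded",
                          options={"xatol": tol})
    t_hat = float(res.x)
    # interior optimum can be beaten by the saturation boundary
    if _pair_log_likelihood(cap, counts, pi0, pi1) > -res.fun:
        t_hat = cap
    if t_hat >= cap - 10 * tol:
        warnings.warn("pairwise distance saturated at cap", RuntimeWarning,
                      stacklevel=2)
        return cap
    return t_hat


def distance_matrix(pattern, freqs=None, cap: float = DEFAULT_DISTANCE_CAP) -> DistanceMatrix:
    """All-pairs ML distance matrix for the taxa of a phyletic pattern."""
    if freqs is None:
        freqs = two_state_frequencies(pattern)
    X = np.asarray(pattern.matrix, dtype=np.int8)
    n = X.shape[0]
    d = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = ml_pairwise_distance(X[i], X[j], freqs, cap=cap)
    return DistanceMatrix(labels=list(pattern.taxa), d=d, cap=cap)


# --------------------------------------------------------------------- NJ

def neighbor_joining(dm: DistanceMatrix) -> Phylogeny:
    """Saitou–Nei neighbor joining, rooted at the path midpoint.

    Ties in the Q criterion are broken by the lowest (i, j) index pair in the
    current active ordering; negative limb estimates are clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise TreeError("neighbor joining requires at least 3 taxa")

    # adjacency over growing node set; leaves are 0..n-1
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    labels: dict[int, str] = {i: str(lb) for i, lb in enumerate(dm.labels)}
    next_id = n

    active = list(range(n))
    D = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i < j}

    def dist(a, b):
        return D[(a, b)] if a < b else D[(b, a)]

    def connect(a, b, length):
        length = max(0.0, float(length))
        adj[a].append((b, length))
        adj[b].append((a, length))

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        u = next_id
        next_id += 1
        adj[u] = []
        connect(a, u, la)
        connect(b, u, lb)
        for c in active:
            if c not in (a, b):
                duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
                D[(min(u, c), max(u, c))] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    # join the final three nodes at a central vertex (three-point formulas)
    a, b, c = active
    u = next_id
    adj[u] = []
    connect(a, u, 0.5 * (dist(a, b) + dist(a, c) - dist(b, c)))
    connect(b, u, 0.5 * (dist(a, b) + dist(b, c) - dist(a, c)))
    connect(c, u, 0.5 * (dist(a, c) + dist(b, c) - dist(a, b)))

    return _root_at_midpoint(adj, labels)


def _farthest(adj, start):
    """Distances and predecessors from ``start`` on an acyclic adjacency."""
    dist = {start: 0.0}
    prev = {start: None}
    stack = [start]
    while stack:
        v = stack.pop()
        for w, ln in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + ln
                prev[w] = v
                stack.append(w)
    far = max(dist, key=lambda k: (dist[k], -k))
    return far, dist, prev


def _root_at_midpoint(adj, labels) -> Phylogeny:
    """Root an unrooted adjacency at the midpoint of its longest leaf path."""
    leaves = [v for v in adj if len(adj[v]) == 1]
    u, _, _ = _farthest(adj, leaves[0])
    v, dist, prev = _farthest(adj, u)
    total = dist[v]

    # path u .. v
    path = [v]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path.reverse()  # starts at u

    if total <= 0:
        # degenerate (all-zero) distances: root at an internal node
        root = next(w for w in adj if len(adj[w]) > 1)
    else:
        half = total / 2.0
        cum = 0.0
        root = None
        for k in range(len(path) - 1):
            a, b = path[k], path[k + 1]
            ln = next(l for w, l in adj[a] if w == b)
            if cum + ln >= half - 1e-15:
                off = half - cum
                if abs(off) < 1e-12 and len(adj[a]) > 1:
                    root = a
                elif abs(off - ln) < 1e-12 and len(adj[b]) > 1:
                    root = b
                else:
                    # split edge (a,b) at offset `off` from a
                    r = max(adj) + 1
                    adj[a] = [(w, l) for w, l in adj[a] if w != b]
                    adj[b] = [(w, l) for w, l in adj[b] if w != a]
                    adj[r] = []
                    adj[a].append((r, off))
                    adj[r].append((a, off))
                    adj[b].append((r, ln - off))
                    adj[r].append((b, ln - off))
                    root = r
                break
            cum += ln
        if root is None:  # numerical fallback
            root = path[len(path) // 2]

    # BFS from root -> parent arrays
    order = {root: 0}
    parent = {root: (-1, 0.0)}
    queue = [root]
    while queue:
        x = queue.pop(0)
        for w, ln in adj[x]:
            if w not in order:
                order[w] = len(order)
                parent[w] = (order[x], ln)
                queue.append(w)
    n = len(order)
    par = np.full(n, -1, dtype=np.int64)
    lens = np.zeros(n)
    labs: list[str | None] = [None] * n
    for node, idx in order.items():
        par[idx], lens[idx] = parent[node]
        labs[idx] = labels.get(node)
    return Phylogeny(par, lens, labs)
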