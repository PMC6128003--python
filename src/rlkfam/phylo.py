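"""p-distance, neighbor joining with bootstrap, and subclade assignment.

The classification recipe: align family members together with labeled
reference proteins, compute pairwise p-distances (proportion of differing
residues among compared positions), build an unrooted neighbor-joining
tree, attach bootstrap supports by resampling alignment columns, and label
each query by the references it co-clusters with — the smallest
edge-delimited cluster (bipartition side) containing the query and at
least one labeled reference votes by majority.

Two gap treatments are provided because the source protocol is ambiguous
between them: ``complete_deletion`` drops every column containing a gap
before any comparison; ``pairwise_deletion`` drops gapped columns per
sequence pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align import MultipleAlignment
from .types import RlkfamError, SubcladeAssignment


@dataclass
class DistanceMatrix:
    """Symmetric matrix of p-distances in [0, 1]."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise RlkfamError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise RlkfamError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise RlkfamError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 1 + 1e-12):
            raise RlkfamError("p-distances must lie in [0, 1]")


class PhyloTree:
    """An unrooted tree with branch lengths and optional edge supports.

    Stored as an adjacency map; leaves carry string labels. Internal nodes
    of a binary unrooted tree have degree 3 (the central node of the final
    three-way join is trifurcating, the usual NJ convention).
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self.supports: dict[frozenset[int], int] = {}
        self._next = 0

    # -- construction -------------------------------------------------
    def add_node(self, label: Optional[str] = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    # -- basic queries -------------------------------------------------
    @property
    def leaf_ids(self) -> list[int]:
        return sorted(n for n in self.adj if n in self.labels)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[n] for n in self.leaf_ids]

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u in sorted(self.adj):
            for v, w in sorted(self.adj[u].items()):
                if u < v:
                    out.append((u, v, w))
        return out

    def _side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the *v* side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            node = stack.pop()
            if node in self.labels:
                out.append(self.labels[node])
            for nbr in self.adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def bipartitions(self, nontrivial: bool = True) -> dict[frozenset[int], frozenset[str]]:
        """Map each edge to a canonical split (side not holding the
        alphabetically first leaf label)."""
        anchor = min(self.leaf_labels)
        out = {}
        for u, v, _ in self.edges():
            side = self._side_leaves(u, v)
            if anchor in side:
                side = frozenset(self.leaf_labels) - side
            if nontrivial and not (1 < len(side) < len(self.labels) - 1):
                continue
            out[frozenset((u, v))] = side
        return out

    def patristic(self, label_a: str, label_b: str) -> float:
        """Path length between two leaves."""
        rev = {lab: nid for nid, lab in self.labels.items()}
        src, dst = rev[label_a], rev[label_b]
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            if node == dst:
                return dist[node]
            for nbr, w in self.adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        return dist[dst]

    # -- Newick --------------------------------------------------------
    def to_newick(self, precision: int = 6) -> str:
        """Newick text; bootstrap supports become internal-node labels."""
        if not self.adj:
            raise RlkfamError("empty tree")
        internal = [n for n in sorted(self.adj) if n not in self.labels]
        root = max(internal) if internal else min(self.adj)

        def fmt(node: int, parent: Optional[int]) -> str:
            children = [n for n in sorted(self.adj[node]) if n != parent]
            if not children:
                name = self.labels.get(node, "")
                return name
            inner = ",".join(
                f"{fmt(c, node)}:{self.adj[node][c]:.{precision}g}" for c in children
            )
            label = ""
            if parent is not None:
                sup = self.supports.get(frozenset((node, parent)))
                if sup is not None:
                    label = str(sup)
            return f"({inner}){label}"

        return fmt(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        tree = cls()
        node_map: dict = {}

        for node in dtree.preorder_node_iter():
            label = node.taxon.label.replace(" ", "_") if node.taxon else None
            nid = tree.add_node(label)
            node_map[node] = nid
            if node.parent_node is not None:
                pid = node_map[node.parent_node]
                length = node.edge.length if node.edge.length is not None else 0.0
                tree.add_edge(pid, nid, float(length))
                if node.label is not None and str(node.label).isdigit():
                    tree.supports[frozenset((pid, nid))] = int(node.label)
        # suppress a degree-2 artificial root so the tree is unrooted
        for nid in list(tree.adj):
            if nid not in tree.labels and len(tree.adj[nid]) == 2:
                (a, wa), (b, wb) = tree.adj[nid].items()
                del tree.adj[a][nid]
                del tree.adj[b][nid]
                del tree.adj[nid]
                tree.add_edge(a, b, wa + wb)
        return tree


# ---------------------------------------------------------------------------
# p-distance

GAP = "-"


def p_distance(aln: MultipleAlignment, gap_mode: str = "complete_deletion") -> DistanceMatrix:
    """Pairwise proportion of mismatches over retained columns.

    ``complete_deletion`` removes every column with a gap in any row
    first; ``pairwise_deletion`` removes, per pair, only columns gapped in
    either member of the pair. A pair left with zero comparable columns is
    an error.
    """
    if len(aln) < 2:
        raise RlkfamError("p_distance needs >= 2 rows")
    if gap_mode not in {"complete_deletion", "pairwise_deletion"}:
        raise RlkfamError(f"unknown gap_mode {gap_mode!r}")
    arr = aln.to_array()
    n = len(aln)
    if gap_mode == "complete_deletion":
        keep = ~(arr == GAP).any(axis=0)
        if not keep.any():
            raise RlkfamError("no usable columns after complete deletion")
        arr = arr[:, keep]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    else:
        d = np.zeros((n, n))
        gaps = arr == GAP
        for i in range(n):
            for j in range(i + 1, n):
                keep = ~(gaps[i] | gaps[j])
                if not keep.any():
                    raise RlkfamError(
                        f"no comparable columns between {aln.ids[i]} and {aln.ids[j]}"
                    )
                d[i, j] = d[j, i] = np.mean(arr[i, keep] != arr[j, keep])
    return DistanceMatrix(ids=list(aln.ids), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic neighbor joining (Saitou & Nei).

    Q(i,j) = (n-2) d(i,j) - R_i - R_j with R the row sums; the arg-min
    pair is joined (ties -> lexicographically smallest index pair, so runs
    are deterministic), branch lengths follow the standard two-point
    formula, and negative lengths are clamped to zero with the deficit
    moved to the sister edge so the pair distance is preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise RlkfamError("neighbor_joining needs >= 3 taxa")

    tree = PhyloTree()
    active: list[int] = [tree.add_node(label) for label in dm.ids]
    d = dm.d.astype(float).copy()

    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum = smallest (i, j)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        new = tree.add_node()
        tree.add_edge(active[i], new, bi)
        tree.add_edge(active[j], new, bj)

        du = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d = d_new
        active = [active[k] for k in keep] + [new]

    # final three-way join: closed-form pendant lengths
    (a, b, c) = active
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    center = tree.add_node()
    for node, length in (
        (a, (dab + dac - dbc) / 2),
        (b, (dab + dbc - dac) / 2),
        (c, (dac + dbc - dab) / 2),
    ):
        tree.add_edge(node, center, max(length, 0.0))
    return tree


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "complete_deletion",
) -> PhyloTree:
    """NJ tree of the full alignment with column-resampling supports.

    Columns are drawn uniformly with replacement per replicate from a
    seeded 64-bit generator; an internal edge's support is the integer
    percentage of replicate trees containing the same leaf bipartition.
    Replicates whose resampled columns leave no usable position are
    discarded and the percentage is taken over the valid replicates.
    """
    tree = neighbor_joining(p_distance(aln, gap_mode))
    splits = tree.bipartitions()
    counts = {edge: 0 for edge in splits}
    target = set(splits.values())

    rng = np.random.default_rng(seed)
    ncol = aln.ncol
    valid = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row[c] for c in cols) for row in aln.rows]
        rep_aln = MultipleAlignment(ids=list(aln.ids), rows=rep_rows)
        try:
            rep_tree = neighbor_joining(p_distance(rep_aln, gap_mode))
        except RlkfamError:
            continue
        valid += 1
        rep_splits = set(rep_tree.bipartitions().values())
        for edge, split in splits.items():
            if split in rep_splits:
                counts[edge] += 1
    denom = max(valid, 1)
    tree.supports = {
        edge: int(np.floor(100.0 * c / denom + 0.5)) for edge, c in counts.items()
    }
    return tree


# ---------------------------------------------------------------------------
# Subclade assignment

def assign_subclades(
    tree: PhyloTree, reference_labels: dict[str, str]
) -> list[SubcladeAssignment]:
    """Label query leaves by the references they co-cluster with.

    For each query (a leaf absent from *reference_labels*), bipartition
    sides containing the query are scanned from smallest to largest; the
    first side holding at least one labeled reference decides the label by
    majority vote (support = winning votes / labeled references in the
    side; vote ties resolved in favour of the reference nearest by
    patristic distance). References mapped to an empty label act as
    unlabeled anchors. A query that reaches the whole tree without meeting
    a labeled reference is "unassigned".
    """
    labeled_refs = {k: v for k, v in reference_labels.items() if v}
    leaves = set(tree.leaf_labels)
    queries = sorted(leaves - set(reference_labels))

    # all proper sides of every edge (including pendant-edge complements)
    sides: list[frozenset[str]] = []
    for u, v, _ in tree.edges():
        s = tree._side_leaves(u, v)
        for side in (s, frozenset(leaves) - s):
            if 0 < len(side) < len(leaves):
                sides.append(side)

    out: list[SubcladeAssignment] = []
    for q in queries:
        nearest_ref, nearest_d = None, float("inf")
        for ref in reference_labels:
            if ref in leaves:
                dist = tree.patristic(q, ref)
                if dist < nearest_d:
                    nearest_ref, nearest_d = ref, dist
        label, support = "unassigned", 0.0
        candidates = sorted(
            (s for s in sides if q in s and any(r in labeled_refs for r in s)),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        if candidates:
            cluster = candidates[0]
            votes: dict[str, int] = {}
            for ref in cluster & set(labeled_refs):
                votes[labeled_refs[ref]] = votes.get(labeled_refs[ref], 0) + 1
            best = max(votes.values())
            tied = sorted(lab for lab, v in votes.items() if v == best)
            if len(tied) == 1:
                label = tied[0]
            else:
                # tie: side with the patristically nearest reference
                best_d = float("inf")
                for ref in sorted(cluster & set(labeled_refs)):
                    if labeled_refs[ref] in tied:
                        dist = tree.patristic(q, ref)
                        if dist < best_d:
                            best_d, label = dist, labeled_refs[ref]
            support = best / sum(votes.values())
        out.append(
            SubcladeAssignment(
                query_id=q,
                label=label,
                support=support,
                nearest_reference=nearest_ref,
                nearest_distance=nearest_d if nearest_ref else float("nan"),
            )
        )
    return out
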