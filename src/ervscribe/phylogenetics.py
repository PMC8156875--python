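"""Distance-based phylogenetics: p/K2P distances, NJ, bootstrap, monophyly.

Distances are computed on a fixed multiple alignment with the pairwise
deletion policy (per pair, any site gapped or ambiguous in either sequence
is excluded).  Trees are built with canonical neighbor-joining (Q-matrix
selection, standard branch-length formulas, negative branch lengths clamped
to zero).  Tie-breaking is deterministic: among equal Q values the pair
whose canonical labels sort first lexicographically is joined, where an
internal node is labelled by the smallest leaf name in its subtree.

Bootstrap support of an internal edge is the percentage of column-resampled
replicate trees containing the same bipartition.  A bipartition is stored
canonically as the frozenset of leaf names on the side *not* containing the
lexicographically smallest taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

_VALID = frozenset(b"ACGT")
_PURINES = frozenset(b"AG")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined entries as NaN."""

    labels: list[str]
    matrix: np.ndarray
    method: str  # "p_distance" | "k2p"
    deletion_policy: str = "pairwise"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        self.matrix = m

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                if np.isnan(self.matrix[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


def _encode(msa: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(msa)
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    arr = np.frombuffer(
        "".join(msa[l].upper() for l in labels).encode("ascii"), dtype=np.uint8
    ).reshape(len(labels), -1)
    return labels, arr


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    mask = np.zeros(arr.shape, dtype=bool)
    for b in _VALID:
        mask |= arr == b
    return mask


def p_distance_matrix(msa: Mapping[str, str]) -> DistanceMatrix:
    """Proportion of differing sites among pairwise-comparable sites."""
    labels, arr = _encode(msa)
    valid = _valid_mask(arr)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            diff = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = diff / total
    return DistanceMatrix(labels, d, "p_distance")


def k2p_distance_matrix(msa: Mapping[str, str]) -> DistanceMatrix:
    """Kimura 2-parameter distance; saturated pairs are NaN-flagged.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P, Q the transition
    and transversion proportions over comparable sites.
    """
    labels, arr = _encode(msa)
    valid = _valid_mask(arr)
    purine = (arr == ord("A")) | (arr == ord("G"))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            diff = (arr[i] != arr[j]) & both
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int((diff & (purine[i] != purine[j])).sum())
            P, Q = ts / total, tv / total
            a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if a1 <= 0 or a2 <= 0:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    return DistanceMatrix(labels, d, "k2p")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Unrooted tree: adjacency with branch lengths plus leaf labels."""

    adjacency: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf labels on the v-side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            node = stack.pop()
            if node in self.leaf_labels:
                out.add(self.leaf_labels[node])
            for nb in self.adjacency[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return out

    def canonical_split(self, side: set[str]) -> frozenset:
        """Canonical form: the side not containing the first-sorted taxon."""
        ref = min(self.leaves)
        return frozenset(self.leaves) - frozenset(side) if ref in side else frozenset(side)

    def bipartitions(self) -> dict[frozenset, tuple[int, int]]:
        """Non-trivial splits (canonical frozenset -> defining edge)."""
        n = len(self.leaf_labels)
        out: dict[frozenset, tuple[int, int]] = {}
        seen_edges = set()
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if (v, u) in seen_edges:
                    continue
                seen_edges.add((u, v))
                side = self._side_leaves(u, v)
                if 2 <= len(side) <= n - 2:
                    out[self.canonical_split(side)] = (u, v)
        return out

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        start = next(k for k, lab in self.leaf_labels.items() if lab == a)
        goal = next(k for k, lab in self.leaf_labels.items() if lab == b)
        stack = [(start, 0.0)]
        seen = {start}
        while stack:
            node, dist = stack.pop()
            if node == goal:
                return dist
            for nb, w in self.adjacency[node].items():
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, dist + w))
        raise KeyError(f"no path between {a} and {b}")

    def newick(self, with_supports: bool = True) -> str:
        """Newick string; bootstrap supports as internal node labels."""
        root = max(
            self.adjacency, key=lambda nd: (len(self.adjacency[nd]), -nd)
        )

        def render(node: int, parent: int | None) -> str:
            children = [nb for nb in self.adjacency[node] if nb != parent]
            if not children:
                return self.leaf_labels[node]
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.6f}" for c in sorted(
                    children, key=lambda c: min(self._subtree_labels(c, node))
                )
            )
            label = ""
            if with_supports and parent is not None:
                side = self._side_leaves(parent, node)
                sup = self.supports.get(self.canonical_split(side))
                if sup is not None:
                    label = f"{sup:.0f}"
            return f"({inner}){label}"

        return render(root, None) + ";"

    def _subtree_labels(self, node: int, parent: int) -> set[str]:
        return self._side_leaves(parent, node)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical NJ with deterministic lexicographic tie-breaking.

    Exactly recovers topology and branch lengths from an additive matrix.
    Negative branch lengths are clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if np.isnan(dm.matrix).any():
        raise ValueError(f"undefined distances: {dm.undefined_pairs}")

    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dm.matrix
    active = list(range(n))
    canon = {i: dm.labels[i] for i in range(n)}
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    next_id = n

    def connect(u: int, v: int, w: float) -> None:
        w = max(0.0, w)
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = (q, *sorted((canon[i], canon[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        vj = D[i, j] - vi
        u = next_id
        next_id += 1
        connect(u, i, vi)
        connect(u, j, vj)
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        canon[u] = min(canon[i], canon[j])
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = sorted(active, key=lambda x: canon[x])
    u = next_id
    connect(u, i, 0.5 * (D[i, j] + D[i, k] - D[j, k]))
    connect(u, j, 0.5 * (D[i, j] + D[j, k] - D[i, k]))
    connect(u, k, 0.5 * (D[i, k] + D[j, k] - D[i, j]))
    leaf_labels = {idx: dm.labels[idx] for idx in range(n)}
    return PhyloTree(adjacency=adjacency, leaf_labels=leaf_labels)


_METHODS = {"p_distance": p_distance_matrix, "p": p_distance_matrix,
            "k2p": k2p_distance_matrix}


def build_nj_tree(msa: Mapping[str, str], method: str = "p_distance") -> PhyloTree:
    """Distance matrix plus NJ in one call."""
    return neighbor_joining(_METHODS[method](msa))


def bootstrap_support(
    msa: Mapping[str, str],
    replicates: int = 1000,
    seed: int = 0,
    method: str = "p_distance",
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``replicates`` times; the support
    of each internal edge of the point tree is the percentage of replicate
    trees containing the same bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    tree = build_nj_tree(msa, method)
    splits = list(tree.bipartitions())
    counts = {s: 0 for s in splits}
    labels = sorted(msa)
    length = len(next(iter(msa.values())))
    rows = {l: np.frombuffer(msa[l].upper().encode("ascii"), dtype=np.uint8) for l in labels}
    for _ in range(replicates):
        idx = rng.integers(0, length, size=length)
        rep_msa = {l: rows[l][idx].tobytes().decode("ascii") for l in labels}
        try:
            rep_tree = build_nj_tree(rep_msa, method)
        except ValueError:
            continue  # undefined distances in a sparse replicate
        rep_splits = set(rep_tree.bipartitions())
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    tree.supports = {s: 100.0 * c / replicates for s, c in counts.items()}
    return tree


def is_monophyletic(tree: PhyloTree, taxa_subset) -> tuple[bool, float | None]:
    """Whether an edge separates exactly ``taxa_subset`` from the rest.

    Returns the verdict and, when the tree carries bootstrap supports, the
    supporting edge's value (None when non-monophyletic or unsupported).
    """
    subset = set(taxa_subset)
    leaves = set(tree.leaves)
    unknown = subset - leaves
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    if not 2 <= len(subset) < len(leaves):
        raise ValueError("subset must be non-trivial (2 <= |subset| < n)")
    split = tree.canonical_split(subset)
    if split in tree.bipartitions():
        return True, tree.supports.get(split)
    return False, None


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(dm.labels) + "\n")
        for i, lab in enumerate(dm.labels):
            row = "\t".join(
                "NA" if np.isnan(x) else f"{x:.6f}" for x in dm.matrix[i]
            )
            fh.write(f"{lab}\t{row}\n")
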