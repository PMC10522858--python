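"""Homology analysis of top clonotypes: pairwise global-alignment identity
distances, neighbor-joining trees, and single-linkage threshold clusters.

Scoring is deliberately simple and explicit (match +1, mismatch 0, linear
gap -1); identity is matches / alignment length over the optimal alignment,
with ties broken toward more matches so the identity is unique.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

MATCH = 1
MISMATCH = 0
GAP = -1

# matches never exceed 64 for CDR3-scale strings, so packing
# (score, matches) as score*_PACK + matches keeps the order lexicographic.
_PACK = 64


def nw_identity(a: str, b: str, match: int = MATCH, mismatch: int = MISMATCH,
                gap: int = GAP) -> float:
    """Global-alignment identity between two sequences.

    Needleman-Wunsch maximizing (score, matches) lexicographically; identity
    is matches / alignment length. Among alignments optimal under that order
    the gap count -- hence the alignment length -- is fixed, so the value is
    deterministic without a traceback.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        raise ValueError("sequences must be non-empty")
    if max(la, lb) >= _PACK:
        raise ValueError("sequences too long for the packed DP")
    prev = [j * gap * _PACK for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [i * gap * _PACK] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1]:
                diag = prev[j - 1] + match * _PACK + 1
            else:
                diag = prev[j - 1] + mismatch * _PACK
            up = prev[j] + gap * _PACK
            left = cur[j - 1] + gap * _PACK
            cur[j] = diag if diag >= up else up
            if left > cur[j]:
                cur[j] = left
        prev = cur
    packed = prev[lb]
    matches = packed % _PACK
    score = (packed - matches) // _PACK
    # score = match*M + mismatch*X + gap*G and la+lb = 2(M+X)+G pin down the
    # gap count G -- hence the alignment length -- once (score, M) is fixed.
    if mismatch != 0:
        raise ValueError("identity recovery requires mismatch score 0")
    n_gaps = (match * matches - score) / -gap
    align_len = (la + lb + n_gaps) / 2
    return matches / align_len


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def validate(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal not zero")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


def pairwise_distances(seqs: Sequence[str]) -> DistanceMatrix:
    """1 - identity distances for every sequence pair."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for s in seqs:
        if not s or not set(s) <= AA_ALPHABET:
            raise ValueError(f"not an amino-acid sequence: {s!r}")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - nw_identity(seqs[i], seqs[j])
    return DistanceMatrix(labels=list(seqs), d=d)


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: Optional[list[tuple["TreeNode", float]]] = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name] if self.name else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root for serialization."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if not node.children:
                return node.name or ""
            inner = ",".join(
                f"{render(child)}:{length:.6f}" for child, length in node.children
            )
            return f"({inner})"

        return render(self.root) + ";"


def nj_tree(m: DistanceMatrix) -> Tree:
    """Classical neighbor-joining (Q-criterion, iterative pair joining).

    Negative branch-length estimates are clamped to 0 with a warning. The
    output is deterministic given the input label order.
    """
    m.validate()
    n = len(m.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.all(np.isfinite(m.d)):
        raise ValueError("non-finite distances")
    if n == 2:
        leaf_a = TreeNode(name=m.labels[0])
        leaf_b = TreeNode(name=m.labels[1])
        half = float(m.d[0, 1]) / 2.0
        return Tree(root=TreeNode(children=[(leaf_a, half), (leaf_b, half)]))

    nodes: list[TreeNode] = [TreeNode(name=label) for label in m.labels]
    d = m.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("negative NJ branch length %.6g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[ai] - r[aj]) / (2 * (k - 2)))
        lj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (k - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_idx = d.shape[0]
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        for other in active:
            if other in (i, j):
                continue
            dist = 0.5 * (d[i, other] + d[j, other] - dij)
            d[new_idx, other] = d[other, new_idx] = max(dist, 0.0)
        active = [x for x in active if x not in (i, j)] + [new_idx]

    # join the final three nodes at one internal vertex
    i, j, k = active
    li = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return Tree(root=root)


def assign_clusters(m: DistanceMatrix, threshold: float = 0.5) -> dict[str, int]:
    """Single-linkage clusters: connected components of {d[i][j] <= threshold}.

    Cluster ids are assigned by descending cluster size, ties broken by the
    lexicographically smallest member, so the labeling is order-invariant.
    """
    m.validate()
    n = len(m.labels)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if m.d[i, j] <= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for idx, label in enumerate(m.labels):
        groups.setdefault(find(idx), []).append(label)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    assignment: dict[str, int] = {}
    for cluster_id, members in enumerate(ordered):
        for label in members:
            assignment[label] = cluster_id
    return assignment


def write_distance_tsv(path: str, m: DistanceMatrix) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t" + "\t".join(m.labels) + "\n")
        for i, label in enumerate(m.labels):
            row = "\t".join(f"{x:.6f}" for x in m.d[i])
            out.write(f"{label}\t{row}\n")
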