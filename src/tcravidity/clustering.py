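"""UPGMA tree construction, avidity-hotspot detection and its permutation null.

UPGMA (unweighted pair group method with arithmetic mean) agglomerates the
two closest clusters at each step, with the inter-cluster distance defined as
the arithmetic mean of all cross-pair distances. Merge height is half that
average distance, so the path height between two leaves equals their average
distance and the tree is ultrametric.

The hotspot search scans every clade of the tree for the one most enriched in
intermediate/high-avidity TCRs (half-life above a threshold, 10 s by
default). Because the best clade is *selected*, its enrichment is judged
against a max-statistic permutation null: half-life labels are shuffled
across leaves and the maximal clade enrichment recomputed each time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .atchley import TcrDistanceMatrix
from .core import INTERMEDIATE_AVIDITY_THRESHOLD_S


@dataclass
class TreeNode:
    """A node of the binary merge tree. Leaves carry ``tcr_id``; internal
    nodes carry the merge ``height`` (distance units / 2) and two children."""

    height: float
    tcr_id: Optional[str] = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    leaf_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def size(self) -> int:
        return len(self.leaf_ids)


@dataclass
class DendroTree:
    """A rooted ultrametric dendrogram over a set of tcr_ids."""

    root: TreeNode

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return self.root.leaf_ids

    def internal_nodes(self) -> list[TreeNode]:
        """All internal nodes, root included, in post-order."""
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.children is not None:
                for child in node.children:
                    walk(child)
                out.append(node)

        walk(self.root)
        return out

    def clades(self, min_size: int = 1) -> list[TreeNode]:
        """Candidate clades: internal nodes (and leaves if min_size == 1)."""
        nodes: list[TreeNode] = self.internal_nodes()
        if min_size <= 1:
            nodes = self._leaves() + nodes
        return [n for n in nodes if n.size >= min_size]

    def _leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out

    def cophenetic_matrix(self) -> tuple[list[str], np.ndarray]:
        """Pairwise cophenetic distances: twice the height of the lowest
        common ancestor (so two leaves merged at height h are at distance 2h,
        i.e. their average input distance)."""
        ids = list(self.leaf_ids)
        index = {t: i for i, t in enumerate(ids)}
        n = len(ids)
        out = np.zeros((n, n))

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            left, right = node.children
            for a in left.leaf_ids:
                for b in right.leaf_ids:
                    i, j = index[a], index[b]
                    out[i, j] = out[j, i] = 2.0 * node.height
            walk(left)
            walk(right)

        walk(self.root)
        return ids, out

    def to_newick(self) -> str:
        """Newick string with branch lengths (parent height - child height)."""

        def fmt(node: TreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.tcr_id}:{length:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{length:.6g}"

        left, right = self.root.children if self.root.children else (None, None)
        if self.root.is_leaf:
            return f"{self.root.tcr_id}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def upgma(matrix: TcrDistanceMatrix) -> DendroTree:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Merge height is half the inter-cluster average distance. When two
    candidate pairs tie on distance, the pair whose smallest member ids sort
    first lexicographically merges first, making trees reproducible.
    """
    d = np.asarray(matrix.values, dtype=float)
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 leaves")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix has negative entries")

    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, tcr_id=t, leaf_ids=(t,)) for i, t in enumerate(matrix.ids)
    }
    sizes = {i: 1 for i in range(n)}
    # rep id used for deterministic tie-breaking
    reps = {i: matrix.ids[i] for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_idx = n

    while len(clusters) > 1:
        best = None
        for key, val in dist.items():
            i, j = sorted(key, key=lambda k: reps[k])
            tie_key = (val, reps[i], reps[j])
            if best is None or tie_key < best[0]:
                best = (tie_key, i, j)
        _, i, j = best
        dij = dist.pop(frozenset((i, j)))
        node = TreeNode(
            height=dij / 2.0,
            children=(clusters[i], clusters[j]),
            leaf_ids=clusters[i].leaf_ids + clusters[j].leaf_ids,
        )
        si, sj = sizes[i], sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_idx, k))] = (si * dik + sj * djk) / (si + sj)
        del clusters[i], clusters[j], sizes[i], sizes[j], reps[i], reps[j]
        clusters[next_idx] = node
        sizes[next_idx] = si + sj
        reps[next_idx] = min(node.leaf_ids)
        next_idx += 1

    return DendroTree(root=next(iter(clusters.values())))


@dataclass
class HotspotReport:
    """The avidity hotspot: the clade maximising the fraction of members with
    half-life above the threshold.

    ``purity`` is the maximised quantity (fraction of clade members above
    threshold). ``inside_high_fraction`` is the fraction of *all* above-
    threshold TCRs that fall inside the clade; ``outside_low_fraction`` the
    fraction of TCRs outside the clade that are below threshold — the two
    summary figures usually quoted for such a cluster.
    """

    member_ids: tuple[str, ...]
    purity: float
    inside_high_fraction: float
    outside_low_fraction: float
    threshold_s: float
    min_size: int
    height: float
    n_scored: int
    p_value: Optional[float] = None


def _scored_leaves(
    leaf_ids: Sequence[str], halflives: Mapping[str, Optional[float]]
) -> tuple[list[str], np.ndarray]:
    scored = [t for t in leaf_ids if halflives.get(t) is not None]
    if not scored:
        raise ValueError("all half-lives missing: nothing to score")
    values = np.array([halflives[t] for t in scored], dtype=float)
    return scored, values


def _clade_membership(
    tree: DendroTree, scored: Sequence[str], min_size: int
) -> tuple[list[TreeNode], np.ndarray]:
    """Boolean membership matrix (n_clades x n_scored) for eligible clades.

    Eligibility (size >= min_size) counts scored members only, so leaves with
    missing half-life neither qualify a clade nor dilute its enrichment.
    """
    index = {t: k for k, t in enumerate(scored)}
    nodes, rows = [], []
    for node in tree.clades(min_size=1):
        row = np.zeros(len(scored), dtype=bool)
        for t in node.leaf_ids:
            if t in index:
                row[index[t]] = True
        if row.sum() >= min_size:
            nodes.append(node)
            rows.append(row)
    if not nodes:
        raise ValueError(f"no clade has {min_size} or more scored members")
    return nodes, np.stack(rows)


def find_hotspot(
    tree: DendroTree,
    halflives: Mapping[str, Optional[float]],
    threshold_s: float = INTERMEDIATE_AVIDITY_THRESHOLD_S,
    min_size: int = 5,
) -> HotspotReport:
    """Locate the clade most enriched in TCRs with half-life > threshold.

    Ties on enrichment go to the larger clade, then to the lower merge
    height. Leaves without a half-life are excluded from scoring.
    """
    scored, values = _scored_leaves(tree.leaf_ids, halflives)
    high = values > threshold_s
    nodes, member = _clade_membership(tree, scored, min_size)
    counts = member.sum(axis=1)
    purities = (member & high).sum(axis=1) / counts
    order = sorted(
        range(len(nodes)),
        key=lambda k: (-purities[k], -counts[k], nodes[k].height),
    )
    best = order[0]
    node, row = nodes[best], member[best]
    n_high_total = int(high.sum())
    inside_high = (row & high).sum() / n_high_total if n_high_total else float("nan")
    outside = ~row
    outside_low = (
        (outside & ~high).sum() / outside.sum() if outside.sum() else float("nan")
    )
    return HotspotReport(
        member_ids=node.leaf_ids,
        purity=float(purities[best]),
        inside_high_fraction=float(inside_high),
        outside_low_fraction=float(outside_low),
        threshold_s=threshold_s,
        min_size=min_size,
        height=node.height,
        n_scored=len(scored),
    )


def cluster_enrichment_null(
    tree: DendroTree,
    halflives: Mapping[str, Optional[float]],
    observed_purity: float,
    threshold_s: float = INTERMEDIATE_AVIDITY_THRESHOLD_S,
    min_size: int = 5,
    b: int = 1000,
    seed: int = 0,
    return_distribution: bool = False,
):
    """Max-statistic permutation p-value for the observed hotspot enrichment.

    Half-life labels are permuted across scored leaves ``b`` times; each
    replicate records the maximal clade enrichment over the same candidate
    set, which controls the selection effect of picking the best clade.
    Returns the add-one p-value (1 + #{replicate max >= observed}) / (b + 1),
    never exactly zero.
    """
    if b < 1:
        raise ValueError("need at least one permutation replicate")
    scored, values = _scored_leaves(tree.leaf_ids, halflives)
    high = values > threshold_s
    _, member = _clade_membership(tree, scored, min_size)
    counts = member.sum(axis=1)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(high) for _ in range(b)])  # (b, n_scored)
    # (n_clades, b) clade high-counts per replicate
    rep_counts = member.astype(np.int64) @ perms.T.astype(np.int64)
    rep_max = (rep_counts / counts[:, None]).max(axis=0)
    p = (1.0 + np.sum(rep_max >= observed_purity - 1e-12)) / (b + 1.0)
    if return_distribution:
        return float(p), rep_max
    return float(p)
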