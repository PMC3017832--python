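"""Distance-based tree building: neighbor joining and UPGMA, with
nonparametric bootstrap support.

NJ follows Saitou & Nei's agglomeration: at each step join the pair
minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j, with branch lengths from the
standard two-point formulas. Ties are broken lexicographically by the sorted
label pair so the output is deterministic. Negative estimated branch lengths
are clamped to zero and the deficit moved to the sister branch, preserving
the pair's summed length (the usual NJ fix-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import CodonAlignment, NamedSequence, parse_newick


class TreeError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise TreeError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise TreeError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise TreeError("diagonal must be zero")
        if not np.all(np.isfinite(m)):
            raise TreeError("non-finite distances")
        self.matrix = m

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows))

    def to_phylip(self) -> str:
        out = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.matrix):
            out.append(lab + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(out) + "\n"


def _new_tree(newick: str) -> dendropy.Tree:
    return parse_newick(newick)


class _Node:
    __slots__ = ("label", "children", "edge")

    def __init__(self, label=None, children=(), edge=None):
        self.label = label
        self.children = list(children)
        self.edge = edge  # (child, length) pairs stored on parent instead

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{length:.10g}" for child, length in self.children
        )
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei NJ; returns an unrooted tree (trifurcating root)."""
    n = len(dm.labels)
    if n < 3:
        raise TreeError(f"NJ needs at least 3 taxa, got {n}")
    nodes = [_Node(label=lab) for lab in dm.labels]
    # sort key per node: min leaf label below it, for deterministic ties
    keys = list(dm.labels)
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                if best is None or (q, tie) < (best[0], best[1]):
                    best = (q, tie, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives, transfer deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        parent = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        k_new = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k_new, x] = d[x, k_new] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [k_new]

    # join the last three on a trifurcating root
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    lens = [max(x, 0.0) for x in (li, lj, lk)]
    root = _Node(children=list(zip((nodes[i], nodes[j], nodes[k]), lens)))
    return _new_tree(root.newick() + ";")


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage clustering; returns an ultrametric rooted tree."""
    n = len(dm.labels)
    if n < 2:
        raise TreeError(f"UPGMA needs at least 2 taxa, got {n}")
    nodes = [_Node(label=lab) for lab in dm.labels]
    heights = [0.0] * n
    sizes = [1] * n
    keys = list(dm.labels)
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                tie = tuple(sorted((keys[i], keys[j])))
                if best is None or (d[i, j], tie) < (best[0], best[1]):
                    best = (d[i, j], tie, i, j)
        dist, _, i, j = best
        h = dist / 2.0
        parent = _Node(children=[
            (nodes[i], max(h - heights[i], 0.0)),
            (nodes[j], max(h - heights[j], 0.0)),
        ])
        k_new = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k_new, x] = d[x, k_new] = (
                sizes[i] * d[i, x] + sizes[j] * d[j, x]
            ) / (sizes[i] + sizes[j])
        nodes.append(parent)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [k_new]

    return _new_tree(nodes[active[0]].newick() + ";")


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial unrooted bipartitions as canonical frozensets of labels.

    Each internal edge splits the leaves in two; the side NOT containing the
    alphabetically first leaf is the canonical representative.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def _resample_alignment(aln: CodonAlignment, rng, unit: str) -> CodonAlignment:
    if unit == "codon":
        n = aln.n_codons
        idx = rng.integers(0, n, size=n)
        members = [
            NamedSequence(m.name, "".join(m.codon(i) for i in idx))
            for m in aln.members
        ]
    else:
        L = aln.n_codons * 3
        idx = rng.integers(0, L, size=L)
        # keep length a multiple of 3 so CodonAlignment stays valid
        members = [
            NamedSequence(m.name, "".join(m.residues[i] for i in idx))
            for m in aln.members
        ]
    return CodonAlignment(members, aln.code)


def bootstrap_support(aln: CodonAlignment, builder, B: int = 500,
                      seed: int = 0, unit: str = "nucleotide") -> dendropy.Tree:
    """Attach bootstrap percentages to the point-estimate tree.

    ``builder`` maps a CodonAlignment to a dendropy Tree (distance metric and
    algorithm are the caller's choice). Columns (codon or nucleotide) are
    resampled with replacement B times; support for each internal bipartition
    of the point tree = percentage of replicate trees containing it.
    """
    if B < 2:
        raise TreeError(f"B must be >= 2, got {B}")
    point = builder(aln)
    target = bipartitions(point)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(B):
        rep = _resample_alignment(aln, rng, unit)
        try:
            rep_tree = builder(rep)
        except Exception:
            skipped += 1
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped > 0.05 * B:
        raise TreeError(f"builder failed in {skipped}/{B} replicates")
    used = B - skipped
    leaves = sorted(lf.taxon.label for lf in point.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    for node in point.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if side in counts:
            node.label = str(int(round(100.0 * counts[side] / used)))
    return point


def support_for_clade(tree: dendropy.Tree, clade_labels) -> int | None:
    """Bootstrap percentage for the bipartition isolating ``clade_labels``."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    want = frozenset(clade_labels)
    if ref in want:
        want = all_set - want
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if side == want:
            return int(node.label)
    return None
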