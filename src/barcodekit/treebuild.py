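"""Neighbour-joining trees with non-parametric bootstrap support.

The NJ agglomeration is the canonical Saitou-Nei procedure: at each step the
pair minimising the Q-criterion ``Q_ij = (n-2) d_ij - r_i - r_j`` is joined,
with Studier-Keppler distance updates. Ties are broken on the lowest
(row, column) index pair in the current label ordering so rebuilds are
reproducible. Negative branch lengths are clamped to zero and the total
clamped deficit recorded on the tree.

Bootstrap support resamples alignment columns with replacement, rebuilds the
NJ tree per replicate with the same distance engine (pairwise deletion
inside every replicate), and scores each internal edge of the original tree
by the percentage of completed replicates whose tree contains the identical
leaf bipartition (Felsenstein's method). Replicates producing an undefined
distance are skipped and counted; more than 50% skipped is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix, encode_alignment, matrix_from_encoded
from .seqio import Alignment

__all__ = ["PhyloNode", "PhyloTree", "nj_tree", "bootstrap_support"]


@dataclass
class PhyloNode:
    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        if self.is_leaf:
            return [self]
        out: list[PhyloNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with a basal multifurcation."""

    root: PhyloNode
    clamped_deficit: float = 0.0  # total negative branch length set to 0

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def bipartitions(self) -> dict[frozenset, PhyloNode]:
        """Internal-edge bipartitions, keyed by their canonical leaf side.

        Each internal edge splits the leaves in two; the canonical side is
        the one not containing the first leaf label, so identical splits
        compare equal across trees on the same leaf set.
        """
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        out: dict[frozenset, PhyloNode] = {}

        def walk(node: PhyloNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if ref in below else below
                out[side] = node
            return below

        walk(self.root)
        return out

    def tip_to_tip_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every leaf pair (labels sorted per key)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: PhyloNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: node.length}
            sub = [walk(c) for c in node.children]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i].items():
                        for lb, db in sub[j].items():
                            dists[tuple(sorted((la, lb)))] = da + db
            merged = {l: d for s in sub for l, d in s.items()}
            return {l: d + node.length for l, d in merged.items()}

        walk(self.root)
        return dists

    def newick(self, min_support: float = 50.0) -> str:
        def fmt(node: PhyloNode) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None and node.support >= min_support:
                label = f"{node.support:g}"
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:g}"

        return fmt(self.root) + ";"


def _check_defined(dm: DistanceMatrix) -> None:
    bad = dm.undefined_pairs
    if bad:
        raise ValueError(f"undefined distances among inputs: {bad}")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Build the neighbour-joining tree for a distance matrix."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    _check_defined(dm)

    d = dm.values.astype(float).copy()
    nodes: list[PhyloNode] = [PhyloNode(label=l) for l in dm.labels]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0.0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # only i<j considered; row-major argmin = lowest (i, j) tie-break
        iu = np.triu_indices(m, k=1)
        flat = np.full((m, m), np.inf)
        flat[iu] = q[iu]
        i, j = np.unravel_index(int(np.argmin(flat)), (m, m))
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = PhyloNode(children=[child_i, child_j])
        # Studier-Keppler update
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # final three-point join
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    return PhyloTree(PhyloNode(children=[a, b, c]), clamped_deficit=deficit)


def bootstrap_support(
    aln: Alignment,
    model: str = "k2p",
    replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports attached.

    Deterministic for a fixed seed. Supports are percentages of completed
    (non-skipped) replicates containing each original internal bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    enc = encode_alignment(aln)
    labels = aln.specimen_ids
    tree = nj_tree(matrix_from_encoded(enc, labels, model=model))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    ncols = enc.shape[1]
    skipped = 0
    completed = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        dm_rep = matrix_from_encoded(enc[:, cols], labels, model=model)
        if dm_rep.undefined_pairs:
            skipped += 1
            continue
        completed += 1
        for bp in nj_tree(dm_rep).bipartitions():
            if bp in counts:
                counts[bp] += 1
    if skipped > replicates / 2:
        raise RuntimeError(
            f"{skipped}/{replicates} bootstrap replicates had undefined "
            "distances; alignment too gappy for bootstrap"
        )
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / completed
    return tree
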