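"""Distance-based phylogenetics: coverage masking, p/Poisson distances, NJ, bootstrap.

Trees are built by plain neighbor joining on pairwise distances computed from
a protein MSA.  Columns failing a site-coverage cutoff (default 95% non-gap)
are removed first; remaining gaps are handled by pairwise deletion.  Two
distance models are offered: the raw proportion of differing sites
(p-distance) and its Poisson multiple-hit correction d = -ln(1 - p).

Neighbor joining uses the standard Q criterion with deterministic
tie-breaking (lexicographically smallest pair index) and clamps negative
branch lengths to zero with a warning.  Bootstrap support for each internal
bipartition is the percentage of column-resampled replicates whose NJ tree
contains that bipartition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from htr3evo.align import GAP, MSAView


def mask_columns(msa: MSAView, coverage: float = 0.95) -> MSAView:
    """Drop columns whose non-gap fraction is below ``coverage``."""
    if not msa.rows:
        return msa
    n = len(msa.rows)
    keep = []
    for col in range(msa.n_cols):
        non_gap = sum(1 for _, seq in msa.rows if seq[col] != GAP)
        if non_gap / n >= coverage:
            keep.append(col)
    return MSAView([(acc, "".join(seq[c] for c in keep)) for acc, seq in msa.rows])


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def pairwise_distance(msa: MSAView, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion of gapped sites.

    ``p_distance`` is mismatches over shared non-gap columns; ``poisson``
    applies d = -ln(1 - p).  A pair sharing no non-gap column is an error.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa.rows) < 2:
        raise ValueError("need at least two sequences")
    labels = msa.accessions
    arr = np.array([list(seq) for _, seq in msa.rows])
    non_gap = arr != GAP
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = non_gap[i] & non_gap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no aligned sites"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / n_shared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {labels[i]!r}/{labels[j]!r}: p = 1"
                    )
                dist = -math.log1p(-p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an (unrooted, rendered-rooted) phylogenetic tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree rendered with a (tri- or bi-furcating) root node."""

    root: TreeNode

    @property
    def labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised to the side that
        excludes the lexicographically smallest taxon."""
        all_taxa = frozenset(self.root.leaves())
        anchor = min(all_taxa)
        out: set[frozenset[str]] = set()

        def visit(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(side if anchor not in side else all_taxa - side)
                visit(child)

        visit(self.root)
        return out

    def annotate_supports(self, supports: dict[frozenset[str], float]) -> None:
        all_taxa = frozenset(self.root.leaves())
        anchor = min(all_taxa)

        def visit(node: TreeNode):
            for child, _ in node.children:
                if not child.is_leaf:
                    side = frozenset(child.leaves())
                    key = side if anchor not in side else all_taxa - side
                    if key in supports:
                        child.support = supports[key]
                visit(child)

        visit(self.root)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with deterministic tie-breaking.

    Agglomerates the pair minimising the Q criterion; ties resolve to the
    lexicographically smallest index pair.  Negative limb lengths are clamped
    to zero with a warning.  For n = 2 the result is a single edge split
    evenly; for n = 3 the three-point formulas give the pendant lengths.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    d = dm.d.copy()

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:  # true negatives only; ignore float epsilon
                warnings.warn(
                    f"negative branch length {x:.4g} clamped to 0", stacklevel=3
                )
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d2

    if len(nodes) == 2:
        half = 0.5 * d[0, 1]
        root = TreeNode(children=[(nodes[0], clamp(half)), (nodes[1], clamp(half))])
    else:
        l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        root = TreeNode(
            children=[
                (nodes[0], clamp(l0)),
                (nodes[1], clamp(l1)),
                (nodes[2], clamp(l2)),
            ]
        )
    return PhyloTree(root)


def to_newick(tree: PhyloTree, with_supports: bool = True) -> str:
    """Render a tree as Newick; bootstrap supports become internal node labels."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(f"{render(c)}:{bl:.6f}" for c, bl in node.children)
        label = ""
        if with_supports and node.support is not None:
            label = str(int(round(node.support)))
        return f"({inner}){label}"

    return render(tree.root) + ";"


def from_newick(newick: str) -> PhyloTree:
    """Parse Newick text (supports as internal labels) into a PhyloTree."""
    dt = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(name=dnode.taxon.label)
        node = TreeNode()
        if dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass
        for child in dnode.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            node.children.append((convert(child), float(bl)))
        return node

    return PhyloTree(convert(dt.seed_node))


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds distance between two Newick trees."""
    a = from_newick(newick_a).bipartitions()
    b = from_newick(newick_b).bipartitions()
    return len(a ^ b)


def bootstrap(
    msa: MSAView,
    n_reps: int = 500,
    seed: int = 0,
    model: str = "p_distance",
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal bipartition of the full-data tree is the percentage of
    replicate NJ trees containing it.  Supports are attached to the returned
    tree and also returned as a mapping.  ``n_reps = 0`` returns the tree
    with no supports.
    """
    tree = neighbor_joining(pairwise_distance(msa, model))
    if n_reps == 0:
        return tree, {}
    rng = np.random.default_rng(seed)
    target = tree.bipartitions()
    hits = {bp: 0 for bp in target}
    n_cols = msa.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = MSAView([(acc, "".join(seq[c] for c in cols)) for acc, seq in msa.rows])
        try:
            with warnings.catch_warnings():
                # replicate trees routinely need clamping; not worth a warning each
                warnings.simplefilter("ignore", UserWarning)
                rep_tree = neighbor_joining(pairwise_distance(rep, model))
        except ValueError:
            continue  # replicate lost all shared sites for some pair
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    supports = {bp: 100.0 * k / n_reps for bp, k in hits.items()}
    tree.annotate_supports(supports)
    return tree, supports
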