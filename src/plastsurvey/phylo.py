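"""Distance-based tree inference, bootstrap support and tree comparison.

The built-in engine is neighbor joining over K80 distances — a deliberate,
desk-scale replacement for heavyweight maximum-likelihood inference; every
consumer of trees also accepts externally computed newick trees, so users
can substitute their preferred engine.  Robinson-Foulds distances and
support aggregation operate on bipartition sets, so polytomies need no
special-casing.

dendropy is used as the newick carrier; bipartition extraction, NJ and RF
are implemented here.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from .alignment import MultipleAlignment
from .divstats import (
    SaturationError,
    UndefinedDistanceError,
    k80_from_counts,
    pairwise_counts,
)

__all__ = [
    "UnrootedTree",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "rf_distance",
    "mean_support",
]

Bipartition = frozenset  # one side of a leaf split, canonicalized


class UnrootedTree:
    """Leaf-labeled unrooted tree with branch lengths and edge supports.

    Internally a (rooted) dendropy tree; all comparisons go through the
    bipartition set, which is invariant to the rooting.  Supports live in a
    mapping from canonical bipartition (the side not containing the
    lexicographically smallest leaf) to a value in [0, 100].
    """

    def __init__(self, dtree: dendropy.Tree, supports: dict | None = None):
        self._tree = dtree
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        self.leaves: frozenset[str] = frozenset(labels)
        self._anchor = min(self.leaves)
        self.supports: dict[Bipartition, float] = (
            dict(supports) if supports is not None else {}
        )
        if supports is None:
            self._supports_from_labels()
        self._biparts: frozenset | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as err:  # dendropy raises several internal types
            raise ValueError(f"malformed newick: {err}") from err
        return cls(dtree)

    def canonical(self, side) -> Bipartition:
        side = frozenset(side)
        if self._anchor in side:
            side = self.leaves - side
        return side

    def _node_leafset(self, node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def _supports_from_labels(self) -> None:
        n = len(self.leaves)
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            side = self._node_leafset(node)
            if 2 <= len(side) <= n - 2:
                try:
                    self.supports[self.canonical(side)] = float(node.label)
                except ValueError:
                    pass

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self) -> frozenset:
        """Canonical non-trivial bipartitions (internal edges)."""
        if self._biparts is None:
            n = len(self.leaves)
            out = set()
            for node in self._tree.preorder_node_iter():
                if node.is_leaf() or node.parent_node is None:
                    continue
                side = self._node_leafset(node)
                if 2 <= min(len(side), n - len(side)):
                    out.add(self.canonical(side))
            self._biparts = frozenset(out)
        return self._biparts

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick with supports written as internal node labels."""
        n = len(self.leaves)
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = self._node_leafset(node)
            if not (2 <= min(len(side), n - len(side))):
                continue
            sup = self.supports.get(self.canonical(side))
            if sup is not None:
                node.label = (
                    str(int(sup)) if float(sup).is_integer() else f"{sup:g}"
                )
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return text.strip()

    # -- operations --------------------------------------------------------

    def prune_to(self, keep) -> "UnrootedTree":
        """Restriction of the tree to a subset of its leaves."""
        keep = frozenset(keep)
        missing = keep - self.leaves
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        clone = UnrootedTree.from_newick(self.to_newick())
        clone._tree.retain_taxa_with_labels(sorted(keep))
        return UnrootedTree(clone._tree)

    def __repr__(self) -> str:
        return f"UnrootedTree({len(self.leaves)} leaves)"


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    """Robinson-Foulds: size of the symmetric difference of bipartition sets."""
    if t1.leaves != t2.leaves:
        raise ValueError(
            f"leaf sets differ: {sorted(t1.leaves ^ t2.leaves)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


def mean_support(tree: UnrootedTree) -> float | None:
    """Arithmetic mean of internal-edge supports; None if none are present."""
    if not tree.supports:
        return None
    return float(np.mean(list(tree.supports.values())))


# ---------------------------------------------------------------------------
# Distance matrix


def distance_matrix(aln: MultipleAlignment, model: str = "K80") -> np.ndarray:
    """Symmetric K80 distance matrix over the alignment's taxa.

    Saturated pairs are imputed as twice the largest defined entry (with a
    warning); a pair with zero comparable sites is an error.
    """
    if model != "K80":
        raise ValueError(f"unsupported model {model!r}")
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa for a distance matrix")
    n = aln.n_taxa
    codes = aln.codes()
    D = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            c = pairwise_counts(codes[i], codes[j])
            if c.compared_sites == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {aln.taxa[i]!r} "
                    f"and {aln.taxa[j]!r}"
                )
            try:
                D[i, j] = D[j, i] = k80_from_counts(
                    c.transitions, c.transversions, c.compared_sites
                )
            except SaturationError:
                saturated.append((i, j))
    if saturated:
        finite_max = D.max()
        warnings.warn(
            f"{len(saturated)} saturated pair(s) imputed as 2 x max distance",
            stacklevel=2,
        )
        for i, j in saturated:
            D[i, j] = D[j, i] = 2.0 * finite_max
    return D


# ---------------------------------------------------------------------------
# Neighbor joining


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def nj_tree(matrix: np.ndarray, labels: list[str]) -> UnrootedTree:
    """Standard neighbor-joining agglomeration.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge (their sum is preserved).  Tie-breaking in the Q matrix
    is by smallest (i, j) index pair, so the result is deterministic.
    """
    D = np.array(matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ValueError("matrix/labels shape mismatch")
    if not np.isfinite(D).all():
        raise ValueError("non-finite entries in distance matrix")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")

    frags = [label.replace(" ", "_") for label in labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        # new node u replaces slot i
        others = [a for a in active if a not in (i, j)]
        for kk in others:
            duk = 0.5 * (D[i, kk] + D[j, kk] - dij)
            D[i, kk] = D[kk, i] = duk
        frags[i] = f"({frags[i]}:{_fmt(li)},{frags[j]}:{_fmt(lj)})"
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = (
        f"({frags[a]}:{_fmt(la)},{frags[b]}:{_fmt(lb)},{frags[c]}:{_fmt(lc)});"
    )
    return UnrootedTree.from_newick(newick)


# ---------------------------------------------------------------------------
# Bootstrap


def _pair_site_classes(codes: np.ndarray) -> tuple[np.ndarray, list]:
    """Per-pair, per-column site class: 0 invalid, 1 same, 2 ts, 3 tv."""
    n, width = codes.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    cls = np.empty((len(pairs), width), dtype=np.int8)
    for p, (i, j) in enumerate(pairs):
        valid = (codes[i] < 4) & (codes[j] < 4)
        x = codes[i] ^ codes[j]
        out = np.where(x == 0, 1, np.where(x == 2, 2, 3)).astype(np.int8)
        out[~valid] = 0
        cls[p] = out
    return cls, pairs


def _matrix_from_classes(
    cls_cols: np.ndarray, pairs: list, n: int
) -> np.ndarray | None:
    """Distance matrix from resampled site classes; None if unusable."""
    npairs = cls_cols.shape[0]
    offsets = (np.arange(npairs, dtype=np.int64) * 4)[:, None]
    tallies = np.bincount(
        (cls_cols + offsets).ravel(), minlength=4 * npairs
    ).reshape(npairs, 4)
    D = np.zeros((n, n))
    saturated = []
    finite_max = 0.0
    for p, (i, j) in enumerate(pairs):
        _, same, ts, tv = tallies[p]
        length = int(same + ts + tv)
        if length == 0:
            return None
        try:
            d = k80_from_counts(int(ts), int(tv), length)
        except SaturationError:
            saturated.append((i, j))
            continue
        D[i, j] = D[j, i] = d
        finite_max = max(finite_max, d)
    if saturated:
        if len(saturated) == len(pairs):
            return None
        for i, j in saturated:
            D[i, j] = D[j, i] = 2.0 * finite_max
    return D


def bootstrap_support(
    aln: MultipleAlignment, B: int, seed: int, model: str = "K80"
) -> UnrootedTree:
    """Point-estimate NJ tree with nonparametric bootstrap edge supports.

    Columns are resampled with replacement to the original width; the NJ
    tree is rebuilt per replicate, and each internal edge of the point tree
    gets the percentage of replicates containing the same bipartition.
    Replicate r draws from the deterministic substream (seed, r), so runs
    are reproducible and individual replicates can be re-derived.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    point = nj_tree(distance_matrix(aln, model=model), aln.taxa)
    edges = point.bipartitions()
    if not edges or aln.n_taxa < 4:
        point.supports = {}
        return point

    codes = aln.codes()
    cls, pairs = _pair_site_classes(codes)
    width = aln.width
    tally: dict = {bp: 0 for bp in edges}
    used = 0
    for r in range(B):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, width, size=width)
        D = _matrix_from_classes(cls[:, idx], pairs, aln.n_taxa)
        if D is None:
            continue
        rep = nj_tree(D, aln.taxa)
        used += 1
        for bp in rep.bipartitions():
            if bp in tally:
                tally[bp] += 1
    if used == 0:
        warnings.warn("all bootstrap replicates unusable", stacklevel=2)
        point.supports = {}
        return point
    if used < B:
        warnings.warn(
            f"{B - used} bootstrap replicate(s) dropped (degenerate resample)",
            stacklevel=2,
        )
    point.supports = {bp: 100.0 * k / used for bp, k in tally.items()}
    return point
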