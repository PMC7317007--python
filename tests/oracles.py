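"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: site censuses use
per-column Counters, pi uses a double loop over pairs and sites, RF works
on nested-tuple topologies, NJ is checked against least-squares fits over
exhaustively enumerated topologies, and inverted repeats are found by a
full per-diagonal scan.
"""

from collections import Counter
from itertools import combinations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def census_site_classes(rows: list[str]) -> tuple[int, int]:
    """(variable, parsimony-informative) site counts by per-column census."""
    variable = pis = 0
    for col in zip(*rows):
        counts = Counter(c for c in col if c in "ACGT")
        if len(counts) >= 2:
            variable += 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            pis += 1
    return variable, pis


def brute_pi(rows: list[str]) -> float | None:
    """Nucleotide diversity by an explicit pair/site double loop."""
    ratios = []
    for a, b in combinations(rows, 2):
        compared = diffs = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                compared += 1
                if x != y:
                    diffs += 1
        if compared:
            ratios.append(diffs / compared)
    if not ratios:
        return None
    return sum(ratios) / len(ratios)


# ---------------------------------------------------------------------------
# Trees as nested tuples; leaves are strings.


def topology_splits(tree, all_leaves: frozenset) -> set[frozenset]:
    """Non-trivial splits of a nested-tuple unrooted tree (root = trifurcation)."""
    anchor = min(all_leaves)
    splits: set[frozenset] = set()

    def leafset(node) -> frozenset:
        if isinstance(node, str):
            return frozenset([node])
        out = frozenset()
        for child in node:
            out |= leafset(child)
        return out

    def walk(node):
        if isinstance(node, str):
            return
        for child in node:
            side = leafset(child)
            if 2 <= len(side) <= len(all_leaves) - 2:
                canon = side if anchor not in side else all_leaves - side
                splits.add(canon)
            walk(child)

    walk(tree)
    return splits


def rf_oracle(t1, t2, leaves: frozenset) -> int:
    return len(topology_splits(t1, leaves) ^ topology_splits(t2, leaves))


def all_unrooted_topologies(labels: list[str]):
    """All (2n-5)!! unrooted binary topologies by recursive edge insertion."""
    base = (labels[0], labels[1], labels[2])
    trees = [base]
    for label in labels[3:]:
        nxt = []
        for tree in trees:
            for variant in _insert_on_every_edge(tree, label):
                nxt.append(variant)
        trees = nxt
    return trees


def _insert_on_every_edge(tree, label):
    # Insertion on an edge = replacing a child subtree c with (c, label);
    # the (virtual) root trifurcation has no parent edge.
    def variants(node):
        if isinstance(node, str):
            return []
        out = []
        for i, child in enumerate(node):
            replaced = tuple(
                (child, label) if j == i else c for j, c in enumerate(node)
            )
            out.append(replaced)
            for sub in variants(child):
                out.append(tuple(sub if j == i else c for j, c in enumerate(node)))
        return out

    return variants(tree)


def to_newick(tree) -> str:
    def render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(c) for c in node) + ")"

    return render(tree) + ";"


def tree_path_matrix(tree, lengths: dict) -> tuple[list[str], np.ndarray]:
    """Leaf labels and additive (path-length) distance matrix.

    ``lengths`` maps each subtree (by its frozen leafset) to its parent-edge
    length; pendant edges use the single-leaf frozenset.
    """
    leaves = sorted(_leaflist(tree))
    idx = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    groups = []
    for child in tree:
        ls = frozenset(_leaflist(child))
        depths = _depths_below(child, lengths)
        groups.append({lf: d + lengths[ls] for lf, d in depths.items()})
    for g1, g2 in combinations(groups, 2):
        for l1, d1 in g1.items():
            for l2, d2 in g2.items():
                D[idx[l1], idx[l2]] = D[idx[l2], idx[l1]] = d1 + d2
    # fill within-group distances recursively
    for child in tree:
        if not isinstance(child, str):
            _fill_within(child, lengths, idx, D)
    return leaves, D


def _leaflist(tree):
    if isinstance(tree, str):
        return [tree]
    out = []
    for child in tree:
        out.extend(_leaflist(child))
    return out


def _fill_within(node, lengths, idx, D):
    groups = []
    for child in node:
        ls = frozenset(_leaflist(child))
        depths = _depths_below(child, lengths)
        groups.append({lf: d + lengths[ls] for lf, d in depths.items()})
        if not isinstance(child, str):
            _fill_within(child, lengths, idx, D)
    for g1, g2 in combinations(groups, 2):
        for l1, d1 in g1.items():
            for l2, d2 in g2.items():
                D[idx[l1], idx[l2]] = D[idx[l2], idx[l1]] = d1 + d2


def _depths_below(node, lengths):
    if isinstance(node, str):
        return {node: 0.0}
    out = {}
    for child in node:
        ls = frozenset(_leaflist(child))
        for lf, d in _depths_below(child, lengths).items():
            out[lf] = d + lengths[ls]
    return out


def random_additive_tree(n: int, rng) -> tuple[object, list[str], np.ndarray]:
    """Random binary topology with random positive lengths and its matrix."""
    labels = [f"L{i}" for i in range(n)]
    tree = (labels[0], labels[1], labels[2])
    for label in labels[3:]:
        options = _insert_on_every_edge(tree, label)
        tree = options[int(rng.integers(len(options)))]
    lengths = {}

    def collect(node):
        for child in node if not isinstance(node, str) else []:
            lengths[frozenset(_leaflist(child))] = float(rng.uniform(0.1, 2.0))
            collect(child)

    collect(tree)
    labels_sorted, D = tree_path_matrix(tree, lengths)
    return tree, labels_sorted, D


def least_squares_best_topology(labels: list[str], D: np.ndarray):
    """Exhaustive topology search scored by least-squares branch fitting."""
    n = len(labels)
    order = sorted(labels)
    idx = {lf: i for i, lf in enumerate(order)}
    pairs = list(combinations(range(n), 2))
    d_vec = np.array([D[i, j] for i, j in pairs])
    best = None
    for topo in all_unrooted_topologies(order):
        edges = []  # each edge as the leafset on one side

        def collect(node):
            if isinstance(node, str):
                return
            for child in node:
                edges.append(frozenset(_leaflist(child)))
                collect(child)

        collect(topo)
        A = np.zeros((len(pairs), len(edges)))
        for p, (i, j) in enumerate(pairs):
            for e, side in enumerate(edges):
                if (order[i] in side) != (order[j] in side):
                    A[p, e] = 1.0
        fit, *_ = np.linalg.lstsq(A, d_vec, rcond=None)
        sse = float(((A @ fit) - d_vec) ** 2 @ np.ones(len(pairs)))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, topo)
    return best[1]


# ---------------------------------------------------------------------------
# Inverted repeats


def ir_oracle(residues: str) -> int:
    """Length of the maximal disjoint reverse-complement pair on a circle.

    Full per-diagonal scan: for every anti-diagonal c, find the maximal
    circular runs of positions p with s[p] == complement(s[(c - p) mod n]);
    a self-mirrored (palindromic) run holds both copies, otherwise the run
    and its mirror are the two copies.
    """
    n = len(residues)
    s = np.frombuffer(residues.encode(), dtype=np.uint8)
    comp_map = np.zeros(256, dtype=np.uint8)
    for a, b in _COMP.items():
        comp_map[ord(a)] = ord(b)
    comp = comp_map[s]
    p = np.arange(n)
    best = 0
    for c in range(n):
        match = s == comp[(c - p) % n]
        if not match.any():
            continue
        if match.all():
            best = max(best, n // 2)
            continue
        # circular run-lengths: double, then cap at n
        m2 = np.concatenate([match, match]).astype(np.int8)
        d = np.diff(np.concatenate([[0], m2, [0]]))
        starts = np.flatnonzero(d == 1)
        lens = np.flatnonzero(d == -1) - starts
        interesting = (starts < n) & (lens > max(best, 1))
        for start, length in zip(starts[interesting], lens[interesting]):
            start = int(start)
            length = int(min(length, n))
            a = start % n
            b = (a + length - 1) % n
            mirror_a = (c - b) % n
            if mirror_a == a:
                best = max(best, length // 2)
            else:
                if 2 * length <= n:
                    best = max(best, length)
    return best
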