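"""Synthetic plastome-like datasets with known ground truth.

Generates an annotated reference, a multiple alignment evolved along a known
tree under the Kimura two-parameter (K2P) substitution process with
per-marker rate multipliers, optional phylogenetically coherent indels, and
a planted quadripartite genome for the structure stage.  The defaults
emulate the study conditions the pipeline is aimed at: 17 homologous
plastome-like sequences with marker-to-marker rate heterogeneity and one
clearly fastest-evolving ("hot") marker as ground truth for the ranking.

Substitution is simulated with the exact closed-form K2P transition
probabilities per branch (no event-by-event simulation); all randomness
flows from one seed through named substreams, so identical configurations
reproduce identical datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotatedPlastome, FeatureRecord, GenomeSequence
from .phylo import UnrootedTree
from .alignment import MultipleAlignment

__all__ = [
    "MarkerSpec",
    "IRPlan",
    "SimulationConfig",
    "SyntheticDataset",
    "default_marker_plan",
    "simulate_tree",
    "simulate_alignment",
    "plant_quadripartite",
    "k2p_probabilities",
]

_BASES = "ACGT"

# substream tags (mixed with the user seed into the bit generator)
_TAG_TREE, _TAG_ROOT, _TAG_BRANCH, _TAG_INDEL = 11, 13, 17, 19


@dataclass
class MarkerSpec:
    """One marker in the genome plan: name, class, length, rate multiplier."""

    name: str
    marker_class: str  # cpCDS / cpNCDS / cpIGS
    length: int
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"marker {self.name!r}: length must be positive")
        if not math.isfinite(self.rate) or self.rate < 0:
            raise ValueError(f"marker {self.name!r}: bad rate {self.rate}")


@dataclass
class IRPlan:
    ir_length: int
    ssc_length: int
    total_length: int


@dataclass
class SimulationConfig:
    seed: int = 0
    n_taxa: int = 17
    tree: str | None = None  # newick; simulated when absent
    # Branch-length law for the simulated tree, calibrated so that rate-1
    # markers show plastome-scale divergence (overall pi of a few percent,
    # matching the nucleotide diversity printed for real plastome panels);
    # the floor keeps every internal edge statistically resolvable.
    tree_mean_branch: float = 0.0035
    tree_min_branch: float = 0.001
    kappa: float = 2.0  # transition/transversion rate ratio
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    marker_plan: list[MarkerSpec] = field(default_factory=lambda: default_marker_plan())
    indel_rate: float = 0.0  # events per site per unit branch length
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass
class MarkerTruth:
    marker_class: str
    rate: float
    interval: tuple[int, int]  # on the reference, 0-based half-open


@dataclass
class SyntheticDataset:
    reference: AnnotatedPlastome
    alignment: MultipleAlignment
    true_tree: UnrootedTree
    truth: dict[str, MarkerTruth]


def default_marker_plan(
    n_markers: int = 20, hot_rate: float = 4.0
) -> list[MarkerSpec]:
    """The study-condition marker plan: one hot marker among twenty.

    Marker 1 is the planted best marker (1,800 bp, rate multiplier
    ``hot_rate``); the remaining markers cycle through the three classes
    with lengths 300-1,500 bp and multipliers 0.2-1.0.
    """
    plan = [MarkerSpec("gene01", "cpCDS", 1800, hot_rate)]
    lengths = [300, 500, 800, 1000, 1200, 1500]
    rates = [0.2, 0.4, 0.6, 0.8, 1.0]
    classes = ["cpCDS", "cpIGS", "cpNCDS", "cpCDS", "cpIGS"]
    for i in range(1, n_markers):
        plan.append(
            MarkerSpec(
                name=f"gene{i + 1:02d}",
                marker_class=classes[i % len(classes)],
                length=lengths[i % len(lengths)],
                rate=rates[i % len(rates)],
            )
        )
    return plan


# ---------------------------------------------------------------------------
# Random trees


def _list_edges(node, parent_holder):
    # every (container, index) pair whose slot holds a subtree or leaf
    out = []
    for i, child in enumerate(node):
        out.append((node, i))
        if isinstance(child, list):
            out.extend(_list_edges(child, node))
    return out


def simulate_tree(
    n_taxa: int,
    seed: int,
    mean_branch: float = 0.05,
    min_branch: float = 0.0,
) -> UnrootedTree:
    """Random binary unrooted topology by sequential random attachment.

    Each new leaf subdivides a uniformly chosen edge, which makes the
    topology uniform over labeled unrooted binary shapes; branch lengths
    (substitutions/site) are exponential with the given mean, optionally
    shifted by ``min_branch`` so every edge carries resolvable signal (a
    pure exponential puts substantial mass on edges too short for any
    finite alignment to recover).
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if not (0 <= min_branch < mean_branch):
        raise ValueError("need 0 <= min_branch < mean_branch")
    rng = np.random.default_rng([int(seed), _TAG_TREE])
    labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    tree: list = [labels[0], labels[1], labels[2]]
    for label in labels[3:]:
        edges = _list_edges(tree, None)
        holder, idx = edges[int(rng.integers(len(edges)))]
        holder[idx] = [holder[idx], label]

    def draw() -> float:
        return min_branch + rng.exponential(mean_branch - min_branch)

    def render(node) -> str:
        if isinstance(node, str):
            return f"{node}:{draw():.10g}"
        inner = ",".join(render(c) for c in node)
        return f"({inner}):{draw():.10g}"

    newick = "(" + ",".join(render(c) for c in tree) + ");"
    return UnrootedTree.from_newick(newick)


# ---------------------------------------------------------------------------
# K2P substitution process


def k2p_probabilities(
    distance: float, kappa: float
) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after ``distance`` subs/site.

    Closed form for the K2P chain normalized so that the expected number of
    substitutions per site equals ``distance``.
    """
    if distance < 0:
        raise ValueError("negative branch length")
    beta_t = distance / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e4 = math.exp(-4.0 * beta_t)
    e2 = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e4
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return p_same, p_ts, p_tv_each


def _evolve(parent: np.ndarray, t_sites: np.ndarray, kappa: float, rng) -> np.ndarray:
    """One branch of K2P evolution; per-site branch lengths in subs/site."""
    child = parent.copy()
    # few distinct per-site rates -> closed form per distinct value
    p_same = np.empty_like(t_sites)
    p_ts = np.empty_like(t_sites)
    for value in np.unique(t_sites):
        ps, pt, _ = k2p_probabilities(float(value), kappa)
        mask = t_sites == value
        p_same[mask] = ps
        p_ts[mask] = pt
    u = rng.random(parent.size)
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv_mask = u >= p_same + p_ts
    child[ts_mask] ^= 2  # A<->G, C<->T under the 0..3 coding
    n_tv = int(tv_mask.sum())
    if n_tv:
        # the two transversion targets of x are x^1 and x^3, equiprobable
        flips = np.where(rng.integers(0, 2, size=n_tv) == 0, 1, 3).astype(np.int8)
        child[tv_mask] ^= flips
    return child


@dataclass
class _IndelEvent:
    eid: int
    kind: str  # "ins" | "del"
    anchor: int
    length: int
    residues: str = ""


def simulate_alignment(config: SimulationConfig) -> SyntheticDataset:
    """Evolve the marker plan along the tree; return data plus ground truth.

    The root sequence is drawn from the base composition; each branch
    applies exact K2P transition probabilities with the marker's rate
    multiplier scaling the branch length.  Indels (optional) are drawn per
    branch as Poisson events with geometric lengths (mean 3) and are
    inherited by all descendants, so gap patterns are phylogenetically
    coherent; inserted residues do not evolve further.  The reference taxon
    row is emitted ungapped whenever the indel rate is zero.
    """
    if not config.marker_plan:
        raise ValueError("marker plan is empty")
    utree = (
        UnrootedTree.from_newick(config.tree)
        if config.tree
        else simulate_tree(
            config.n_taxa,
            config.seed,
            mean_branch=config.tree_mean_branch,
            min_branch=config.tree_min_branch,
        )
    )
    dtree = utree._tree
    L = sum(m.length for m in config.marker_plan)
    rates = np.empty(L)
    truth: dict[str, MarkerTruth] = {}
    cursor = 0
    for m in config.marker_plan:
        rates[cursor : cursor + m.length] = m.rate
        truth[m.name] = MarkerTruth(m.marker_class, m.rate, (cursor, cursor + m.length))
        cursor += m.length

    rng_root = np.random.default_rng([int(config.seed), _TAG_ROOT])
    rng_indel = np.random.default_rng([int(config.seed), _TAG_INDEL])
    root_seq = rng_root.choice(4, size=L, p=config.base_composition).astype(np.int8)

    seqs: dict = {id(dtree.seed_node): root_seq}
    events: dict = {id(dtree.seed_node): []}
    all_insertions: list[_IndelEvent] = []
    eid = 0
    for b_index, node in enumerate(dtree.preorder_node_iter()):
        if node is dtree.seed_node:
            continue
        b = float(node.edge.length or 0.0)
        rng = np.random.default_rng([int(config.seed), _TAG_BRANCH, b_index])
        parent_seq = seqs[id(node.parent_node)]
        seqs[id(node)] = _evolve(parent_seq, rates * b, config.kappa, rng)
        inherited = list(events[id(node.parent_node)])
        if config.indel_rate > 0 and b > 0:
            n_events = int(rng_indel.poisson(config.indel_rate * L * b))
            for _ in range(n_events):
                kind = "ins" if rng_indel.integers(2) == 0 else "del"
                length = int(rng_indel.geometric(1.0 / 3.0))
                if kind == "del":
                    anchor = int(rng_indel.integers(0, L))
                    length = min(length, L - anchor)
                    ev = _IndelEvent(eid, "del", anchor, length)
                else:
                    anchor = int(rng_indel.integers(0, L + 1))
                    residues = "".join(
                        _BASES[c]
                        for c in rng_indel.choice(
                            4, size=length, p=config.base_composition
                        )
                    )
                    ev = _IndelEvent(eid, "ins", anchor, length, residues)
                    all_insertions.append(ev)
                inherited.append(ev)
                eid += 1
        events[id(node)] = inherited

    leaves = sorted(dtree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    taxa = [lf.taxon.label for lf in leaves]
    all_insertions.sort(key=lambda ev: (ev.anchor, ev.eid))

    rows: list[str] = []
    leaf_del_masks: dict[str, np.ndarray] = {}
    for leaf in leaves:
        core = seqs[id(leaf)]
        own = {ev.eid for ev in events[id(leaf)]}
        del_mask = np.zeros(L, dtype=bool)
        for ev in events[id(leaf)]:
            if ev.kind == "del":
                del_mask[ev.anchor : ev.anchor + ev.length] = True
        leaf_del_masks[leaf.taxon.label] = del_mask
        if not all_insertions:
            chars = np.array(list(_BASES), dtype="U1")[core]
            chars[del_mask] = "-"
            rows.append("".join(chars))
            continue
        pieces: list[str] = []
        prev = 0
        for ev in all_insertions:
            seg = np.array(list(_BASES), dtype="U1")[core[prev : ev.anchor]]
            seg[del_mask[prev : ev.anchor]] = "-"
            pieces.append("".join(seg))
            pieces.append(ev.residues if ev.eid in own else "-" * ev.length)
            prev = ev.anchor
        seg = np.array(list(_BASES), dtype="U1")[core[prev:]]
        seg[del_mask[prev:]] = "-"
        pieces.append("".join(seg))
        rows.append("".join(pieces))

    alignment = MultipleAlignment(taxa=taxa, rows=rows)

    ref_taxon = config.reference_taxon or taxa[0]
    if ref_taxon not in taxa:
        raise ValueError(f"reference taxon {ref_taxon!r} not among leaves")
    ref_row = rows[taxa.index(ref_taxon)]
    ref_residues = ref_row.replace("-", "")

    # Map core coordinates to reference ungapped coordinates.
    ref_leaf = next(lf for lf in leaves if lf.taxon.label == ref_taxon)
    ref_own = {ev.eid for ev in events[id(ref_leaf)]}
    keep = ~leaf_del_masks[ref_taxon]
    prefix = np.zeros(L + 1, dtype=np.int64)
    prefix[1:] = np.cumsum(keep)
    ins_before = np.zeros(L + 1, dtype=np.int64)
    for ev in all_insertions:
        if ev.eid in ref_own:
            ins_before[ev.anchor :] += ev.length

    def to_ref(pos: int) -> int:
        return int(prefix[pos] + ins_before[pos])

    features: list[FeatureRecord] = []
    fclass = {"cpCDS": "CDS", "cpNCDS": "tRNA", "cpIGS": None}
    for m in config.marker_plan:
        s, e = truth[m.name].interval
        cls = fclass[m.marker_class]
        if cls is None:
            continue
        rs, re = to_ref(s), to_ref(e)
        if re <= rs:
            warnings.warn(
                f"marker {m.name!r} deleted from the reference lineage",
                stacklevel=2,
            )
            continue
        features.append(
            FeatureRecord(gene_name=m.name, feature_class=cls, strand="+", parts=[(rs, re)])
        )

    reference = AnnotatedPlastome(
        sequence=GenomeSequence(id=ref_taxon, residues=ref_residues, circular=False),
        features=features,
    )
    return SyntheticDataset(
        reference=reference,
        alignment=alignment,
        true_tree=utree,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Planted quadripartite circles


def plant_quadripartite(
    total_length: int,
    ir_length: int | None = None,
    ssc_length: int | None = None,
    seed: int = 0,
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> GenomeSequence:
    """Random circular genome LSC + IRa + SSC + IRb with exact IR copies.

    IRb is the reverse complement of IRa.  Without an IR plan a plain random
    circle is returned.
    """
    rng = np.random.default_rng([int(seed), 23])

    def random_block(length: int) -> str:
        return "".join(
            _BASES[c] for c in rng.choice(4, size=length, p=base_composition)
        )

    if ir_length is None:
        return GenomeSequence(
            id="synthetic_circle",
            residues=random_block(total_length),
            circular=True,
        )
    if ssc_length is None:
        raise ValueError("ssc_length required when ir_length is given")
    lsc_length = total_length - ssc_length - 2 * ir_length
    if lsc_length < ssc_length:
        raise ValueError(
            "planned lengths exceed the total (LSC would be shorter than SSC)"
        )
    from .io import reverse_complement

    ira = random_block(ir_length)
    residues = list(
        random_block(lsc_length) + ira + random_block(ssc_length) + reverse_complement(ira)
    )
    # Break chance complement matches at the four region boundaries so the
    # planted repeat length is exact (the maximal pair cannot extend).
    comp = dict(zip("ACGT", "TGCA"))

    def decouple(x: int, y: int) -> None:
        if residues[x] == comp[residues[y]]:
            residues[x] = next(
                b for b in "ACGT" if b != comp[residues[y]] and b != residues[x]
            )

    a = lsc_length  # IRa start; IRb ends at the origin
    if lsc_length > 0:
        decouple(a - 1, 0)
    if ssc_length > 1:
        decouple(a + ir_length, a + ir_length + ssc_length - 1)
    return GenomeSequence(
        id="synthetic_plastome", residues="".join(residues), circular=True
    )
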