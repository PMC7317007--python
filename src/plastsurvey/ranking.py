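"""Marker ranking by weighted relative values, top-k datasets and primers.

Markers are ranked by a weighted mean of min-max-normalized metrics:
number of variable sites (weight 1), mean bootstrap support (weight 2) and
Robinson-Foulds distance to the whole-plastome tree (weight 3, inverted so
that a lower distance means more phylogenetic information).  Normalization
bounds may be derived from the ranked set or supplied explicitly.

The primer picker is a deliberately simplified design tool: it scans the
flanks of a target for 18-24 nt oligos under hard GC/Tm/homopolymer/product
constraints using the basic Wallace-style melting formula
Tm = 64.9 + 41 * (GC - 16.4) / length; it implements no nearest-neighbor
thermodynamics and no dimer checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import MarkerDefinition, MultipleAlignment, extract_marker
from .io import AnnotatedPlastome, GenomeSequence, reverse_complement

__all__ = [
    "RankingConfig",
    "MarkerMetrics",
    "RankedMarker",
    "PrimerPair",
    "PrimerConstraints",
    "rank_markers",
    "select_top",
    "concatenate_markers",
    "size_filter",
    "pick_primers",
    "locate_amplicon",
    "primer_tm",
    "primer_gc",
]


@dataclass
class RankingConfig:
    """Weights and normalization bounds for the relative-value score."""

    weight_variable: float = 1.0
    weight_bootstrap: float = 2.0
    weight_distance: float = 3.0
    # Optional explicit (min, max) bounds; None means derive from the set.
    variable_range: tuple[float, float] | None = None
    bootstrap_range: tuple[float, float] | None = None
    distance_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for w in (self.weight_variable, self.weight_bootstrap, self.weight_distance):
            if w <= 0:
                raise ValueError("weights must be positive")


@dataclass
class MarkerMetrics:
    """The per-marker metric bundle the ranking consumes."""

    name: str
    marker_class: str = ""
    mean_length: float | None = None
    aligned_length: int | None = None
    variable_sites: int | None = None
    parsimony_informative_sites: int | None = None
    gap_sites: int | None = None
    mean_k80: float | None = None
    tree_distance: float | None = None
    mean_bootstrap: float | None = None


@dataclass
class RankedMarker:
    name: str
    r_var: float
    r_bs: float
    r_dist: float
    score: float
    rank: int
    variable_sites: int


def _relative(value: float, lo: float, hi: float, invert: bool = False) -> float:
    if hi == lo:
        return 0.0
    r = (value - lo) / (hi - lo)
    return (1.0 - r) if invert else r


def rank_markers(
    metrics: list[MarkerMetrics], config: RankingConfig | None = None
) -> list[RankedMarker]:
    """Score and densely rank markers by the weighted relative-value mean.

    Markers missing any of the three metrics (typically because no tree
    could be built) are excluded with a warning.  Ties are broken by raw
    variable-site count, then by name.
    """
    config = config or RankingConfig()
    usable = []
    for m in metrics:
        if None in (m.variable_sites, m.mean_bootstrap, m.tree_distance):
            warnings.warn(
                f"marker {m.name!r} lacks a metric; excluded from ranking",
                stacklevel=2,
            )
            continue
        usable.append(m)
    if len(usable) < 2:
        raise ValueError("need at least 2 fully scored markers to rank")

    def bounds(values, given):
        return given if given is not None else (min(values), max(values))

    v_lo, v_hi = bounds([m.variable_sites for m in usable], config.variable_range)
    b_lo, b_hi = bounds([m.mean_bootstrap for m in usable], config.bootstrap_range)
    d_lo, d_hi = bounds([m.tree_distance for m in usable], config.distance_range)

    total_w = (
        config.weight_variable + config.weight_bootstrap + config.weight_distance
    )
    scored = []
    for m in usable:
        r_var = _relative(m.variable_sites, v_lo, v_hi)
        r_bs = _relative(m.mean_bootstrap, b_lo, b_hi)
        r_dist = _relative(m.tree_distance, d_lo, d_hi, invert=True)
        score = (
            config.weight_variable * r_var
            + config.weight_bootstrap * r_bs
            + config.weight_distance * r_dist
        ) / total_w
        scored.append((m, r_var, r_bs, r_dist, score))

    scored.sort(key=lambda t: (-t[4], -t[0].variable_sites, t[0].name))
    if len({round(t[4], 12) for t in scored}) == 1:
        warnings.warn("all scores equal; every marker gets rank 1", stacklevel=2)

    ranked: list[RankedMarker] = []
    rank = 0
    prev_score = None
    for m, r_var, r_bs, r_dist, score in scored:
        if prev_score is None or score < prev_score - 1e-12:
            rank += 1  # dense ranks: equal scores share a rank
            prev_score = score
        ranked.append(
            RankedMarker(
                name=m.name,
                r_var=r_var,
                r_bs=r_bs,
                r_dist=r_dist,
                score=score,
                rank=rank,
                variable_sites=m.variable_sites,
            )
        )
    return ranked


def select_top(ranked: list[RankedMarker], k: int) -> list[str]:
    """Names of the k best-ranked markers, in rank order."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the {len(ranked)} ranked markers")
    return [r.name for r in ranked[:k]]


def concatenate_markers(
    aln: MultipleAlignment, markers: list[MarkerDefinition]
) -> MultipleAlignment:
    """Column-wise concatenation of the markers, in the order given."""
    if not markers:
        raise ValueError("no markers to concatenate")
    index = np.concatenate(
        [
            np.concatenate([np.arange(s, e) for s, e in sorted(m.columns)])
            for m in markers
        ]
    )
    return aln.take_columns(index)


def size_filter(
    metrics: list[MarkerMetrics], max_len: float = 900.0
) -> list[MarkerMetrics]:
    """Keep markers whose mean ungapped length is below ``max_len`` bp."""
    return [m for m in metrics if m.mean_length is not None and m.mean_length < max_len]


# ---------------------------------------------------------------------------
# Primer picking


def primer_gc(oligo: str) -> float:
    """GC percentage of an oligo."""
    return 100.0 * sum(oligo.count(b) for b in "GC") / len(oligo)


def primer_tm(oligo: str) -> float:
    """Melting temperature, Tm = 64.9 + 41 * (#GC - 16.4) / length (degC)."""
    gc = sum(oligo.count(b) for b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(oligo)


@dataclass
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 24
    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 57.0
    tm_max: float = 63.0
    max_homopolymer: int = 4  # runs of 5+ identical bases are rejected
    max_product: int = 1100
    flank: int = 200


@dataclass
class PrimerPair:
    """A forward/reverse oligo pair bracketing a target region.

    The reverse primer is written 5'->3' on the opposite strand;
    ``reverse_site`` is its binding interval on the plus strand, and the
    product spans [forward_site.start, reverse_site.end).
    """

    forward: str
    reverse: str
    forward_site: tuple[int, int]
    reverse_site: tuple[int, int]
    forward_tm: float
    reverse_tm: float
    forward_gc: float
    reverse_gc: float
    product_size: int


def _has_homopolymer(oligo: str, max_run: int) -> bool:
    run, prev = 0, ""
    for ch in oligo:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > max_run:
            return True
    return False


def _candidate_ok(oligo: str, c: PrimerConstraints, tally: dict) -> bool:
    ok = True
    if not (c.gc_min <= primer_gc(oligo) <= c.gc_max):
        tally["gc"] += 1
        ok = False
    if not (c.tm_min <= primer_tm(oligo) <= c.tm_max):
        tally["tm"] += 1
        ok = False
    if _has_homopolymer(oligo, c.max_homopolymer):
        tally["homopolymer"] += 1
        ok = False
    if set(oligo) - set("ACGT"):
        tally["ambiguity"] += 1
        ok = False
    return ok


def _score(oligo: str) -> float:
    return abs(primer_tm(oligo) - 60.0) + abs(primer_gc(oligo) - 50.0) / 10.0


def pick_primers(
    reference: AnnotatedPlastome | GenomeSequence,
    target: tuple[int, int],
    constraints: PrimerConstraints | None = None,
) -> tuple[PrimerPair | None, dict]:
    """Best feasible primer pair flanking a target interval, or None.

    All plus-strand substrings of length 18-24 in the upstream flank are
    forward candidates; reverse candidates are reverse complements of
    substrings in the downstream flank.  Candidates are scored by
    |Tm - 60| + |GC - 50| / 10 under hard GC, Tm, homopolymer and
    product-size constraints, and the pair minimizing the summed score whose
    product fully contains the target wins.  Returns (pair, failure_tally);
    the tally explains infeasibility when no pair exists.
    """
    c = constraints or PrimerConstraints()
    seq = reference.sequence if isinstance(reference, AnnotatedPlastome) else reference
    residues = seq.residues
    n = len(residues)
    t_start, t_end = target
    if not (0 <= t_start < t_end <= n):
        raise ValueError(f"target [{t_start}, {t_end}) outside reference")

    tally = {"gc": 0, "tm": 0, "homopolymer": 0, "ambiguity": 0, "product": 0}

    fwd: list[tuple[float, int, int, str]] = []  # (score, start, end, oligo)
    lo = max(0, t_start - c.flank)
    for start in range(lo, t_start):
        for length in range(c.min_len, c.max_len + 1):
            end = start + length
            if end > t_start:
                break
            oligo = residues[start:end]
            if _candidate_ok(oligo, c, tally):
                fwd.append((_score(oligo), start, end, oligo))

    rev: list[tuple[float, int, int, str]] = []  # binding site on plus strand
    hi = min(n, t_end + c.flank)
    for end in range(t_end + c.min_len, hi + 1):
        for length in range(c.min_len, c.max_len + 1):
            start = end - length
            if start < t_end:
                break
            site = residues[start:end]
            oligo = reverse_complement(site)
            if _candidate_ok(oligo, c, tally):
                rev.append((_score(oligo), start, end, oligo))

    if not fwd or not rev:
        return None, tally

    # For each forward candidate the product constraint caps the reverse
    # end; sweep reverse candidates by end with a running best.
    rev.sort(key=lambda t: (t[2], t[0], t[1]))
    rev_ends = [r[2] for r in rev]
    best_upto: list[tuple[float, int, int, str]] = []
    best = None
    for r in rev:
        if best is None or (r[0], r[1], r[2]) < (best[0], best[1], best[2]):
            best = r
        best_upto.append(best)

    winner = None
    feasible = False
    for fs_score, fs, fe, foligo in sorted(fwd):
        cap = fs + c.max_product
        k = np.searchsorted(rev_ends, cap, side="right") - 1
        if k < 0:
            continue
        feasible = True
        r_score, rs, re, roligo = best_upto[k]
        total = fs_score + r_score
        cand = (total, fs, rs, fe, re, foligo, roligo)
        if winner is None or cand < winner:
            winner = cand
    if winner is None:
        if not feasible:
            tally["product"] += 1
        return None, tally

    total, fs, rs, fe, re, foligo, roligo = winner
    return (
        PrimerPair(
            forward=foligo,
            reverse=roligo,
            forward_site=(fs, fe),
            reverse_site=(rs, re),
            forward_tm=primer_tm(foligo),
            reverse_tm=primer_tm(roligo),
            forward_gc=primer_gc(foligo),
            reverse_gc=primer_gc(roligo),
            product_size=re - fs,
        ),
        tally,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return out
        out.append(pos)
        start = pos + 1


def locate_amplicon(
    reference: GenomeSequence | AnnotatedPlastome, forward: str, reverse: str
) -> int:
    """Expected product size of a primer pair on a reference sequence.

    The forward primer must occur exactly once on the plus strand and the
    reverse complement of the reverse primer exactly once downstream of it;
    the product counts both primers.
    """
    seq = reference.sequence if isinstance(reference, AnnotatedPlastome) else reference
    residues = seq.residues.upper()
    fhits = _find_all(residues, forward.upper())
    rhits = _find_all(residues, reverse_complement(reverse.upper()))
    if len(fhits) != 1 or len(rhits) != 1:
        raise ValueError(
            f"expected exactly one binding site per primer; "
            f"forward matches {len(fhits)}, reverse matches {len(rhits)}"
        )
    f_start = fhits[0]
    r_end = rhits[0] + len(reverse)
    if r_end <= f_start:
        raise ValueError("reverse binding site is not downstream of forward")
    return r_end - f_start
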