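"""Per-alignment sequence-diversity statistics.

Variable and parsimony-informative sites, Kimura two-parameter (K80)
pairwise distances, nucleotide diversity (pi) and its sliding-window track.

Gap handling is pairwise deletion throughout: each pair of rows is compared
over the columns where both carry an unambiguous A/C/G/T.  Ambiguity codes
are treated as missing, never expanded fractionally.  This differs from the
complete-deletion default of DnaSP; see the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP_CODE, MultipleAlignment, encode_row

__all__ = [
    "SiteClassCounts",
    "PairwiseCounts",
    "WindowTrack",
    "UndefinedDistanceError",
    "SaturationError",
    "site_classes",
    "pairwise_counts",
    "k80_distance",
    "k80_from_counts",
    "mean_k80",
    "nucleotide_diversity",
    "sliding_window_pi",
]


class UndefinedDistanceError(ValueError):
    """No comparable sites between two rows."""


class SaturationError(ValueError):
    """Divergence beyond the domain of the K80 correction."""


@dataclass
class SiteClassCounts:
    aligned_length: int
    variable_sites: int
    parsimony_informative_sites: int
    gap_sites: int
    mean_ungapped_length: float
    min_ungapped_length: int
    max_ungapped_length: int


@dataclass
class PairwiseCounts:
    """Transition/transversion tallies over the sites compared in one pair."""

    compared_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites


@dataclass
class WindowTrack:
    window_length: int
    step: int
    windows: list[tuple[int, float, float]] = field(default_factory=list)
    # each entry: (start column, midpoint column, pi)


def _codes_of(x) -> np.ndarray:
    if isinstance(x, str):
        return encode_row(x)
    return np.asarray(x, dtype=np.int8)


def site_classes(aln: MultipleAlignment) -> SiteClassCounts:
    """Census every column for variability, parsimony informativeness, gaps.

    Gaps and ambiguities are excluded from state counting.  A column is
    variable iff at least two distinct unambiguous states remain, and
    parsimony-informative iff at least two states are each carried by at
    least two taxa.
    """
    if aln.width == 0:
        raise ValueError("zero-width alignment")
    codes = aln.codes()
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    distinct = (counts > 0).sum(axis=0)
    variable = int((distinct >= 2).sum())
    pis = int(((counts >= 2).sum(axis=0) >= 2).sum())
    gap_sites = int((codes == GAP_CODE).any(axis=0).sum())
    ungapped = (codes != GAP_CODE).sum(axis=1)
    return SiteClassCounts(
        aligned_length=aln.width,
        variable_sites=variable,
        parsimony_informative_sites=pis,
        gap_sites=gap_sites,
        mean_ungapped_length=float(ungapped.mean()),
        min_ungapped_length=int(ungapped.min()),
        max_ungapped_length=int(ungapped.max()),
    )


def pairwise_counts(row_i, row_j) -> PairwiseCounts:
    """Compared sites and transition/transversion counts for one row pair.

    Sites where either row carries a gap or ambiguity are excluded.
    Transitions are the purine-purine and pyrimidine-pyrimidine changes
    (A<->G, C<->T); everything else is a transversion.
    """
    a, b = _codes_of(row_i), _codes_of(row_j)
    if a.shape != b.shape:
        raise ValueError("rows have unequal lengths")
    valid = (a < 4) & (b < 4)
    x = (a ^ b)[valid]
    length = int(valid.sum())
    transitions = int((x == 2).sum())  # A^G == C^T == 2 under the 0..3 coding
    diffs = int((x != 0).sum())
    return PairwiseCounts(
        compared_sites=length,
        transitions=transitions,
        transversions=diffs - transitions,
    )


def k80_from_counts(transitions: int, transversions: int, length: int) -> float:
    """K80 distance from raw counts: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    if length == 0:
        raise UndefinedDistanceError("no comparable sites")
    P = transitions / length
    Q = transversions / length
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(
            f"K80 correction undefined at P={P:.4g}, Q={Q:.4g}"
        )
    return (-0.5 * math.log(a) - 0.25 * math.log(b)) + 0.0


def k80_distance(row_i, row_j) -> float:
    """Pairwise K80 distance (substitutions/site) with pairwise deletion."""
    c = pairwise_counts(row_i, row_j)
    return k80_from_counts(c.transitions, c.transversions, c.compared_sites)


def mean_k80(aln: MultipleAlignment) -> float | None:
    """Mean K80 distance over unordered pairs; saturated pairs are skipped.

    Returns None when no pair has a defined distance.
    """
    codes = aln.codes()
    values = []
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            try:
                values.append(k80_distance(codes[i], codes[j]))
            except (SaturationError, UndefinedDistanceError):
                continue
    return float(np.mean(values)) if values else None


def nucleotide_diversity(aln: MultipleAlignment) -> float | None:
    """pi: mean over unordered pairs of (differences / compared sites).

    Pairwise deletion of gapped/ambiguous sites; pairs with no comparable
    sites are skipped, and None is returned if no pair is comparable.
    """
    codes = aln.codes()
    ratios = []
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            valid = (codes[i] < 4) & (codes[j] < 4)
            compared = int(valid.sum())
            if compared == 0:
                continue
            diffs = int(((codes[i] != codes[j]) & valid).sum())
            ratios.append(diffs / compared)
    return float(np.mean(ratios)) if ratios else None


def sliding_window_pi(
    aln: MultipleAlignment, window: int = 800, step: int = 200
) -> WindowTrack:
    """pi in windows of ``window`` columns advanced by ``step`` columns.

    Windows start at columns 0, step, 2*step, ... while the full window fits;
    the final partial window is dropped.  If the alignment is narrower than
    one window, a single whole-alignment window is returned with a warning.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    track = WindowTrack(window_length=window, step=step)
    if aln.width < window:
        warnings.warn(
            f"alignment width {aln.width} < window {window}; "
            "falling back to a single whole-alignment window",
            stacklevel=2,
        )
        pi = nucleotide_diversity(aln)
        track.windows.append(
            (0, aln.width / 2.0, math.nan if pi is None else pi)
        )
        return track
    codes = aln.codes()
    for start in range(0, aln.width - window + 1, step):
        sub = codes[:, start : start + window]
        pi = _pi_codes(sub)
        track.windows.append(
            (start, start + window / 2.0, math.nan if pi is None else pi)
        )
    return track


def _pi_codes(codes: np.ndarray) -> float | None:
    n = codes.shape[0]
    ratios = []
    for i in range(n):
        vi = codes[i] < 4
        for j in range(i + 1, n):
            valid = vi & (codes[j] < 4)
            compared = int(valid.sum())
            if compared == 0:
                continue
            diffs = int(((codes[i] != codes[j]) & valid).sum())
            ratios.append(diffs / compared)
    return float(np.mean(ratios)) if ratios else None
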