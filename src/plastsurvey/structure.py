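"""Quadripartite plastome architecture, composition and pseudogene screen.

A canonical plastome is a circle of four regions: the large and small
single-copy regions (LSC, SSC) separated by two exact reverse-complement
copies of the same block (IRa, IRb).  :func:`find_inverted_repeat` locates
the maximal such pair by seed-and-extend on k-mer matches against the
reverse complement, requiring exact identity between the copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotatedPlastome, GenomeSequence, reverse_complement

__all__ = [
    "RegionPartition",
    "GeneInventory",
    "PseudogeneReport",
    "find_inverted_repeat",
    "gc_content",
    "gene_inventory",
    "composition_table",
    "screen_pseudogene",
]

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

REGIONS = ("LSC", "SSC", "IRa", "IRb")

# Plastid (bacterial-style) genetic code essentials.
START_CODONS = frozenset({"ATG", "GTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class RegionPartition:
    """The four structural intervals covering the circular genome.

    Intervals are 0-based half-open (start, end); ``end <= start`` denotes
    wrapping through the origin.  ``degenerate`` is set when no inverted
    repeat of the requested size exists and the whole genome is reported as
    LSC.
    """

    genome_length: int
    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    irb: tuple[int, int]
    ir_length: int
    degenerate: bool = False

    def lengths(self) -> dict[str, int]:
        n = self.genome_length
        if self.degenerate:
            return {"LSC": n, "SSC": 0, "IRa": 0, "IRb": 0}

        def ln(iv):
            return (iv[1] - iv[0]) % n

        return {
            "LSC": ln(self.lsc),
            "SSC": ln(self.ssc),
            "IRa": self.ir_length,
            "IRb": self.ir_length,
        }

    def region_ids(self) -> np.ndarray:
        """Per-position region index into REGIONS; LSC everywhere if degenerate."""
        n = self.genome_length
        ids = np.zeros(n, dtype=np.int8)
        if self.degenerate:
            return ids

        lens = self.lengths()

        def fill(iv, code, length):
            if length == 0:
                return
            s, e = iv
            if e > s:
                ids[s:e] = code
            else:  # wraps
                ids[s:] = code
                ids[:e] = code

        fill(self.lsc, 0, lens["LSC"])
        fill(self.ssc, 1, lens["SSC"])
        fill(self.ira, 2, lens["IRa"])
        fill(self.irb, 3, lens["IRb"])
        return ids

    def validate(self, seq: GenomeSequence) -> None:
        """Assert the structural invariants against the actual sequence."""
        n = self.genome_length
        if n != len(seq):
            raise ValueError("partition built for a different genome length")
        lens = self.lengths()
        if sum(lens.values()) != n:
            raise ValueError("regions do not cover the genome exactly")
        if lens["LSC"] < lens["SSC"]:
            raise ValueError("|LSC| < |SSC|")
        if not self.degenerate:
            ira = seq.slice_circular(*self.ira)
            irb = seq.slice_circular(*self.irb)
            if ira != reverse_complement(irb):
                raise ValueError("IRa is not the reverse complement of IRb")


def gc_content(residues: str) -> float:
    """Fraction of G+C (plus the S ambiguity) over unambiguous positions.

    The denominator counts A, C, G, T plus the two-state codes S (G/C) and
    W (A/T), whose GC contribution is unambiguous.
    """
    if not residues:
        raise ValueError("empty residue string")
    up = residues.upper()
    gc = sum(up.count(b) for b in "GCS")
    denom = sum(up.count(b) for b in "ACGTSW")
    if denom == 0:
        raise ValueError("no unambiguous positions for GC content")
    return gc / denom


# ---------------------------------------------------------------------------
# Inverted-repeat detection


def _diagonal_run(s: str, comp: str, n: int, c: int, p0: int) -> tuple[int, int]:
    """Maximal circular run of positions p around p0 with s[p] == comp[(c-p) % n].

    Returns (a, m): run start and length (m == n means the whole circle).
    """
    # extend left
    a = p0
    m = 1
    while m < n:
        q = (a - 1) % n
        if s[q] == comp[(c - q) % n]:
            a = q
            m += 1
        else:
            break
    # extend right
    b = p0
    while m < n:
        q = (b + 1) % n
        if s[q] == comp[(c - q) % n]:
            b = q
            m += 1
        else:
            break
    return a, m


def find_inverted_repeat(
    seq: GenomeSequence, min_len: int = 1000, k: int = 21
) -> RegionPartition:
    """Locate the maximal exact inverted-repeat pair on a circular genome.

    Seed-and-extend: k-mers of the sequence are matched against reverse
    complements of k-mers, seeds are grouped by their anti-diagonal
    (i + j constant on the circle) and extended maximally in both
    directions.  Exact identity is required between the two copies.  The
    longer gap between the copies is labeled LSC, the shorter SSC, and the
    repeat copy immediately following the LSC is IRa.  Ties between equal
    maximal pairs are broken by minimal SSC length, then by the smallest
    start coordinate.  If no pair of length >= min_len exists, a degenerate
    partition (whole genome as LSC) is returned with a warning.
    """
    if not seq.circular:
        raise ValueError("inverted-repeat search requires a circular sequence")
    if min_len < 100:
        raise ValueError("min_len must be >= 100")
    n = len(seq)
    s = seq.residues
    comp = s.translate(_COMP)

    def degenerate() -> RegionPartition:
        warnings.warn(
            f"no inverted repeat of length >= {min_len} found", stacklevel=2
        )
        return RegionPartition(
            genome_length=n,
            lsc=(0, n),
            ssc=(0, 0),
            ira=(0, 0),
            irb=(0, 0),
            ir_length=0,
            degenerate=True,
        )

    if n < 2 * min_len or n < k:
        return degenerate()

    s2 = s + s[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(s2[i : i + k], []).append(i)

    candidates: dict[tuple[int, int, int], None] = {}
    seen: set[tuple[int, int]] = set()
    for j in range(n):
        rc = reverse_complement(s2[j : j + k])
        for i in index.get(rc, ()):
            c = (i + j + k - 1) % n
            if (c, i) in seen:
                continue
            a, m = _diagonal_run(s, comp, n, c, i)
            for p in range(m):
                seen.add((c, (a + p) % n))
            if m >= n:  # whole circle self-complementary; no usable pair
                continue
            mirror_a = (c - ((a + m - 1) % n)) % n
            if mirror_a == a:  # palindromic run holds both copies
                half = m // 2
                if half < min_len:
                    continue
                i1, i2 = a, (a + m - half) % n
                length = half
            else:
                if m < min_len:
                    continue
                i1, i2 = sorted((a, mirror_a))
                length = m
            key = (min(i1, i2), max(i1, i2), length)
            candidates[key] = None

    usable = []
    for i1, i2, length in candidates:
        if 2 * length > n:
            continue
        gap1 = (i2 - (i1 + length)) % n
        gap2 = (i1 - (i2 + length)) % n
        if gap1 < 0 or gap2 < 0:
            continue
        usable.append((length, min(gap1, gap2), i1, i2, gap1, gap2))
    if not usable:
        return degenerate()

    usable.sort(key=lambda t: (-t[0], t[1], t[2]))
    length, _, i1, i2, gap1, gap2 = usable[0]

    copy_a = (i1, (i1 + length) % n)
    copy_b = (i2, (i2 + length) % n)
    # gap1 follows copy_a; gap2 follows copy_b
    if gap1 >= gap2:
        lsc = (copy_a[1], i2)
        ssc = (copy_b[1], i1)
        ira, irb = copy_b, copy_a  # IRa follows the LSC
        lsc_len, ssc_len = gap1, gap2
    else:
        lsc = (copy_b[1], i1)
        ssc = (copy_a[1], i2)
        ira, irb = copy_a, copy_b
        lsc_len, ssc_len = gap2, gap1
    part = RegionPartition(
        genome_length=n,
        lsc=lsc,
        ssc=ssc,
        ira=ira,
        irb=irb,
        ir_length=length,
    )
    part.validate(seq)
    return part


# ---------------------------------------------------------------------------
# Gene inventory / composition table


@dataclass
class GeneInventory:
    """Region-by-class gene counts, with pseudogenes tallied separately."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    pseudogene_counts: dict[str, int] = field(default_factory=dict)

    def class_total(self, feature_class: str) -> int:
        return sum(
            v for (_, cls), v in self.counts.items() if cls == feature_class
        )

    def region_total(self, region: str) -> int:
        return sum(v for (reg, _), v in self.counts.items() if reg == region)

    @property
    def total_genes(self) -> int:
        return sum(self.counts.values())

    @property
    def total_pseudogenes(self) -> int:
        return sum(self.pseudogene_counts.values())


_COUNTED_CLASSES = ("CDS", "tRNA", "rRNA")


def gene_inventory(
    plastome: AnnotatedPlastome, partition: RegionPartition
) -> GeneInventory:
    """Assign each gene to the region holding the majority of its bases.

    Introns and misc features are excluded; genes duplicated in the two IR
    copies count once per copy; pseudogenes are counted within their class
    and tallied separately per region.
    """
    ids = partition.region_ids()
    inv = GeneInventory()
    for region in REGIONS:
        for cls in _COUNTED_CLASSES:
            inv.counts.setdefault((region, cls), 0)
        inv.pseudogene_counts.setdefault(region, 0)
    for feat in plastome.features:
        if feat.feature_class not in _COUNTED_CLASSES:
            continue
        per_region = np.zeros(4, dtype=np.int64)
        for s, e in feat.parts:
            per_region += np.bincount(ids[s:e], minlength=4)
        touched = int((per_region > 0).sum())
        if touched > 2:
            warnings.warn(
                f"gene {feat.gene_name!r} spans {touched} regions; "
                "assigned by majority rule",
                stacklevel=2,
            )
        region = REGIONS[int(per_region.argmax())]
        inv.counts[(region, feat.feature_class)] += 1
        if feat.pseudogene:
            inv.pseudogene_counts[region] += 1
    return inv


def composition_table(
    plastome: AnnotatedPlastome, partition: RegionPartition
) -> pd.DataFrame:
    """Per-region size, GC% and gene counts, plus a whole-genome row."""
    seq = plastome.sequence
    inv = gene_inventory(plastome, partition)
    lens = partition.lengths()
    intervals = {
        "LSC": partition.lsc,
        "SSC": partition.ssc,
        "IRa": partition.ira,
        "IRb": partition.irb,
    }
    rows = [
        {
            "region": "Genome",
            "size_bp": len(seq),
            "gc_pct": round(100 * gc_content(seq.residues), 1),
            "genes": inv.total_genes,
            "pseudogenes": inv.total_pseudogenes,
            "cds": inv.class_total("CDS"),
            "trna": inv.class_total("tRNA"),
            "rrna": inv.class_total("rRNA"),
        }
    ]
    for region in REGIONS:
        residues = (
            seq.slice_circular(*intervals[region]) if lens[region] else ""
        )
        rows.append(
            {
                "region": region,
                "size_bp": lens[region],
                "gc_pct": (
                    round(100 * gc_content(residues), 1) if residues else None
                ),
                "genes": inv.region_total(region),
                "pseudogenes": inv.pseudogene_counts[region],
                "cds": inv.counts[(region, "CDS")],
                "trna": inv.counts[(region, "tRNA")],
                "rrna": inv.counts[(region, "rRNA")],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pseudogene screen


@dataclass
class PseudogeneReport:
    """Why a spliced CDS fails to form its full coding sequence."""

    gene_name: str
    reasons: frozenset[str]

    @property
    def flagged(self) -> bool:
        return bool(self.reasons)


def screen_pseudogene(
    cds_residues: str,
    gene_name: str = "",
    expected_length: int | None = None,
) -> PseudogeneReport:
    """Screen a spliced, strand-oriented CDS for coding-structure defects.

    Reasons: ``internal_stop`` (an in-frame stop before the final codon),
    ``length_not_multiple_of_3``, ``missing_start`` (first codon not ATG/GTG
    under the plastid code), ``missing_stop`` (final codon not a stop).
    When an expected full-length is supplied, an observed open reading frame
    shorter than half of it adds ``small_orf``; without it that criterion is
    not applied.
    """
    if "-" in cds_residues:
        raise ValueError("CDS residues must be ungapped")
    if not cds_residues:
        raise ValueError("empty CDS")
    up = cds_residues.upper()
    reasons: set[str] = set()
    if len(up) % 3 != 0:
        reasons.add("length_not_multiple_of_3")
    codons = [up[i : i + 3] for i in range(0, len(up) - 2, 3)]
    if not codons:
        return PseudogeneReport(gene_name, frozenset({"length_not_multiple_of_3"}))
    if codons[0] not in START_CODONS:
        reasons.add("missing_start")
    if codons[-1] not in STOP_CODONS:
        reasons.add("missing_stop")
    internal = [i for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]
    if internal:
        reasons.add("internal_stop")
    if expected_length is not None:
        orf_codons = (internal[0] + 1) if internal else len(codons)
        if 3 * orf_codons < 0.5 * expected_length:
            reasons.add("small_orf")
    return PseudogeneReport(gene_name, frozenset(reasons))
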