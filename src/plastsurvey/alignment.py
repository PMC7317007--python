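"""Whole-plastome alignment handling: masking, coordinate maps, markers.

The alignment itself is an input (computed elsewhere, e.g. with MAFFT); this
module masks heavily gapped/ambiguous columns, maps ungapped reference
positions to alignment columns, and cuts the alignment into the three marker
classes: protein-coding sequences (cpCDS, pseudogenes included), non-coding
genic regions (cpNCDS: tRNA/rRNA genes and full spans of intron-containing
genes), and intergenic spacers (cpIGS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "MultipleAlignment",
    "ColumnMap",
    "MarkerDefinition",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "mask_columns",
    "build_column_map",
    "partition_markers",
    "extract_marker",
    "marker_usable",
]

# Residue codes: A=0 C=1 G=2 T=3, gap=4, anything else (ambiguity)=5.
GAP_CODE = 4
AMBIG_CODE = 5

_CODE_TABLE = np.full(256, AMBIG_CODE, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i  # lower case
_CODE_TABLE[ord("-")] = GAP_CODE


def encode_row(row: str) -> np.ndarray:
    """Encode a residue string as int8 codes (A=0..T=3, gap=4, ambig=5)."""
    return _CODE_TABLE[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


@dataclass
class MultipleAlignment:
    """Taxa-by-columns residue matrix over IUPAC codes plus ``-``."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("an alignment needs at least 2 taxa")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(widths)}")
        self._codes: np.ndarray | None = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """(n_taxa, width) int8 code matrix; cached."""
        if self._codes is None:
            self._codes = (
                np.vstack([encode_row(r) for r in self.rows])
                if self.width
                else np.zeros((self.n_taxa, 0), dtype=np.int8)
            )
        return self._codes

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def take_columns(self, index: np.ndarray) -> "MultipleAlignment":
        """New alignment from the given column indices (order preserved)."""
        codes = self.codes()[:, index]
        return MultipleAlignment(
            taxa=list(self.taxa),
            rows=["".join(r) for r in _decode_matrix(codes, self.rows, index)],
        )


def _decode_matrix(codes, rows, index):
    # Decoding must preserve the original characters (ambiguity codes are
    # retained, not collapsed), so slice the source strings directly.
    idx = np.asarray(index)
    for row in rows:
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        yield arr[idx].tobytes().decode("ascii")


def read_alignment_fasta(path) -> MultipleAlignment:
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MultipleAlignment(taxa=taxa, rows=rows)


def write_alignment_fasta(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Masking


def mask_columns(
    aln: MultipleAlignment, threshold: float = 0.8
) -> tuple[MultipleAlignment, np.ndarray]:
    """Strip columns whose gap+ambiguity fraction exceeds ``threshold``.

    Returns the masked alignment and the removed column indices (for
    coordinate bookkeeping).  A column is removed iff
    ``(gaps + ambiguities) / n_taxa > threshold`` — strictly greater, so at
    the default 0.8 a 17-taxon column needs 14 or more bad characters.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    codes = aln.codes()
    bad_frac = (codes >= GAP_CODE).sum(axis=0) / aln.n_taxa
    removed = np.flatnonzero(bad_frac > threshold)
    kept = np.flatnonzero(bad_frac <= threshold)
    if kept.size == 0:
        warnings.warn("masking removed every column", stacklevel=2)
        return (
            MultipleAlignment(taxa=list(aln.taxa), rows=[""] * aln.n_taxa),
            removed,
        )
    return aln.take_columns(kept), removed


# ---------------------------------------------------------------------------
# Reference-to-column map


@dataclass
class ColumnMap:
    """Monotone map from ungapped reference positions to alignment columns.

    ``positions[i]`` is the alignment column holding the (i+1)-th non-gap
    character of the reference row, or -1 if that position was lost to
    masking (see :meth:`after_masking`).
    """

    ref_taxon: str
    positions: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def columns_of(self, start: int, end: int) -> tuple[int, int] | None:
        """Image of reference interval [start, end) as one column interval.

        Returns None when every position in the interval was masked away.
        """
        sub = self.positions[start:end]
        alive = sub[sub >= 0]
        if alive.size == 0:
            return None
        return int(alive.min()), int(alive.max()) + 1

    def after_masking(self, removed: np.ndarray, old_width: int) -> "ColumnMap":
        """Compose with a masking step: re-index into the masked alignment.

        Reference positions whose column was removed map to -1.
        """
        removed = np.asarray(removed, dtype=np.int64)
        keep_mask = np.ones(old_width, dtype=bool)
        keep_mask[removed] = False
        new_index = np.cumsum(keep_mask) - 1  # old column -> new column
        out = np.where(
            (self.positions >= 0) & keep_mask[self.positions],
            new_index[self.positions],
            -1,
        )
        return ColumnMap(ref_taxon=self.ref_taxon, positions=out)


def build_column_map(aln: MultipleAlignment, ref_taxon: str) -> ColumnMap:
    """Column of each non-gap reference character, strictly increasing."""
    if ref_taxon not in aln.taxa:
        raise ValueError(f"reference taxon {ref_taxon!r} not in alignment")
    row = encode_row(aln.row(ref_taxon))
    positions = np.flatnonzero(row != GAP_CODE)
    if positions.size == 0:
        raise ValueError(f"reference row {ref_taxon!r} is all gaps")
    return ColumnMap(ref_taxon=ref_taxon, positions=positions)


# ---------------------------------------------------------------------------
# Marker partition


@dataclass
class MarkerDefinition:
    """A named set of alignment column intervals with its marker class."""

    name: str
    marker_class: str  # cpCDS, cpNCDS or cpIGS
    columns: list[tuple[int, int]] = field(default_factory=list)

    _CLASSES = frozenset({"cpCDS", "cpNCDS", "cpIGS"})

    def __post_init__(self) -> None:
        if self.marker_class not in self._CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")
        if sum(e - s for s, e in self.columns) <= 0:
            raise ValueError(f"marker {self.name!r} has no columns")
        ivs = sorted(self.columns)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"marker {self.name!r}: overlapping intervals")

    @property
    def n_columns(self) -> int:
        return sum(e - s for s, e in self.columns)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.columns)


def _merge_touching(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _unique_name(name: str, used: set[str]) -> str:
    out, i = name, 2
    while out in used:
        out = f"{name}_{i}"
        i += 1
    used.add(out)
    return out


def partition_markers(plastome, cmap: ColumnMap) -> list[MarkerDefinition]:
    """Cut the alignment into cpCDS / cpNCDS / cpIGS markers.

    The plastome must be the reference the column map was built on (with one
    inverted-repeat copy already stripped, so each marker appears once).
    cpCDS: one marker per CDS feature, pseudogenes included.  cpNCDS: one per
    tRNA or rRNA gene, plus the full exon+intron span of every
    intron-containing gene (e.g. the trnK gene region spanning matK).  cpIGS:
    one per maximal reference interval not covered by any feature span,
    named "upstream-downstream" after the flanking genes; abutting features
    leave no spacer.  On a circular reference the spacer wrapping the origin
    is emitted as a single final marker with two column intervals.
    """
    ref_len = len(cmap)
    if ref_len != len(plastome.sequence):
        raise ValueError(
            f"column map covers {ref_len} positions but the reference is "
            f"{len(plastome.sequence)} bp — was it built on this plastome?"
        )

    def image(parts) -> list[tuple[int, int]]:
        out = []
        for s, e in parts:
            if e > ref_len:
                raise ValueError(f"feature part [{s}, {e}) outside reference")
            iv = cmap.columns_of(s, e)
            if iv is not None:
                out.append(iv)
        return _merge_touching(out)

    markers: list[MarkerDefinition] = []
    used_cds: set[str] = set()
    used_ncds: set[str] = set()

    ordered = sorted(plastome.features, key=lambda f: f.span)
    for feat in ordered:
        if feat.feature_class == "CDS":
            cols = image(feat.parts)
            if cols:
                markers.append(
                    MarkerDefinition(
                        name=_unique_name(feat.gene_name, used_cds),
                        marker_class="cpCDS",
                        columns=cols,
                    )
                )
            if len(feat.parts) > 1:  # intron-containing gene: full span
                cols = image([feat.span])
                if cols:
                    markers.append(
                        MarkerDefinition(
                            name=_unique_name(feat.gene_name, used_ncds),
                            marker_class="cpNCDS",
                            columns=cols,
                        )
                    )
        elif feat.feature_class in {"tRNA", "rRNA"}:
            cols = image([feat.span])
            if cols:
                markers.append(
                    MarkerDefinition(
                        name=_unique_name(feat.gene_name, used_ncds),
                        marker_class="cpNCDS",
                        columns=cols,
                    )
                )

    # Intergenic spacers: complement of all feature spans on the reference.
    spans = _merge_touching([f.span for f in plastome.features])
    used_igs: set[str] = set()

    def flank_names(pos_before: int, pos_after: int) -> tuple[str, str]:
        up = next(
            (f.gene_name for f in reversed(ordered) if f.span[1] == pos_before),
            "start",
        )
        down = next(
            (f.gene_name for f in ordered if f.span[0] == pos_after), "end"
        )
        return up, down

    gaps: list[tuple[int, int]] = []
    prev = 0
    for s, e in spans:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < ref_len:
        gaps.append((prev, ref_len))

    circular = getattr(plastome.sequence, "circular", False)
    wrap_pair = None
    if circular and len(gaps) >= 2 and gaps[0][0] == 0 and gaps[-1][1] == ref_len:
        wrap_pair = (gaps[-1], gaps[0])
        gaps = gaps[1:-1]

    for s, e in gaps:
        up, down = flank_names(s, e)
        cols = image([(s, e)])
        if cols:
            markers.append(
                MarkerDefinition(
                    name=_unique_name(f"{up}-{down}", used_igs),
                    marker_class="cpIGS",
                    columns=cols,
                )
            )
    if wrap_pair is not None:
        (s1, e1), (s2, e2) = wrap_pair
        up = next((f.gene_name for f in reversed(ordered) if f.span[1] == s1), "start")
        down = next((f.gene_name for f in ordered if f.span[0] == e2), "end")
        cols = image([(s1, e1)]) + image([(s2, e2)])
        if cols:
            markers.append(
                MarkerDefinition(
                    name=_unique_name(f"{up}-{down}", used_igs),
                    marker_class="cpIGS",
                    columns=cols,
                )
            )

    markers.sort(key=lambda m: (m.start, m.marker_class, m.name))
    return markers


def extract_marker(aln: MultipleAlignment, marker: MarkerDefinition) -> MultipleAlignment:
    """Sub-alignment of the marker's columns, taxa order preserved."""
    if marker.columns and max(e for _, e in marker.columns) > aln.width:
        raise ValueError(
            f"marker {marker.name!r} extends past alignment width {aln.width}"
        )
    index = np.concatenate(
        [np.arange(s, e) for s, e in sorted(marker.columns)]
    )
    return aln.take_columns(index)


def marker_usable(
    aln: MultipleAlignment, marker: MarkerDefinition, min_taxa: int = 4
) -> bool:
    """Whether enough taxa have any residue in the marker to build a tree.

    Trees on fewer than 4 taxa have no internal edges, so such markers are
    excluded from tree-based metrics.
    """
    sub = extract_marker(aln, marker)
    ungapped = (sub.codes() != GAP_CODE).sum(axis=1)
    return int((ungapped > 0).sum()) >= min_taxa
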