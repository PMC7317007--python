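"""Readers and writers for the formats the pipeline touches.

GenBank flat files and FASTA go through Biopython; newick goes through
dendropy (wrapped by :class:`~plastsurvey.phylo.UnrootedTree`); tabular
reports are written as TSV via pandas.  All internal coordinates are
0-based half-open; GenBank's 1-based inclusive locations are converted at
this boundary and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter

from .phylo import UnrootedTree

__all__ = [
    "GenomeSequence",
    "FeatureRecord",
    "AnnotatedPlastome",
    "GenBankParseError",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "write_tsv",
    "reverse_complement",
]

# IUPAC nucleotide codes (ambiguities retained, never converted to N).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(residues: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return residues.translate(_COMPLEMENT)[::-1]


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be interpreted."""


@dataclass(frozen=True)
class GenomeSequence:
    """A plastome (or plastome-like) nucleotide sequence.

    Residues are upper-case IUPAC codes; gap characters are illegal here —
    gapped rows belong in a :class:`~plastsurvey.alignment.MultipleAlignment`.
    """

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has zero length")
        bad = set(self.residues) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice_circular(self, start: int, end: int) -> str:
        """Substring of the (possibly wrapping) interval [start, end).

        ``end <= start`` denotes an interval wrapping through the origin;
        only legal on circular sequences.
        """
        n = len(self.residues)
        if start < 0 or start >= n:
            raise IndexError(f"start {start} out of range for length {n}")
        if end > start:
            return self.residues[start:end]
        if not self.circular:
            raise ValueError("wrapping interval on a non-circular sequence")
        return self.residues[start:] + self.residues[:end]


@dataclass
class FeatureRecord:
    """A typed, stranded, possibly multi-part annotation on the genome.

    ``parts`` are ordered 0-based half-open intervals in genome orientation;
    a feature spanning the circular origin is represented as two or more
    parts rather than a wrapping interval.
    """

    gene_name: str
    feature_class: str  # one of CDS, tRNA, rRNA, intron, misc
    strand: str  # '+' or '-'
    parts: list[tuple[int, int]] = field(default_factory=list)
    pseudogene: bool = False

    _CLASSES = frozenset({"CDS", "tRNA", "rRNA", "intron", "misc"})

    def __post_init__(self) -> None:
        if self.feature_class not in self._CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.parts:
            if not (0 <= start < end):
                raise ValueError(
                    f"feature {self.gene_name!r}: bad part [{start}, {end})"
                )
        ivs = sorted(self.parts)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"feature {self.gene_name!r}: overlapping parts"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Smallest interval covering all parts (exons plus introns)."""
        return min(s for s, _ in self.parts), max(e for _, e in self.parts)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def spliced(self, sequence: GenomeSequence) -> str:
        """Strand-oriented, spliced residues of the feature."""
        joined = "".join(sequence.residues[s:e] for s, e in sorted(self.parts))
        return joined if self.strand == "+" else reverse_complement(joined)


@dataclass
class AnnotatedPlastome:
    """A genome sequence together with its feature annotations."""

    sequence: GenomeSequence
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for feat in self.features:
            for start, end in feat.parts:
                if end > n:
                    raise ValueError(
                        f"feature {feat.gene_name!r} part [{start}, {end}) "
                        f"exceeds genome length {n}"
                    )


# ---------------------------------------------------------------------------
# GenBank


_GB_CLASS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "intron": "intron"}


def _feature_name(feat) -> str:
    for key in ("gene", "locus_tag", "product", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def read_genbank(path: str | os.PathLike) -> AnnotatedPlastome:
    """Read a single-record GenBank flat file into the internal model.

    Coordinates are converted from GenBank's 1-based inclusive convention to
    0-based half-open; ``join``/``complement`` locations become multi-part
    features with a single strand flag and parts ordered in genome
    orientation.  Multi-record files are rejected outright.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as err:
        raise GenBankParseError(f"cannot parse {path}: {err}") from err
    if len(records) == 0:
        raise GenBankParseError(f"{path}: no GenBank record found")
    if len(records) > 1:
        raise GenBankParseError(
            f"{path}: {len(records)} records found; expected exactly one"
        )
    rec = records[0]
    residues = str(rec.seq).upper()
    if not residues:
        raise GenBankParseError(f"{path}: record has zero-length sequence")
    circular = rec.annotations.get("topology", "").lower() == "circular"
    seq = GenomeSequence(id=rec.id, residues=residues, circular=circular)

    features: list[FeatureRecord] = []
    for feat in rec.features:
        if feat.type == "source":
            continue
        fclass = _GB_CLASS.get(feat.type, "misc")
        strand = "-" if (feat.location.strand or 1) < 0 else "+"
        # Biopython already exposes locations 0-based half-open.
        parts = sorted(
            (int(part.start), int(part.end)) for part in feat.location.parts
        )
        pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        features.append(
            FeatureRecord(
                gene_name=_feature_name(feat),
                feature_class=fclass,
                strand=strand,
                parts=parts,
                pseudogene=pseudo,
            )
        )
    return AnnotatedPlastome(sequence=seq, features=features)


def to_genbank_location(parts: list[tuple[int, int]], strand: str) -> str:
    """Render parts back as a GenBank location string (inverse conversion)."""
    pieces = [f"{s + 1}..{e}" for s, e in parts]
    body = pieces[0] if len(pieces) == 1 else "join(" + ",".join(pieces) + ")"
    return body if strand == "+" else f"complement({body})"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read FASTA into upper-cased sequences; duplicate ids are an error."""
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(GenomeSequence(id=rec.id, residues=str(rec.seq).upper()))
    return seqs


def write_fasta(seqs, path: str | os.PathLike) -> None:
    """Write sequences as FASTA wrapped at 70 columns."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=70)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# newick


def read_newick(text: str) -> UnrootedTree:
    return UnrootedTree.from_newick(text)


def write_newick(tree: UnrootedTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Tab-separated report: header row, UTF-8, '.' for missing values."""
    frame.to_csv(path, sep="\t", index=False, na_rep=".", encoding="utf-8")
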