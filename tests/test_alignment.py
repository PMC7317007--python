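"""Masking, reference-to-column maps and marker partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastsurvey import (
    AnnotatedPlastome,
    FeatureRecord,
    GenomeSequence,
    MarkerDefinition,
    MultipleAlignment,
    build_column_map,
    extract_marker,
    mask_columns,
    marker_usable,
    partition_markers,
)


def _aln(rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return MultipleAlignment(taxa=taxa, rows=rows)


class TestMaskColumns:
    def test_all_gap_column_removed(self):
        rows = ["A-" + "C", "A-" + "C"] + ["A-" + "C"] * 15
        masked, removed = mask_columns(_aln(rows), 0.8)
        assert list(removed) == [1]
        assert masked.width == 2

    def test_below_threshold_column_kept(self):
        # 8 gaps of 17 taxa (47%) stays
        rows = ["A-" for _ in range(8)] + ["AC" for _ in range(9)]
        masked, removed = mask_columns(_aln(rows), 0.8)
        assert removed.size == 0
        assert masked.width == 2

    def test_toy_matrix_exact_columns(self):
        # 5 taxa x 6 columns; columns 1 and 4 have 5/5 bad characters
        rows = [
            "A-CG-T",
            "A-CG-T",
            "ANCGNT",
            "A-CG-T",
            "A-CG-T",
        ]
        masked, removed = mask_columns(_aln(rows), 0.8)
        assert list(removed) == [1, 4]
        assert masked.rows[0] == "ACGT"

    def test_ambiguities_count_toward_removal(self):
        rows = ["N" * 4 + "A"] * 4 + ["ACGTA"]
        masked, removed = mask_columns(_aln(rows), 0.6)
        assert list(removed) == [0, 1, 2, 3]

    def test_strictly_greater_than_threshold(self):
        # exactly at the threshold is kept
        rows = ["-A", "-A", "CA", "CA", "CA"]  # column 0: 2/5 = 0.4 bad
        _, removed = mask_columns(_aln(rows), 0.4)
        assert removed.size == 0


class TestColumnMap:
    def test_example_row(self):
        aln = _aln(["A-CG-", "AACGG"], taxa=["ref", "o"])
        cmap = build_column_map(aln, "ref")
        assert list(cmap.positions) == [0, 2, 3]

    def test_gapless_identity(self):
        aln = _aln(["ACGTA", "ACGTT"], taxa=["ref", "o"])
        cmap = build_column_map(aln, "ref")
        assert list(cmap.positions) == [0, 1, 2, 3, 4]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT-", min_size=1, max_size=80))
    def test_strictly_increasing(self, ref_row):
        if set(ref_row) == {"-"}:
            with pytest.raises(ValueError):
                build_column_map(
                    _aln([ref_row, "A" * len(ref_row)], ["ref", "o"]), "ref"
                )
            return
        cmap = build_column_map(
            _aln([ref_row, "A" * len(ref_row)], ["ref", "o"]), "ref"
        )
        assert (np.diff(cmap.positions) > 0).all()
        assert len(cmap) == sum(1 for c in ref_row if c != "-")

    def test_after_masking_marks_lost_positions(self):
        aln = _aln(["ACGT", "ACGT"], ["ref", "o"])
        cmap = build_column_map(aln, "ref").after_masking(np.array([1]), 4)
        assert list(cmap.positions) == [0, -1, 1, 2]

    def test_missing_ref_taxon(self):
        with pytest.raises(ValueError, match="not in alignment"):
            build_column_map(_aln(["AC", "AC"]), "nope")


def _reference(length, features, circular=False):
    rng = np.random.default_rng(1)
    residues = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return AnnotatedPlastome(
        sequence=GenomeSequence("ref", residues, circular=circular),
        features=features,
    )


def _identity_cmap(aln, ref="ref"):
    return build_column_map(aln, ref)


class TestPartitionMarkers:
    def test_toy_linear_reference(self):
        """CDS at [10,40) and tRNA at [60,70) leave three spacers."""
        plastome = _reference(
            100,
            [
                FeatureRecord("cdsA", "CDS", "+", [(10, 40)]),
                FeatureRecord("trnB", "tRNA", "+", [(60, 70)]),
            ],
        )
        aln = _aln([plastome.sequence.residues, plastome.sequence.residues],
                   ["ref", "o"])
        markers = partition_markers(plastome, _identity_cmap(aln))
        by_class = {}
        for m in markers:
            by_class.setdefault(m.marker_class, []).append(m)
        assert len(by_class["cpCDS"]) == 1
        assert len(by_class["cpNCDS"]) == 1
        igs = sorted(m.columns[0] for m in by_class["cpIGS"])
        assert igs == [(0, 10), (40, 60), (70, 100)]
        names = {m.name for m in by_class["cpIGS"]}
        assert names == {"start-cdsA", "cdsA-trnB", "trnB-end"}

    def test_abutting_features_no_spacer(self):
        plastome = _reference(
            50,
            [
                FeatureRecord("a", "CDS", "+", [(0, 40)]),
                FeatureRecord("b", "tRNA", "+", [(40, 50)]),
            ],
        )
        aln = _aln([plastome.sequence.residues] * 2, ["ref", "o"])
        markers = partition_markers(plastome, _identity_cmap(aln))
        assert not [m for m in markers if m.marker_class == "cpIGS"]

    def test_intron_containing_gene_spans_full_extent(self):
        """Exon parts [5,10)+[20,30) give a cpCDS marker on the exons and a
        cpNCDS marker over the full [5,30) span."""
        plastome = _reference(
            40, [FeatureRecord("g", "CDS", "+", [(5, 10), (20, 30)])]
        )
        aln = _aln([plastome.sequence.residues] * 2, ["ref", "o"])
        markers = partition_markers(plastome, _identity_cmap(aln))
        cds = [m for m in markers if m.marker_class == "cpCDS"][0]
        ncds = [m for m in markers if m.marker_class == "cpNCDS"][0]
        assert cds.columns == [(5, 10), (20, 30)]
        assert ncds.columns == [(5, 30)]

    def test_circular_wraparound_spacer(self):
        plastome = _reference(
            100,
            [
                FeatureRecord("a", "CDS", "+", [(10, 40)]),
                FeatureRecord("b", "CDS", "+", [(60, 90)]),
            ],
            circular=True,
        )
        aln = _aln([plastome.sequence.residues] * 2, ["ref", "o"])
        markers = partition_markers(plastome, _identity_cmap(aln))
        igs = [m for m in markers if m.marker_class == "cpIGS"]
        wrap = [m for m in igs if len(m.columns) == 2]
        assert len(wrap) == 1
        assert wrap[0].columns == [(90, 100), (0, 10)]
        assert wrap[0].name == "b-a"

    def test_igs_cover_complement_exactly(self):
        """Feature spans plus spacers cover the reference once."""
        plastome = _reference(
            200,
            [
                FeatureRecord("a", "CDS", "+", [(20, 50)]),
                FeatureRecord("t", "tRNA", "+", [(80, 95)]),
                FeatureRecord("b", "CDS", "-", [(95, 150)]),
            ],
        )
        aln = _aln([plastome.sequence.residues] * 2, ["ref", "o"])
        markers = partition_markers(plastome, _identity_cmap(aln))
        covered = np.zeros(200, dtype=int)
        for m in markers:
            if m.marker_class == "cpIGS":
                for s, e in m.columns:
                    covered[s:e] += 1
        for f in plastome.features:
            s, e = f.span
            covered[s:e] += 1
        assert (covered == 1).all()

    def test_cds_marker_reproduces_annotated_residues(self):
        """Masking then mapping is consistent: the reference row of an
        extracted cpCDS marker, degapped, equals the annotated CDS."""
        plastome = _reference(
            60, [FeatureRecord("g", "CDS", "+", [(10, 30)])]
        )
        res = plastome.sequence.residues
        # build an alignment with gaps in the reference and a junk column
        ref_row = res[:20] + "--" + res[20:]
        other = res[:20] + "GG" + res[20:]
        third = "-" * 62
        aln = _aln([ref_row, other, third], ["ref", "o1", "o2"])
        from plastsurvey import mask_columns

        masked, removed = mask_columns(aln, 0.6)
        cmap = build_column_map(aln, "ref").after_masking(removed, aln.width)
        markers = partition_markers(plastome, cmap)
        cds = [m for m in markers if m.marker_class == "cpCDS"][0]
        sub = extract_marker(masked, cds)
        degapped = sub.row("ref").replace("-", "")
        assert degapped == res[10:30]


class TestExtractConcat:
    def test_full_marker_is_identity(self):
        aln = _aln(["ACGTAC", "ACGTTT"])
        m = MarkerDefinition("all", "cpCDS", [(0, 6)])
        assert extract_marker(aln, m).rows == aln.rows

    def test_single_column(self):
        aln = _aln(["ACGT", "AGGT"])
        m = MarkerDefinition("one", "cpIGS", [(1, 2)])
        sub = extract_marker(aln, m)
        assert sub.width == 1 and sub.rows == ["C", "G"]

    def test_extracted_markers_recompose_column_multiset(self):
        rng = np.random.default_rng(3)
        rows = ["".join("ACGT-"[i] for i in rng.integers(0, 5, 30)) for _ in range(4)]
        aln = _aln(rows)
        markers = [
            MarkerDefinition("m1", "cpCDS", [(0, 10)]),
            MarkerDefinition("m2", "cpNCDS", [(10, 18)]),
            MarkerDefinition("m3", "cpIGS", [(18, 30)]),
        ]
        pieces = [extract_marker(aln, m) for m in markers]
        recomposed_cols = sorted(
            "".join(p.rows[t][c] for t in range(4))
            for p in pieces
            for c in range(p.width)
        )
        original_cols = sorted(
            "".join(rows[t][c] for t in range(4)) for c in range(30)
        )
        assert recomposed_cols == original_cols

    def test_marker_usable_counts_nonempty_taxa(self):
        aln = _aln(["ACGT", "A-GT", "----", "ACGT", "AC--"])
        m = MarkerDefinition("m", "cpCDS", [(0, 4)])
        assert marker_usable(aln, m, min_taxa=4)
        assert not marker_usable(aln, m, min_taxa=5)
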