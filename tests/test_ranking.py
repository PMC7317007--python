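"""Weighted relative-value marker ranking, top-k datasets, primer picking."""

import numpy as np
import pytest

from plastsurvey import (
    AnnotatedPlastome,
    GenomeSequence,
    MarkerDefinition,
    MarkerMetrics,
    MultipleAlignment,
    RankingConfig,
    concatenate_markers,
    locate_amplicon,
    pick_primers,
    rank_markers,
    select_top,
    size_filter,
)
from plastsurvey.ranking import PrimerConstraints, primer_gc, primer_tm

from conftest import random_residues

# The ten ranked markers of the survey with their printed metric columns
# (variable sites, mean bootstrap, RF distance to the plastome tree) and the
# printed global ranges: bootstrap 0-89, tree distance 6-28.
TOP10_METRICS = [
    ("accD", 966, 88, 10),
    ("ycf1", 958, 76, 8),
    ("ndhD", 210, 79, 6),
    ("trnK_UUU", 173, 82, 8),
    ("psbE-rpl20", 242, 77, 8),
    ("petD", 69, 75, 8),
    ("ccsA", 110, 73, 8),
    ("clpP", 112, 70, 8),
    ("rpoC2", 165, 69, 8),
    ("rpoC1", 86, 69, 8),
]
PRINTED_RANGES = RankingConfig(
    variable_range=(0, 966), bootstrap_range=(0, 89), distance_range=(6, 28)
)


def _metrics():
    return [
        MarkerMetrics(
            name=n, variable_sites=v, mean_bootstrap=b, tree_distance=d
        )
        for n, v, b, d in TOP10_METRICS
    ]


class TestRankMarkers:
    def test_published_top_marker_is_rank_one(self):
        ranked = rank_markers(_metrics(), PRINTED_RANGES)
        assert ranked[0].name == "accD"
        assert ranked[0].rank == 1

    def test_published_top_five_order(self):
        ranked = rank_markers(_metrics(), PRINTED_RANGES)
        assert [r.name for r in ranked[:5]] == [
            "accD",
            "ycf1",
            "ndhD",
            "trnK_UUU",
            "psbE-rpl20",
        ]

    def test_published_order_within_one_adjacent_swap(self):
        """Positions 6-10 agree with the published order up to the single
        adjacent clpP/rpoC2 swap."""
        ranked = rank_markers(_metrics(), PRINTED_RANGES)
        tail = [r.name for r in ranked[5:]]
        published = ["petD", "ccsA", "clpP", "rpoC2", "rpoC1"]
        swaps = sum(1 for a, b in zip(tail, published) if a != b)
        assert swaps <= 2  # one adjacent transposition touches two slots

    def test_hand_computed_weighted_score(self):
        metrics = [
            MarkerMetrics(name="x", variable_sites=10, mean_bootstrap=50, tree_distance=28),
            MarkerMetrics(name="lo", variable_sites=0, mean_bootstrap=0, tree_distance=6),
            MarkerMetrics(name="hi", variable_sites=10, mean_bootstrap=100, tree_distance=6),
        ]
        ranked = rank_markers(metrics)
        x = next(r for r in ranked if r.name == "x")
        # relative values (1.0, 0.5, 0.0) -> (1*1 + 2*0.5 + 3*0)/6
        assert (x.r_var, x.r_bs, x.r_dist) == (1.0, 0.5, 0.0)
        assert x.score == pytest.approx(1 / 3)

    def test_ties_share_rank_and_break_by_name(self):
        metrics = [
            MarkerMetrics(name="b", variable_sites=5, mean_bootstrap=50, tree_distance=10),
            MarkerMetrics(name="a", variable_sites=5, mean_bootstrap=50, tree_distance=10),
            MarkerMetrics(name="c", variable_sites=9, mean_bootstrap=80, tree_distance=5),
        ]
        ranked = rank_markers(metrics)
        assert ranked[0].name == "c" and ranked[0].rank == 1
        assert [r.name for r in ranked[1:]] == ["a", "b"]
        assert ranked[1].rank == ranked[2].rank == 2

    def test_scale_invariance_of_variable_sites(self):
        base = rank_markers(_metrics())
        scaled = rank_markers(
            [
                MarkerMetrics(
                    name=n,
                    variable_sites=v * 7,
                    mean_bootstrap=b,
                    tree_distance=d,
                )
                for n, v, b, d in TOP10_METRICS
            ]
        )
        assert [r.name for r in base] == [r.name for r in scaled]
        assert [r.rank for r in base] == [r.rank for r in scaled]

    def test_bootstrap_monotonicity(self):
        """Raising one marker's mean bootstrap (bounds fixed) never lowers it."""
        cfg = PRINTED_RANGES
        before = rank_markers(_metrics(), cfg)
        rank_before = next(r.rank for r in before if r.name == "ccsA")
        boosted = [
            MarkerMetrics(
                name=n,
                variable_sites=v,
                mean_bootstrap=b + (10 if n == "ccsA" else 0),
                tree_distance=d,
            )
            for n, v, b, d in TOP10_METRICS
        ]
        after = rank_markers(boosted, cfg)
        rank_after = next(r.rank for r in after if r.name == "ccsA")
        assert rank_after <= rank_before

    def test_markers_missing_metrics_excluded_with_warning(self):
        metrics = _metrics() + [MarkerMetrics(name="treeless", variable_sites=4)]
        with pytest.warns(UserWarning, match="treeless"):
            ranked = rank_markers(metrics, PRINTED_RANGES)
        assert "treeless" not in {r.name for r in ranked}

    def test_all_constant_metrics_all_rank_one(self):
        metrics = [
            MarkerMetrics(name=n, variable_sites=5, mean_bootstrap=60, tree_distance=8)
            for n in ("a", "b", "c")
        ]
        with pytest.warns(UserWarning, match="all scores equal"):
            ranked = rank_markers(metrics)
        assert {r.rank for r in ranked} == {1}


class TestTopKAndSizeFilter:
    def test_select_top_one(self):
        ranked = rank_markers(_metrics(), PRINTED_RANGES)
        assert select_top(ranked, 1) == ["accD"]

    def test_concatenated_width_is_sum(self):
        aln = MultipleAlignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        markers = [
            MarkerDefinition("m1", "cpCDS", [(0, 4)]),
            MarkerDefinition("m2", "cpCDS", [(6, 9)]),
        ]
        concat = concatenate_markers(aln, markers)
        assert concat.width == 7

    def test_concatenation_of_everything_recomposes_columns(self, rng):
        rows = ["".join("ACGT"[i] for i in rng.integers(0, 4, 12)) for _ in range(3)]
        aln = MultipleAlignment([f"t{i}" for i in range(3)], rows)
        markers = [
            MarkerDefinition("m1", "cpCDS", [(4, 8)]),
            MarkerDefinition("m2", "cpIGS", [(0, 4), (8, 12)]),
        ]
        concat = concatenate_markers(aln, markers)
        original = sorted("".join(r[c] for r in rows) for c in range(12))
        recomposed = sorted(
            "".join(r[c] for r in concat.rows) for c in range(concat.width)
        )
        assert recomposed == original

    def test_size_filter_threshold(self):
        metrics = [
            MarkerMetrics(name="small", mean_length=860.0),
            MarkerMetrics(name="accD_like", mean_length=1876.0),
        ]
        kept = size_filter(metrics, 900)
        assert [m.name for m in kept] == ["small"]
        assert size_filter(metrics, 2000) == metrics  # configurable threshold
        assert size_filter([], 900) == []


class TestPrimers:
    def test_tm_formula_example(self):
        oligo = "ACGATTGATTGGACCATGCA"  # 20 nt, 9 G/C
        assert primer_gc(oligo) == pytest.approx(45.0)
        assert primer_tm(oligo) == pytest.approx(64.9 + 41 * (9 - 16.4) / 20)
        assert primer_tm(oligo) == pytest.approx(49.73)

    def test_feasible_pair_on_random_flanks_meets_every_constraint(self):
        rng = np.random.default_rng(1234)
        residues = random_residues(rng, 1000)
        ref = GenomeSequence("r", residues)
        c = PrimerConstraints()
        pair, tally = pick_primers(ref, (350, 650), c)
        assert pair is not None, tally
        for oligo, tm, gc in (
            (pair.forward, pair.forward_tm, pair.forward_gc),
            (pair.reverse, pair.reverse_tm, pair.reverse_gc),
        ):
            assert c.min_len <= len(oligo) <= c.max_len
            assert c.gc_min <= gc <= c.gc_max
            assert c.tm_min <= tm <= c.tm_max
            assert not any(b * 5 in oligo for b in "ACGT")
        assert pair.product_size <= c.max_product
        # product contains the full target
        assert pair.forward_site[1] <= 350 and pair.reverse_site[0] >= 650
        assert pair.product_size == pair.reverse_site[1] - pair.forward_site[0]

    def test_homopolymer_flanks_infeasible(self):
        residues = "A" * 200 + "ACGT" * 25 + "A" * 200
        ref = GenomeSequence("r", residues)
        pair, tally = pick_primers(ref, (200, 300))
        assert pair is None
        assert tally["homopolymer"] > 0 and tally["gc"] > 0

    def test_amplicon_size_arithmetic(self, rng):
        residues = random_residues(rng, 1200)
        fwd = residues[100:120]
        rev_site = residues[1000:1020]
        from plastsurvey import reverse_complement

        rev = reverse_complement(rev_site)
        ref = GenomeSequence("r", residues)
        if residues.count(fwd) == 1 and residues.count(rev_site) == 1:
            assert locate_amplicon(ref, fwd, rev) == 920

    def test_absent_primer_is_error(self, rng):
        ref = GenomeSequence("r", "ACGT" * 100)
        with pytest.raises(ValueError, match="binding site"):
            locate_amplicon(ref, "TTTTTTTTTTTTTTTTTTTT", "GGGGGGGGGGGGGGGGGGGG")

    def test_planted_primer_pair_product(self, rng):
        """Primer sites planted 931 bp apart are recovered exactly."""
        fwd = "ACCAAGGCAAACCCATGGAA"
        rev = "TCCCCTTCTTACCAGCATCA"
        from plastsurvey import reverse_complement

        middle = random_residues(rng, 931 - 40)
        residues = (
            random_residues(rng, 120)
            + fwd
            + middle
            + reverse_complement(rev)
            + random_residues(rng, 150)
        )
        ref = GenomeSequence("r", residues)
        assert locate_amplicon(ref, fwd, rev) == 931
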