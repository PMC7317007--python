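# Methods

This note documents the models, numerical choices and known limitations of
plastsurvey, stage by stage.

## Inverted-repeat detection and the quadripartite partition

A canonical plastome is a circle LSC–IR–SSC–IR in which the two inverted
repeats are exact reverse-complement copies. `find_inverted_repeat` seeds
k-mer matches (k = 21) between the sequence and its reverse complement,
groups seeds by anti-diagonal (i + j constant on the circle, which is
invariant under extension of a reverse-complement match), and extends each
seeded run maximally in both directions with exact identity required. A
contiguous self-mirrored run is a palindromic arrangement (abutting copies);
its two halves are the copies. The maximal pair wins; ties are broken by
minimal SSC length, then smallest start coordinate, so the result is
deterministic. The longer gap between the copies is labeled LSC, the
shorter SSC, and the copy immediately following the LSC is IRa. When no
pair of at least `min_len` (default 1,000 bp; the spurious-repeat background
in random sequence is ~15 bp) exists, a degenerate partition — whole genome
as LSC — is returned with a warning rather than an error, since
single-copy plastomes occur in nature.

Mismatch-tolerant (divergent) inverted repeats, as reported in some cacti
at sub-kilobase scale, are out of scope: identity is exact by design, which
keeps the detector oracle-checkable against a full per-diagonal scan.

GC content is (G + C + S) over unambiguous positions (A, C, G, T, S, W); S
and W are the two two-state codes whose GC contribution is certain. Genes
are assigned to regions by majority rule over their bases (a gene
straddling a boundary belongs to the region holding most of it); genes
duplicated in the two IR copies count once per copy.

The pseudogene screen translates the spliced, strand-oriented CDS under the
plastid (bacterial-style) code: starts ATG/GTG; stops TAA/TAG/TGA. Reasons
reported: `internal_stop`, `length_not_multiple_of_3`, `missing_start`,
`missing_stop`, and — only when an expected full length is supplied —
`small_orf` when the observed open reading frame is shorter than half the
expectation. No threshold for "small" is universal; 50 % is the package's
documented, configurable choice.

## Alignment masking, coordinate maps, marker partition

Whole-plastome alignments are inputs (typically MAFFT output), not computed
here. Masking removes a column iff (gaps + ambiguities) / n_taxa strictly
exceeds the threshold (default 0.8). The column map records, for each
ungapped reference position, its alignment column; after masking, positions
whose column was stripped map to −1 and marker intervals are built from the
surviving positions' extrema — so a marker's columns may include inserted
columns interior to its span, which is intended (the marker is the aligned
region, not the reference residues alone).

Marker classes: cpCDS = one marker per CDS feature, pseudogenes included,
columns being the images of the exon parts; cpNCDS = tRNA and rRNA genes
plus the full exon+intron span of each intron-containing gene (so a
trnK-like gene region containing an embedded CDS yields both a cpNCDS span
marker and the inner cpCDS marker — columns may be shared across classes,
never within one); cpIGS = maximal reference intervals covered by no
feature span, named `upstream-downstream` from the flanking genes, with the
origin-wrapping spacer of a circular reference emitted once with two column
intervals. Markers with fewer than four taxa carrying any residue are
flagged unusable for tree metrics (no internal edges exist below four
leaves).

## Diversity statistics

Gap handling is pairwise deletion throughout: each pair is compared over
the columns where both rows carry an unambiguous A/C/G/T; ambiguity codes
are treated as missing and never expanded fractionally. This differs from
the complete-deletion default of DnaSP: on ragged plastome alignments
complete deletion can discard most columns, while pairwise deletion keeps
windows comparable; absolute π values from the two conventions differ, so
cross-tool comparisons should expect order-of-magnitude, not exact,
agreement.

A column is variable iff ≥ 2 distinct unambiguous states remain after
exclusion, and parsimony-informative iff ≥ 2 states are each carried by
≥ 2 taxa. K80 distance is d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with P and Q the
transition and transversion proportions over the compared sites; pairs at
or beyond the logarithms' domain (1−2P−Q ≤ 0 or 1−2Q ≤ 0) are saturated
and excluded from means (never imputed with a ceiling there). π is the
mean over unordered pairs of (differences / compared sites). Sliding
windows start at columns 0, step, 2·step, … while a full window fits
(defaults 800/200 columns); the final partial window is dropped, and an
alignment narrower than one window falls back to a single whole-alignment
window with a warning. Window coordinates are alignment columns; reports
also carry the reference position of each window start via the column map.

## Trees

The built-in engine is neighbor joining over K80 distances — deliberately,
instead of maximum likelihood: it is fast, deterministic, exactly
recoverable on additive matrices (tested), and requires no external binary.
Every consumer of trees accepts externally computed newick files, so a
user can substitute an ML engine and feed its trees to the RF and support
metrics unchanged. In the distance matrix (only), saturated pairs are
imputed as twice the largest defined distance with a warning, since NJ
needs a complete matrix; a pair with zero comparable sites is an error.
Negative NJ branch lengths are clamped to zero with the deficit moved to
the sibling edge (their sum is preserved). Q-matrix ties resolve to the
smallest index pair.

Bootstrap: columns are resampled with replacement to the original width;
replicate r draws from the deterministic substream (seed, r), so runs are
reproducible and individual replicates re-derivable. Support of each
internal edge of the point-estimate tree is the percentage of replicates
containing the same bipartition. Degenerate resamples (a pair with no
comparable sites, or all pairs saturated) are dropped with a warning and
the denominator adjusted.

RF distance is the size of the symmetric difference of the two trees'
non-trivial bipartition sets; polytomies need no special-casing. When a
marker lacks taxa (all-gap rows dropped), the comparison tree is pruned to
the marker's leaf set before RF computation — the package's choice, as no
convention is universal.

## Ranking and primers

Markers are scored by a weighted mean of relative values: min–max
normalization of variable sites (weight 1), mean bootstrap (weight 2) and
RF distance to the whole-plastome tree (weight 3), the last inverted
(r = (max−d)/(max−min)) so that topological agreement scores high;
score = Σ wᵢrᵢ / Σ wᵢ ∈ [0, 1]. Normalization bounds may be derived from
the ranked set (CLI default) or supplied explicitly, e.g. known global
ranges of a larger marker panel. Ranks are dense; ties break by raw
variable-site count, then name. Markers lacking a tree are excluded with a
warning. "Relative values" admits several readings; min–max with distance
inversion is adopted because it reproduces the published ordering of a
ten-marker reference panel at positions 1–5 exactly and 6–10 up to one
adjacent transposition (clpP/rpoC2), which is recorded as an accepted
ambiguity of the definition.

The primer picker is a deliberately simplified design tool: it scans all
18–24 nt plus-strand substrings of the 200 bp flanks (downstream flank
reverse-complemented), requires GC ∈ [40, 60] %, Tm ∈ [57, 63] °C by
Tm = 64.9 + 41·(#GC − 16.4)/length, no run of five identical bases, and
product ≤ 1,100 bp containing the whole target; among feasible pairs it
minimizes |Tm − 60| + |GC − 50|/10 summed over the two primers. There is
no nearest-neighbor thermodynamic model, no dimer/hairpin check and no
mispriming scan — published primer sets designed with full-featured tools
are treated as data (e.g. for amplicon-size verification), not as outputs
this picker should reproduce. The size filter for Sanger-amplifiable
markers uses mean ungapped length < 900 bp by default (aligned versus raw
length is not distinguished in common usage; mean ungapped is the package's
choice).

## Synthetic data generator

The generator emulates the kind of study the pipeline serves: ~17
homologous plastome-like sequences, one annotated reference, twenty markers
of the three classes with marker-to-marker rate heterogeneity, and one
clearly fastest marker (1,800 bp at 4× rate; the rest 300–1,500 bp at
0.2–1×) as planted ground truth for the ranking.

Substitution follows the Kimura two-parameter chain (default κ = 2, equal
base frequencies), applied per branch with exact closed-form transition
probabilities — no event-by-event simulation — with the marker's rate
multiplier scaling the branch length. Random topologies come from
sequential random attachment (uniform over labeled binary shapes). Branch
lengths for generated study trees are shifted-exponential: floor 0.001,
mean 0.0035 substitutions/site. The mean is calibrated so that rate-1
markers show plastome-panel divergence (overall π ≈ 0.02, the level
reported for real congeneric plastome panels); a pure exponential with a
plastome-realistic mean leaves ~10 % of 17-taxon trees with an internal
edge expecting fewer than ~6 substitutions even at 100+ kb — truth no
finite alignment can recover — so the floor keeps the planted topology
identifiable, which a recovery benchmark requires. `simulate_tree` itself
retains a larger default mean (0.05, no floor) for generic use.

Optional indels are drawn per branch as Poisson events (rate per site per
unit branch length), geometric lengths with mean 3, insertion/deletion
equiprobable, inherited by all descendants so gap patterns are
phylogenetically coherent; inserted residues do not evolve further
(a documented simplification), and the reference row is ungapped whenever
the indel rate is zero. Planted quadripartite circles place
LSC + IRa + SSC + IRb with IRb the exact reverse complement of IRa; the
four region-boundary bases are adjusted to break chance complement matches
so the planted repeat length is exact.

What the generator does **not** emulate: within-marker rate variation
(gamma), base-composition bias and GC heterogeneity between regions,
inversions/translocations, sequencing or assembly error, and alignment
error (rows are generated aligned). Passing recovery tests therefore show
the pipeline's statistics and ranking behave correctly on data matching its
model assumptions; they do not certify robustness to misalignment or
model violation on real data.

## Pipeline and reproducibility

All stage outputs are plain files (FASTA, newick, TSV, JSON); reruns with
identical configuration and seed are byte-identical, and the manifest
records configuration, package versions, seed and all collected warnings
(degenerate partitions, saturated pairs, dropped replicates, pruned taxa).
Defaults: masking threshold 0.8; windows 800/200; 1,000 bootstrap
replicates for the full alignment and concatenated datasets and 100 per
marker; ranking weights (1, 2, 3); top-k ∈ {5, 10}; primer size cutoff
900 bp. Test and demonstration runs use smaller bootstrap counts and
alignments of ~18–30 kb — the statistics are width-agnostic, and these
sizes keep the full suite fast while the per-marker replicate count of the
recovery benchmark stays at the protocol's 100.
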