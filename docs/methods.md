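# Methods

`exaptscan` studies one evolutionary event end to end: a DNA transposon
of the *hAT* superfamily inserts near a gene, decays neutrally, and a
non-coding stretch of it becomes the protein-coding last exon of a
chimeric gene after two point mutations. Because the real event is only
observable once, every stage is validated on synthetic genomes where the
truth — insertion loci, copy ages, the mutation script — is known.

## The simulated system

`simulate.generate_te_consensus` builds a random element whose first
`tir_length` bases equal the reverse complement of its last
`tir_length` bases (terminal inverted repeats, the structural signature
of DNA transposons; 14 bp by default). The base immediately inside the
TIR is chosen so the repeat does not extend by chance; without this, a
detector scanning all lengths correctly reports `tir_length + 1` with
probability 1/4 per extra base, and the implanted length would not be a
well-defined truth.

`evolve_copy` decays a copy to a target Jukes-Cantor divergence *d* by
substituting each site independently with probability
p = (3/4)(1 − e^(−4d/3)) — the exact inverse of the JC correction — to a
uniformly chosen different base. Substitution is JC-only: dating uses JC
distances, so a richer simulation model would only test machinery that
is out of scope. Indels are available (per-site rate, geometric lengths
with mean 2) but off by default; no published indel model exists for
these elements. `implant_copies` places copies at offsets with a
guaranteed minimum spacing (sorted uniforms on the spacing-reduced
interval), records truth as d = r·T with r in substitutions/site/year
and T in Ma, and inserts on random strands.

### The chimeric locus

The exon-source fragment is constructed backwards from the derived
state: 71 sense codons (codon 44 fixed to CAG), a TAG, and a short
tail containing a TAA in the +1-shifted frame. The ancestral state adds
one base at position 90 (a frameshift relative to the eventual coding
frame) and carries CAG where the stop will arise; rejection sampling
guarantees the ancestral read-through has no in-frame stop (it is
genuinely non-coding) and that the 16-nt-deletion variant terminates at
the tail TAA. Three scripts regenerate the observed variant set:

| script | events on the ancestral fragment | peptide |
|---|---|---|
| default | 1-nt deletion + CAG→TAG substitution | 71 aa, TAG |
| premature stop | default + upstream CAG→TAG | 43 aa, TAG |
| 16-nt deletion | default + frameshifting 16-nt deletion | 67 aa, TAA |

`implant_chimeric_locus` embeds the scripted fragment as exon 4 of a
four-exon gene, with an AG splice acceptor immediately 5' of the exon
and 133 bp / 207 bp of element homology in the intron-3 tail and the 3'
flank (the pattern of homology crossing the exon boundary on both
sides). Truth records exon intervals, acceptor, CDS interval, expected
peptide length and the script. Coordinates are 0-based half-open
internally and 1-based inclusive only in GFF3.

## Homology search and census

`scan_genome` is seed-and-extend: exact 11-mer matches nominate
windows, each realigned with a self-implemented affine-gap
Smith-Waterman (numba-compiled; a gap of length k costs
gap_open + k·gap_extend; defaults match +2 / mismatch −3 / open −5 /
extend −2). After a hit, the window's flanks are realigned so several
nearby copies in one window are all found. An E-value cutoff is not
reproducible without database-wide statistics, so retention uses a raw
score minimum (60). Identity is matches over aligned non-gap columns
(the value over all columns is also kept); coverage is the aligned
query fraction.

`census` applies exclusive thresholds (identity > 0.65, coverage >
0.60, mirroring the ">65% over >60% of query length" convention), then
keeps hits best-score-first, discarding any hit whose start lies within
`dedup_window` bp of a kept hit's start on the same contig (150 bp for
exon-CDS-like fragments; 1 kb and 10 kb for the longer fragment
classes). Start-to-start distance is a documented choice — the
duplicate-removal rule is otherwise underspecified. The census is
idempotent and monotone in both thresholds.

## Block segmentation and TIRs

`segment_blocks` aligns locus to reference (mild scoring, +1/−1/−2/−1,
which stays positive in expectation down to ~55% identity so a single
local alignment spans low-identity interior regions) and partitions the
alignment columns into identity blocks. Windowed identity (30 bp,
step 1) is only used to *estimate* the two identity levels by a 2-means
split; the segmentation itself is the most probable two-state path
under Bernoulli column emissions with a switch penalty (6 nats). A bare
threshold at 0.65 is not robust here: at a 57-60% identity level the
windowed values straddle 0.65 constantly and the low region shatters.
The penalty suppresses excursions shorter than the evidence for them;
residual runs under `min_block` (40 columns) are absorbed, and adjacent
runs whose exact identities differ by < 0.08 are merged. Per-block
identity is recomputed exactly from alignment columns. Blocks are
labeled A, B, C… 5'→3', and `low_identity` marks blocks below the 0.65
threshold. On the three-segment fixture (150 bp at d≈0.2 / 220 bp at
d≈0.55 / 320 bp at d≈0.25) this recovers the high-low-high pattern; the
segmentation is still a heuristic and boundary placement is only
window-accurate.

`find_tir` is exhaustive: the longest L in [min_len, max_len] whose
prefix matches the reverse-complemented suffix with at most
`max_mismatch` mismatches. Elements are short, so no indexing is
needed.

## Consensus, distances, landscape, age

`majority_consensus` takes the per-column most frequent base among
A/C/G/T, drops columns where gaps hold a strict majority, and breaks
ties alphabetically. `p_distance` uses pairwise gap deletion;
`jc_distance` d = −(3/4)ln(1 − 4p/3) (undefined at p ≥ 0.75; saturated
records are excluded from medians and counted); `k2p_distance`
d = −½ln(1−2P−Q) − ¼ln(1−2Q) with P transitions, Q transversions.
Gamma rate heterogeneity is deliberately not modeled.

The repeat landscape bins each copy's corrected divergence (bin width
0.01) and weights by copy length over genome size, so per-family
fractions sum to the family's annotated genome fraction exactly.

Age uses divergence-to-consensus directly: T = d/r, no factor of two,
because copies decay independently from the ancestral consensus-like
state rather than diverging pairwise. With the lineage rate bracket
r = 3.0-3.2 × 10⁻⁹ substitutions/site/year, a median divergence of
0.054 converts to 16.875-18.0 Ma (17-18 Ma at integer rounding). The
median is unweighted by default (length-weighting available). In the
pipeline, where copy counts are small (20 copies of 1 kb by default),
the rate bracket alone is far narrower than the sampling noise of the
median (±~0.002 in d), so the *reported* interval folds a seeded
bootstrap 95% CI of the median into the rate bracket; `estimate_age`
itself remains the pure d/r arithmetic.

`center_star_align` is a progressive star alignment around the
best-scoring center ("once a gap, always a gap"), intended for ≤ 50
sequences; larger sets must arrive pre-aligned (aligned FASTA in).

## Exonization reconstruction

The exon is read in the frame continuing from the upstream exon
(`frame_offset` is an input, not inferred — the peptide is a C-terminal
continuation, not an ATG-initiated ORF). `exon_cds` returns the segment
up to and including the first in-frame stop; no stop means an ancestral
read-through. `diff_events` collapses gap runs into single indel events
and projects positions onto both sequences; applying the events to the
ancestral reconstructs the candidate exactly (round-trip tested on 200
random pairs).

`reconstruct_path` aligns the candidate with its homologs, calls an
event wherever the candidate differs from the *strict majority* of
homologs (ties are unpolarizable and excluded from the minimal set),
and searches subsets of events (exhaustive to size 6, greedy beyond)
for the smallest set whose application to the ancestral reconstruction
reproduces the candidate's peptide length — frame restored and stop
present. Frameshift direction is oriented against a reference frame
defined as the indel subset maximizing the achievable peptide: indels
inside that subset are `frameshift_remove`, outside it
`frameshift_introduce`. Among stop-creating substitutions evaluated on
the reference-frame sequence, the downstream-most is the `stop_gain`
and any earlier one a `premature_stop`; this matches the variant
biology, where the shared terminal stop is the gain and the
lineage-specific upstream TAG truncates the peptide. With a single
homolog, events are reported unpolarized with a warning.

## Trees

`distance_matrix` wraps the distance functions pairwise (saturated
pairs raise an error naming the pair). `neighbor_joining` is the
standard Q-criterion agglomeration; ties go to the smallest (i, j)
index pair so topologies are deterministic, and negative branch lengths
are clamped to zero with a note. Additive matrices are recovered
exactly (tested against path-sum constructions and cross-checked
against an independent implementation). `bootstrap` resamples columns
with replacement, drops replicates with saturated pairs (counting
them; the support denominator is successful replicates), and maps
bipartition frequencies onto the full-data tree; 1000 replicates by
default.

## Pipeline and problem sizes

`run_pipeline` executes simulate → scan/census → blocks/TIR →
date/landscape → exonize → tree, logging structured lines and writing a
summary JSON stamped with a config hash; one seed fans out as
seed + stage index, and reruns are byte-identical. Defaults are the
study conditions at desk scale: a 60 kb background genome, a 1 kb
element with 14-bp TIRs, 20 copies decayed to d = r·T with T = 17.5 Ma
and r = 3.1 × 10⁻⁹ (median divergence ≈ 0.054), 4 near-ancestral
homolog copies (3 Ma) for event polarization, and the two-mutation
ORF-gain script. These sizes keep a full run around a few seconds while
leaving every estimator in its working regime; the parameter-recovery
test uses 200 copies of 5 kb, where the median's sampling noise is
negligible against the rate bracket.

## What the simulations do and do not show

The generator reproduces the quantities the analysis consumes —
divergence-to-consensus of independently decaying copies, TIR
structure, the exon's mutation script, homolog polarization — under JC
substitution with uniform base usage and, by default, no indels, no
rate heterogeneity across sites or copies, no nested or truncated
insertions, no subgenome structure, and no selection. Passing tests
therefore demonstrate the estimators are correct on their own model;
they do not demonstrate robustness to CpG effects, fragmented copies,
alignment error from real indel patterns, or reference bias in real
assemblies. Genome-scale censuses on real assemblies are out of scope.

## Numerical and degenerate-input choices

Saturated distances (p ≥ 0.75, inadmissible K2P fractions) raise a
typed error and are excluded-and-counted wherever aggregation occurs.
Consensus ties break alphabetically; NJ ties break on the smallest
index pair; census dedup ties break best-score-then-leftmost. Zero-TIR
elements, empty age lists, empty truth files and single-member variant
tables are all defined. The aligner treats any non-ACGT symbol as a
mismatch. Known limitations: the census counts each window's best local
alignment, so two overlapping copies on the same strand merge into one
hit; block boundaries are window-accurate only; bootstrap supports on
near-star genealogies are legitimately low.
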