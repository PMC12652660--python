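# Methods

## Scoring model

Motifs are classical zeroth-order PWMs. From a 4×L count matrix the weight of
base *b* at column *j* against background *q* is
log₂[(n<sub>bj</sub> + q<sub>b</sub>·s)/(N<sub>j</sub> + s)/q<sub>b</sub>],
with the total pseudocount *s* shared across bases in proportion to the
background. Defaults: uniform background, *s* = 1.0 per column. The
background-proportional pseudocount is the common JASPAR-ecosystem
convention; it keeps zero counts finite and makes a background-proportional
column score exactly zero. Log base 2 (bits) is a display choice only — the
base rescales scores and cancels in p-value ranks. Setting *s* = 0 is allowed
when all counts are positive, in which case weights are scale-invariant in
the counts. The background can be uniform, estimated from the promoter set,
or supplied explicitly; frequencies must be strictly positive.

## Exact p-values

Each weight cell is rounded once onto an integer grid (`grid_scale`, default
10 000 units per bit — fine enough that distinct score levels of realistic
matrices never merge, cheap enough that the dense convolution array stays
small). A word's discretized score is the sum of its rounded cells, and the
null distribution of that sum for an i.i.d. background word is computed
exactly by one convolution step per column. P(S ≥ s) and threshold cutoffs
are therefore exact at grid resolution: the cutoff for threshold *p* is the
smallest integer score whose tail is strictly below *p* (matching the
strict "p <" reading of a significance threshold), and a scan at that cutoff
emits precisely the words with p-value < *p*. Under a uniform background all
word probabilities are dyadic, so the convolution and a brute-force
enumeration over all 4^L words agree bit-for-bit; the test suite asserts
this exact equivalence for L ≤ 8 and uses enumeration as the independent
oracle throughout. Refining the grid changes any p-value by at most the
probability mass sharing one coarse cell.

## Scanning conventions

Windows are TSS-anchored with EPD-style coordinates: no position 0, +1 is the
first downstream base, so −5000…+1000 spans 6000 bases. Both strands are
scanned; a minus-strand window is scored through the reverse-complemented
matrix, and the hit's `start` is always the 5′-most base of the matched
window in forward-strand space — one unambiguous anchor for region
classification (a TSS-spanning hit is classified by that start). Hits on
opposite strands at the same start are distinct events, and overlapping hits
are all reported; no greedy pruning. Windows containing N are skipped rather
than scored (no worst-case imputation) and tallied per gene as
`masked_windows` in the scan provenance. Scans are deterministic; re-running
a scan yields byte-identical tables.

## Profiling definitions

Region counts are hit events (matrix × position × strand), not distinct TFs
— the magnitudes a several-hundred-matrix library produces per promoter only
arise under event counting — with a distinct-TF summary carried alongside.
The lenient tier contains the stringent tier by construction, so stringent
counts can never exceed lenient counts. MRTF and gene-specific logic
aggregate at `tf_name` level by default (a TF binds if any of its matrices
hits); `matrix_id` aggregation is available. Gene-specific sets are computed
on the lenient tier only. The MRTF "core" is kept as an explicit
intersection of the lenient and stringent sets even though nesting makes it
equal to the stringent set within one scan — hit tables produced by
different scans can then be intersected meaningfully. The CArG matcher
searches CC(A/T)₆GG on the forward strand only, which suffices because the
pattern is its own reverse complement; overlapping matches are reported.

## Expression

RPKM = C·10⁹/(N·L), RPM = C·10⁶/N. N is the per-sample total mapped reads
supplied with the table (library sizes are inputs, never recomputed), and L
is the supplied per-gene summed exon length — the pipeline starts from
mapped counts, not reads. CV% uses the sample standard deviation (n−1).
Ranking is dense by mean with ties broken by table order, so it is always a
permutation. The optional +1 offset exists solely for log-scale heatmap
export; `replicate_stats` refuses +1 tables. Group ratios (e.g.
control/treated RPM) are report annotations, not tests — no differential
expression model is fitted.

## Networks

Self-loop handling in degrees is an explicit policy because conventions
differ: the default `out_only` (self-loop adds 1 to out-degree, nothing to
in-degree) is the convention under which the packaged floral fixture
reproduces its published hub values (SEP3 out 5 / in 4); `both` and `none`
are selectable. Clustering coefficients are computed on the undirected
simple projection (directions and self-loops dropped), 2·Δ(v)/(k(k−1)) with
k < 2 giving 0. The packaged fixture `data/floral_edges.tsv` is a
transcription of reported activation relationships among the floral MADS-box
and timing genes (18 edges over 13 genes); "may activate" edges are tagged
`putative`. Binding-derived edges (TF's own gene → target, one per TF–gene
pair with a lenient hit) are provenance-tagged so curated and predicted
topology stay distinguishable.

## Synthetic data

Generators emulate the real inputs at chosen difficulty and are pure
functions of (seed, parameters). Matrix sharpness is the per-column
consensus probability (counts at depth 1000, remainder split across the
other bases); sharpness 1.0 gives single-positive-count columns. Promoter
backgrounds are order-0 i.i.d. — A/T-richness can be set via the
composition, but dinucleotide structure, CpG effects and chromatin context
are not modeled, so passing recovery tests demonstrates correctness of the
machinery, not performance on real promoters. Plants overwrite the
background with the matrix consensus (reverse-complemented for minus-strand
plants); overlapping plants are rejected with the offending pair named, so
ground truth is exact. Count simulation draws negative-binomial counts with
mean rate·N·L/10⁹ (rates are expected RPKM) and variance μ + αμ²;
dispersion 0 gives Poisson.

### What planted-recovery experiments can and cannot show

With exact p-values, a lenient threshold of 10⁻⁴ over megabases of scanned
background necessarily yields chance hits: for a sharpness-0.97 10-mer, the
consensus plus its 30 one-mismatch neighbours have tail probability
31/4¹⁰ ≈ 3 × 10⁻⁵ < 10⁻⁴, so every one-mismatch word in the background is a
legitimate lenient hit — about 6 expected per matrix across 17 foreign 6-kb
promoters, the same multiple-testing arithmetic that gives real promoter
surveys hundreds of sites per gene. Consequently planted *panel-wide* TFs
are recovered as the exact MRTF set (chance coverage of every one of 18
promoters is vanishingly rare, ≈ 3 × 10⁻¹⁰ per matrix) and planted sites are
recovered at their exact positions and tiers, but *exclusivity* of a
single-gene plant is destroyed with near certainty by those chance hits.
The recovery tests therefore assert what the statistics guarantee — exact
MRTF sets and exact planted-site recovery — and the gene-specific analysis
is validated on fabricated hit tables (`make_profile_fixture`), where
exclusivity is true by construction.

## Numerical and degenerate-input choices

Probabilities from the convolution must sum to 1 within 10⁻⁹ (asserted).
Cutoff queries require p ∈ (0, 1]; at p = 1 no word passes for a flat matrix
(P(S ≥ min) = 1 is not < 1), the documented boundary semantics. Windows
shorter than the motif produce an empty table with a warning rather than an
error. Duplicate matrix ids in a library, duplicate promoter gene ids,
ragged matrix rows, zero backgrounds, single-gene fixture panels, and
stringent-above-lenient thresholds are all rejected with named errors.
Problem sizes in tests and the acceptance script (panels of 4–18 six-kb
promoters, libraries of 2–20 matrices, enumeration oracles up to L = 8) were
chosen as the smallest sizes at which every claimed property is
distinguishable from chance; the planted-recovery experiment runs the full
18-promoter × 20-matrix design in about a second.

## Known limitations

Zeroth-order background and independent-column motif model (no
dinucleotide dependence); no chromatin-accessibility weighting; no
higher-order background for p-values; promoter extraction, read alignment
and GO/pathway annotation are out of scope. Numeric agreement with hit lists
produced by other scanners depends on their (often undocumented) pseudocount,
background and p-value conventions and is not guaranteed.
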