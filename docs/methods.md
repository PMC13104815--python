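# Methods

## The measurement being modeled

A lentiviral library delivers a 265-bp semi-random barcode into the 3′UTR of
a reporter transcript, so every transduced founder cell and its descendants
express a clone-specific sequence recoverable from RNA-seq reads. In reads,
the barcode sits immediately downstream of a fixed 33-bp vector-backbone
anchor (`CAGATCTTAGCCACTTTTTAAAAGAAAAGGGGG`); the first 10 barcode bases are
used as the compact clone identifier ("barcode suffix"). Transduction at
MOI < 0.4 keeps multiple integrations rare (Poisson: at MOI 0.4 about 18.7 %
of barcoded cells carry ≥ 2), and cells where more than one genuine barcode
survives QC are discarded rather than deconvolved.

## Barcode extraction and the QC cascade

Anchor search is an exhaustive sliding-window Hamming scan; the leftmost
window within `max_mismatches` (default 2 over 33 bp) wins. Two mismatches
tolerate ~1 % per-base sequencing error (the anchor is error-free in
0.99³³ ≈ 72 % of such reads, within 2 errors in ≈ 99.6 %) while keeping
chance matches negligible (a random 33-mer window matches within 2 errors
with probability ≈ 3·10⁻¹⁷). Untagged (bulk) reads are also scanned in
reverse complement; tagged 10x-style reads are single-orientation by
construction and are not.

Each read receives exactly one status — reads are conserved across
categories:

* `NO_ANCHOR` — no qualifying window on the relevant strand(s).
* `SHORT_BARCODE` — fewer than `id_length` bases follow the anchor.
* `EMPTY_VECTOR` — the post-anchor window matches the fixed downstream
  vector sequence within `max_mismatches` *and* at least as well as a
  pattern-conformant barcode would. The comparative clause matters only for
  restrictive degenerate patterns; under the default fully random `N`²⁶⁵
  pattern the absolute threshold does the work. The comparison window is
  `min(len(downstream_fixed), bases available)` and requires at least
  `id_length` bases, so truncated reads fall into `SHORT_BARCODE` first.
  The default downstream signature is the 5′ end of the WPRE element, a
  standard lentiviral 3′-cassette component.
* `BAD_PATTERN` — the 10-base clone-ID region violates the degenerate
  pattern (meaningful when a non-`N` design is configured; the true
  semi-random design is proprietary to the platform, so the pattern is fully
  configurable and defaults to `N`²⁶⁵).
* `PASS` — clone ID = first `id_length` bases after the anchor.

UMI deduplication is exact-match: one molecule per distinct
(sample, cell barcode, UMI, clone ID), read counts retained. No directional
UMI-network collapse is attempted; at 10–12 bp UMIs and the molecule counts
involved, UMI collisions are a second-order effect.

**Cell resolution.** Within a cell, clone IDs are first collapsed by a
directional adjacency rule borrowed from UMI-collapse practice: ID *a*
merges into the more abundant *b* when Hamming(*a*, *b*) ≤ 1 and
2·count(*a*) ≤ count(*b*). This removes the spurious "second barcodes" that
single-base errors in the 10-mer create (at 1 % error, ~10 % of reads carry
an errored ID; without collapse, two such reads hitting the same neighbor ID
in one cell would masquerade as a double integration and the cell would be
lost). Genuine co-integrations are untouched: two real barcodes are Hamming-1
neighbors with probability ≈ 30/4¹⁰ ≈ 3·10⁻⁵, and balanced counts (e.g.
20 vs 18) never merge. After collapse, IDs supported by < `noise_min_umis`
(default 2) UMIs **and** < `noise_min_fraction` (default 10 %) of the cell's
barcode UMIs are dropped as ambient/chimeric noise. A cell keeping exactly
one ID is assigned; ≥ 2 → rejected `MULTI_BARCODE`; 0 → `NO_BARCODE`.

**Expression QC.** Cells with < 2,000 detected genes, > 50,000 UMIs, > 20 %
mitochondrial reads, or > 20 % mouse-mapped reads (xenograft host filter;
column optional) are removed. Boundary values are retained — the thresholds
are strict inequalities on the rejection side.

## Diversity and fate statistics

Shannon diversity is computed in natural-log units over the clone abundance
distribution (cells per clone for single-cell data, UMI-deduplicated
molecules or reads for bulk); H = 0 for a monoclonal sample, H = ln S for a
uniform one. The variance estimator is Hutcheson's,
var(H) = [Σ pᵢ(ln pᵢ)² − H²]/N + (S−1)/(2N²), and two samples are compared
with t = (H₁−H₂)/√(var₁+var₂) on Welch–Satterthwaite degrees of freedom
(var₁+var₂)²/(var₁²/N₁ + var₂²/N₂), two-tailed. Two degenerate cases:
identical indices with zero variance return t = 0, p = 1; zero variance with
unequal indices is impossible under the estimator and raises. Simulation at
the null (two multinomial draws from one frequency vector, N = 800, 20
clones, 1,000 replicates) puts the empirical type-I error at ≈ 0.057 for
α = 0.05.

Fate classification labels each primary-detected clone by the set of
metastatic sites where its abundance reaches `min_count` (default 1 — pure
presence; sequencing-noise floors can be imposed by raising it). For the
canonical two-organ design the labels are tumor_only / lung_only /
liver_only / shared; other site sets generalize to `<site>_only`, `shared`
(all sites), and '+'-joined subsets. Clones found only in a metastasis are
labeled metastasis_only and excluded from both percentage denominators.
Percentages are rounded to one decimal, half away from zero, to match how
such fractions are conventionally printed; rounded fractions therefore sum
to 100 ± 0.2.

## Consensus reconstruction

Reads sharing a clone ID are stacked at their anchor offset and assumed
co-linear — there is no indel handling, which is acceptable because
substitutions dominate Illumina error profiles; an indel-bearing read
shifts out of frame, depresses the majority fraction at downstream
positions, and surfaces as ambiguity rather than as a wrong call. Per
position, the plurality base is called when depth ≥ `min_depth` (default 3)
and plurality fraction ≥ `min_majority` (default 0.6); ties, failed
majorities and under-covered interior positions yield `N` and are logged as
ambiguous; the consensus truncates at the last position meeting the depth
floor. At 1 % substitution error and depth 30 the per-position accuracy
exceeds 99.9 %. Bulk and single-cell hit sets are pooled without source
weighting — both observe the same molecule population and plurality voting
needs no reweighting.

## The generative model (and what it does not emulate)

Defaults describe the intended experimental regime: MOI 0.3; a library
(10,000 barcodes) much larger than the founder population so barcode
collisions between founders are rare; Dirichlet-multinomial expansion with
concentration 0.3 over founders, producing the hierarchical skew that
characterizes tumor outgrowth (a lognormal-fitness birth–death weighting is
available as the alternative mechanism — the data constrain the outcome,
not the mechanism); metastatic seeding as sampling without replacement from
the primary population, either `cells` (default — dissemination is a
cell-level event; hypergeometric over clone counts) or whole `clones`
(niche-colonization view; both are exposed because the data cannot
distinguish them); ~12 barcode molecules per cell (a highly expressed
reporter transcript) at sequencing saturation ~2 reads per molecule;
per-base substitution errors applied uniformly across the read, including
anchor and clone-ID regions.

Simulated reads default to 318 bp — 20 bp of 5′ vector context, the 33-bp
anchor and the full 265-bp barcode — so that single reads can cover the
whole barcode; real 3′-end libraries cover the barcode piecewise and would
reconstruct it from partial stacks (which the consensus module supports via
`read_length`). Other simplifications: no transcriptome, doublets, ambient
RNA, UMI-tag errors, or indels; empty vectors are drawn per molecule (an
insert-less integration produces its own transcripts), so with one read per
molecule the empty-read count is exactly binomial. Passing tests therefore
demonstrate correctness of the algorithms under this error model, not
robustness to artifacts the simulator does not produce.

Determinism: every stochastic step derives from `numpy.random.default_rng`
seeded from `SimulationConfig.seed` (stage offsets +1/+2 keep stages
decoupled); a fixed config reproduces reads bitwise.

## Problem sizes

Test and demonstration runs use hundreds of founders, thousands of primary
cells, 100–400 sequenced cells per site and 10³–10⁴ reads per run; null
calibration uses 1,000 replicates and monotonicity checks 100 replicates.
These sizes give stable statistics (binomial/multinomial SEs well inside the
asserted bands) while keeping any single suite comfortably fast; all
qualitative conclusions are size-independent.

## Known limitations

* The true semi-random barcode design is not public; with the default `N`
  pattern the `BAD_PATTERN` filter is inert (nothing violates `N`), so
  pattern-based error rejection only activates for user-supplied designs.
* Clone identity is the 10-base suffix: distinct 265-mers sharing a suffix
  collide (probability governed by library size / 4¹⁰; at 10⁴ barcodes,
  ~4.6 % of libraries contain at least one suffix pair, and truth tables
  track full barcodes so collisions are measurable).
* The Hutcheson test inherits the usual large-N normality caveats; for very
  small samples its p-values are approximate.
* Multi-integration cells are rejected, not deconvolved; their clones are
  invisible to single-cell fate calls (bulk read counting still sees them).
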