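# Methods

## Super-enhancer calling

Enhancer candidates are H3K27ac peaks supplied as BED/narrowPeak; peaks
overlapping a blacklist region or a ±2 kb window around any TSS are removed
before stitching. Peaks on one chromosome whose gap (end to next start) is
at most the stitch gap (default 12 500 bp, the customary ROSE default) are
merged transitively; each stitched region's signal is the plain sum of its
constituents' scores (narrowPeak signalValue, column 7 — column 5 is capped
at 1000 and never used). No length normalization or input subtraction is
applied: scores are taken as the peak caller produced them, which keeps the
ranking reproducible from peak files alone; their exact semantics (height
vs area) are delegated to the input.

The super/regular split follows the geometric argument: sort total signals
ascending, rescale rank index and signal each to [0, 1], and find the first
discrete step whose slope exceeds 1. Regions with signal strictly above the
signal at that step are super-enhancers. Degenerate inputs: a perfectly
linear curve has no step above unit slope and flags nothing; fewer than 3
regions flags nothing (with a warning); constant signals flag nothing.

## Interaction significance

Contacts are tab-separated (mid1, mid2, count) triples per chromosome, or
5-column records with chromosome names (inter-chromosomal rows are dropped
with a logged count). Bins are anchored to the genome grid — bin *k* covers
[k·res, (k+1)·res) with midpoint k·res + res/2 — matching published 5 kb
matrix dialects.

Each chromosome's dense symmetric matrix is balanced by iterative
correction: divide entry (i, j) by bᵢbⱼ, with b the row-sum vector rescaled
to mean 1 over non-empty rows, until the coefficient of variation of row
sums falls below 1e-6 (default; at most 500 iterations). The accumulated
bias vector satisfies raw = norm · bᵢ · bⱼ exactly. All-zero rows are
masked: their bias stays 1 and they remain zero. Self-pairs stay in the
matrix for balancing but are excluded from testing by the distance window.

Significance is a deliberately simplified Fit-Hi-C: pairs with
10 kb ≤ d ≤ 2 Mb (inclusive) are partitioned into up to 100 equal-occupancy
distance bins (ties at one distance never split); each bin's expected
contact probability is (Σ normalized counts)/(N·pairs-in-bin), where N is
the rounded total normalized count in range; probabilities are pooled to be
monotone non-increasing (weighted isotonic regression). Each pair's p-value
is the upper-tail binomial probability of at least its (rounded normalized)
count in N trials at the expected probability for its distance, with
Benjamini–Hochberg control and significance at q ≤ 0.01. This preserves the
published method's contract — distance-corrected, FDR-controlled calls —
without the two-pass spline refinement; pre-called pairs can bypass it
entirely. Zero-count pairs are kept in the table and tested: restricting
the test to observed-positive pairs makes the null p-values conditionally
anti-conservative and breaks FDR calibration.

Bin frequencies: each significant pair increments the bin of each midpoint
by 1; a pair with both midpoints in one bin increments it by 2 (documented
choice; "associated with the bin" is otherwise ambiguous). In pre-called
pair mode each anchor interval increments every bin it overlaps by 1.

## H-score and hub classification

SE spans are intersected with the genome-grid bins (a partially covered bin
counts its full frequency: the frequency is a property of the Hi-C bin, not
of the overlap fraction). Frequencies are standardized with the population
SD (divide by n); this gives the clean extremal bound H ≤ √(n−1) and makes
an 8-bin one-hot frequency pattern score √7 ≈ 2.646. A constant vector
(including all-zero) is defined as H = 0, never hierarchical. Thresholding
is strict (H > t, z > t; default t = 1.5, sweeps such as 1.25/1.75
supported). Hub labels exist only inside hierarchical SEs: a constituent is
hub iff it overlaps (half-open) at least one bin with z above the
threshold. The tool reports the empirical percentile of the threshold over
all SE bins but does not calibrate with it. Interaction-subtype leave-outs
re-classify each significant pair by what its two anchor bins overlap
(enhancer / CTCF / promoter; labels may co-occur) and drop pairs matching
the excluded unordered label pair before recomputing frequencies.

## Annotation statistics

Variant enrichment is (m/n)/(M/N): by default m counts group loci
overlapping ≥ 1 variant (matching figure labels of the form "number of
enhancers overlapping eQTLs"); a per-variant mode is available. The genome
background is the regular-enhancer list shuffled uniformly per chromosome
(chromosome drawn proportional to eligible start positions), 10× by
default, seeded; the Fisher exact test is two-sided on
[[m, n−m], [M, N−M]]. The background scored against itself gives exactly 1.
Shuffling can exclude regions (default: none — whether the original
analysis avoided blacklist regions is unstated).

CTCF context: peaks overlapping both a hub enhancer and a TAD boundary are
excluded; otherwise hub > TAD-boundary > non-hub > other, giving a strict
partition. Cell-type consensus is the percentage of cell-type peak sets
with any overlap. Motif scores are max log₂-odds over both strands
(pseudocount 1e-3 per PWM cell before column normalization; ambiguous bases
score 0). Signal profiles average a bedGraph-like track in offset bins
around anchor midpoints, strand-ignored; point features are counted per
offset before averaging; smoothing is a centered moving average of the
stated bp window. Enhancer–promoter edges require a significant pair with
one anchor bin on the enhancer, the other on the ±2 kb promoter window, and
enhancer, promoter and both anchors contained in a single TAD. When only
TAD intervals are given, boundaries are ±(res/2) windows around TAD edges.
Expression specificity is expression in the target cell over the mean
across cell types (zero-mean genes are missing).

## Synthetic data

The generator emulates the features the pipeline depends on, at desk scale
(defaults: 4 chromosomes × 1.5 Mb at 5 kb; 56 SEs of 8 bins, half
hierarchical; 40 isolated regular enhancers; 400 variants):

- **Peaks.** Each SE is 4–7 constituents evenly spread over a 40 kb span
  (always within stitching distance), scores log-normal with SE
  constituents well above regular enhancers so the rank cutoff has a
  planted answer. Decoy peaks inside the blacklist and within 2 kb of a TSS
  exercise the candidate filter.
- **Contacts.** Pair (i, j) at distance d bins is Poisson with mean
  μ·d^(−α) (μ = 10 at adjacent bins, α = 1), doubled within a TAD
  (~750 kb domains with edges between SE/RE units) to emulate domain
  insulation; the diagonal gets 4μ and is excluded from testing by the
  distance window. All pairs, including zero counts, are emitted.
- **Hubs.** Each hierarchical SE's last bin is its hub, connected to
  partner bins 2 and 3 bins away (10/15 kb, same TAD, outside the SE) with
  the pair mean multiplied by the hub fold (default 5). The enhancement is
  deliberately loop-sparse: multiplying *every* contact touching a bin is
  exactly a multiplicative row bias D·C·D, which matrix balancing removes
  in full — such a "hub" is unrecoverable by construction through any
  ICE-based pipeline. Sparse partner loops are also the biologically
  sensible picture of a hub element engaging distal partners. The
  within-TAD enrichment matters here too: it raises the short-range
  expected counts to a regime where a 5-fold loop clears genome-wide FDR
  control robustly rather than marginally.
- **Variants** are placed uniformly over bins with hub bins oversampled by
  a configurable fold (default 5); CTCF peaks sit at hub bins and TAD
  boundaries; TSS/promoters at loop partner bins and in empty regions.

What the generator does *not* model: coverage/mappability bias and GC or
fragment effects (so ICE is bias-free on these data and acts only as the
pipeline's normalization contract), compartments, loop extrusion geometry,
replicate structure, and sequence content. Passing tests therefore
demonstrate the statistical contracts of the method — recovery of planted
concentration structure, FDR calibration, balancing invariants — not
performance on real Hi-C libraries.

Measured under the default planted conditions (hub fold 5, background mean
10, seed 7): hub-bin sensitivity and precision and hierarchical/
non-hierarchical accuracy are all ≥ 0.95, while with no planted structure
(fold 1) across 10 seeds no SE is called hierarchical and the self-simulated
null yields a discovery fraction ≤ 0.02 at FDR 0.01 with super-uniform
p-values (`tests/test_acceptance.py`, `scripts/acceptance.py`).

## Numerical and design notes

- Coordinates are 0-based half-open everywhere; BED verbatim; strand is
  ignored in all overlap logic. Overlap queries use a per-chromosome
  sorted-start index with prefix-max ends.
- Ranking ties break by (chrom, start); region ranks are a permutation of
  1..N.
- Shuffling rejects placements overlapping the excluded set up to 1000
  times per interval, then errors.
- The binomial test uses rounded normalized counts; expected probability 0
  with a positive observation yields p = 0 with a warning.
- Golden regression: the packaged fixture (2 chromosomes × 2 Mb, 12 SEs,
  60 REs) is regenerated from a stored seed at test time and compared
  byte-for-byte against frozen outputs shipped in `sehier/data/golden/`.
- The ChIA-PET-style pre-called-pairs mode reuses the Hi-C hub definitions
  unchanged.

## Limitations

The significance caller is not the published two-pass spline Fit-Hi-C and
will differ in detail on real data; biological SE counts and enrichment
values reported in the literature depend on external ENCODE/Hi-C/GWAS
resources and are out of scope here. H-scores compare bins *within* an SE
only, so an SE whose interactions are uniformly high scores low by design.
Very long SEs (many bins) can reach high H-scores from modest outliers;
thresholds should be swept when bin counts vary widely.
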