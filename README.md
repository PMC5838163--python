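# sehier

Dissect the internal hierarchy of super-enhancers (SEs) from chromatin
interaction data.

Super-enhancers — clusters of enhancer peaks with unusually high aggregate
H3K27ac signal — are not homogeneous: in many SEs the long-range chromatin
interactions concentrate on one or a few constituent elements. `sehier`
quantifies this with the **H-score** and classifies SEs and their
constituents accordingly:

1. **SE calling.** H3K27ac peaks (minus blacklist and ±2 kb promoter
   regions) are stitched when closer than 12.5 kb, ranked by total signal,
   and split into super vs regular enhancers at the point where the rescaled
   signal-vs-rank curve reaches unit slope (the ROSE geometric cutoff).
2. **Interaction frequencies.** Raw intra-chromosomal contact matrices are
   balanced by iterative correction (ICE), and statistically significant
   interactions are called with a distance-corrected binomial test
   (equal-occupancy distance bins, isotonic monotone expected model,
   Benjamini–Hochberg FDR, defaults 10 kb ≤ d ≤ 2 Mb, FDR 0.01). Each 5 kb
   bin's *interaction frequency* is the number of significant interactions
   touching it. Pre-called interaction pairs (e.g. ChIA-PET PET clusters)
   can be supplied instead.
3. **H-score.** Each SE is divided into 5 kb bins; bin frequencies
   f₁…fₙ are standardized within the SE, zᵢ = (fᵢ − mean f)/sd(f), and
   H = max zᵢ. SEs with H > 1.5 are **hierarchical**; within them,
   constituents overlapping a bin with z > 1.5 are **hub enhancers**, the
   rest non-hub. (With population-SD standardization H ≤ √(n−1), so SEs of
   ≤ 3 bins are never hierarchical at the default threshold.)
4. **Annotation statistics.** Variant fold-enrichment
   (m/n)/(M/N) against a shuffled-enhancer background with Fisher exact
   tests, CTCF binding-context classification (hub / non-hub /
   TAD-boundary), PWM motif scanning, signal profiles around anchors, and
   enhancer–promoter mapping constrained to TADs.

A seedable synthetic-data generator produces complete desk-scale fixtures —
peaks with planted SE structure, distance-decay contacts with planted hub
loops, TADs, CTCF peaks, and hub-enriched variants — with ground-truth
labels for every downstream test.

## Worked example

Generate a synthetic dataset (56 SEs on 4 × 1.5 Mb chromosomes, half with a
planted hub) and run the full pipeline:

```sh
sehier simulate --seed 7 --out fixture
sehier run-all \
    --peaks fixture/peaks.narrowPeak --contacts fixture/contacts.tsv \
    --chrom-sizes fixture/chrom.sizes --blacklist fixture/blacklist.bed \
    --tss fixture/tss.bed --tads fixture/tads.bed \
    --variants fixture/variants.bed --seed 1 --out results
```

`results/hierarchy_calls.tsv` lists every SE with its bin count, H-score
and class:

```
# se_id  chrom  start    end      n_bins  h_score   class             n_hub_bins
SE_1     chr3   210300   249700   8       2.645751  hierarchical      1
SE_2     chr1   1110300  1149700  8       2.645751  hierarchical      1
SE_3     chr2   1410300  1449700  8       0.000000  non-hierarchical  0
```

An H-score of 2.646 = √7 is the maximum for an 8-bin SE: all significant
interactions sit in a single bin. `results/enrichment.tsv` reports variant
fold-enrichment per enhancer group against a 10× shuffled background:

```
# group   m   n    M   N    score     fisher_p
hub       15  28   40  400  5.357143  7.206505e-08
non-hub   18  137  40  400  1.313869  3.386944e-01
regular   5   40   40  400  1.250000  5.855250e-01
```

Hub enhancers carry a 5.4-fold variant enrichment (15 of 28 hub enhancers
overlap a variant, vs 40 of 400 background loci), while non-hub and regular
enhancers sit near background — the planted structure of the fixture. The
run manifest records all parameters and summary counts
(`56 super-enhancers, 28 hierarchical, 28 hub enhancers`).

Other subcommands: `call-ses`, `hic-sig`, `hscore`, `enrich`,
`ctcf-context`, `sitepro`, `ep-map`; see `sehier <cmd> --help`. All of this
is equally available as a library (`sehier.se_calling`, `sehier.hic`,
`sehier.hierarchy`, `sehier.annotation`, `sehier.simulate`,
`sehier.pipeline.analyze`).

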