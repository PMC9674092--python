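# Methods

This note records the statistical procedures, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Gene lists and catalog scoring

Up-regulated genes are `log2fc > lfc_min` with adjusted significance below
the active cutoff; down-regulated genes mirror this with `log2fc <
-lfc_min`. All inequalities are strict. Defaults: `lfc_min = 0.3`,
`q_max = 0.1` for the broad program definition; the motif gene list uses
adjusted p < 0.05 and the ChIP gene list adjusted p < 0.01 (both applied to
the table's adjusted-significance column), and the motif list is optionally
truncated to the top 1,000 genes after sorting by log₂FC. Ties in top-N
sorting break by ascending q and then lexicographic gene id, so outputs are
reproducible. Gene-id matching is case-insensitive exact match; aliases are
an ingestion concern.

Catalog over-representation uses the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n) with N = features detected in the table
(not the whole genome — detection limits the comparison), K = catalog genes
among them, n = size of the up list, k = catalog genes in the up list.
"Changed" in grouped counts and in the cross-dataset activation matrix is
|log₂FC| > 0.3 and q < 0.1, i.e., the union of the up and down rules;
configurable. Ingested q-values are used as-is when present (they come from
the upstream DE fit); a Benjamini–Hochberg helper is provided for tables
that ship only raw p-values. Row Z-scores use the sample standard deviation;
zero-variance rows map to zeros with a warning rather than NaNs.

## Promoter motif analysis

Windows span `half_width = 500` bp on each side of the TSS. Both strands use
the same genomic interval `[tss − hw, tss + hw)`; minus-strand windows are
reverse-complemented, so offsets are always in gene orientation with
upstream negative. Edge windows are clipped and flagged.

PWMs are per-position probability matrices with a pseudocount (default
0.01 per cell, renormalized) and a background model (default uniform;
recommended: the negative set's base composition). Scores are log-odds in
bits; an ambiguous base contributes 0 (background). The default scan
threshold is 80% of the maximal attainable log-odds; hit centers sit
`floor(width/2)` bases from the hit start, which is deterministic for even
widths (strand-symmetry of the center holds exactly for odd widths and to
±1 bp for even widths). The best hit per gene is the maximal score, ties
resolved toward the most TSS-central, then 5′-most, position.

Central enrichment: for a central half-width w, π(w) is the fraction of
negative-set genes (denominator includes hitless genes) whose best hit lies
within ±w; the number of target genes inside is tested against
Binomial(n_target, π(w)) upper tail. π is clamped below by 1/(2·n_negative)
so the tail is defined when the negative set is bare. The default is a
single pre-chosen central region of w = 250 bp — half the window — so the
reported p-value has calibrated size; a grid of widths may be supplied, in
which case the minimal p is Bonferroni-corrected by the grid size and the
winning width reported (conservative by construction). The negative set is
a uniform draw of genes (default 1,000) excluding the target genes;
exclusion is configurable.

## TSS-proximal peak enrichment

Peak membership is by peak center, `floor((start+end)/2)`, giving every
peak an unambiguous signed distance; BED input is 0-based half-open, GFF3
is converted from 1-based inclusive internally. One TSS per gene is
selected as the 5′-most transcript start in gene orientation. Distances are
negated for minus-strand genes so upstream is always negative; profiles bin
the window (±10 kb, 500 bp bins by default).

The enrichment statistic is the mean number of peak centers within ±10 kb
per target gene. The null resamples negative gene sets of matched size
(|draw| = |target|) B times from the configured pool — random genome genes,
or genes expressed but unchanged — and p = (1 + #{null ≥ obs})/(B + 1),
a valid (slightly conservative under ties) permutation-style estimate.
Matched-size resampling makes the statistic scale-free; the raw
1,000-gene negative-set distance profile is also emitted for the
distribution overlay. An exhaustive mode enumerates all C(pool, k) subsets
with p = mean(null ≥ obs) for small instances; it backs the test-suite
oracle. B defaults to 999 (resolution floor p = 0.001).

## Cilium morphometry

Traces are ordered 3D polylines in µm (the unit is declared in the file and
enforced). Arc length is the sum of segment norms; the chord is the
endpoint distance; tortuosity is arc/chord. The length proxy is the longest
edge of an oriented bounding box minimizing (volume, then longest edge).
Degenerate ranks are handled explicitly: collinear sets use the line
extent; planar sets use the exact edge-aligned minimal-area rectangle
(rotating calipers — an edge-aligned orientation always attains the minimal
area); full-rank sets search hull-face-aligned orientations (each face
normal as a box axis with in-plane calipers) plus the principal-axis
orientation. This face-flush construction is the standard minimal-volume
heuristic; it is rotation-equivariant, which the tests check to 10⁻⁶ µm.
Note a geometric property of any minimal-volume box: for strongly curved
traces its longest edge can fall a few percent below the chord, so the
proxy–chord ordering is only guaranteed for elongated shapes.

Morphology classes are explicit rules replacing by-eye assignment:
straight if tortuosity < 1.05; contorted if tortuosity ≥ 1.5 *or* the trace
returns within 0.2 µm of a point more than 1 µm away along its own contour
(a self-proximal loop — the contour-gap condition stops smooth local
curvature from counting); otherwise bent. Boundaries are half-open
(tortuosity exactly 1.05 is bent). All thresholds are configurable and
echoed in outputs.

Group comparison: two-sample Kolmogorov–Smirnov on per-cilium lengths
(exact p when either group has fewer than 25 cilia, asymptotic otherwise),
and one-way ANOVA of length by genotype computed twice — with the cilium
and with the per-mouse mean as the unit of analysis — because nesting of
cilia within animals makes the cilium-level test anti-conservative; both
are reported. Class proportions are per genotype.

## Synthetic data generator

The generator emulates the study conditions each stage is benchmarked
under; its defaults are fixed once:

- **Genome**: uniform random TSSs with a 10 kb end margin and ≥ 2 kb
  spacing, strands ~50/50, one TSS per gene.
- **Differential table**: a planted fraction (default 0.6) of the catalog
  is forced up-regulated with log₂FC ~ N(2.0, 0.5) and p ~ Beta(0.002, 1);
  all other genes draw log₂FC ~ N(0, 0.1) and p ~ U(0, 1); q is BH over the
  table. The planted Beta shape is extreme enough that a forced gene
  survives BH at q < 0.1 with probability > 0.98 at the default table size,
  which is what "forced up-regulated" must mean for recovery tests.
- **Promoters**: i.i.d. background (uniform by default, configurable);
  the consensus (random strand) is inserted with its center at
  N(0, 50 bp) relative to the TSS for planted genes; true offsets are
  returned.
- **Peaks**: uniform background at 2×10⁻⁵ peaks/bp; Poisson(2) excess
  peaks per target gene at N(0, 1000 bp) around the TSS; 200 bp wide.
- **Cilia**: fixed-step directed walks whose direction receives an
  isotropic Gaussian kick of magnitude `curvature` per step; arc length
  N(3.8, 1.0) µm with curvature 0.08 for control and N(5.6, 1.4) µm with
  curvature 0.25 for the mutant group, chosen to emulate a population that
  is both longer and visibly more bent/contorted, with box-length ranges
  and a KS separation of the magnitude reported for astrocyte cilia under
  mitochondrial dysfunction.

What the generator does *not* emulate: mappability and GC structure of real
promoters, dinucleotide background, ChIP fragment-size effects, correlated
multi-TSS gene models, segmentation noise in traces, or between-animal
variance components. Passing recovery tests therefore demonstrates the
statistics are correct and calibrated under their stated models, not that
real-data confounders are handled.

All randomness flows from one explicit seed; every written file carries the
seed in its header, and the pipeline derives stable per-stage seeds from
the run seed by hashing.

## Calibration checks and problem sizes

The test suite verifies, at sizes chosen to keep the default run fast:
gene-list equality with a brute-force filter on 1,000 random tables;
hypergeometric tails against exhaustive enumeration for universes ≤ 12;
scan equality with a naive rescan on 500 random windows; signed distances
against all-pairs brute force; KS statistics against exhaustive ECDF-gap
maximization; OBB proxies against a 0.1° rotation-grid search on planar
polylines; empirical type-I error of both enrichment tests within two
binomial standard deviations of the nominal 0.05 over 200 null replicates
(the calibration scans use a permissive weight-6 PWM at a 4-bit absolute
threshold so background best-hits exist for essentially every gene — a
sharp consensus PWM at the default threshold has no background hits and the
null statistic would be degenerate); planted-signal power at p ≤ 0.01 with
200 target genes and B = 999; and recovery of the planted 0.6 activation
fraction to within ±0.05 over 200 seeds at a 92-gene catalog.

## Known limitations

- The central-enrichment p-value treats the negative-set concentration
  π(w) as known; with the default 2:1-or-larger negative:target ratio the
  extra variance inflates the size by at most a few hundredths, which the
  calibration test bounds.
- The resampling positional test conditions on the observed peak set; it
  does not model biological replication of the ChIP experiment.
- The OBB length proxy slightly underestimates curved-object length by
  construction (box geometry), exactly as any bounding-box length does.
- Proteomic and metabolite tables reuse the RNA threshold machinery; the
  "changed" rule for those modalities is configurable because upstream
  pipelines differ in their adjusted-significance conventions.
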