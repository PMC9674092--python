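# astrocilia

Detection of **motile-ciliogenesis program activation** from bulk
differential-expression data, with promoter-motif and ChIP-peak positional
enrichment and cilium morphometry.

Astrocytes normally carry a single immotile primary cilium. Under chronic
metabolic stress (e.g., mitochondrial DNA depletion) they can aberrantly
switch on the transcriptional program that builds *motile* cilia — dynein
arms, radial spokes, the central microtubule pair — driven by the RFX
transcription-factor family and FOXJ1, while the cilium itself elongates and
becomes contorted. `astrocilia` packages the computational analyses needed
to detect and quantify such a program switch, for transcriptomics or
proteomics differential tables plus standard genomic annotation formats:

1. **Gene lists and catalog scoring** (`astrocilia.de_programs`) — strict
   threshold rules (log₂FC > 0.3 and q < 0.1 by default; stricter adjusted-p
   rules for the motif and ChIP gene lists; optional top-N sorted by log₂FC)
   and program scoring of curated catalogs (motile-specific /
   primary-specific / pan-ciliary, astrogliosis markers, lipid classes):
   up/down/changed counts, a hypergeometric over-representation tail
   P(X ≥ k) with X ~ Hypergeom(N, K, n) over the detected-feature universe,
   cross-dataset activation matrices, and row Z-scores for heatmaps.
2. **Promoter motif enrichment** (`astrocilia.motifs`) — TSS ± 500 bp
   windows, both-strand log-odds PWM scanning
   (score = Σᵢ log₂ pᵢ(b)/q(b), in bits; JASPAR PFM and MEME-minimal input),
   best hit per gene, and a *central enrichment* test: with π(w) the
   fraction of a random-gene negative set whose best hit lies within ±w of
   the TSS, the target count is tested against Binomial(n, π(w)) upper tail.
3. **TSS-proximal ChIP-peak enrichment** (`astrocilia.peaks`) — signed
   peak-center-to-TSS distances (upstream negative, gene orientation) within
   ±10 kb, distance-distribution profiles, and an empirical resampling
   test: statistic = mean peaks per gene in the window; the null is built
   from B matched-size draws out of a negative gene pool (random genome
   draw, or expressed-but-unchanged genes); p = (1 + #{null ≥ obs})/(B + 1).
4. **Cilium morphometry** (`astrocilia.morphometry`) — per-cilium arc
   length, end-to-end chord, tortuosity (arc/chord ≥ 1), a length proxy
   (longest edge of a minimal oriented bounding box of the 3D trace), rule
   based straight/bent/contorted classification, and distributional group
   comparison (two-sample Kolmogorov–Smirnov, one-way ANOVA at cilium and
   mouse level, class proportions).
5. **Synthetic data with planted signal** (`astrocilia.synthetic`) — every
   input the pipeline consumes can be generated with known ground truth
   (planted up-regulated catalog, motif offsets, peak excess, two cilium
   populations), so each stage has a parameter-recovery test.

## Worked example

Run the whole pipeline on its synthetic study conditions (2,000 genes, a
92-gene ciliary catalog with 60% planted up-regulation, planted promoter
motifs at σ = 50 bp around the TSS, ~2 excess peaks per target TSS, and
150 cilia per genotype):

```bash
astrocilia report --seed 7 --outdir demo_run
```

`demo_run/run_report.json` then contains, per stage (abridged):

```
de_programs: n_up=54  n_down=0  catalog_n_up=54  catalog_p_up=2.7e-81  frac_changed=0.587
motif:       n_target=54  central_half_width=250  fold=2000.0  pvalue=5.6e-179
peaks:       statistic=2.74  null_mean=0.61  fold=4.51  pvalue=0.001
cilia:       ks_statistic=0.38  ks_pvalue=3.0e-10  anova_pvalue=1.4e-09
```

Reading: 54 of the 55 planted catalog genes pass the up-filter and the
catalog is overwhelmingly over-represented among up-genes
(p ≈ 10⁻⁸¹); best motif hits of the up-gene promoters concentrate inside
±250 bp of the TSS far beyond the random-gene negative set; up-gene TSSs
carry 2.74 peaks per ±10 kb window versus 0.61 expected under matched-size
negative resampling (fold 4.5, p = 0.001 at B = 999, the resolution floor);
and the mutant cilium population separates from control in length
distribution (KS D = 0.38) and by ANOVA. Individual stages are available as
`astrocilia simulate | de-programs | motif | peaks | cilia`, all driven by a
YAML config mirrored by CLI flags; see `astrocilia --help`.

## Scope

The package starts from differential tables, peak coordinates, annotations,
sequences and segmented 3D traces; read-level RNA-seq quantification,
DE model fitting, peak calling, GO enrichment and image segmentation are
out of scope.
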