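# Methods

## Scope and data model

`stiffprime` operates downstream of read processing: its inputs are a peak
or consensus-region set (BED/narrowPeak), ATAC-seq counts over those regions,
RNA-seq counts over genes, a sample sheet describing the 2×2 design
(stiffness soft/stiff × day 2/4, ≥2 replicates per condition), and — for the
enrichment layer — a genome FASTA, per-base signal tracks (bedGraph), a
chromatin-state segmentation (BED with state labels), motif models (JASPAR
PFM), and TF peak calls. All coordinates are 0-based half-open internally;
regions are unstranded; a region's anchor point is its integer midpoint
`(start + end) // 2`.

## Differential count model

Counts are treated as negative binomial, variance μ + αμ². The pipeline
deliberately implements its own test rather than wrapping an external
differential package, so every statistic it reports is defined by code in
this repository:

- **Normalization.** Median-of-ratios: rows with no zero define the
  reference; g_i is the geometric mean of row i across all samples and
  s_j = median_i(c_ij/g_i). If no all-positive row exists the caller is told
  to add a pseudo-reference explicitly — there is no silent fallback.
  A consequence of the geometric-mean reference worth knowing: scaling one
  column by k changes its size factor *relative to the others* by exactly k,
  but every absolute factor also moves by k^(1/n). Normalized counts are
  shifted by a common factor, which cancels from all fold changes up to the
  pseudo-count term (negligible at counts ≫ 1).
- **Dispersion.** Per-feature method of moments on normalized counts pooled
  within groups: α̂ = max((pooled within-group variance − mean)/mean², 1e-8).
  With 2–3 replicates per group this estimate has 1–4 degrees of freedom and
  is far too noisy to plug into a Wald test directly: used raw with a normal
  reference the test rejects at ~0.12 instead of 0.05; used raw with a
  t(n_A+n_B−2) reference it is calibrated but loses so much power that
  intersection-based cluster calls degrade badly at 2 replicates. We
  therefore moderate: α_i = (d·α̂_i + d0·ᾱ)/(d + d0) with residual df d,
  prior df d0 = 10, and trend ᾱ the mean of the per-feature estimates with
  the top 5% clipped (robust to a heavy upper tail). This is the standard
  empirical-Bayes move of the established differential-expression testers.
- **Test.** log2FC = log2((μ_B + c0)/(μ_A + c0)) with c0 = 0.5 so zero-count
  groups stay finite; SE by the delta method from the NB variance μ + αμ²
  per group; the Wald statistic is referred to a two-sided t with d + d0
  degrees of freedom (the moderated-variance reference). Features with zero
  counts in both groups are untestable: log2FC 0, p and padj missing.
  BH adjustment runs over testable features (statsmodels).
- **Calling.** Default thresholds: fold change ≥ 2 and raw p < 0.05, with
  `use_adjusted` available. Raw p is the default because the upstream
  protocol this pipeline mirrors thresholds raw p; FDR control is one flag
  away.

Measured behavior (also recomputed by `scripts/acceptance.py`): null NB
simulation (5000 features, 3 vs 3, μ=100, α=0.05) rejects 3.3–3.9% at
p<0.05 across seeds; planted 4-fold effects at μ=200, α=0.02, n=3 in a
matrix with 10% differential features give a median log2FC ≈ 1.94. The
small downward bias is real and comes from normalization, not the test:
with an asymmetric differential fraction the median ratio shifts slightly,
and part of the effect is absorbed into the size factors. At a 20%
one-sided differential fraction the median drops to ≈ 1.86 — worth knowing
when interpreting effect sizes in heavily perturbed designs.

## The four comparisons and the eight clusters

Comparisons (positive direction = second condition higher): C1 soft-vs-stiff
at day 2, C2 soft-vs-stiff at day 4, C3 day2-vs-day4 on soft, C4
day2-vs-day4 on stiff. Each region gets a direction signature in
{A_higher, B_higher, ns}⁴, and signatures map to labels:

| label | requires |
|---|---|
| D2stiff_D4stiff (primed candidates) | stiff-higher in C1 and C2 |
| D2soft_D4soft | soft-higher in C1 and C2 |
| D2soft_D2stiff | day2-higher in C3 and C4 |
| D4soft_D4stiff | day4-higher in C3 and C4 |
| D4_stiff | day4-higher in C4, stiff-higher in C2 |
| D2_stiff | stiff-higher in C1, day2-higher in C4 |
| D4_soft | soft-higher in C2, day4-higher in C3 |
| D2_soft | soft-higher in C1, day2-higher in C3 |

Shared labels are evaluated first and win over unique labels; two or more
matches within a tier give `ambiguous`; no match gives `unassigned`. The
shared-first precedence and the ambiguous bucket are design choices made so
the eight clusters partition the labeled regions — the upstream description
of the clustering does not specify what happens on rule collisions. A
`strict_shared` flag additionally requires ns in the off-axis comparisons
for shared labels (off by default). The classifier is a pure function of the
direction table and is verified against an exhaustive 81-row truth table
written independently in the tests.

## Peak-gene linking and the priming call

"Adjacent gene" is operationalized as the nearest TSS by absolute
midpoint-to-TSS distance, within a 100 kb window; ties break to the smaller
TSS coordinate, then the lexicographically smaller gene id; one gene per
region. Nearest-TSS-within-a-window is the common default when no
chromatin-contact data is available; the window guards against gene-desert
artifacts; both are configurable. Expression trajectories combine the day-2
and day-4 stiff-vs-soft calls: `up_d4_only` means *not up* at day 2 (ns or
down) and up at day 4 — deliberately "not up" rather than strictly ns, to
capture delayed activation literally. A region is primed iff cluster =
D2stiff_D4stiff ∧ within-window ∧ trajectory = up_d4_only. All
primed-cluster regions are reported with their evidence, so near-misses are
inspectable.

## Enrichment layer

- **Motif scanning.** Log2-odds against the PWM background at every offset
  on both strands; N contributes 0; hit threshold 0.8 × maximum achievable
  score. PFMs get +0.25 per cell before column normalization. A region
  counts once per motif regardless of hit multiplicity.
- **Motif enrichment.** Hypergeometric upper tail P[X ≥ k] for k hit regions
  among the K cluster regions, drawn from the K+N consensus regions with
  k+n total hit regions; the background is the non-cluster consensus
  regions (self-contained and exactly testable; GC-matched genomic
  backgrounds are a possible extension, not implemented). BH across motifs.
- **Footprints.** Mean per-base insertion signal in ±100 bp around motif
  centers, minus-strand sites reversed; depth = 1 − mean(core)/mean(outer
  20% of each flank). No Tn5 sequence-bias correction: the readout is the
  soft-vs-stiff contrast on the *same* sites, in which the bias cancels.
  The depth statistic is internal and only compared between conditions.
- **Chromatin states.** fold = (cluster bases in state / cluster bases) /
  (state bases / genome size), after self-merging both interval sets.
- **Binding fractions.** Each TF peak takes the cluster label of the first
  region (coordinate order) it overlaps, else "outside"; fractions sum to 1.
- **Profiles.** Tracks are rescaled to genome-wide mean coverage 1 before
  binning ±3 kb around midpoints into 60 bins (bin value = mean base
  value); rows ordered by row sum descending.

## Synthetic generator

The generator emulates the 2×2×2-replicate design on a toy genome
(2 × 10 Mb, i.i.d. bases at GC 0.41). Defaults mirror the study conditions:
4000 regions (widths 300–800 bp), 1500 genes, NB dispersion 0.05,
accessibility log2FC 2.0 for a region's class conditions, expression log2FC
1.5 for primed-linked genes in day-4 stiff only, class proportions 5%
primed, 2.5% for each of the seven other clusters, the rest stable,
per-sample depth factors log-uniform in [0.7, 1.4], AP-1 consensus planted
in 60% of primed vs 10% of other regions, footprint dip factor 0.4 over the
7 bp core (stiff tracks only), enhancer-state coverage probability 0.7 over
primed regions vs 0.1 elsewhere (including inter-region segments, so the
stable background sits at fold ≈ 1 by construction), and 70% of 400 TF
peaks inside primed regions.

Placement: gene TSSs sit on a jittered grid (minimum spacing ≈ 8 kb);
primed regions are placed 200–2500 bp from their dedicated gene's TSS,
which is strictly less than half the minimum TSS spacing, so the linked
gene is provably the nearest — truth links are unambiguous and verified at
test time. Other regions fill a jittered genome-wide grid with bounded
collision retries. Effects are planted on the multiplicative NB-mean scale,
matching the test's model, so parameter recovery is a meaningful oracle.
All randomness flows from one seed through named substreams spawned in a
fixed order; identical seeds give byte-identical bundles.

Insertion tracks are piecewise constant: background 0.2, region segments
scaled by the region's condition mean with 25 bp Poisson texture, and an
exact rectangular dip at planted motifs in stiff conditions. What the
generator does *not* emulate: real sequence composition and mappability,
fragment-length structure, Tn5 sequence bias, peak-width/signal correlation,
many-to-many enhancer-gene wiring, and biological dispersion trends
(dispersion varying with mean). Passing recovery tests therefore
demonstrates the pipeline's logic and calibration under its own model
assumptions — not robustness to every artifact of real ATAC-seq.

## Numerical choices and degenerate inputs

Dispersion floor 1e-8; log2FC pseudo-count 0.5; PFM pseudo-count 0.25;
motif score fraction 0.8; promoter window TSS ± 2 kb (strand-aware),
TTS flank ± 1 kb, annotation precedence promoter > exon > intron > TTS >
intergenic at the region midpoint; consensus regions merge book-ended
peaks (gap 0) and drop merged widths < 50 bp. Empty peak unions, empty
clusters, zero-hit footprints, missing conditions, and gene-universe
mismatches raise errors naming the offending input. All-zero features are
propagated as untestable rather than dropped, so feature universes stay
aligned across comparisons.

## Problem sizes used in validation

The shipped validation runs the full default design (4000 regions, 1500
genes) once through the pipeline (~20 s on one core), a 5000-feature null
calibration, a 5000-feature effect-recovery simulation with 10%
differential features, exhaustive rule enumeration (81 signatures), and
oracle comparisons on ≥500 random instances per interval operation. These
sizes were chosen to keep the complete validation comfortably under a
minute while leaving multinomial sampling error on recovery metrics below
a few percent.

## Known limitations

- No GLM covariates, paired designs, or interaction terms; strictly the
  four pairwise comparisons.
- No dispersion-mean trend fitting; the moderation target is a single
  scalar trend.
- One-gene-per-region linking is a simplification; distal many-to-many
  regulation is out of scope.
- Known-PWM enrichment only; de novo motif discovery is out of scope.
- Chromatin-state segmentations are consumed, never trained.
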