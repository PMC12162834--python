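# stiffprime

Detection of **mechanically primed chromatin** from stiffness time-course
multi-omics data.

When cells such as hepatic stellate cells are cultured on a stiff matrix
(~40 kPa, cirrhotic-liver-like) versus a soft one (~2 kPa, healthy-liver-like),
part of the chromatin response *precedes* the transcriptional response: some
regions gain ATAC-seq accessibility already at day 2 of stiff culture and stay
open at day 4, while their adjacent gene is upregulated only at day 4. These
regions are called *primed chromatin*. `stiffprime` implements the full
analysis that detects them from counts and peaks, together with the
downstream cluster characterization (motif enrichment, TF footprints,
chromatin-state overlap, TF-binding fractions, signal profiles), and ships a
synthetic multi-omics generator with planted ground truth so the whole
pipeline can be validated end to end without any external data.

## The method

Inputs are a consensus region set with ATAC-seq counts, RNA-seq gene counts,
and a sample sheet over the four conditions soft/stiff × day 2/day 4 with
replicates.

1. **Differential testing.** Counts c_ij are modeled as negative binomial
   with variance μ + αμ². Size factors s_j come from median-of-ratios
   normalization (g_i the geometric mean of feature i over samples,
   s_j = median_i c_ij/g_i over all-positive rows). For a comparison A vs B,
   log2FC = log2((μ_B + 0.5)/(μ_A + 0.5)) on normalized counts, the
   per-feature method-of-moments dispersion is moderated toward the
   across-feature trend (empirical Bayes, prior df 10), and the Wald
   statistic log2FC/SE is referred to a t distribution with residual + prior
   degrees of freedom. Features are called differential at fold change ≥ 2
   and p < 0.05 (configurable; BH-adjusted p optional).
2. **Accessibility clustering.** Four comparisons are run — soft vs stiff at
   each day, day 2 vs day 4 on each stiffness — and every region's direction
   signature is mapped to one of eight unique/shared clusters
   (`D2_soft`, ..., `D2stiff_D4stiff`, ...), evaluated shared-first so the
   clusters are disjoint. The `D2stiff_D4stiff` cluster (more accessible on
   stiff at both days) is the primed-chromatin candidate set.
3. **Priming call.** Each region is linked to the nearest TSS within 100 kb
   of its midpoint. A gene's trajectory is derived from the day-2 and day-4
   stiff-vs-soft RNA tests (`up_d4_only`, `up_both`, ...). A region is
   **primed** iff it is in `D2stiff_D4stiff`, its linked gene is within the
   window, and that gene is `up_d4_only`.
4. **Characterization.** PWM scanning (log2-odds, threshold 0.8 × max score)
   with hypergeometric enrichment of hit regions in a cluster against the
   remaining consensus regions; aggregate Tn5-insertion footprints around
   motif hits with a depth statistic (1 − core/flank-edge mean); per-state
   fold enrichment (cluster base fraction in state ÷ state fraction of
   genome); per-cluster TF-peak binding fractions; and ±3 kb signal profile
   matrices around region midpoints after 1× coverage normalization.

The synthetic generator (`stiffprime.synthdata`) plants all of this: region
classes for the eight clusters, primed regions placed near dedicated genes
whose expression rises only at day 4 on stiff, an AP-1 consensus (TGACTCA)
written into the genome of 60% of primed vs 10% of other regions, a 7-bp
footprint dip in stiff-condition insertion tracks, an H3K27ac elevation over
primed and D2-stiff regions on stiff, a 10-state segmentation whose
active-enhancer-like state preferentially covers primed regions, and a
p-JUN-like TF peak set concentrated in primed regions.

## Worked example

```python
from stiffprime.synthdata import SimConfig, simulate, score_recovery
from stiffprime.pipeline import RunConfig, run_all
import pandas as pd

cfg = SimConfig(seed=1, n_chroms=1, chrom_length=2_000_000,
                n_genes=300, n_regions=800)
bundle = simulate(cfg, "data/demo")
run_all(RunConfig(data_dir="data/demo", out_dir="results/demo"))

clusters = pd.read_csv("results/demo/cluster_assignment.tsv", sep="\t", index_col=0)["label"]
primed = pd.read_csv("results/demo/primed_regions.tsv", sep="\t", index_col=0)
print(clusters.value_counts().to_string())
print("primed calls:", int(primed["primed"].sum()),
      "of", len(primed), "regions in the D2stiff_D4stiff cluster")
sc = score_recovery(primed, bundle.region_truth)
print(f"sensitivity={sc.sensitivity:.3f} precision={sc.precision:.3f}")
```

prints

```
unassigned         630
D2stiff_D4stiff     43
D4soft_D4stiff      27
D4_soft             21
D2_stiff            19
D2soft_D2stiff      17
D2_soft             17
D2soft_D4soft       14
D4_stiff            12
primed calls: 40 of 43 regions in the D2stiff_D4stiff cluster
sensitivity=0.930 precision=1.000
```

Most regions are unassigned (planted stable), the eight clusters recover the
planted class sizes, and 40 of the 43 primed-cluster regions pass the
delayed-expression test — 93% of the planted primed regions, with no false
calls. The motif table in `results/demo/motif_enrichment.tsv` ranks the
planted AP-1 motif first (fold 3.2, p ≈ 2e-8 in this run).

The same steps are available from the shell:

```
stiffprime simulate --outdir data/demo --seed 1
stiffprime run-all --data-dir data/demo --out-dir results/demo
```

with `difftest`, `cluster`, `prime`, and `enrich` subcommands for running
stages on intermediate TSVs.

## Layout

- `stiffprime.genomeio` — BED/narrowPeak, FASTA, bedGraph, JASPAR PFM,
  counts TSV, gene models; interval merge/overlap algebra.
- `stiffprime.difftest` — size factors, the NB Wald test, significance calls.
- `stiffprime.regioncluster` — consensus regions, the four comparisons,
  8-way clustering, genomic-feature annotation.
- `stiffprime.priming` — peak-gene linking, trajectories, the primed call.
- `stiffprime.enrichment` — motifs, footprints, states, binding fractions,
  profiles.
- `stiffprime.synthdata` — the labeled generator and recovery scoring.
- `stiffprime.pipeline` / `stiffprime.cli` — orchestration and the
  `stiffprime` command.

See `docs/methods.md` for modeling details, parameter defaults, and known
limitations.
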