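"""Consensus regions, the four spatiotemporal comparisons, and the 8-way
unique/shared accessibility clustering, plus genomic-feature annotation.

The four comparisons (A vs B; positive direction = higher in B):

    C1: D2_soft vs D2_stiff     (stiffness at day 2)
    C2: D4_soft vs D4_stiff     (stiffness at day 4)
    C3: D2_soft vs D4_soft      (time on soft)
    C4: D2_stiff vs D4_stiff    (time on stiff)

A region is assigned to one of four "shared" clusters (accessibility gained
under two conditions) or, failing that, one of four "unique" clusters, from
the per-comparison direction calls alone. Shared labels take precedence so
the eight clusters partition the labeled regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .difftest import ComparisonSpec, CountMatrix, call_significant, estimate_size_factors, nb_wald_test
from .genomeio import GeneModel, GenomicInterval, merge_intervals

__all__ = [
    "COMPARISONS",
    "CLUSTER_LABELS",
    "ClusterParams",
    "build_consensus",
    "run_comparisons",
    "classify_clusters",
    "annotate_region_location",
]

COMPARISONS = (
    ComparisonSpec("D2_soft", "D2_stiff"),
    ComparisonSpec("D4_soft", "D4_stiff"),
    ComparisonSpec("D2_soft", "D4_soft"),
    ComparisonSpec("D2_stiff", "D4_stiff"),
)
C1, C2, C3, C4 = (c.name for c in COMPARISONS)

UNIQUE_LABELS = ("D2_soft", "D2_stiff", "D4_soft", "D4_stiff")
SHARED_LABELS = ("D2soft_D4soft", "D2stiff_D4stiff", "D2soft_D2stiff", "D4soft_D4stiff")
CLUSTER_LABELS = SHARED_LABELS + UNIQUE_LABELS

# (comparison, required direction) pairs per label. "B" = second condition
# higher, "A" = first condition higher.
_SHARED_RULES = {
    "D2stiff_D4stiff": ((C1, "B"), (C2, "B")),
    "D2soft_D4soft": ((C1, "A"), (C2, "A")),
    "D2soft_D2stiff": ((C3, "A"), (C4, "A")),
    "D4soft_D4stiff": ((C3, "B"), (C4, "B")),
}
_UNIQUE_RULES = {
    "D4_stiff": ((C4, "B"), (C2, "B")),
    "D2_stiff": ((C1, "B"), (C4, "A")),
    "D4_soft": ((C2, "A"), (C3, "B")),
    "D2_soft": ((C1, "A"), (C3, "A")),
}
_DIRECTION_CODE = {"A": "A_higher", "B": "B_higher"}


@dataclass
class ClusterParams:
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    use_adjusted: bool = False
    strict_shared: bool = False


def build_consensus(
    peak_sets: list[list[GenomicInterval]], min_width: int = 50
) -> list[GenomicInterval]:
    """Union-merge all per-sample peak sets into named consensus regions.

    Merged regions narrower than ``min_width`` are dropped; survivors get
    deterministic ids ``cons_<k>`` in coordinate order.
    """
    pooled = [iv for peaks in peak_sets for iv in peaks]
    if not pooled:
        raise ValueError("empty peak union; no consensus regions to build")
    merged = [iv for iv in merge_intervals(pooled, min_gap=0) if iv.width >= min_width]
    if not merged:
        raise ValueError(f"all merged regions are narrower than {min_width} bp")
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, f"cons_{k}")
        for k, iv in enumerate(merged)
    ]


def run_comparisons(
    counts: CountMatrix, params: ClusterParams | None = None
) -> pd.DataFrame:
    """Direction table: per region x comparison, one of A_higher/B_higher/ns."""
    params = params or ClusterParams()
    present = set(counts.samples["condition"])
    for cond in ("D2_soft", "D2_stiff", "D4_soft", "D4_stiff"):
        if cond not in present:
            raise ValueError(f"condition {cond!r} missing from the count matrix")
    sf = estimate_size_factors(counts)
    dirs = pd.DataFrame("ns", index=counts.table.index, columns=[c.name for c in COMPARISONS])
    for comp in COMPARISONS:
        res = nb_wald_test(counts, comp, sf)
        up, down = call_significant(
            res, params.fc_threshold, params.p_threshold, params.use_adjusted
        )
        dirs.loc[list(up), comp.name] = "B_higher"
        dirs.loc[list(down), comp.name] = "A_higher"
    return dirs


def _label_matches(row, rules, extra_ns=()) -> list[str]:
    hits = []
    for label, conds in rules.items():
        ok = all(row[c] == _DIRECTION_CODE[d] for c, d in conds)
        if ok and extra_ns:
            ok = all(row[c] == "ns" for c in extra_ns.get(label, ()))
        if ok:
            hits.append(label)
    return hits


def classify_clusters(dirs: pd.DataFrame, strict_shared: bool = False) -> pd.Series:
    """Assign each region one of the 8 cluster labels, ambiguous, or unassigned.

    Shared labels are evaluated first; a region matching two or more labels
    within the same tier is ``ambiguous``. With ``strict_shared`` the shared
    stiffness clusters additionally require ns in the temporal comparisons
    (and vice versa for the temporal shared clusters).
    """
    extra = {}
    if strict_shared:
        extra = {
            "D2stiff_D4stiff": (C3, C4),
            "D2soft_D4soft": (C3, C4),
            "D2soft_D2stiff": (C1, C2),
            "D4soft_D4stiff": (C1, C2),
        }
    labels = []
    for _, row in dirs.iterrows():
        shared = _label_matches(row, _SHARED_RULES, extra)
        if len(shared) == 1:
            labels.append(shared[0])
            continue
        if len(shared) > 1:
            labels.append("ambiguous")
            continue
        unique = _label_matches(row, _UNIQUE_RULES)
        if len(unique) == 1:
            labels.append(unique[0])
        elif len(unique) > 1:
            labels.append("ambiguous")
        else:
            labels.append("unassigned")
    return pd.Series(labels, index=dirs.index, name="cluster")


@dataclass
class AnnotationParams:
    promoter_up: int = 2000
    promoter_down: int = 2000
    tts_flank: int = 1000


def _promoter_window(gene: GeneModel, up: int, down: int) -> tuple[int, int]:
    # strand-aware: "up" extends 5' of the TSS on the gene strand
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down + 1
    return gene.tss - down, gene.tss + up + 1


def _tss_distance(gene: GeneModel, pos: int) -> int:
    # negative = upstream of the TSS on the gene strand
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def annotate_region_location(
    regions: list[GenomicInterval],
    gene_models: list[GeneModel],
    params: AnnotationParams | None = None,
) -> pd.DataFrame:
    """Midpoint-based feature annotation with precedence
    promoter > exon > intron > TTS > intergenic, plus signed distance to the
    nearest TSS."""
    params = params or AnnotationParams()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for iv in regions:
        mid = iv.midpoint
        genes = by_chrom.get(iv.chrom, [])
        category = "intergenic"
        in_promoter = in_exon = in_intron = in_tts = False
        for g in genes:
            lo, hi = _promoter_window(g, params.promoter_up, params.promoter_down)
            if lo <= mid < hi:
                in_promoter = True
            if g.gene_start <= mid < g.gene_end:
                if any(s <= mid < e for s, e in g.exons):
                    in_exon = True
                else:
                    in_intron = True
            if g.tts - params.tts_flank <= mid < g.tts + params.tts_flank + 1:
                in_tts = True
        if in_promoter:
            category = "promoter"
        elif in_exon:
            category = "exon"
        elif in_intron:
            category = "intron"
        elif in_tts:
            category = "TTS"

        if genes:
            nearest = min(genes, key=lambda g: (abs(mid - g.tss), g.tss, g.gene_id))
            dist = _tss_distance(nearest, mid)
        else:
            dist = pd.NA
        rows.append({"region_id": iv.name, "category": category, "distance_to_tss": dist})
    return pd.DataFrame(rows).set_index("region_id")
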