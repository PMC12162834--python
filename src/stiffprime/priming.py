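"""Peak-gene linking and the mechanically-primed-chromatin call.

A region is *primed* when its accessibility is gained on the stiff matrix at
both day 2 and day 4 (cluster ``D2stiff_D4stiff``) while its nearest gene is
upregulated only at day 4 — accessibility precedes expression. "Adjacent
gene" is operationalized as the nearest TSS within a configurable window
(default 100 kb) of the region midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .difftest import call_significant
from .genomeio import GeneModel, GenomicInterval

__all__ = [
    "PRIMED_CLUSTER",
    "TRAJECTORIES",
    "assign_peaks_to_genes",
    "classify_trajectories",
    "trajectory_from_calls",
    "call_primed_regions",
]

PRIMED_CLUSTER = "D2stiff_D4stiff"
TRAJECTORIES = ("up_both", "up_d4_only", "up_d2_only", "down_any", "stable")


def assign_peaks_to_genes(
    regions: list[GenomicInterval],
    gene_models: list[GeneModel],
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """Link each region to the nearest TSS by absolute midpoint distance.

    Ties go to the gene with the smaller TSS coordinate, then the
    lexicographically smaller gene_id. Regions on a chromosome without genes
    get a null link marked out-of-window.
    """
    if not gene_models:
        raise ValueError("empty gene set")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for iv in regions:
        mid = iv.midpoint
        genes = by_chrom.get(iv.chrom)
        if not genes:
            rows.append(
                {"region_id": iv.name, "gene_id": None, "distance": pd.NA, "within_window": False}
            )
            continue
        best = min(genes, key=lambda g: (abs(mid - g.tss), g.tss, g.gene_id))
        dist = abs(mid - best.tss)
        rows.append(
            {
                "region_id": iv.name,
                "gene_id": best.gene_id,
                "distance": dist,
                "within_window": dist <= max_distance,
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


def trajectory_from_calls(d2_call: str, d4_call: str) -> str:
    """Map per-day differential calls (up/down/ns) to a trajectory label."""
    if d2_call == "up" and d4_call == "up":
        return "up_both"
    if d2_call != "up" and d4_call == "up":
        return "up_d4_only"
    if d2_call == "up":
        return "up_d2_only"
    if d2_call == "down" or d4_call == "down":
        return "down_any"
    return "stable"


def classify_trajectories(
    rna_d2: pd.DataFrame,
    rna_d4: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Per-gene expression trajectory from the day-2 and day-4 stiff-vs-soft
    differential tables (stiff oriented as condition_B)."""
    if set(rna_d2.index) != set(rna_d4.index):
        diff = sorted(set(rna_d2.index) ^ set(rna_d4.index))
        raise ValueError(f"gene universes differ between day 2 and day 4: {diff[:10]}")
    calls = {}
    for day, table in (("d2", rna_d2), ("d4", rna_d4)):
        up, down = call_significant(table, fc_threshold, p_threshold, use_adjusted)
        calls[day] = pd.Series(
            ["up" if g in up else "down" if g in down else "ns" for g in rna_d2.index],
            index=rna_d2.index,
        )
    out = pd.DataFrame({"d2_call": calls["d2"], "d4_call": calls["d4"]})
    out["trajectory"] = [
        trajectory_from_calls(a, b) for a, b in zip(out["d2_call"], out["d4_call"])
    ]
    out.index.name = "gene_id"
    return out


def call_primed_regions(
    clusters: pd.Series,
    links: pd.DataFrame,
    trajectories: pd.DataFrame,
) -> pd.DataFrame:
    """Primed-region calls for every region in the primed accessibility cluster.

    primed is True exactly when the region is in ``D2stiff_D4stiff``, its
    nearest gene lies within the linking window, and that gene's trajectory
    is ``up_d4_only``. All primed-cluster regions are reported with their
    evidence either way.
    """
    missing = set(clusters.index) - set(links.index)
    if missing:
        raise ValueError(f"regions without a peak-gene link: {sorted(missing)[:10]}")
    rows = []
    for region_id in clusters.index[clusters == PRIMED_CLUSTER]:
        link = links.loc[region_id]
        gene = link["gene_id"]
        traj = (
            trajectories.loc[gene, "trajectory"]
            if gene is not None and gene in trajectories.index
            else "stable"
        )
        rows.append(
            {
                "region_id": region_id,
                "gene_id": gene,
                "cluster": PRIMED_CLUSTER,
                "trajectory": traj,
                "distance": link["distance"],
                "primed": bool(link["within_window"] and traj == "up_d4_only"),
            }
        )
    cols = ["region_id", "gene_id", "cluster", "trajectory", "distance", "primed"]
    return pd.DataFrame(rows, columns=cols).set_index("region_id")
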