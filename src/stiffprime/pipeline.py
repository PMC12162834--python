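"""End-to-end orchestration: load a dataset bundle, test, cluster, prime,
enrich, and emit a report directory of TSV tables plus a manifest.

Every table in the report is recomputable by calling the module operations
directly with the manifest's configuration; the run is deterministic given
the inputs and seed (the analysis stages themselves use no randomness).
Logging goes to stderr; results are only ever written to files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, genomeio
from .difftest import ComparisonSpec, estimate_size_factors, nb_wald_test
from .enrichment import (
    binding_fraction,
    footprint_profile,
    motif_enrichment,
    scan_motif,
    signal_profile,
    state_fold_enrichment,
)
from .genomeio import StateSegmentation, read_bed, read_bedgraph, read_gene_models
from .priming import assign_peaks_to_genes, call_primed_regions, classify_trajectories
from .regioncluster import (
    CLUSTER_LABELS,
    AnnotationParams,
    ClusterParams,
    annotate_region_location,
    classify_clusters,
    run_comparisons,
)

log = logging.getLogger("stiffprime")

RNA_D2 = ComparisonSpec("D2_soft", "D2_stiff")
RNA_D4 = ComparisonSpec("D4_soft", "D4_stiff")


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    data_dir: str
    out_dir: str
    seed: int = 1
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    use_adjusted: bool = False
    strict_shared: bool = False
    promoter_up: int = 2000
    promoter_down: int = 2000
    tts_flank: int = 1000
    max_distance: int = 100_000
    score_fraction: float = 0.8
    profile_window: int = 3000
    profile_bins: int = 60
    footprint_flank: int = 100
    footprint_motif: str = "AP1_synth"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            self.fc_threshold, self.p_threshold, self.use_adjusted, self.strict_shared
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@dataclass
class Bundle:
    """Parsed inputs of one dataset directory."""

    regions: list
    genes: list
    atac: object
    rna: object
    segmentation: StateSegmentation
    tf_peaks: list
    sequences: dict | None
    tracks: dict
    motifs: list
    manifest: dict
    genome_size: int


@_stage("load")
def load_bundle(data_dir) -> Bundle:
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    sheet = genomeio.read_sample_sheet(data_dir / "samples.tsv")
    atac = genomeio.read_counts(
        data_dir / "atac_counts.tsv", sheet[sheet["assay"] == "ATAC"]
    )
    rna = genomeio.read_counts(data_dir / "rna_counts.tsv", sheet[sheet["assay"] == "RNA"])
    regions = read_bed(data_dir / "regions.bed")
    genes = read_gene_models(data_dir / "genes.tsv")
    seg_ivs = read_bed(data_dir / "segmentation.bed")
    segmentation = StateSegmentation(
        seg_ivs, manifest["genome_size"], tuple(manifest["state_labels"])
    )
    tf_peaks = read_bed(data_dir / "tf_peaks.bed")
    fasta = data_dir / "genome.fa"
    sequences = genomeio.read_fasta(fasta) if fasta.exists() else None
    tracks = {}
    for p in sorted(data_dir.glob("*.bedGraph")):
        tracks[p.stem] = p
    motifs = genomeio.read_jaspar_pfm(data_dir / "motifs_synthetic.jaspar")
    return Bundle(
        regions, genes, atac, rna, segmentation, tf_peaks, sequences, tracks,
        motifs, manifest, manifest["genome_size"],
    )


def region_sequences(bundle: Bundle) -> dict[str, str]:
    if bundle.sequences is None:
        raise ValueError("bundle has no genome FASTA")
    return {
        iv.name: bundle.sequences[iv.chrom][iv.start : iv.end] for iv in bundle.regions
    }


@_stage("difftest")
def stage_difftest(bundle: Bundle, cfg: RunConfig, out: Path) -> dict:
    from .regioncluster import COMPARISONS

    sf = estimate_size_factors(bundle.atac)
    dap_rows = []
    for comp in COMPARISONS:
        res = nb_wald_test(bundle.atac, comp, sf)
        res.to_csv(out / f"diff_atac_{comp.name}.tsv", sep="\t")
        from .difftest import call_significant

        up, down = call_significant(
            res, cfg.fc_threshold, cfg.p_threshold, cfg.use_adjusted
        )
        dap_rows.append(
            {"comparison": comp.name, "more_accessible_B": len(up), "more_accessible_A": len(down)}
        )
    dap = pd.DataFrame(dap_rows).set_index("comparison")
    dap.to_csv(out / "dap_counts.tsv", sep="\t")
    return {"dap_counts": dap}


@_stage("cluster")
def stage_cluster(bundle: Bundle, cfg: RunConfig, out: Path) -> dict:
    dirs = run_comparisons(bundle.atac, cfg.cluster_params)
    clusters = classify_clusters(dirs, cfg.strict_shared)
    dirs.to_csv(out / "direction_table.tsv", sep="\t")
    coord = pd.DataFrame(
        [(iv.name, iv.chrom, iv.start, iv.end) for iv in bundle.regions],
        columns=["region_id", "chrom", "start", "end"],
    ).set_index("region_id")
    coord["label"] = clusters
    coord.to_csv(out / "cluster_assignment.tsv", sep="\t")
    sizes = clusters.value_counts().rename_axis("label").rename("n_regions")
    sizes.to_csv(out / "cluster_sizes.tsv", sep="\t")
    annot = annotate_region_location(
        bundle.regions,
        bundle.genes,
        AnnotationParams(cfg.promoter_up, cfg.promoter_down, cfg.tts_flank),
    )
    annot.to_csv(out / "region_annotation.tsv", sep="\t")
    prop = (
        annot["category"].value_counts(normalize=True).rename_axis("category").rename("proportion")
    )
    prop.to_csv(out / "annotation_proportions.tsv", sep="\t", float_format="%.6f")
    return {"clusters": clusters, "annotation": annot}


@_stage("prime")
def stage_prime(bundle: Bundle, cfg: RunConfig, clusters: pd.Series, out: Path) -> dict:
    sf = estimate_size_factors(bundle.rna)
    rna_d2 = nb_wald_test(bundle.rna, RNA_D2, sf)
    rna_d4 = nb_wald_test(bundle.rna, RNA_D4, sf)
    rna_d2.to_csv(out / "diff_rna_d2.tsv", sep="\t")
    rna_d4.to_csv(out / "diff_rna_d4.tsv", sep="\t")
    traj = classify_trajectories(
        rna_d2, rna_d4, cfg.fc_threshold, cfg.p_threshold, cfg.use_adjusted
    )
    traj.to_csv(out / "gene_trajectories.tsv", sep="\t")
    links = assign_peaks_to_genes(bundle.regions, bundle.genes, cfg.max_distance)
    links.to_csv(out / "peak_gene_links.tsv", sep="\t")
    primed = call_primed_regions(clusters, links, traj)
    primed.to_csv(out / "primed_regions.tsv", sep="\t")
    return {"primed": primed, "trajectories": traj, "links": links}


@_stage("enrich")
def stage_enrich(bundle: Bundle, cfg: RunConfig, clusters: pd.Series, out: Path) -> dict:
    results: dict = {}
    # chromatin-state fold enrichment per cluster
    state_rows = []
    for label in CLUSTER_LABELS:
        ids = set(clusters.index[clusters == label])
        if not ids:
            continue
        cluster_ivs = [iv for iv in bundle.regions if iv.name in ids]
        fe = state_fold_enrichment(cluster_ivs, bundle.segmentation)
        for state, row in fe.iterrows():
            state_rows.append({"cluster": label, "state": state, "fold": row["fold"]})
    state_fe = pd.DataFrame(state_rows)
    state_matrix = state_fe.pivot(index="cluster", columns="state", values="fold")
    state_matrix.to_csv(out / "state_enrichment.tsv", sep="\t", float_format="%.4f")
    results["state_enrichment"] = state_matrix

    # motif enrichment in the primed cluster
    seqs = region_sequences(bundle)
    hits_by_motif = {
        pwm.motif_id: scan_motif(pwm, seqs, cfg.score_fraction) for pwm in bundle.motifs
    }
    primed_ids = set(clusters.index[clusters == "D2stiff_D4stiff"])
    background = set(clusters.index) - primed_ids
    if primed_ids:
        enr = motif_enrichment(hits_by_motif, primed_ids, background)
        enr.sort_values("p").to_csv(out / "motif_enrichment.tsv", sep="\t", float_format="%.6g")
        results["motif_enrichment"] = enr

        # footprints at the configured motif within primed regions, per condition
        pwm = next(p for p in bundle.motifs if p.motif_id == cfg.footprint_motif)
        hits = hits_by_motif[cfg.footprint_motif]
        primed_hits = hits[hits["region_id"].isin(primed_ids)]
        region_index = {iv.name: iv for iv in bundle.regions}
        depths = {}
        if len(primed_hits):
            for cond in ("D2_soft", "D2_stiff", "D4_soft", "D4_stiff"):
                key = f"atac_insertions_{cond}"
                if key not in bundle.tracks:
                    continue
                track = read_bedgraph(bundle.tracks[key])
                fp = footprint_profile(
                    track, primed_hits, region_index, pwm.length, cfg.footprint_flank
                )
                fp.to_frame().to_csv(
                    out / f"footprint_{cfg.footprint_motif}_{cond}.tsv",
                    sep="\t", index=False, float_format="%.6f",
                )
                depths[cond] = fp.depth
        pd.Series(depths, name="depth").rename_axis("condition").to_csv(
            out / "footprint_depths.tsv", sep="\t", float_format="%.6f"
        )
        results["footprint_depths"] = depths

    # TF binding fraction per cluster
    frac = binding_fraction(bundle.tf_peaks, bundle.regions, clusters)
    frac.rename_axis("label").rename("fraction").to_csv(
        out / "binding_fractions.tsv", sep="\t", float_format="%.6f"
    )
    results["binding_fractions"] = frac

    # mark profiles: per cluster mean profile per mark track
    mark_keys = [k for k in bundle.tracks if not k.startswith("atac_insertions")]
    profile_rows = []
    for key in mark_keys:
        track = read_bedgraph(bundle.tracks[key])
        for label in CLUSTER_LABELS:
            ids = set(clusters.index[clusters == label])
            if not ids:
                continue
            ivs = [iv for iv in bundle.regions if iv.name in ids]
            mat = signal_profile(
                track, ivs, cfg.profile_window, cfg.profile_bins,
                genome_size=bundle.genome_size,
            )
            mean_profile = mat.mean(axis=0)
            row = {"track": key, "cluster": label}
            row.update(mean_profile.to_dict())
            profile_rows.append(row)
    if profile_rows:
        profiles = pd.DataFrame(profile_rows).set_index(["track", "cluster"])
        profiles.to_csv(out / "mark_profiles.tsv", sep="\t", float_format="%.5f")
        results["mark_profiles"] = profiles
    return results


def run_all(cfg: RunConfig) -> Path:
    """Run every stage and write the report under ``cfg.out_dir``."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(cfg.data_dir)
    stage_difftest(bundle, cfg, out)
    cluster_out = stage_cluster(bundle, cfg, out)
    clusters = cluster_out["clusters"]
    stage_prime(bundle, cfg, clusters, out)
    stage_enrich(bundle, cfg, clusters, out)
    manifest = {
        "stiffprime_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_regions": len(bundle.regions),
        "n_genes": len(bundle.genes),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
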