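"""Synthetic multi-omics generator emulating the stiffness time-course design.

The generator plants a fully labeled dataset over a toy diploid-free genome:
soft/stiff x day-2/day-4 replicated ATAC-seq and RNA-seq count matrices,
genome sequence with an AP-1 consensus written into motif-planted regions,
per-condition insertion and histone-mark tracks, a 10-state chromatin
segmentation with an active-enhancer-like state concentrated on primed
regions, and a p-JUN-like TF peak set. Region classes follow the eight
accessibility clusters: a class's regions have their NB mean multiplied by
2**accessibility_log2fc in that class's condition(s). Primed-class regions
are placed near a dedicated gene whose expression is raised only in the
day-4 stiff condition, so chromatin opens before transcription by
construction.

All randomness flows from one seed; per-component substreams are spawned in
a fixed order so outputs are bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomeio
from .difftest import CONDITIONS, CountMatrix
from .genomeio import GeneModel, GenomicInterval, SignalTrack, StateSegmentation

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate",
    "score_recovery",
    "RecoveryScore",
    "default_motif_counts",
    "AP1_CONSENSUS",
]

AP1_CONSENSUS = "TGACTCA"

CLASS_CONDITIONS = {
    "D2_soft": ("D2_soft",),
    "D2_stiff": ("D2_stiff",),
    "D4_soft": ("D4_soft",),
    "D4_stiff": ("D4_stiff",),
    "D2soft_D4soft": ("D2_soft", "D4_soft"),
    "D2stiff_D4stiff": ("D2_stiff", "D4_stiff"),
    "D2soft_D2stiff": ("D2_soft", "D2_stiff"),
    "D4soft_D4stiff": ("D4_soft", "D4_stiff"),
    "stable": (),
}
PRIMED_CLASS = "D2stiff_D4stiff"
ENHANCER_STATE = "E7_EnhA"
STATE_LABELS = tuple(f"E{i}_{n}" for i, n in enumerate(
    ["TssA", "TssFlnk", "Tx", "TxWk", "EnhWk", "EnhG", "EnhA", "Het", "Biv", "Quies"],
    start=1,
))


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic bundle."""

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 1500
    n_regions: int = 4000
    replicates: int = 2
    dispersion: float = 0.05
    region_log_mean: float = float(np.log(100.0))
    region_log_sd: float = 0.5
    gene_log_mean: float = float(np.log(300.0))
    gene_log_sd: float = 0.7
    accessibility_log2fc: float = 2.0
    expression_log2fc: float = 1.5
    class_proportions: dict = field(default_factory=lambda: {
        "D2stiff_D4stiff": 0.05,
        "D2_soft": 0.025, "D2_stiff": 0.025, "D4_soft": 0.025, "D4_stiff": 0.025,
        "D2soft_D4soft": 0.025, "D2soft_D2stiff": 0.025, "D4soft_D4stiff": 0.025,
        "stable": 0.775,
    })
    motif_rate_primed: float = 0.6
    motif_rate_background: float = 0.1
    gc_content: float = 0.41
    region_width_range: tuple = (300, 800)
    depth_factor_range: tuple = (0.7, 1.4)
    n_tf_peaks: int = 400
    tf_primed_fraction: float = 0.7
    enhancer_prob_primed: float = 0.7
    enhancer_prob_elsewhere: float = 0.1
    footprint_dip_factor: float = 0.4
    write_tracks: bool = True
    write_fasta: bool = True

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"class proportions sum to {total}, not 1")
        for rate in (self.motif_rate_primed, self.motif_rate_background,
                     self.tf_primed_fraction, self.enhancer_prob_primed,
                     self.enhancer_prob_elsewhere):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_width_range"] = list(self.region_width_range)
        d["depth_factor_range"] = list(self.depth_factor_range)
        return d


@dataclass
class SimBundle:
    """In-memory handle to a simulated dataset plus its on-disk paths."""

    config: SimConfig
    outdir: Path
    regions: list
    genes: list
    atac: CountMatrix
    rna: CountMatrix
    region_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    segmentation: StateSegmentation
    tf_peaks: list
    paths: dict

    @property
    def primed_region_ids(self) -> set:
        t = self.region_truth
        return set(t.index[t["class"] == PRIMED_CLASS])


def default_motif_counts() -> dict[str, np.ndarray]:
    """A small synthetic 5-motif PFM library (counts out of 20 sequences).

    The matrices are synthetic stand-ins shaped like the well-known AP-1,
    TEAD, CTCF-core, SP1 and NFY consensus sequences; they are not the
    curated JASPAR models.
    """

    def from_consensus(consensus: str, strong: int = 17) -> np.ndarray:
        counts = np.ones((4, len(consensus)))
        for j, base in enumerate(consensus):
            counts[genomeio._BASE_INDEX[base], j] = strong
        return counts

    return {
        "AP1_synth": from_consensus("TGACTCA"),
        "TEAD_synth": from_consensus("GGAATGT"),
        "CTCF_synth": from_consensus("CCACCAGGGGG"),
        "SP1_synth": from_consensus("GGGGCGGGG"),
        "NFY_synth": from_consensus("CCAATCA"),
    }


def _spawn_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    gid = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n = int(per_chrom[ci])
        spacing = cfg.chrom_length / (n + 1)
        for k in range(n):
            tss = int((k + 1) * spacing + rng.uniform(-0.2, 0.2) * spacing)
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.uniform(2000, 20000))
            if strand == "+":
                start, end = tss, min(tss + length, cfg.chrom_length)
            else:
                end = tss + 1
                start = max(end - length, 0)
            n_ex = int(rng.integers(2, 5))
            cuts = np.sort(rng.integers(start, end, size=2 * n_ex))
            exons = tuple(
                (int(cuts[2 * i]), int(cuts[2 * i + 1]))
                for i in range(n_ex)
                if cuts[2 * i] < cuts[2 * i + 1]
            )
            genes.append(GeneModel(f"gene_{gid:05d}", chrom, strand, start, end, exons))
            gid += 1
    return genes


def _place_regions(cfg, rng, genes):
    """Place regions: primed ones near their dedicated gene's TSS, the rest on
    a jittered genome-wide grid avoiding collisions."""
    classes = list(CLASS_PROPORTION_ORDER)
    probs = np.array([cfg.class_proportions[c] for c in classes])
    assignment = rng.choice(len(classes), size=cfg.n_regions, p=probs)
    class_of = np.array(classes)[assignment]

    widths = rng.integers(cfg.region_width_range[0], cfg.region_width_range[1] + 1,
                          size=cfg.n_regions)
    n_primed = int((class_of == PRIMED_CLASS).sum())
    primed_idx = np.nonzero(class_of == PRIMED_CLASS)[0]
    other_idx = np.nonzero(class_of != PRIMED_CLASS)[0]

    gene_pick = rng.choice(len(genes), size=n_primed, replace=False)
    placements: dict[int, tuple[str, int, int]] = {}
    primed_gene: dict[int, str] = {}
    occupied: dict[str, list] = {}

    def collides(chrom, start, end):
        ivs = occupied.get(chrom, [])
        starts = [s for s, _ in ivs]
        import bisect

        j = bisect.bisect_left(starts, end)
        for s, e in ivs[max(0, j - 2) : j + 1]:
            if s < end and start < e:
                return True
        return False

    def insert(chrom, start, end):
        import bisect

        ivs = occupied.setdefault(chrom, [])
        bisect.insort(ivs, (start, end))

    for ridx, gi in zip(primed_idx, gene_pick):
        g = genes[gi]
        w = int(widths[ridx])
        for _ in range(50):
            delta = int(rng.uniform(200, 2500)) * (1 if rng.random() < 0.5 else -1)
            mid = g.tss + delta
            start, end = mid - w // 2, mid - w // 2 + w
            if start < 0 or end > cfg.chrom_length:
                continue
            if not collides(g.chrom, start, end):
                break
        else:
            raise RuntimeError(
                "primed region placement failed; lower n_regions or raise chrom_length"
            )
        placements[ridx] = (g.chrom, start, end)
        primed_gene[ridx] = g.gene_id
        insert(g.chrom, start, end)

    genome = cfg.n_chroms * cfg.chrom_length
    spacing = genome / (len(other_idx) + 1)
    for slot, ridx in enumerate(other_idx):
        w = int(widths[ridx])
        base_pos = (slot + 1) * spacing
        for attempt in range(50):
            pos = int(base_pos + rng.uniform(-0.3, 0.3) * spacing) + attempt * 211
            ci, off = divmod(pos, cfg.chrom_length)
            chrom = f"chr{int(ci) % cfg.n_chroms + 1}"
            start = int(off)
            end = start + w
            if end > cfg.chrom_length:
                continue
            if not collides(chrom, start, end):
                break
        else:
            raise RuntimeError(
                "region placement failed after bounded retries; lower n_regions"
            )
        placements[ridx] = (chrom, start, end)
        insert(chrom, start, end)

    order = sorted(range(cfg.n_regions), key=lambda i: (placements[i][0], placements[i][1]))
    regions, rec = [], []
    for rank, ridx in enumerate(order):
        chrom, start, end = placements[ridx]
        name = f"region_{rank:05d}"
        regions.append(GenomicInterval(chrom, start, end, name))
        rec.append(
            {
                "region_id": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "class": class_of[ridx],
                "gene_id": primed_gene.get(ridx, ""),
            }
        )
    truth = pd.DataFrame(rec).set_index("region_id")
    return regions, truth


CLASS_PROPORTION_ORDER = tuple(CLASS_CONDITIONS)


def _sample_sheet(cfg: SimConfig, assay: str) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:
        day, stiffness = cond.split("_")
        for rep in range(1, cfg.replicates + 1):
            rows.append(
                {
                    "sample_id": f"{assay}_{cond}_rep{rep}",
                    "assay": assay,
                    "stiffness": stiffness,
                    "day": int(day[1]),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def _nb_draw(rng, mean, dispersion):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _simulate_counts(cfg, rng, feature_ids, base_means, elevated_conditions, lfc, assay):
    sheet = _sample_sheet(cfg, assay)
    depth = np.exp(
        rng.uniform(np.log(cfg.depth_factor_range[0]), np.log(cfg.depth_factor_range[1]),
                    size=len(sheet))
    )
    cols = {}
    for j, sample_id in enumerate(sheet.index):
        cond = sheet.loc[sample_id]
        cond_name = f"D{cond['day']}_{cond['stiffness']}"
        mult = np.where(elevated_conditions[cond_name], 2.0 ** lfc, 1.0)
        mu = base_means * mult * depth[j]
        cols[sample_id] = _nb_draw(rng, mu, cfg.dispersion)
    table = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    return CountMatrix(table, sheet), depth


def _elevation_masks(names, elevated_map):
    """Per condition: boolean mask over features that are elevated there."""
    masks = {c: np.zeros(len(names), dtype=bool) for c in CONDITIONS}
    for i, name in enumerate(names):
        for cond in elevated_map.get(name, ()):
            masks[cond][i] = True
    return masks


def _make_genome(cfg, rng, regions, truth):
    probs = np.array(
        [(1 - cfg.gc_content) / 2, cfg.gc_content / 2, cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
    )
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    arrays = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        codes = rng.choice(4, size=cfg.chrom_length, p=probs)
        arrays[chrom] = alphabet[codes].copy()

    motif_bytes = np.frombuffer(AP1_CONSENSUS.encode(), dtype=np.uint8)
    motif_start = {}
    for iv in regions:
        planted = truth.loc[iv.name, "motif_planted"]
        if not planted:
            motif_start[iv.name] = -1
            continue
        off = int(rng.integers(50, iv.width - 50 - len(AP1_CONSENSUS)))
        pos = iv.start + off
        arrays[iv.chrom][pos : pos + len(motif_bytes)] = motif_bytes
        motif_start[iv.name] = pos
    for chrom, arr in arrays.items():
        seqs[chrom] = arr.tobytes().decode()
    return seqs, motif_start


def _atac_track(cfg, rng, regions, truth, cond_means, cond_name):
    """Per-base-ish insertion track: constant background, Poisson-textured
    25-bp bins over regions, and a 7-bp dip at planted motifs on stiff."""
    stiff = cond_name.endswith("stiff")
    background = 0.2
    per_chrom: dict[str, list] = {}
    last_end: dict[str, int] = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        per_chrom[chrom] = []
        last_end[chrom] = 0
    for iv in regions:
        segs = per_chrom[iv.chrom]
        if iv.start > last_end[iv.chrom]:
            segs.append((last_end[iv.chrom], iv.start, background))
        v = background + 1.8 * cond_means.loc[iv.name] / 100.0
        mstart = int(truth.loc[iv.name, "motif_start"])
        dip = stiff and mstart >= 0
        if dip:
            mend = mstart + len(AP1_CONSENSUS)
            if mstart > iv.start:
                segs.append((iv.start, mstart, v))
            segs.append((mstart, mend, cfg.footprint_dip_factor * v))
            if mend < iv.end:
                segs.append((mend, iv.end, v))
        else:
            nbins = int(np.ceil(iv.width / 25))
            vals = rng.poisson(v * 25, size=nbins) / 25.0
            for b in range(nbins):
                s = iv.start + 25 * b
                e = min(iv.start + 25 * (b + 1), iv.end)
                segs.append((s, e, float(vals[b])))
        last_end[iv.chrom] = iv.end
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        if last_end[chrom] < cfg.chrom_length:
            per_chrom[chrom].append((last_end[chrom], cfg.chrom_length, background))
    track = SignalTrack()
    for chrom, segs in per_chrom.items():
        arr = np.array(segs, dtype=float)
        track.set_chrom(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return track


def _mark_track(cfg, regions, elevated_ids, elevated_value=1.5, base_value=0.5,
                background=0.1):
    per_chrom: dict[str, list] = {f"chr{i + 1}": [] for i in range(cfg.n_chroms)}
    last_end = {c: 0 for c in per_chrom}
    for iv in regions:
        segs = per_chrom[iv.chrom]
        if iv.start > last_end[iv.chrom]:
            segs.append((last_end[iv.chrom], iv.start, background))
        v = elevated_value if iv.name in elevated_ids else base_value
        segs.append((iv.start, iv.end, v))
        last_end[iv.chrom] = iv.end
    for chrom in per_chrom:
        if last_end[chrom] < cfg.chrom_length:
            per_chrom[chrom].append((last_end[chrom], cfg.chrom_length, background))
    track = SignalTrack()
    for chrom, segs in per_chrom.items():
        arr = np.array(segs, dtype=float)
        track.set_chrom(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return track


def _make_segmentation(cfg, rng, regions, truth) -> StateSegmentation:
    other_states = [s for s in STATE_LABELS if s != ENHANCER_STATE]
    intervals = []
    by_chrom: dict[str, list] = {f"chr{i + 1}": [] for i in range(cfg.n_chroms)}
    for iv in regions:
        by_chrom[iv.chrom].append(iv)

    seg_id = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 0
        boundaries = []
        for iv in by_chrom[chrom]:
            p_enh = (
                cfg.enhancer_prob_primed
                if truth.loc[iv.name, "class"] == PRIMED_CLASS
                else cfg.enhancer_prob_elsewhere
            )
            boundaries.append((iv.start, iv.end, p_enh))
        for start, end, p_enh in boundaries:
            while pos < start:
                length = int(rng.exponential(2000)) + 200
                seg_end = min(pos + length, start)
                state = (
                    ENHANCER_STATE
                    if rng.random() < cfg.enhancer_prob_elsewhere
                    else other_states[int(rng.integers(len(other_states)))]
                )
                intervals.append(GenomicInterval(chrom, pos, seg_end, state))
                seg_id += 1
                pos = seg_end
            state = (
                ENHANCER_STATE
                if rng.random() < p_enh
                else other_states[int(rng.integers(len(other_states)))]
            )
            intervals.append(GenomicInterval(chrom, start, end, state))
            pos = end
        while pos < cfg.chrom_length:
            length = int(rng.exponential(2000)) + 200
            seg_end = min(pos + length, cfg.chrom_length)
            state = (
                ENHANCER_STATE
                if rng.random() < cfg.enhancer_prob_elsewhere
                else other_states[int(rng.integers(len(other_states)))]
            )
            intervals.append(GenomicInterval(chrom, pos, seg_end, state))
            pos = seg_end
    return StateSegmentation(
        intervals, cfg.n_chroms * cfg.chrom_length, state_labels=STATE_LABELS
    )


def _make_tf_peaks(cfg, rng, regions, truth) -> list[GenomicInterval]:
    primed = [iv for iv in regions if truth.loc[iv.name, "class"] == PRIMED_CLASS]
    peaks = []
    width = 200
    n_inside = int(round(cfg.tf_primed_fraction * cfg.n_tf_peaks))
    for k in range(cfg.n_tf_peaks):
        if k < n_inside and primed:
            iv = primed[int(rng.integers(len(primed)))]
            lo = iv.start
            hi = max(iv.end - width, lo + 1)
            start = int(rng.integers(lo, hi))
            end = min(start + width, iv.end)
        else:
            pos = int(rng.integers(0, cfg.n_chroms * cfg.chrom_length - width))
            ci, start = divmod(pos, cfg.chrom_length)
            iv = None
            end = start + width
        chrom = iv.chrom if iv is not None else f"chr{int(pos // cfg.chrom_length) + 1}"
        peaks.append(GenomicInterval(chrom, start, end, f"tf_{k:04d}"))
    return sorted(peaks, key=lambda p: (p.chrom, p.start))


def simulate(config: SimConfig, outdir) -> SimBundle:
    """Generate the full labeled bundle and write it under ``outdir``."""
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = _spawn_rngs(cfg.seed, [
        "genes", "regions", "motifs", "genome", "atac", "rna",
        "tracks", "segmentation", "tf",
    ])

    genes = _place_genes(cfg, rngs["genes"])
    regions, truth = _place_regions(cfg, rngs["regions"], genes)

    # motif planting flags
    rng_m = rngs["motifs"]
    planted = []
    for rid in truth.index:
        rate = (
            cfg.motif_rate_primed
            if truth.loc[rid, "class"] == PRIMED_CLASS
            else cfg.motif_rate_background
        )
        planted.append(bool(rng_m.random() < rate))
    truth["motif_planted"] = planted

    # counts
    rng_a = rngs["atac"]
    region_ids = list(truth.index)
    base_atac = np.exp(rng_a.normal(cfg.region_log_mean, cfg.region_log_sd, len(region_ids)))
    elev_map = {rid: CLASS_CONDITIONS[truth.loc[rid, "class"]] for rid in region_ids}
    atac_masks = _elevation_masks(region_ids, elev_map)
    atac, _ = _simulate_counts(
        cfg, rng_a, region_ids, base_atac, atac_masks, cfg.accessibility_log2fc, "ATAC"
    )

    rng_r = rngs["rna"]
    gene_ids = [g.gene_id for g in genes]
    base_rna = np.exp(rng_r.normal(cfg.gene_log_mean, cfg.gene_log_sd, len(gene_ids)))
    primed_genes = set(truth.loc[truth["class"] == PRIMED_CLASS, "gene_id"])
    rna_elev = {g: ("D4_stiff",) for g in primed_genes}
    rna_masks = _elevation_masks(gene_ids, rna_elev)
    rna, _ = _simulate_counts(
        cfg, rng_r, gene_ids, base_rna, rna_masks, cfg.expression_log2fc, "RNA"
    )
    gene_truth = pd.DataFrame(
        {
            "trajectory": [
                "up_d4_only"
                if (g in primed_genes and cfg.expression_log2fc > 0)
                else "stable"
                for g in gene_ids
            ]
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # genome + motif coordinates
    seqs = None
    if cfg.write_fasta:
        seqs, motif_start = _make_genome(cfg, rngs["genome"], regions, truth)
    else:
        rng_g = rngs["genome"]
        motif_start = {}
        for iv in regions:
            if truth.loc[iv.name, "motif_planted"]:
                off = int(rng_g.integers(50, iv.width - 50 - len(AP1_CONSENSUS)))
                motif_start[iv.name] = iv.start + off
            else:
                motif_start[iv.name] = -1
    truth["motif_start"] = [motif_start[rid] for rid in truth.index]

    segmentation = _make_segmentation(cfg, rngs["segmentation"], regions, truth)
    tf_peaks = _make_tf_peaks(cfg, rngs["tf"], regions, truth)

    # write the bundle
    paths = {}
    genomeio.write_bed(regions, outdir / "regions.bed")
    paths["regions"] = outdir / "regions.bed"
    genomeio.write_gene_models(genes, outdir / "genes.tsv")
    paths["genes"] = outdir / "genes.tsv"
    sheet = pd.concat([atac.samples, rna.samples])
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    paths["samples"] = outdir / "samples.tsv"
    genomeio.write_counts(atac, outdir / "atac_counts.tsv")
    genomeio.write_counts(rna, outdir / "rna_counts.tsv")
    paths["atac_counts"] = outdir / "atac_counts.tsv"
    paths["rna_counts"] = outdir / "rna_counts.tsv"
    if seqs is not None:
        genomeio.write_fasta(seqs, outdir / "genome.fa")
        paths["genome"] = outdir / "genome.fa"
    genomeio.write_jaspar_pfm(default_motif_counts(), outdir / "motifs_synthetic.jaspar")
    paths["motifs"] = outdir / "motifs_synthetic.jaspar"

    if cfg.write_tracks:
        rng_t = rngs["tracks"]
        cond_mean = {}
        for cond in CONDITIONS:
            mult = np.where(atac_masks[cond], 2.0 ** cfg.accessibility_log2fc, 1.0)
            cond_mean[cond] = pd.Series(base_atac * mult, index=region_ids)
        for cond in CONDITIONS:
            track = _atac_track(cfg, rng_t, regions, truth, cond_mean[cond], cond)
            p = outdir / f"atac_insertions_{cond}.bedGraph"
            genomeio.write_bedgraph(track, p)
            paths[f"atac_track_{cond}"] = p
        k27ac_up = set(
            truth.index[truth["class"].isin([PRIMED_CLASS, "D2_stiff"])]
        )
        for cond in CONDITIONS:
            elevated = k27ac_up if cond.endswith("stiff") else set()
            track = _mark_track(cfg, regions, elevated)
            p = outdir / f"H3K27ac_{cond}.bedGraph"
            genomeio.write_bedgraph(track, p)
            paths[f"H3K27ac_{cond}"] = p
        promoter_ids = set()
        by_chrom_tss = {}
        for g in genes:
            by_chrom_tss.setdefault(g.chrom, []).append(g.tss)
        for iv in regions:
            tss = np.asarray(by_chrom_tss.get(iv.chrom, []))
            if tss.size and np.min(np.abs(tss - iv.midpoint)) <= 2000:
                promoter_ids.add(iv.name)
        track = _mark_track(cfg, regions, promoter_ids, elevated_value=1.0)
        genomeio.write_bedgraph(track, outdir / "H3K4me3.bedGraph")
        paths["H3K4me3"] = outdir / "H3K4me3.bedGraph"
        track = _mark_track(cfg, regions, set(), base_value=0.3, background=0.15)
        genomeio.write_bedgraph(track, outdir / "H3K27me3.bedGraph")
        paths["H3K27me3"] = outdir / "H3K27me3.bedGraph"

    genomeio.write_bed(segmentation.intervals, outdir / "segmentation.bed")
    paths["segmentation"] = outdir / "segmentation.bed"
    genomeio.write_bed(tf_peaks, outdir / "tf_peaks.bed")
    paths["tf_peaks"] = outdir / "tf_peaks.bed"

    truth.to_csv(outdir / "regions_truth.tsv", sep="\t")
    gene_truth.to_csv(outdir / "genes_truth.tsv", sep="\t")
    paths["region_truth"] = outdir / "regions_truth.tsv"
    paths["gene_truth"] = outdir / "genes_truth.tsv"

    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "genome_size": cfg.n_chroms * cfg.chrom_length,
        "files": {k: str(v.name) for k, v in paths.items()},
        "state_labels": list(STATE_LABELS),
        "enhancer_state": ENHANCER_STATE,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = outdir / "manifest.json"

    return SimBundle(
        config=cfg,
        outdir=outdir,
        regions=regions,
        genes=genes,
        atac=atac,
        rna=rna,
        region_truth=truth,
        gene_truth=gene_truth,
        segmentation=segmentation,
        tf_peaks=tf_peaks,
        paths=paths,
    )


@dataclass
class RecoveryScore:
    sensitivity: float
    precision: float | None
    confusion: pd.DataFrame

    @property
    def f1(self) -> float | None:
        if self.precision is None or (self.sensitivity + self.precision) == 0:
            return None
        return 2 * self.sensitivity * self.precision / (self.sensitivity + self.precision)


def score_recovery(calls, truth: pd.DataFrame) -> RecoveryScore:
    """Score primed-region or cluster recovery against planted labels.

    ``calls`` is either a priming-call DataFrame (with a boolean ``primed``
    column; scores primed-set recovery) or a Series of cluster labels
    (scores the planted-class confusion and primed-cluster recovery).
    """
    planted = set(truth.index[truth["class"] == PRIMED_CLASS])
    if isinstance(calls, pd.DataFrame) and "primed" in calls.columns:
        called = set(calls.index[calls["primed"].astype(bool)])
        label_series = pd.Series("not_primed", index=truth.index)
        label_series[list(called & set(truth.index))] = PRIMED_CLASS
    elif isinstance(calls, pd.Series):
        unknown = set(calls.index) - set(truth.index)
        if unknown:
            raise ValueError(f"calls for unknown regions: {sorted(unknown)[:5]}")
        called = set(calls.index[calls == PRIMED_CLASS])
        label_series = calls.reindex(truth.index, fill_value="unassigned")
    else:
        raise TypeError("calls must be a priming-call DataFrame or a cluster Series")
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    precision = tp / len(called) if called else None
    confusion = pd.crosstab(
        truth["class"], label_series, rownames=["planted"], colnames=["called"]
    )
    return RecoveryScore(sensitivity, precision, confusion)
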