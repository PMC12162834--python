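"""Downstream characterization of accessibility clusters.

PWM scanning with log2-odds scores, hypergeometric motif enrichment against
a background of the remaining consensus regions, aggregate transcription
factor footprints from per-base insertion tracks, chromatin-state overlap
fold enrichment, per-cluster TF-binding fractions, and signal profile
matrices around region midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import bh_adjust
from .genomeio import (
    _BASE_INDEX,
    PWM,
    GenomicInterval,
    SignalTrack,
    StateSegmentation,
    overlap_bases,
    total_bases,
)

__all__ = [
    "scan_motif",
    "motif_enrichment",
    "footprint_profile",
    "state_fold_enrichment",
    "binding_fraction",
    "signal_profile",
]

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G in ACGT index space


def _encode(seq: str) -> np.ndarray:
    """Map ACGTN to 0..3 with N -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _window_scores(codes: np.ndarray, lo_matrix: np.ndarray) -> np.ndarray:
    """Log2-odds score at every offset; N bases contribute 0."""
    L = lo_matrix.shape[1]
    n_off = len(codes) - L + 1
    if n_off <= 0:
        return np.empty(0)
    # pad the scoring matrix with a zero row for N
    padded = np.vstack([lo_matrix, np.zeros(L)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return padded[windows, np.arange(L)].sum(axis=1)


def scan_motif(
    pwm: PWM,
    sequences: dict[str, str],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Scan each region sequence on both strands for PWM hits.

    A hit is any offset whose log2-odds score reaches
    ``score_fraction * pwm.max_score``. Offsets are relative to the region
    start on the forward strand regardless of hit strand. Regions shorter
    than the motif are skipped (counted in ``df.attrs['skipped']``).
    """
    lo = pwm.log_odds
    L = pwm.length
    threshold = score_fraction * pwm.max_score
    rc_lo = lo[[_COMPLEMENT[i] for i in range(4)], ::-1]
    rows = []
    skipped = 0
    for region_id in sorted(sequences):
        seq = sequences[region_id]
        if len(seq) < L:
            skipped += 1
            continue
        codes = _encode(seq.upper())
        for strand, mat in (("+", lo), ("-", rc_lo)):
            scores = _window_scores(codes, mat)
            for off in np.nonzero(scores >= threshold)[0]:
                rows.append(
                    {
                        "region_id": region_id,
                        "offset": int(off),
                        "strand": strand,
                        "score": float(scores[off]),
                        "motif_id": pwm.motif_id,
                    }
                )
    if skipped:
        warnings.warn(f"{skipped} region(s) shorter than motif {pwm.motif_id} skipped")
    df = pd.DataFrame(rows, columns=["region_id", "offset", "strand", "score", "motif_id"])
    df.attrs["skipped"] = skipped
    return df


def motif_enrichment(
    hits_by_motif: dict[str, pd.DataFrame],
    cluster_regions: set,
    background_regions: set,
) -> pd.DataFrame:
    """Hypergeometric enrichment of motif-hit regions in a cluster.

    k = cluster regions with >= 1 hit, K = cluster size, n = background
    regions with >= 1 hit, N = background size. The population is the K+N
    regions with k+n successes; p is the upper tail P[X >= k] of drawing K.
    """
    if not cluster_regions:
        raise ValueError("empty cluster")
    if cluster_regions & background_regions:
        raise ValueError("cluster and background must be disjoint")
    K, N = len(cluster_regions), len(background_regions)
    rows = []
    for motif_id, hits in hits_by_motif.items():
        hit_regions = set(hits["region_id"])
        k = len(hit_regions & cluster_regions)
        n = len(hit_regions & background_regions)
        fold = (
            np.inf
            if (n == 0 and k > 0)
            else 0.0
            if k == 0
            else (k / K) / (n / N)
        )
        p = float(stats.hypergeom.sf(k - 1, K + N, k + n, K))
        rows.append({"motif_id": motif_id, "k": k, "K": K, "n": n, "N": N, "fold": fold, "p": p})
    df = pd.DataFrame(rows).set_index("motif_id")
    df["padj"] = bh_adjust(df["p"].to_numpy())
    return df


@dataclass
class FootprintProfile:
    """Mean per-base insertion signal around motif centers."""

    offsets: np.ndarray
    mean_insertions: np.ndarray
    depth: float
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_insertions": self.mean_insertions}
        )


def footprint_profile(
    track: SignalTrack,
    hits: pd.DataFrame,
    regions: dict[str, GenomicInterval],
    motif_length: int,
    flank: int = 100,
) -> FootprintProfile:
    """Aggregate insertion profile over motif hits, centered on motif centers.

    Minus-strand sites are reversed before averaging. ``depth`` is
    1 - mean(core) / mean(outer 20% of each flank), where the core spans the
    motif; bases outside the track read 0.
    """
    if len(hits) == 0:
        raise ValueError("no motif hits to aggregate")
    width = 2 * flank + 1
    acc = np.zeros(width)
    n_sites = 0
    for row in hits.itertuples(index=False):
        region = regions[row.region_id]
        center = region.start + row.offset + motif_length // 2
        vals = track.window_values(region.chrom, center - flank, center + flank + 1)
        if row.strand == "-":
            vals = vals[::-1]
        acc += vals
        n_sites += 1
    mean = acc / n_sites
    offsets = np.arange(-flank, flank + 1)
    half_core = motif_length // 2
    core = mean[(offsets >= -half_core) & (offsets <= half_core)]
    edge = max(1, int(0.2 * flank))
    flank_edges = np.concatenate([mean[:edge], mean[-edge:]])
    edge_mean = flank_edges.mean()
    depth = 1.0 - core.mean() / edge_mean if edge_mean > 0 else 0.0
    return FootprintProfile(offsets, mean, float(depth), n_sites)


def state_fold_enrichment(
    cluster_regions: list[GenomicInterval],
    segmentation: StateSegmentation,
) -> pd.DataFrame:
    """Per-state fold enrichment (cluster base fraction in state) /
    (state base fraction of genome)."""
    len_a = total_bases(cluster_regions)
    if len_a == 0:
        raise ValueError("cluster covers zero bases")
    G = segmentation.genome_size
    rows = []
    for state in segmentation.state_labels:
        ivs = segmentation.state_intervals(state)
        len_b = total_bases(ivs) if ivs else 0
        ov = overlap_bases(cluster_regions, ivs) if ivs else 0
        fold = (ov / len_a) / (len_b / G) if len_b > 0 else np.nan
        rows.append(
            {"state": state, "fold": fold, "overlap_bp": ov, "cluster_bp": len_a, "state_bp": len_b}
        )
    return pd.DataFrame(rows).set_index("state")


def binding_fraction(
    tf_peaks: list[GenomicInterval],
    cluster_regions: list[GenomicInterval],
    clusters: pd.Series,
) -> pd.Series:
    """Fraction of TF peaks overlapping each cluster label (plus "outside").

    A peak takes the label of the first cluster region (coordinate order) it
    overlaps; peaks overlapping no labeled region count as "outside".
    """
    if not tf_peaks:
        raise ValueError("no TF peaks")
    ordered = sorted(cluster_regions, key=lambda iv: (iv.chrom, iv.start, iv.end))
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ordered:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    counts: dict[str, int] = {}
    for peak in tf_peaks:
        label = "outside"
        for iv in by_chrom.get(peak.chrom, []):
            if iv.start < peak.end and peak.start < iv.end:
                label = str(clusters.get(iv.name, "outside"))
                break
        counts[label] = counts.get(label, 0) + 1
    frac = pd.Series(counts, dtype=float) / len(tf_peaks)
    return frac.sort_index()


def signal_profile(
    track: SignalTrack,
    regions: list[GenomicInterval],
    window: int = 3000,
    n_bins: int = 60,
    genome_size: int | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Region x bin matrix of mean signal in ±window around region midpoints.

    With ``normalize`` the track is first rescaled to genome-wide mean
    coverage 1 (1x normalization); ``genome_size`` defaults to the track's
    covered bases. Rows are ordered by row sum, descending (heatmap
    convention).
    """
    if not regions:
        raise ValueError("empty region set")
    if (2 * window) % n_bins != 0:
        raise ValueError("n_bins must divide 2*window")
    if normalize:
        G = genome_size if genome_size is not None else track.covered_bases
        mean_cov = track.total_signal / G if G else 0.0
        work = track.scaled(1.0 / mean_cov) if mean_cov > 0 else track
    else:
        work = track
    bin_w = 2 * window // n_bins
    edges_rel = np.arange(n_bins + 1) * bin_w - window
    mat = np.zeros((len(regions), n_bins))
    names = []
    for i, iv in enumerate(regions):
        mids = iv.midpoint + edges_rel
        integrals = work.integrate(iv.chrom, mids[:-1], mids[1:])
        mat[i] = integrals / bin_w
        names.append(iv.name)
    cols = [f"bin_{int(edges_rel[j])}_{int(edges_rel[j + 1])}" for j in range(n_bins)]
    df = pd.DataFrame(mat, index=pd.Index(names, name="region_id"), columns=cols)
    order = df.sum(axis=1).sort_values(ascending=False, kind="stable").index
    return df.loc[order]
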