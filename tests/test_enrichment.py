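"""Motif scanning, enrichment statistics, footprints, state overlap and
signal profiles, each against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from stiffprime.enrichment import (
    binding_fraction,
    footprint_profile,
    motif_enrichment,
    scan_motif,
    signal_profile,
    state_fold_enrichment,
)
from stiffprime.genomeio import PWM, GenomicInterval, SignalTrack, StateSegmentation

from conftest import random_intervals

COMP = str.maketrans("ACGT", "TGCA")


def make_pwm(consensus="TGACTCA", strong=17.0):
    counts = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = strong
    return PWM.from_counts("m", counts)


def brute_score(pwm, seq, offset, strand):
    """Per-offset rescoring oracle: explicit per-base log-odds sum."""
    L = pwm.length
    window = seq[offset : offset + L]
    if strand == "-":
        window = window.translate(COMP)[::-1]
    total = 0.0
    for j, base in enumerate(window):
        if base == "N":
            continue
        i = "ACGT".index(base)
        total += np.log2(pwm.probs[i, j] / pwm.background[i])
    return total


class TestScanMotif:
    def test_consensus_scores_maximal_at_offset_zero(self):
        pwm = make_pwm()
        hits = scan_motif(pwm, {"r": pwm.consensus})
        fwd = hits[hits["strand"] == "+"]
        assert len(fwd) == 1
        assert fwd.iloc[0]["offset"] == 0
        assert fwd.iloc[0]["score"] == pytest.approx(pwm.max_score)

    def test_reverse_complement_hits_minus_strand_same_score(self):
        pwm = make_pwm("TGACTCG")  # not palindromic
        rc = pwm.consensus.translate(COMP)[::-1]
        hits = scan_motif(pwm, {"r": rc})
        minus = hits[hits["strand"] == "-"]
        assert len(minus) == 1
        assert minus.iloc[0]["score"] == pytest.approx(pwm.max_score)

    def test_short_region_skipped_with_warning(self):
        pwm = make_pwm()
        with pytest.warns(UserWarning, match="skipped"):
            hits = scan_motif(pwm, {"r": "ACG"})
        assert len(hits) == 0

    def test_matches_brute_force_rescoring(self):
        rng = np.random.default_rng(9)
        pwm = make_pwm("TGACTCA", strong=10.0)
        seqs = {
            f"r{i}": "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                        size=300))
            for i in range(100)
        }
        threshold = 0.8 * pwm.max_score
        hits = scan_motif(pwm, seqs, score_fraction=0.8)
        expected = set()
        for rid, seq in seqs.items():
            for off in range(len(seq) - pwm.length + 1):
                for strand in "+-":
                    if brute_score(pwm, seq, off, strand) >= threshold - 1e-9:
                        expected.add((rid, off, strand))
        got = set(zip(hits["region_id"], hits["offset"], hits["strand"]))
        assert got == expected

    def test_hit_set_invariant_under_region_order(self):
        pwm = make_pwm()
        rng = np.random.default_rng(10)
        seqs = {f"r{i}": "".join(rng.choice(list("ACGT"), size=100)) for i in range(20)}
        a = scan_motif(pwm, seqs)
        b = scan_motif(pwm, dict(reversed(list(seqs.items()))))
        key = lambda df: sorted(zip(df["region_id"], df["offset"], df["strand"]))
        assert key(a) == key(b)


def hypergeom_tail(k, K, n, N):
    """Exact enumeration oracle: P[X >= k], X ~ Hypergeom(K+N, k+n, K)."""
    M, S, D = K + N, k + n, K
    total = comb(M, D, exact=True)
    acc = 0
    for x in range(k, min(S, D) + 1):
        acc += comb(S, x, exact=True) * comb(M - S, D - x, exact=True)
    return acc / total


class TestMotifEnrichment:
    def run_one(self, k, K, n, N):
        cluster = {f"c{i}" for i in range(K)}
        background = {f"b{i}" for i in range(N)}
        hit_regions = list(cluster)[:k] + list(background)[:n]
        hits = {"m": pd.DataFrame({"region_id": hit_regions})}
        return motif_enrichment(hits, cluster, background).loc["m"]

    def test_equal_rates_give_unit_fold(self):
        row = self.run_one(5, 10, 45, 90)
        assert row["fold"] == pytest.approx(1.0)

    def test_exact_tail_matches_enumeration(self):
        row = self.run_one(8, 10, 10, 90)
        assert row["p"] == pytest.approx(hypergeom_tail(8, 10, 10, 90), abs=1e-10)

    @pytest.mark.parametrize("k,K,n,N", [(0, 10, 5, 50), (3, 20, 7, 100), (10, 10, 0, 30)])
    def test_enumeration_oracle_small_populations(self, k, K, n, N):
        row = self.run_one(k, K, n, N)
        assert row["p"] == pytest.approx(hypergeom_tail(k, K, n, N), abs=1e-10)

    def test_zero_hits_fold_zero_p_one(self):
        row = self.run_one(0, 10, 5, 50)
        assert row["fold"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_region_counted_once_despite_multiple_hits(self):
        cluster, background = {"c0", "c1"}, {"b0", "b1"}
        hits = {"m": pd.DataFrame({"region_id": ["c0", "c0", "c0"]})}
        row = motif_enrichment(hits, cluster, background).loc["m"]
        assert row["k"] == 1

    def test_overlapping_cluster_background_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            motif_enrichment({}, {"a"}, {"a", "b"})

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motif_enrichment({}, set(), {"b"})


def uniform_track(value, length=100_000, chrom="c1"):
    return SignalTrack({chrom: (np.array([0]), np.array([length]), np.array([value]))})


class TestFootprint:
    def hits_at(self, positions, strand="+"):
        return pd.DataFrame(
            {"region_id": [f"r{i}" for i in range(len(positions))],
             "offset": [100] * len(positions),
             "strand": [strand] * len(positions)}
        )

    def regions_at(self, positions, width=400):
        return {
            f"r{i}": GenomicInterval("c1", p, p + width, f"r{i}")
            for i, p in enumerate(positions)
        }

    def test_uniform_track_flat_profile_zero_depth(self):
        track = uniform_track(2.0)
        positions = [1000, 5000, 9000]
        fp = footprint_profile(track, self.hits_at(positions), self.regions_at(positions),
                               motif_length=7, flank=100)
        assert np.allclose(fp.mean_insertions, 2.0)
        assert fp.depth == pytest.approx(0.0)
        assert len(fp.mean_insertions) == 201

    def test_planted_rectangular_dip_recovered(self):
        # value 2.0 everywhere, 7-bp dip at 0.5 centered on each motif
        starts, ends, values = [0], [], []
        sites = [1000 + 600 * i for i in range(10)]
        motif_len = 7
        segs = []
        pos = 0
        for p in sites:
            center = p + 100 + motif_len // 2
            lo, hi = center - motif_len // 2, center + motif_len // 2 + 1
            segs.append((pos, lo, 2.0))
            segs.append((lo, hi, 0.5))
            pos = hi
        segs.append((pos, 20_000, 2.0))
        arr = np.array(segs)
        track = SignalTrack({"c1": (arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2])})
        fp = footprint_profile(track, self.hits_at(sites), self.regions_at(sites),
                               motif_length=motif_len, flank=100)
        # hand-computed per-offset means: 0.5 in the core, 2.0 outside
        core = (fp.offsets >= -3) & (fp.offsets <= 3)
        assert np.allclose(fp.mean_insertions[core], 0.5)
        assert np.allclose(fp.mean_insertions[~core], 2.0)
        assert fp.depth == pytest.approx(1 - 0.5 / 2.0)

    def test_mirror_symmetric_track_gives_symmetric_profile(self):
        # ramp up then down, symmetric about the motif center
        center = 5000 + 100 + 3
        starts = np.arange(center - 150, center + 151)
        values = 10.0 - np.abs(starts - center) / 20.0
        track = SignalTrack({"c1": (starts, starts + 1, values)})
        fp = footprint_profile(track, self.hits_at([5000]), self.regions_at([5000]),
                               motif_length=7, flank=100)
        assert np.allclose(fp.mean_insertions, fp.mean_insertions[::-1])

    def test_minus_strand_sites_reversed(self):
        # asymmetric track: value 5 left of center, 1 right of center
        center = 5000 + 100 + 3
        track = SignalTrack(
            {"c1": (np.array([0, center]), np.array([center, 20_000]), np.array([5.0, 1.0]))}
        )
        plus = footprint_profile(track, self.hits_at([5000], "+"), self.regions_at([5000]),
                                 motif_length=7, flank=100)
        minus = footprint_profile(track, self.hits_at([5000], "-"), self.regions_at([5000]),
                                  motif_length=7, flank=100)
        assert np.allclose(plus.mean_insertions, minus.mean_insertions[::-1])

    def test_zero_hits_rejected(self):
        with pytest.raises(ValueError, match="no motif hits"):
            footprint_profile(uniform_track(1.0), pd.DataFrame(), {}, 7)


class TestStateEnrichment:
    def test_whole_genome_state_fold_one(self):
        seg = StateSegmentation([GenomicInterval("c1", 0, 100_000, "S1")], 100_000)
        cluster = [GenomicInterval("c1", 500, 900, "r")]
        fe = state_fold_enrichment(cluster, seg)
        assert fe.loc["S1", "fold"] == pytest.approx(1.0)

    def test_cluster_inside_ten_percent_state_fold_ten(self):
        seg = StateSegmentation(
            [GenomicInterval("c1", 0, 10_000, "S1"), GenomicInterval("c1", 10_000, 100_000, "S2")],
            100_000,
        )
        cluster = [GenomicInterval("c1", 1000, 2000, "r")]
        fe = state_fold_enrichment(cluster, seg)
        assert fe.loc["S1", "fold"] == pytest.approx(10.0)

    def test_matches_base_mask_oracle(self):
        rng = np.random.default_rng(17)
        G = 50_000
        cuts = np.sort(rng.choice(np.arange(1, G), size=60, replace=False))
        bounds = np.concatenate([[0], cuts, [G]])
        labels = rng.choice(["S1", "S2", "S3"], size=len(bounds) - 1)
        ivs = [
            GenomicInterval("c1", int(a), int(b), lab)
            for a, b, lab in zip(bounds[:-1], bounds[1:], labels)
        ]
        seg = StateSegmentation(ivs, G)
        cluster = random_intervals(rng, 30, chroms=("c1",), max_pos=G - 500, max_len=400)
        fe = state_fold_enrichment(cluster, seg)
        # oracle: per-base masks
        cl_mask = np.zeros(G, dtype=bool)
        for iv in cluster:
            cl_mask[iv.start : iv.end] = True
        for state in ("S1", "S2", "S3"):
            st_mask = np.zeros(G, dtype=bool)
            for iv in ivs:
                if iv.name == state:
                    st_mask[iv.start : iv.end] = True
            expected = ((cl_mask & st_mask).sum() / cl_mask.sum()) / (st_mask.sum() / G)
            assert fe.loc[state, "fold"] == pytest.approx(expected)

    def test_empty_cluster_rejected(self):
        seg = StateSegmentation([GenomicInterval("c1", 0, 100, "S1")], 100)
        with pytest.raises(ValueError):
            state_fold_enrichment([], seg)


class TestBindingFraction:
    def test_all_peaks_inside_one_cluster(self):
        regions = [GenomicInterval("c1", 1000, 2000, "r1")]
        clusters = pd.Series({"r1": "D2stiff_D4stiff"})
        peaks = [GenomicInterval("c1", 1100 + i * 200, 1250 + i * 200, f"p{i}") for i in range(4)]
        frac = binding_fraction(peaks, regions, clusters)
        assert frac["D2stiff_D4stiff"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(23)
        regions = random_intervals(rng, 50, chroms=("c1",), max_pos=100_000, max_len=500)
        clusters = pd.Series(
            rng.choice(["A", "B", "C"], size=len(regions)),
            index=[iv.name for iv in regions],
        )
        peaks = random_intervals(rng, 200, chroms=("c1",), max_pos=110_000, max_len=300)
        frac = binding_fraction(peaks, regions, clusters)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_first_overlap_scan_oracle(self):
        rng = np.random.default_rng(24)
        regions = random_intervals(rng, 40, chroms=("c1", "c2"), max_pos=50_000, max_len=800)
        clusters = pd.Series(
            rng.choice(["X", "Y"], size=len(regions)), index=[iv.name for iv in regions]
        )
        peaks = random_intervals(rng, 300, chroms=("c1", "c2"), max_pos=55_000, max_len=400)
        frac = binding_fraction(peaks, regions, clusters)
        ordered = sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.end))
        counts = {}
        for p in peaks:
            label = "outside"
            for iv in ordered:
                if iv.chrom == p.chrom and iv.start < p.end and p.start < iv.end:
                    label = clusters[iv.name]
                    break
            counts[label] = counts.get(label, 0) + 1
        for label, cnt in counts.items():
            assert frac[label] == pytest.approx(cnt / len(peaks))


class TestSignalProfile:
    def regions(self, n=5, spacing=20_000):
        return [
            GenomicInterval("c1", 10_000 + i * spacing, 10_400 + i * spacing, f"r{i}")
            for i in range(n)
        ]

    def test_constant_track_normalizes_to_one(self):
        track = uniform_track(7.0, length=200_000)
        mat = signal_profile(track, self.regions(), window=3000, n_bins=60)
        assert np.allclose(mat.to_numpy(), 1.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(31)
        starts = np.arange(0, 200_000, 50)
        values = rng.uniform(0.1, 5.0, size=len(starts))
        track = SignalTrack({"c1": (starts, starts + 50, values)})
        m1 = signal_profile(track, self.regions(), 3000, 60)
        m2 = signal_profile(track.scaled(2.0), self.regions(), 3000, 60)
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_hand_binned_rectangular_peak(self):
        # one rectangular bump of height 3 over [9800, 10200); elsewhere 1
        track = SignalTrack(
            {"c1": (np.array([0, 9800, 10_200]), np.array([9800, 10_200, 100_000]),
                     np.array([1.0, 3.0, 1.0]))}
        )
        region = [GenomicInterval("c1", 9000, 11_400, "r")]  # midpoint 10200
        mat = signal_profile(track, region, window=3000, n_bins=60, normalize=False)
        # bin width 100; window [7200, 13200); bump covers [9800,10200)
        vals = mat.loc["r"].to_numpy()
        expected = np.ones(60)
        expected[26:30] = 3.0  # bases 9800-10200 fall in bins 26..29
        assert np.allclose(vals, expected)

    def test_rows_ordered_by_row_sum(self):
        track = SignalTrack(
            {"c1": (np.array([9000, 29_000]), np.array([11_000, 31_000]),
                     np.array([5.0, 1.0]))}
        )
        regions = self.regions(2)
        mat = signal_profile(track, regions, 3000, 60, normalize=False)
        sums = mat.sum(axis=1)
        assert list(sums.index) == list(sums.sort_values(ascending=False).index)

    def test_bins_must_partition_window(self):
        with pytest.raises(ValueError, match="divide"):
            signal_profile(uniform_track(1.0), self.regions(), window=3000, n_bins=7)

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            signal_profile(uniform_track(1.0), [], 3000, 60)
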