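"""Probe normalization, tiling, Z-transform, region calling and metaplots."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from suvrkit import chip
from suvrkit.chip import (
    DegenerateTrackError, aggregate_bins, call_decreased_regions, center_scale,
    geneset_signal_summary, merge_regions, metaprofile, probe_log_ratio,
    tile_genome, zscore_transform,
)


def make_track(chrom_sizes, scores=None, rng=None, sd=0.2):
    bins = tile_genome(chrom_sizes)
    if scores is not None:
        bins["score"] = scores
    elif rng is not None:
        bins["score"] = rng.normal(0, sd, len(bins))
    return bins


class TestProbeLogRatio:
    @pytest.mark.parametrize("ip,inp,expected", [(3.0, 3.0, 0.0), (8.0, 2.0, 2.0),
                                                 (1.0, 2.0, -1.0)])
    def test_examples(self, ip, inp, expected):
        table = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50],
                              "ip": [ip], "input": [inp]})
        assert probe_log_ratio(table)["log_ratio"].iloc[0] == pytest.approx(expected)

    def test_nonpositive_intensity_names_probe(self):
        table = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [150],
                              "ip": [0.0], "input": [2.0]})
        with pytest.raises(ValueError, match="chr1:100-150"):
            probe_log_ratio(table)


class TestCenterScale:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3], [-1, 0, 1]),
        ([-1, 0, 1], [-1, 0, 1]),
        ([5, 5], [0, 0]),
    ])
    def test_examples(self, values, expected):
        assert np.allclose(center_scale(values), expected)

    def test_single_probe_rejected(self):
        with pytest.raises(ValueError):
            center_scale([1.0])


class TestTileGenome:
    def test_single_full_bin(self):
        bins = tile_genome({"c": 500})
        assert bins[["start", "end"]].values.tolist() == [[0, 500], [250, 500]]

    def test_start_arithmetic_with_truncation(self):
        bins = tile_genome({"c": 1250})
        assert bins["start"].tolist() == [0, 250, 500, 750, 1000]
        assert bins["end"].tolist() == [500, 750, 1000, 1250, 1250]

    def test_chromosome_shorter_than_bin(self):
        bins = tile_genome({"c": 400})
        assert bins[["start", "end"]].values.tolist() == [[0, 400], [250, 400]]

    def test_step_must_not_exceed_bin(self):
        with pytest.raises(ValueError):
            tile_genome({"c": 1000}, bin=200, step=300)


class TestAggregateBins:
    def test_single_probe_fills_containing_bins(self):
        probes = pd.DataFrame({"chrom": ["c"], "start": [300], "end": [350],
                               "log_ratio": [1.5]})
        track = aggregate_bins(probes, tile_genome({"c": 1000}))
        # midpoint 325 lies in bins [0,500) and [250,750)
        assert track["score"].iloc[0] == pytest.approx(1.5)
        assert track["score"].iloc[1] == pytest.approx(1.5)
        assert np.isnan(track["score"].iloc[2])

    def test_no_probes_all_missing(self):
        probes = pd.DataFrame(columns=["chrom", "start", "end", "log_ratio"])
        track = aggregate_bins(probes, tile_genome({"c": 1000}))
        assert track["score"].isna().all()
        assert (track["n_probes"] == 0).all()

    def test_half_open_membership_on_boundary(self):
        # midpoint exactly 250: in [250,750) and in [0,500), not in [500,1000)
        probes = pd.DataFrame({"chrom": ["c"], "start": [225], "end": [275],
                               "log_ratio": [2.0]})
        track = aggregate_bins(probes, tile_genome({"c": 1250}))
        assert track["n_probes"].tolist() == [1, 1, 0, 0, 0]


class TestZscore:
    def test_hand_computation(self):
        z = zscore_transform([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1.22474487, 0, 1.22474487])  # population sd

    def test_large_sample_standardized(self, rng):
        z = zscore_transform(rng.normal(3.0, 2.0, 10_000))
        assert abs(np.mean(z)) < 1e-9 and abs(np.std(z) - 1) < 1e-9

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateTrackError):
            zscore_transform([5.0, 5.0])

    def test_missing_propagates(self):
        z = zscore_transform([1.0, np.nan, 3.0])
        assert np.isnan(z[1]) and not np.isnan(z[0])

    def test_shift_invariance_composition(self, rng):
        values = rng.normal(2, 1, 500)
        direct = zscore_transform(values)
        composed = zscore_transform(center_scale(values))
        assert np.allclose(direct, composed)


class TestMergeRegions:
    def test_within_gap_merges(self):
        assert merge_regions([(0, 100), (2100, 2200)], gap=2500) == [(0, 2200)]

    def test_beyond_gap_stays_separate(self):
        assert merge_regions([(0, 100), (5000, 5100)], gap=2500) == [(0, 100), (5000, 5100)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            merge_regions([(100, 200), (0, 50)], gap=10)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 400)), max_size=15),
           st.integers(0, 1000))
    def test_idempotent(self, raw, gap):
        intervals = sorted((s, s + l) for s, l in raw)
        once = merge_regions(intervals, gap)
        assert merge_regions(once, gap) == once


class TestCallDecreasedRegions:
    def test_identical_tracks_degenerate(self, rng):
        track = make_track({"c": 100_000}, rng=rng)
        with pytest.raises(DegenerateTrackError):
            call_decreased_regions(track, track.copy())

    def test_mismatched_tilings_rejected(self, rng):
        a = make_track({"c": 100_000}, rng=rng)
        b = make_track({"c": 50_000}, rng=rng)
        with pytest.raises(ValueError, match="tiling"):
            call_decreased_regions(a, b)

    def test_merge_rule_arithmetic(self):
        # three flagged clusters: gaps of 2400 (merges) and 3000 (does not)
        sizes = {"c": 200_000}
        rng = np.random.default_rng(1)
        wt = make_track(sizes, rng=rng, sd=0.05)
        mut = make_track(sizes, rng=np.random.default_rng(2), sd=0.05)
        for s, e in [(0, 1500), (3900, 5400), (8400, 9900)]:
            mask = (mut["start"] >= s) & (mut["start"] < e)
            mut.loc[mask, "score"] -= 3.0
        regions = call_decreased_regions(mut, wt, merge_gap=2500)
        assert len(regions) == 2
        assert regions["end"].iloc[0] >= 5400 and regions["start"].iloc[1] >= 8000

    def test_planted_patch_recovery_with_boundaries(self):
        sizes = {"c1": 500_000, "c2": 500_000}
        rng = np.random.default_rng(9)
        wt = make_track(sizes, rng=rng)
        mut = make_track(sizes, rng=np.random.default_rng(10))
        truth = [("c1", 100_000, 105_000), ("c2", 300_000, 305_000)]
        for chrom, s, e in truth:
            mask = (mut["chrom"] == chrom) & (mut["start"] >= s) & (mut["start"] < e)
            mut.loc[mask, "score"] -= 2.0
        regions = call_decreased_regions(mut, wt)
        assert len(regions) == 2
        for (chrom, s, e), (_, reg) in zip(truth, regions.iterrows()):
            assert reg["chrom"] == chrom
            assert abs(reg["start"] - s) <= 500 and abs(reg["end"] - e) <= 500
            assert reg["mean_z"] < -3

    def test_pure_noise_flag_rate_matches_normal_tail(self):
        # before merging/support filtering, about Phi(-3) of bins are flagged
        sizes = {"c": 2_000_000}
        n_flagged = 0
        n_bins = 0
        for seed in range(10):
            wt = make_track(sizes, rng=np.random.default_rng(100 + seed))
            mut = make_track(sizes, rng=np.random.default_rng(200 + seed))
            z = chip.difference_zscores(mut, wt)
            n_flagged += int((z < -3).sum())
            n_bins += len(z)
        rate = n_flagged / n_bins
        expected = 0.00135
        sd = np.sqrt(expected * (1 - expected) / n_bins)
        assert abs(rate - expected) < 4 * sd

    def test_regions_never_overlap(self, rng):
        sizes = {"c": 300_000}
        wt = make_track(sizes, rng=rng)
        mut = make_track(sizes, rng=np.random.default_rng(5))
        mut.loc[(mut["start"] >= 50_000) & (mut["start"] < 60_000), "score"] -= 2.5
        regions = call_decreased_regions(mut, wt)
        regions = regions.sort_values(["chrom", "start"])
        assert (regions["end"].shift() <= regions["start"])[1:].all()
        assert (regions["end"] - regions["start"]).sum() <= 300_000


class TestMetaprofile:
    def constant_track(self, value=1.0):
        bins = tile_genome({"c": 50_000})
        bins["score"] = value
        return bins

    def test_constant_signal_flat_profile(self):
        features = pd.DataFrame({"chrom": ["c"] * 3, "start": [10_000, 20_000, 30_000],
                                 "end": [12_000, 23_000, 31_000], "strand": ["+", "-", "+"]})
        prof = metaprofile(self.constant_track(), features, flank=1000,
                           body_bins=10, flank_bins=5)
        assert np.allclose(prof["mean"], 1.0)
        assert (prof["n"] == 3).all()

    def test_step_signal_body_high_flank_low(self):
        bins = tile_genome({"c": 50_000})
        inside = (bins["start"] >= 20_000) & (bins["end"] <= 24_000)
        bins["score"] = np.where(inside, 1.0, 0.0)
        features = pd.DataFrame({"chrom": ["c"], "start": [20_000], "end": [24_000],
                                 "strand": ["+"]})
        prof = metaprofile(bins, features, flank=4000, body_bins=8, flank_bins=8)
        body = prof["mean"][8:16]
        assert body.mean() > 0.9
        assert prof["mean"][:4].mean() < 0.2 and prof["mean"][-4:].mean() < 0.2

    def test_minus_strand_reverses_orientation(self):
        bins = tile_genome({"c": 20_000}, bin=250, step=250)
        bins["score"] = bins["start"].astype(float)  # ascending along the genome
        feat = pd.DataFrame({"chrom": ["c"], "start": [5_000], "end": [15_000],
                             "strand": ["-"]})
        prof = metaprofile(bins, feat, flank=0, body_bins=10, flank_bins=0)
        means = prof["mean"].to_numpy()
        assert (np.diff(means) < 0).all()  # 5'->3' on minus strand = descending coords

    def test_feature_order_invariance(self, rng):
        bins = tile_genome({"c": 50_000})
        bins["score"] = rng.normal(0, 1, len(bins))
        features = pd.DataFrame({"chrom": ["c"] * 3, "start": [5_000, 15_000, 30_000],
                                 "end": [8_000, 20_000, 33_000], "strand": ["+", "-", "+"]})
        a = metaprofile(bins, features, flank=1000, body_bins=6, flank_bins=3)
        b = metaprofile(bins, features.iloc[::-1], flank=1000, body_bins=6, flank_bins=3)
        assert np.allclose(a["mean"], b["mean"], equal_nan=True)

    def test_short_features_skipped_with_warning(self):
        features = pd.DataFrame({"chrom": ["c", "c"], "start": [100, 10_000],
                                 "end": [105, 14_000], "strand": ["+", "+"]})
        with pytest.warns(UserWarning, match="skipped 1"):
            prof = metaprofile(self.constant_track(), features, flank=500,
                               body_bins=10, flank_bins=2)
        assert prof["n"].max() == 1


class TestGenesetSignalSummary:
    def gene_frame(self):
        return pd.DataFrame({"id": [f"g{i}" for i in range(10)], "chrom": "c",
                             "start": np.arange(10) * 4000 + 1000,
                             "end": np.arange(10) * 4000 + 3000, "strand": "+"})

    def test_constant_track_constant_scores(self):
        bins = tile_genome({"c": 50_000})
        bins["score"] = 2.5
        table, summary, p = geneset_signal_summary({"a": bins, "b": bins},
                                                   self.gene_frame())
        assert np.allclose(table["a"], 2.5) and np.allclose(table["b"], 2.5)
        assert summary.loc["50%", "a"] == pytest.approx(2.5)

    def test_uniform_shift_moves_median_by_shift(self, rng):
        bins = tile_genome({"c": 50_000})
        bins["score"] = rng.normal(1.0, 0.2, len(bins))
        shifted = bins.copy()
        shifted["score"] = bins["score"] - 1.0
        table, summary, p = geneset_signal_summary({"a": bins, "b": shifted},
                                                   self.gene_frame())
        assert np.allclose(table["a"] - table["b"], 1.0)
        assert summary.loc["50%", "a"] - summary.loc["50%", "b"] == pytest.approx(1.0)
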