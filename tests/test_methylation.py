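"""Cytosine context classification, weighted levels, tracks and clone analysis."""

import re

import numpy as np
import pandas as pd
import pytest

from suvrkit import synthetic
from suvrkit.methylation import (
    Methylome, classify_contexts, clone_percent_methylation, meth_metaprofile,
    weighted_level, windowed_track,
)
from suvrkit.motif import reverse_complement


def regex_oracle(seq: str):
    """Independent context classifier: regex lookahead on both strands."""
    out = {}
    for m in re.finditer("(?=C(.)?(.)?)", seq):
        i = m.start()
        n1, n2 = m.group(1), m.group(2)
        if n1 is None:
            ctx = "incomplete"
        elif n1 == "G":
            ctx = "CG"
        elif n2 is None:
            ctx = "incomplete"
        else:
            ctx = "CHG" if n2 == "G" else "CHH"
        out[(i, "+")] = ctx
    rc = reverse_complement(seq)
    L = len(seq)
    for m in re.finditer("(?=C(.)?(.)?)", rc):
        i = m.start()
        n1, n2 = m.group(1), m.group(2)
        if n1 is None:
            ctx = "incomplete"
        elif n1 == "G":
            ctx = "CG"
        elif n2 is None:
            ctx = "incomplete"
        else:
            ctx = "CHG" if n2 == "G" else "CHH"
        out[(L - 1 - i, "-")] = ctx
    return out


def make_methylome(rows):
    return Methylome(pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                                 "meth_count", "total_count"]))


class TestClassifyContexts:
    @pytest.mark.parametrize("seq,pos,strand,expected", [
        ("TTCGGA", 2, "+", "CG"),
        ("CAGAAA", 0, "+", "CHG"),
        ("CATAAA", 0, "+", "CHH"),
        ("TTCGGA", 3, "-", "CG"),
    ])
    def test_definition_examples(self, seq, pos, strand, expected):
        table = classify_contexts({"c": seq}).set_index(["pos", "strand"])
        assert table.loc[(pos, strand), "context"] == expected

    def test_end_of_chromosome_incomplete(self):
        table = classify_contexts({"c": "AAC"}).set_index(["pos", "strand"])
        assert table.loc[(2, "+"), "context"] == "incomplete"

    def test_cg_palindrome_pairing(self, toy_genome):
        table = classify_contexts(toy_genome.chromosomes)
        cg = table[table["context"] == "CG"]
        plus = cg[cg["strand"] == "+"]
        minus = cg[cg["strand"] == "-"]
        assert len(plus) == len(minus)
        # every + strand CG at i pairs with a - strand CG at i+1
        plus_keys = set(zip(plus["chrom"], plus["pos"] + 1))
        minus_keys = set(zip(minus["chrom"], minus["pos"]))
        assert plus_keys == minus_keys

    def test_agrees_with_regex_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(bases[rng.integers(0, 4, 50)])
            table = classify_contexts({"c": seq})
            got = {(int(r["pos"]), r["strand"]): r["context"]
                   for _, r in table.iterrows()}
            assert got == regex_oracle(seq)


class TestWeightedLevel:
    def test_weighted_definition(self):
        m = make_methylome([("c", 10, "+", "CG", 5, 10), ("c", 20, "+", "CG", 0, 10)])
        assert weighted_level(m, "CG") == pytest.approx(0.25)

    def test_equal_depth_equals_mean_of_fractions(self):
        m = make_methylome([("c", i, "+", "CHH", k, 10) for i, k in
                            [(0, 1), (5, 3), (9, 8)]])
        assert weighted_level(m, "CHH") == pytest.approx(np.mean([0.1, 0.3, 0.8]))

    def test_interval_additivity(self):
        m = make_methylome([("c", 10, "+", "CG", 2, 10), ("c", 50, "+", "CG", 8, 20)])
        a = weighted_level(m, "CG", ("c", 0, 30))
        b = weighted_level(m, "CG", ("c", 30, 100))
        combined = weighted_level(m, "CG", ("c", 0, 100))
        assert combined == pytest.approx((a * 10 + b * 20) / 30)

    def test_no_calls_returns_missing(self):
        m = make_methylome([("c", 10, "+", "CG", 2, 10)])
        assert weighted_level(m, "CHH") is None
        assert weighted_level(m, "CG", ("c", 100, 200)) is None


class TestWindowedTrack:
    def test_uniform_methylome_constant_windows(self, rng):
        rows = [("c", p, "+", "CG", 8, 10) for p in range(0, 30_000, 100)]
        track = windowed_track(make_methylome(rows), {"c": 30_000},
                               window=10_000, step=5_000)
        assert np.allclose(track["CG"].dropna(), 0.8)

    def test_zero_methylation_patch_visible(self):
        rows = []
        for p in range(0, 60_000, 100):
            meth = 0 if 20_000 <= p < 30_000 else 8
            rows.append(("c", p, "+", "CG", meth, 10))
        track = windowed_track(make_methylome(rows), {"c": 60_000},
                               window=5_000, step=5_000)
        inside = track[(track["start"] >= 20_000) & (track["end"] <= 30_000)]
        outside = track[(track["end"] <= 20_000) | (track["start"] >= 30_000)]
        assert inside["CG"].max() == 0.0
        assert outside["CG"].min() > 0.5

    def test_empty_context_missing_not_zero(self):
        rows = [("c", 10, "+", "CG", 5, 10)]
        track = windowed_track(make_methylome(rows), {"c": 5_000},
                               window=5_000, step=5_000)
        assert np.isnan(track["CHH"].iloc[0])


class TestMethMetaprofile:
    def test_constant_methylome_flat_profiles(self):
        rows = []
        for p in range(0, 40_000, 50):
            rows += [("c", p, "+", "CG", 8, 10), ("c", p + 1, "+", "CHG", 4, 10),
                     ("c", p + 2, "+", "CHH", 1, 10)]
        m = make_methylome(rows)
        features = pd.DataFrame({"chrom": ["c"], "start": [15_000], "end": [25_000],
                                 "strand": ["+"]})
        profs = meth_metaprofile(m, features, flank=2000, body_bins=10, flank_bins=5)
        assert np.allclose(profs["CG"]["mean"].dropna(), 0.8, atol=0.01)
        assert np.allclose(profs["CHG"]["mean"].dropna(), 0.4, atol=0.01)

    def test_identical_methylomes_identical_profiles(self, toy_genome):
        features = toy_genome.tes_frame().head(20)
        a = synthetic.simulate_methylome(toy_genome, depth=10, seed=5)
        b = synthetic.simulate_methylome(toy_genome, depth=10, seed=5)
        pa = meth_metaprofile(a, features, flank=1000, body_bins=10, flank_bins=5)
        pb = meth_metaprofile(b, features, flank=1000, body_bins=10, flank_bins=5)
        for ctx in ("CG", "CHG", "CHH"):
            assert np.allclose(pa[ctx]["mean"], pb[ctx]["mean"], equal_nan=True)

    def test_te_body_exceeds_flanks_in_cg(self, toy_genome):
        m = synthetic.simulate_methylome(toy_genome, depth=20, seed=6)
        # arm TEs: heterochromatic levels inside the TE, arm levels outside,
        # so the body should stand clearly above the flanks
        arm_tes = [t for t in toy_genome.tes
                   if not toy_genome.in_pericentromere(t.chrom, t.start - 2000,
                                                       t.end + 2000)]
        features = pd.DataFrame([(t.chrom, t.start, t.end, t.strand) for t in arm_tes],
                                columns=["chrom", "start", "end", "strand"])
        profs = meth_metaprofile(m, features, flank=2000, body_bins=10, flank_bins=5)
        cg = profs["CG"]["mean"]
        assert cg[5:15].mean() > cg[:3].mean() + 0.2


class TestCloneAnalysis:
    def test_two_of_three_unconverted(self):
        result = clone_percent_methylation("ACGA", ["ACGA", "ACGA", "ATGA"])
        site = result[(result["pos"] == 1) & (result["strand"] == "+")]
        assert site["percent"].iloc[0] == pytest.approx(100 * 2 / 3)

    def test_fully_converted_is_zero(self):
        result = clone_percent_methylation("CCAA", ["TTAA", "TTAA"])
        assert (result[result["strand"] == "+"]["percent"] == 0).all()

    def test_fully_unconverted_is_hundred(self):
        result = clone_percent_methylation("CCAA", ["CCAA", "CCAA"])
        assert (result[result["strand"] == "+"]["percent"] == 100).all()

    def test_invalid_base_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            result = clone_percent_methylation("ACGA", ["ACGA", "AGGA"])
        site = result[(result["pos"] == 1) & (result["strand"] == "+")]
        assert site["total"].iloc[0] == 1

    def test_minus_strand_clones_read_g_to_a(self):
        result = clone_percent_methylation("ACGA", ["ACAA", "ACGA"],
                                           clone_strands=["-", "-"])
        site = result[(result["pos"] == 2) & (result["strand"] == "-")]
        assert site["percent"].iloc[0] == pytest.approx(50.0)


def test_simulated_levels_recovered_within_binomial_ci(toy_genome):
    """Planted compartment levels recovered within 99% CIs for all contexts."""
    from scipy import stats as ss
    m = synthetic.simulate_methylome(toy_genome, depth=50, seed=7)
    calls = m.calls
    peri = {c: iv for c, iv in toy_genome.pericentromeres.items()}
    for ctx in ("CG", "CHG", "CHH"):
        for comp, expected in (("het", synthetic.DEFAULT_CONTEXT_LEVELS["het"][ctx]),):
            sub = []
            for chrom, (s, e) in ((c, iv[0]) for c, iv in peri.items() if iv):
                cdf = calls[(calls["chrom"] == chrom) & (calls["context"] == ctx)
                            & (calls["pos"] >= s) & (calls["pos"] < e)]
                sub.append(cdf)
            sub = pd.concat(sub)
            total = int(sub["total_count"].sum())
            level = sub["meth_count"].sum() / total
            lo, hi = ss.binom.interval(0.99, total, expected)
            assert lo / total <= level <= hi / total, (ctx, comp, level, expected)


def test_methylome_tsv_round_trip(tmp_path, toy_genome):
    m = synthetic.simulate_methylome(toy_genome, depth=5, seed=3)
    path = tmp_path / "meth.tsv"
    m.to_tsv(path)
    back = Methylome.from_tsv(path)
    pd.testing.assert_frame_equal(m.calls, back.calls)
    # positions on disk are 1-based
    first_line = path.read_text().splitlines()[1].split("\t")
    assert int(first_line[1]) == int(m.calls["pos"].iloc[0]) + 1
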