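import math

import numpy as np
import pytest

from rdhfp.fingerprint import (
    Censor,
    RatioProfile,
    bin_ratio,
    compute_ratios,
    cophenetic_matrix,
    cut_dendrogram,
    dendrogram_to_newick,
    heatmap_table,
    pearson_similarity,
    upgma,
    SIXTEEN_S,
)
from rdhfp.qpcr import Measurement

from oracles import naive_upgma


def meas(sample, target, copies, censored=False, mdl=100.0):
    return Measurement(
        sample_id=sample,
        target=target,
        copies_per_unit=mdl if censored else copies,
        unit="copies/mL",
        censored=censored,
        mdl_per_unit=mdl,
    )


class TestComputeRatios:
    def test_basic_ratio(self):
        p = compute_ratios([
            meas("s1", SIXTEEN_S, 1e8),
            meas("s1", "vcrA", 6e7),
        ])
        assert p.values["vcrA"] == pytest.approx(0.6)
        assert p.dhc_16s_copies == 1e8

    def test_censored_gene_below_detection(self):
        p = compute_ratios([
            meas("s1", SIXTEEN_S, 1e8),
            meas("s1", "bvcA", 0.0, censored=True, mdl=1e3),
        ])
        assert p.state("bvcA") is Censor.BELOW_DETECTION
        assert "bvcA" not in p.values
        assert p.below_detection["bvcA"] == pytest.approx(1e-5)

    def test_censored_16s_undefined_profile(self):
        p = compute_ratios([
            meas("s1", SIXTEEN_S, 0.0, censored=True, mdl=1e3),
            meas("s1", "vcrA", 6e7),
        ])
        assert p.undefined
        assert p.state("vcrA") is Censor.UNDEFINED

    def test_missing_16s_error(self):
        with pytest.raises(ValueError, match=SIXTEEN_S):
            compute_ratios([meas("s1", "vcrA", 6e7)])

    def test_ratio_above_one_flagged(self):
        p = compute_ratios([
            meas("s1", SIXTEEN_S, 1e8),
            meas("s1", "geneX", 2e8),
        ])
        assert "geneX" in p.gt_one
        assert p.values["geneX"] == pytest.approx(2.0)

    def test_16s_self_ratio_is_one(self):
        p = compute_ratios([
            meas("s1", SIXTEEN_S, 3.7e7),
            meas("s1", "g", 3.7e7),
        ])
        assert p.values["g"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = [meas("s1", SIXTEEN_S, 1e8), meas("s1", "g", 2.5e7)]
        scaled = [meas("s1", SIXTEEN_S, 7e8), meas("s1", "g", 7 * 2.5e7)]
        assert compute_ratios(base).values["g"] == pytest.approx(
            compute_ratios(scaled).values["g"]
        )


class TestBins:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.35, "0.1_to_0.6"),
            (0.6, "gt_0.6"),  # lower edge inclusive
            (5.0, "gt_0.6"),
            (0.1, "0.1_to_0.6"),
            (0.05, "0.01_to_0.1"),
            (0.01, "0.01_to_0.1"),
            (0.005, "0.001_to_0.01"),
            (0.001, "0.001_to_0.01"),
            (0.0005, "lt_0.001"),
        ],
    )
    def test_edges(self, value, expected):
        assert bin_ratio(value) == expected

    def test_censored_to_nd(self):
        assert bin_ratio(Censor.BELOW_DETECTION) == "nd"
        assert bin_ratio(Censor.UNDEFINED) == "nd"
        assert bin_ratio(None) == "nd"

    def test_negative_error(self):
        with pytest.raises(ValueError):
            bin_ratio(-0.1)


def profile(sample, ratios, below=None):
    return RatioProfile(sample_id=sample, values=dict(ratios),
                        below_detection=dict(below or {}))


class TestPearson:
    def test_identical_profiles(self):
        p1 = profile("a", {"g1": 0.5, "g2": 0.05, "g3": 0.005})
        p2 = profile("b", {"g1": 0.5, "g2": 0.05, "g3": 0.005})
        labels, r = pearson_similarity([p1, p2])
        assert labels == ["a", "b"]
        assert r[0, 1] == pytest.approx(1.0)

    def test_anticorrelated(self):
        p1 = profile("a", {"g1": 1e-3, "g2": 1e-2, "g3": 1e-1})
        p2 = profile("b", {"g1": 1e-1, "g2": 1e-2, "g3": 1e-3})
        _, r = pearson_similarity([p1, p2])
        assert r[0, 1] == pytest.approx(-1.0)
        assert 1 - r[0, 1] == pytest.approx(2.0)  # distance

    def test_matches_direct_formula(self):
        vals = {
            "a": {"g1": 0.5, "g2": 0.04, "g3": 0.3},
            "b": {"g1": 0.1, "g2": 0.2, "g3": 0.02},
            "c": {"g1": 0.9, "g2": 0.01, "g3": 0.6},
            "d": {"g1": 0.05, "g2": 0.5, "g3": 0.001},
        }
        profiles = [profile(s, v) for s, v in vals.items()]
        labels, r = pearson_similarity(profiles)
        for i, si in enumerate(labels):
            for j, sj in enumerate(labels):
                x = np.log10([vals[si][g] for g in ("g1", "g2", "g3")])
                y = np.log10([vals[sj][g] for g in ("g1", "g2", "g3")])
                expect = np.corrcoef(x, y)[0, 1]
                assert r[i, j] == pytest.approx(expect)

    def test_censored_imputed_at_floor(self):
        p1 = profile("a", {"g1": 0.5, "g2": 0.05}, below={"g3": 1e-5})
        p2 = profile("b", {"g1": 0.5, "g2": 0.05, "g3": 1e-4})
        _, r = pearson_similarity([p1, p2])
        assert r[0, 1] == pytest.approx(1.0)

    def test_log_shift_invariance(self):
        p1 = profile("a", {"g1": 0.5, "g2": 0.05, "g3": 0.002})
        p2 = profile("b", {"g1": 0.25, "g2": 0.025, "g3": 0.001})
        # p2 = p1 / 2 gene-wise: a constant log shift leaves r at 1
        _, r = pearson_similarity([p1, p2])
        assert r[0, 1] == pytest.approx(1.0)

    def test_too_few_shared_entries_error(self):
        p1 = profile("a", {"g1": 0.5})
        p2 = profile("b", {"g1": 0.4})
        with pytest.raises(ValueError, match="fewer than 2"):
            pearson_similarity([p1, p2])

    def test_gene_axis(self):
        p1 = profile("a", {"g1": 0.5, "g2": 0.05})
        p2 = profile("b", {"g1": 0.1, "g2": 0.01})
        p3 = profile("c", {"g1": 0.9, "g2": 0.09})
        labels, r = pearson_similarity([p1, p2, p3], axis="genes")
        assert labels == ["g1", "g2"]
        assert r[0, 1] == pytest.approx(1.0)


class TestUpgma:
    def test_three_item_example(self):
        d = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        dg = upgma(["x", "y", "z"], d)
        assert dg.merges[0][:3] == (0, 1, 0.1)
        assert dg.merges[1][2] == pytest.approx(0.5)
        assert dg.similarity_percent[0] == pytest.approx(90.0)

    def test_matches_naive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 8))
            d = rng.uniform(0.05, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dg = upgma([f"i{k}" for k in range(n)], d)
            expect = naive_upgma(d)
            assert len(dg.merges) == len(expect)
            for got, exp in zip(dg.merges, expect):
                assert got[0] == exp[0] and got[1] == exp[1]
                assert got[2] == pytest.approx(exp[2], abs=1e-12)

    def test_monotone_heights_and_ultrametric(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            d = rng.uniform(0.05, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dg = upgma([f"i{k}" for k in range(n)], d)
            heights = [h for _, _, h, _ in dg.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))
            c = cophenetic_matrix(dg)
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert max(c[i, k], c[j, k]) >= c[i, j] - 1e-12

    def test_ultrametric_fixed_point(self):
        # cophenetic distances of an ultrametric input reproduce the input
        d = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]
        )
        dg = upgma(list("abcd"), d)
        assert np.allclose(cophenetic_matrix(dg), d)

    def test_single_item_error(self):
        with pytest.raises(ValueError):
            upgma(["a"], np.zeros((1, 1)))

    def test_newick_depths_halve_heights(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        dg = upgma(list("abc"), d)
        nwk = dendrogram_to_newick(dg)
        assert nwk == "(c:0.300000,(a:0.100000,b:0.100000):0.200000);"

    def test_cut(self):
        d = np.array([[0, 0.1, 0.9, 0.9], [0.1, 0, 0.9, 0.9],
                      [0.9, 0.9, 0, 0.1], [0.9, 0.9, 0.1, 0]])
        dg = upgma(list("abcd"), d)
        labels = cut_dendrogram(dg, 2)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]


class TestHeatmapTable:
    def test_two_by_two(self):
        p1 = profile("s1", {"g1": 0.7, "g2": 0.05})
        p2 = profile("s2", {"g1": 0.002}, below={"g2": 1e-5})
        table = heatmap_table([p1, p2])
        assert len(table) == 4
        cell = table[(table.gene == "g1") & (table.sample_id == "s1")]
        assert cell["bin"].iloc[0] == "gt_0.6"
        nd = table[(table.gene == "g2") & (table.sample_id == "s2")]
        assert nd["bin"].iloc[0] == "nd"

    def test_input_order_invariance(self):
        p1 = profile("s1", {"g1": 0.7, "g2": 0.05})
        p2 = profile("s2", {"g1": 0.002, "g2": 0.3})
        a = heatmap_table([p1, p2], gene_order=["g2", "g1"], sample_order=["s2", "s1"])
        b = heatmap_table([p2, p1], gene_order=["g2", "g1"], sample_order=["s2", "s1"])
        assert a.equals(b)
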