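import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sweepscan import (
    BreedModel,
    ConfigError,
    GenomicWindow,
    breed_mean_fst,
    make_windows,
    pair_fst_tracks,
    sample_pool_reads,
    simulate_frequencies,
    snp_fst,
    snp_fst_values,
    window_mean_fst,
    apply_filters,
)
from sweepscan.windows import window_mean


def brute_force_fst(p1, p2):
    """Independent coding of the two-population weighted F_ST.

    Uses the statistics module for the sample variance over the two
    frequencies rather than the package's vectorized expression.
    """
    r = 2
    p_bar = statistics.mean([p1, p2])
    s2 = statistics.variance([p1, p2])  # n-1 denominator
    denom = p_bar * (1 - p_bar) + s2 / r
    return s2 / denom if denom > 0 else 0.0


class TestSnpFst:
    def test_identical_frequencies_give_zero(self):
        assert snp_fst(0.5, 0.5).fst == 0.0
        assert snp_fst(0.0, 0.0).fst == 0.0
        assert snp_fst(1.0, 1.0).fst == 0.0

    def test_fixed_difference_gives_one(self):
        res = snp_fst(0.0, 1.0)
        assert res.fst == 1.0
        assert res.p_bar == 0.5 and res.s2 == 0.5

    def test_hand_computed_value(self):
        # p_bar = 0.5, s2 = 0.18, denom = 0.25 + 0.09
        assert snp_fst(0.2, 0.8).fst == pytest.approx(0.18 / 0.34, rel=1e-12)

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(123)
        p1 = rng.uniform(0, 1, 10_000)
        p2 = rng.uniform(0, 1, 10_000)
        ours = snp_fst_values(p1, p2)
        theirs = np.array([brute_force_fst(a, b) for a, b in zip(p1, p2)])
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_bounded_on_grid(self):
        grid = np.arange(0, 1.0001, 0.01)
        p1, p2 = np.meshgrid(grid, grid)
        fst = snp_fst_values(p1.ravel(), p2.ravel())
        assert fst.min() >= 0.0 and fst.max() <= 1.0

    @given(
        st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
    )
    def test_symmetry(self, a, b):
        assert snp_fst(a, b).fst == snp_fst(b, a).fst

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ConfigError):
            snp_fst(-0.1, 0.5)
        with pytest.raises(ConfigError):
            snp_fst_values(np.array([0.2]), np.array([1.2]))


class TestMakeWindows:
    def test_chrom_of_150kb_has_six_starts(self):
        w = make_windows({"chr1": 150_000})
        assert w["start"].tolist() == [0, 25_000, 50_000, 75_000, 100_000, 125_000]
        assert (w["end"] - w["start"] == 100_000).all()

    def test_short_chromosome_single_window(self):
        w = make_windows({"chr1": 10_000})
        assert len(w) == 1 and w["start"].iloc[0] == 0

    def test_snp_membership_half_open(self):
        # 1-based position 100,000 (0-based 99,999) sits in the windows
        # starting at 0, 25k, 50k and 75k, not the one starting at 100k
        w = make_windows({"chr1": 500_000})
        for start in (0, 25_000, 50_000, 75_000):
            assert GenomicWindow("chr1", start, start + 100_000).contains(100_000)
        assert not GenomicWindow("chr1", 100_000, 200_000).contains(100_000)
        n, _ = window_mean(
            w, np.array(["chr1"], dtype=object), np.array([100_000]),
            np.array([0.5]), min_snps=1,
        )
        assert n[:6].tolist() == [1, 1, 1, 1, 0, 0]

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigError):
            make_windows({"chr1": 100_000}, window_size=100_000, step=30_000)
        with pytest.raises(ConfigError):
            make_windows({"chr1": -5})


class TestWindowMeanFst:
    def test_mean_and_mask_thresholds(self):
        w = make_windows({"chr1": 100_000})
        chrom = np.array(["chr1"] * 30, dtype=object)
        pos = np.arange(1, 31) * 100
        track = window_mean_fst(w, chrom, pos, np.full(30, 0.2))
        assert track["n_snps"].iloc[0] == 30
        assert track["fst"].iloc[0] == pytest.approx(0.2)
        track29 = window_mean_fst(w, chrom[:29], pos[:29], np.full(29, 0.2))
        assert np.isnan(track29["fst"].iloc[0])  # 29 SNPs < 30: masked

    def test_overlapping_window_membership(self):
        # SNP at 1-based 30,000 contributes to windows starting 0 and 25k only
        w = make_windows({"chr1": 200_000})
        track = window_mean_fst(
            w, np.array(["chr1"], dtype=object), np.array([30_000]),
            np.array([0.4]), min_snps=1,
        )
        contributing = track.loc[track["n_snps"] > 0, "start"].tolist()
        assert contributing == [0, 25_000]

    def test_matches_exhaustive_per_snp_enumeration(self):
        rng = np.random.default_rng(5)
        w = make_windows({"chr1": 300_000, "chr2": 120_000})
        chrom = np.array(
            ["chr1"] * 400 + ["chr2"] * 100, dtype=object
        )
        pos = np.concatenate(
            [np.sort(rng.choice(np.arange(1, 300_001), 400, replace=False)),
             np.sort(rng.choice(np.arange(1, 120_001), 100, replace=False))]
        )
        vals = rng.uniform(0, 1, 500)
        track = window_mean_fst(w, chrom, pos, vals, min_snps=5)
        for _, row in track.iterrows():
            inside = (chrom == row["chrom"]) & (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
            n = int(inside.sum())
            assert n == row["n_snps"]
            if n >= 5:
                assert row["fst"] == pytest.approx(vals[inside].mean(), rel=1e-12)
            else:
                assert np.isnan(row["fst"])


class TestBreedMeanFst:
    def _pair_tracks(self, values_by_pair, n_snps=40):
        w = make_windows({"chr1": 50_000})
        out = {}
        for pair, v in values_by_pair.items():
            t = w.copy()
            t["n_snps"] = n_snps
            t["fst"] = v
            out[pair] = t
        return out

    def test_mean_of_five_comparisons(self):
        breeds = ["f", "a", "b", "c", "d", "e"]
        tracks = self._pair_tracks(
            {("f", o): v for o, v in zip("abcde", [0.1, 0.2, 0.3, 0.2, 0.2])}
        )
        merged = breed_mean_fst(tracks, "f", breeds)
        assert merged["fst"].iloc[0] == pytest.approx(0.2)

    def test_masked_in_any_pair_masks_breed_window(self):
        breeds = ["f", "a", "b"]
        tracks = self._pair_tracks({("f", "a"): 0.1, ("f", "b"): np.nan})
        merged = breed_mean_fst(tracks, "f", breeds)
        assert np.isnan(merged["fst"].iloc[0])

    def test_missing_comparison_is_configuration_error(self):
        breeds = ["f", "a", "b"]
        tracks = self._pair_tracks({("f", "a"): 0.1})
        with pytest.raises(ConfigError):
            breed_mean_fst(tracks, "f", breeds)

    def test_six_breeds_fifteen_pairs(self):
        models = [BreedModel(f"b{i}", 20, 0.1, 26.0) for i in range(6)]
        sim = simulate_frequencies({"chr1": 200_000}, models, snp_per_kb=2.0, seed=0)
        counts = sample_pool_reads(sim, models, seed=1)
        filt = apply_filters(counts)
        w = make_windows({"chr1": 200_000})
        tracks = pair_fst_tracks(counts, filt, w)
        assert len(tracks) == 15
        # each focal breed averages exactly five comparisons
        merged = breed_mean_fst(tracks, "b0", [m.name for m in models])
        assert len(merged) == len(w)


class TestNeutralSymmetry:
    def test_no_focal_breed_bias_under_neutrality(self):
        # with identical F_drift everywhere, genome-wide mean window F_ST
        # is the same for every focal breed up to Monte-Carlo error
        models = [BreedModel(f"b{i}", 20, 0.1, 26.0) for i in range(6)]
        lengths = {"chr1": 4_000_000}
        sim = simulate_frequencies(lengths, models, snp_per_kb=2.5, seed=21)
        counts = sample_pool_reads(sim, models, seed=22)
        filt = apply_filters(counts)
        w = make_windows(lengths)
        tracks = pair_fst_tracks(counts, filt, w)
        means = [
            np.nanmean(breed_mean_fst(tracks, m.name, [x.name for x in models])["fst"])
            for m in models
        ]
        assert max(means) - min(means) < 0.01
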