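import numpy as np
import pytest

from sweepscan import (
    BreedModel,
    ConfigError,
    DataError,
    PlacementError,
    SweepTruth,
    emit_toy_annotation,
    implant_sweep,
    read_gff3_genes,
    sample_pool_reads,
    simulate_frequencies,
    snp_fst_values,
)

LENGTHS = {"chr1": 1_000_000}


def panel(n=2, F=0.1, depth=26.0):
    return [BreedModel(f"b{i+1}", 20, F, depth) for i in range(n)]


class TestBreedModel:
    @pytest.mark.parametrize(
        "kwargs", [{"F_drift": 0.0}, {"F_drift": 1.0}, {"n_individuals": 0}, {"mean_depth": 0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            BreedModel("x", **{**{"n_individuals": 20}, **kwargs})


class TestSimulateFrequencies:
    def test_same_seed_bit_identical(self):
        a = simulate_frequencies(LENGTHS, panel(), seed=7)
        b = simulate_frequencies(LENGTHS, panel(), seed=7)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_zero_drift_limit_tracks_ancestral(self):
        models = [BreedModel("b1", 20, 1e-6, 26.0)]
        sim = simulate_frequencies(LENGTHS, models, snp_per_kb=1.0, seed=3)
        assert np.all(np.abs(sim.freqs[:, 0] - sim.p_anc) < 0.01)

    def test_density_and_bounds(self):
        sim = simulate_frequencies(LENGTHS, panel(), snp_per_kb=2.5, seed=1)
        assert len(sim.pos) == 2500
        assert sim.pos.min() >= 1 and sim.pos.max() <= LENGTHS["chr1"]
        assert len(np.unique(sim.pos)) == len(sim.pos)
        assert np.all((sim.p_anc >= 0.05) & (sim.p_anc <= 0.95))

    def test_balding_nichols_variance_identity(self):
        # Var(p_breed - p_anc | p_anc) = F * p_anc (1 - p_anc); Monte-Carlo
        # over 1e5 sites the averaged identity holds within 5% relative error.
        F = 0.1
        sim = simulate_frequencies(
            {"chr1": 40_000_000}, [BreedModel("b1", 20, F, 26.0)], snp_per_kb=2.5, seed=11
        )
        assert len(sim.pos) == 100_000
        observed = np.mean((sim.freqs[:, 0] - sim.p_anc) ** 2)
        expected = F * np.mean(sim.p_anc * (1 - sim.p_anc))
        assert abs(observed - expected) / expected < 0.05

    def test_invalid_drift_rejected(self):
        with pytest.raises(ConfigError):
            simulate_frequencies(LENGTHS, [BreedModel("b1", 20, 1.5, 26.0)], seed=0)


class TestImplantSweep:
    def test_fixes_locally_common_allele(self):
        sim = simulate_frequencies(LENGTHS, panel(), seed=5)
        sweep = SweepTruth("b1", "chr1", 200_000, 400_000, 1.0)
        out = implant_sweep(sim, sweep)
        in_region = (sim.pos - 1 >= 200_000) & (sim.pos - 1 < 400_000)
        swept = out.freqs[in_region, 0]
        assert np.all((swept == 0.0) | (swept == 1.0))
        # the chosen pole is the one nearer the pre-sweep frequency
        closer_to_one = sim.freqs[in_region, 0] >= 0.5
        np.testing.assert_array_equal(swept == 1.0, closer_to_one)
        # other breed untouched, outside region untouched
        np.testing.assert_array_equal(out.freqs[:, 1], sim.freqs[:, 1])
        np.testing.assert_array_equal(out.freqs[~in_region, 0], sim.freqs[~in_region, 0])

    def test_region_outside_chromosome_rejected(self):
        sim = simulate_frequencies(LENGTHS, panel(), seed=5)
        with pytest.raises(DataError):
            implant_sweep(sim, SweepTruth("b1", "chr1", 900_000, 1_200_000, 0.98))
        with pytest.raises(DataError):
            implant_sweep(sim, SweepTruth("b1", "chrX", 0, 100, 0.98))

    def test_unknown_breed_rejected(self):
        sim = simulate_frequencies(LENGTHS, panel(), seed=5)
        with pytest.raises(ConfigError):
            implant_sweep(sim, SweepTruth("nope", "chr1", 0, 1000, 0.98))

    def test_sweep_raises_fst_above_neutral_background(self):
        # With target 0.98 at F = 0.1, the per-SNP F_ST between the focal and
        # the other breed inside the sweep region exceeds the genome-wide mean
        # in every one of 20 seeded replicates.
        wins = 0
        for seed in range(20):
            sim = simulate_frequencies(LENGTHS, panel(), snp_per_kb=2.0, seed=seed)
            out = implant_sweep(sim, SweepTruth("b1", "chr1", 300_000, 500_000, 0.98))
            fst = snp_fst_values(out.freqs[:, 0], out.freqs[:, 1])
            in_region = (out.pos - 1 >= 300_000) & (out.pos - 1 < 500_000)
            wins += fst[in_region].mean() > fst.mean()
        assert wins == 20


class TestSamplePoolReads:
    def test_fixed_alt_allele_error_free(self):
        sim = simulate_frequencies(LENGTHS, panel(1), snp_per_kb=0.5, seed=9)
        sim.freqs[:] = 1.0
        counts = sample_pool_reads(sim, panel(1), error_rate=0.0, seed=9)
        assert (counts.n_ref == 0).all()
        assert counts.n_alt.sum() > 0

    def test_binomial_concentration_at_extreme_depth(self):
        sim = simulate_frequencies({"chr1": 20_000}, panel(1, depth=1e6), snp_per_kb=1.0, seed=2)
        sim.freqs[:] = 0.5
        counts = sample_pool_reads(sim, panel(1, depth=1e6), error_rate=0.0, seed=2)
        f = counts.n_alt[:, 0] / counts.depth[:, 0]
        assert np.all(np.abs(f - 0.5) < 0.002)

    def test_same_seed_identical_tables(self):
        sim = simulate_frequencies(LENGTHS, panel(), seed=4)
        a = sample_pool_reads(sim, panel(), seed=8)
        b = sample_pool_reads(sim, panel(), seed=8)
        np.testing.assert_array_equal(a.n_ref, b.n_ref)
        np.testing.assert_array_equal(a.n_alt, b.n_alt)
        assert list(a.ref) == list(b.ref)

    def test_emitted_sites_satisfy_invariants(self):
        sim = simulate_frequencies(LENGTHS, panel(), seed=4)
        counts = sample_pool_reads(sim, panel(), seed=8)
        counts.validate()
        site = counts[0]
        assert site.ref_allele != site.alt_allele

    def test_invalid_error_rate_rejected(self):
        sim = simulate_frequencies(LENGTHS, panel(), seed=4)
        with pytest.raises(ConfigError):
            sample_pool_reads(sim, panel(), error_rate=0.5, seed=8)


class TestToyAnnotation:
    def test_zero_genes_header_only(self, tmp_path):
        p = tmp_path / "g.gff3"
        emit_toy_annotation(LENGTHS, 0, seed=1, path=p)
        assert all(line.startswith("#") for line in p.read_text().splitlines())

    def test_round_trip_and_non_overlap(self, tmp_path):
        p = tmp_path / "g.gff3"
        emit_toy_annotation(LENGTHS, 12, seed=1, path=p)
        genes = read_gff3_genes(p)
        assert len(genes) == 12
        assert len({g.gene_id for g in genes}) == 12
        spans = sorted((g.start, g.end) for g in genes)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
        assert all(5_000 <= g.end - g.start + 1 <= 50_000 for g in genes)

    def test_fixed_seed_identical_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        emit_toy_annotation(LENGTHS, 10, seed=3, path=p1)
        emit_toy_annotation(LENGTHS, 10, seed=3, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_impossible_placement_rejected(self):
        with pytest.raises(PlacementError):
            emit_toy_annotation({"chr1": 30_000}, 10, seed=1)
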