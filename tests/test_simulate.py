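"""Simulator: founders, meiosis, funnels, genotype emission."""

import numpy as np
import pytest

from magicqtl.gmap import demo_map
from magicqtl.simulate import (
    HaplotypeTrack,
    emit_genotypes,
    meiosis,
    simulate_founders,
    simulate_funnel,
    simulate_population_mosaics,
)

from conftest import make_map


class TestSimulateFounders:
    def test_two_founders_full_divergence_differ_everywhere(self, tiny_map):
        f = simulate_founders(tiny_map, 2, 1.0, seed=0)
        assert (f.haplotypes[0] != f.haplotypes[1]).all()

    def test_mean_pairwise_difference_matches_target(self):
        gmap = make_map({"1A": 100.0}, n=1000)
        f = simulate_founders(gmap, 8, 0.5, seed=3)
        diffs = [
            (f.haplotypes[i] != f.haplotypes[j]).mean()
            for i in range(8) for j in range(i + 1, 8)
        ]
        # binomial error at 1000 markers x 28 pairs, plus the slight
        # polymorphism-conditioning shift
        assert abs(np.mean(diffs) - 0.5) < 0.02

    def test_every_marker_polymorphic(self, small_founders):
        sums = small_founders.haplotypes.sum(axis=0)
        assert (sums > 0).all() and (sums < 8).all()

    def test_deterministic_under_seed(self, tiny_map):
        a = simulate_founders(tiny_map, 8, 0.4, seed=5)
        b = simulate_founders(tiny_map, 8, 0.4, seed=5)
        assert (a.haplotypes == b.haplotypes).all() and a.names == b.names

    def test_zero_divergence_rejected(self, tiny_map):
        with pytest.raises(ValueError, match="divergence"):
            simulate_founders(tiny_map, 8, 0.0, seed=0)

    def test_unattainable_divergence_rejected(self, tiny_map):
        with pytest.raises(ValueError, match="unattainable"):
            simulate_founders(tiny_map, 8, 0.9, seed=0)


class TestMeiosis:
    def test_zero_length_chromosome_returns_parental_homolog(self):
        rng = np.random.default_rng(0)
        a = HaplotypeTrack(0.0, np.array([1e-9]), np.array([3]))
        b = HaplotypeTrack(0.0, np.array([1e-9]), np.array([5]))
        for _ in range(20):
            g = meiosis((a, b), rng)
            assert g.founders.tolist() in ([3], [5])

    def test_crossover_count_mean_one_per_100cM(self):
        rng = np.random.default_rng(1)
        a = HaplotypeTrack(0.0, np.array([100.0]), np.array([0]))
        b = HaplotypeTrack(0.0, np.array([100.0]), np.array([1]))
        n_x = [meiosis((a, b), rng).n_segments() - 1 for _ in range(4000)]
        assert abs(np.mean(n_x) - 1.0) < 0.06

    def test_haldane_recombinant_fraction_at_50cM(self):
        # two loci 50 cM apart: recombinant fraction (1 - e^-1)/2 ~ 0.316
        rng = np.random.default_rng(2)
        a = HaplotypeTrack(0.0, np.array([50.0]), np.array([0]))
        b = HaplotypeTrack(0.0, np.array([50.0]), np.array([1]))
        pos = np.array([0.0, 50.0])
        rec = 0
        n = 4000
        for _ in range(n):
            g = meiosis((a, b), rng)
            ends = g.founder_at(pos)
            rec += ends[0] != ends[1]
        expected = (1 - np.exp(-1.0)) / 2
        assert abs(rec / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_gamete_tiles_span(self):
        rng = np.random.default_rng(3)
        a = HaplotypeTrack(10.0, np.array([40.0, 110.0]), np.array([2, 6]))
        b = HaplotypeTrack(10.0, np.array([70.0, 110.0]), np.array([1, 4]))
        for _ in range(50):
            g = meiosis((a, b), rng)
            assert g.start == 10.0 and g.end == 110.0
            assert (np.diff(g.ends) > 0).all()


class TestFunnel:
    def test_residual_heterozygosity_halves_per_selfing(self, small_founders, tiny_map):
        rng = np.random.default_rng(4)
        het = []
        for _ in range(300):
            order = tuple(rng.permutation(8))
            mos = simulate_funnel(small_founders, order, tiny_map, n_self=5, seed=rng)
            het.append(mos.heterozygosity(tiny_map))
        # (1/2)^5 of the post-funnel (~fully heterozygous) level
        assert abs(np.mean(het) - 2 ** -5) < 0.01

    def test_founder_shares_uniform(self, small_founders, tiny_map):
        mosaics, _ = simulate_population_mosaics(
            small_founders, tiny_map, n_lines=500, seed=6
        )
        pos = tiny_map.positions("2B")
        counts = np.zeros(8)
        for mos in mosaics:
            f = mos.founders_at("2B", pos)
            for k in range(8):
                counts[k] += (f == k).sum()
        shares = counts / counts.sum()
        assert np.abs(shares - 1 / 8).max() < 0.02

    def test_mosaics_tile_chromosomes(self, small_population, tiny_map):
        mosaics, _, _ = small_population
        for mos in mosaics:
            mos.validate(tiny_map)

    def test_deterministic_under_seed(self, small_founders, tiny_map):
        a = simulate_funnel(small_founders, tuple(range(8)), tiny_map, seed=9)
        b = simulate_funnel(small_founders, tuple(range(8)), tiny_map, seed=9)
        assert a.segment_table("x").equals(b.segment_table("x"))

    def test_repeated_founder_rejected(self, small_founders, tiny_map):
        with pytest.raises(ValueError, match="distinct"):
            simulate_funnel(small_founders, (0, 0, 1, 2, 3, 4, 5, 6), tiny_map)


class TestEmitGenotypes:
    def test_noiseless_emission_matches_mosaic(self, small_population, small_founders,
                                               tiny_map):
        mosaics, ids, _ = small_population
        geno = emit_genotypes(mosaics, small_founders, 0.0, 0.0, seed=0,
                              line_ids=ids)
        # reconstruct from truth: allele sum of the two homologs
        H = small_founders.haplotypes
        for i in (0, 7, 23):
            for chrom in tiny_map.chromosomes:
                sl = tiny_map.chrom_slice(chrom)
                pos = tiny_map.positions(chrom)
                dip = mosaics[i].founders_at(chrom, pos)
                idx = np.arange(sl.start, sl.stop)
                expected = H[dip[:, 0], idx] + H[dip[:, 1], idx]
                assert (geno.matrix[i, sl] == expected).all()

    def test_missing_rate_recovered(self):
        gmap = demo_map(60)
        founders = simulate_founders(gmap, 8, 0.5, seed=21)
        mosaics, ids = simulate_population_mosaics(founders, gmap, 208, seed=22)
        geno = emit_genotypes(mosaics, founders, 0.0, 0.0219, seed=23, line_ids=ids)
        frac = geno.missing_fraction()
        n_cells = geno.matrix.size
        se = np.sqrt(0.0219 * (1 - 0.0219) / n_cells)
        assert abs(frac - 0.0219) < 4 * se

    def test_half_error_rate_is_uninformative(self):
        # with allele-flip probability 0.5 the emitted genotype is symmetric
        # in the founder allele, so both founders are equally likely
        from magicqtl.hmm import _dosage_emission_table
        t = _dosage_emission_table(0.5)
        assert np.allclose(t[0], t[2])

    def test_invalid_rates_rejected(self, small_population, small_founders):
        mosaics, ids, _ = small_population
        with pytest.raises(ValueError):
            emit_genotypes(mosaics, small_founders, error_rate=1.0, seed=0)
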