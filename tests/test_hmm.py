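"""Founder-descent HMM: transitions, emissions, exact posteriors, Viterbi."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magicqtl.gmap import GeneticMap
from magicqtl.hmm import (
    FounderHMM,
    HMMParams,
    emission_prob,
    forward_backward,
    transition_matrix,
    viterbi_mosaic,
)
from magicqtl.simulate import MISSING, FounderSet, true_diplotypes

from conftest import make_map


def brute_force_posteriors(G, H, pos, params):
    """Exhaustive founder-path enumeration oracle for one chromosome.

    Sums the joint probability of every founder path from the closed-form
    transition and emission definitions; feasible for <= 4 loci and <= 3
    founders.
    """
    m = len(pos)
    s = H.shape[0]
    eps = params.error_rate

    def emit(obs, allele):
        if obs == MISSING:
            return 1.0
        if obs == 1:
            return 0.5
        match = (obs == 2) == (allele == 1)
        return 1.0 - eps if match else eps

    def trans(d, a, b):
        stay = np.exp(-params.generations * d / 100.0)
        return stay + (1 - stay) / s if a == b else (1 - stay) / s

    post = np.zeros((m, s))
    total = 0.0
    for path in itertools.product(range(s), repeat=m):
        p = 1.0 / s * emit(G[0], H[path[0], 0])
        for k in range(1, m):
            p *= trans(pos[k] - pos[k - 1], path[k - 1], path[k])
            p *= emit(G[k], H[path[k], k])
        total += p
        for k in range(m):
            post[k, path[k]] += p
    return post / total, np.log(total)


def tiny_founders(H, pos):
    gmap = GeneticMap(pd.DataFrame({
        "marker": [f"m{i}" for i in range(len(pos))],
        "chrom": "1A", "cM": pos,
    }))
    names = tuple(f"F{i}" for i in range(H.shape[0]))
    return FounderSet(names, H, gmap)


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        T = transition_matrix(0.0, HMMParams(), 8)
        assert np.allclose(T, np.eye(8))

    def test_infinite_distance_is_uniform(self):
        T = transition_matrix(1e7, HMMParams(), 8)
        assert np.allclose(T, 1 / 8)

    def test_closed_form_diagonal(self):
        # S=8, g=8, d=10 cM: diagonal e^-0.8 + (1 - e^-0.8)/8
        T = transition_matrix(10.0, HMMParams(generations=8), 8)
        expected = np.exp(-0.8) + (1 - np.exp(-0.8)) / 8
        assert np.allclose(np.diag(T), expected)
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-1.0, HMMParams(), 8)


class TestEmissionProb:
    @pytest.mark.parametrize("obs,allele,eps,expected", [
        (MISSING, 0, 0.01, 1.0),
        (MISSING, 1, 0.01, 1.0),
        (2, 1, 0.0, 1.0),
        (0, 0, 0.0, 1.0),
        (0, 1, 0.01, 0.01),
        (2, 0, 0.01, 0.01),
        (1, 0, 0.01, 0.5),
        (1, 1, 0.01, 0.5),
    ])
    def test_emission_table(self, obs, allele, eps, expected):
        assert emission_prob(obs, allele, eps) == pytest.approx(expected)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            emission_prob(3, 0, 0.01)


class TestForwardBackward:
    def test_all_missing_gives_uniform_posterior(self):
        H = np.array([[0, 1, 0], [1, 0, 1]], dtype=np.int8)
        founders = tiny_founders(H, [0.0, 10.0, 20.0])
        G = np.full(3, MISSING, dtype=np.int8)
        post, _ = forward_backward(G, founders)
        assert np.allclose(post, 0.5)

    def test_single_informative_marker_pins_founder(self):
        # only founder 2 carries the alternate allele at the middle marker
        H = np.array([[0, 0, 0], [0, 0, 0], [0, 1, 0]], dtype=np.int8)
        founders = tiny_founders(H, [0.0, 5.0, 10.0])
        G = np.array([MISSING, 2, MISSING], dtype=np.int8)
        post, _ = forward_backward(G, founders, params=HMMParams(error_rate=0.0))
        assert post[1, 2] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        s = int(rng.integers(2, 4))
        H = rng.integers(0, 2, size=(s, m)).astype(np.int8)
        pos = np.sort(rng.uniform(0, 30, size=m))
        pos[0] = 0.0
        G = rng.choice([0, 1, 2, MISSING], size=m).astype(np.int8)
        params = HMMParams(generations=float(rng.uniform(2, 10)),
                           error_rate=float(rng.uniform(0.001, 0.2)))
        founders = tiny_founders(H, pos)
        post, ll = forward_backward(G, founders, params=params)
        expected, ll_expected = brute_force_posteriors(G, H, pos, params)
        assert np.abs(post - expected).max() < 1e-9
        assert ll == pytest.approx(ll_expected, abs=1e-9)

    def test_posteriors_sum_to_one(self, small_population, small_founders):
        _, _, geno = small_population
        F = FounderHMM().fit(small_founders).transform(geno)
        assert np.abs(F.probs.sum(axis=2) - 1.0).max() < 1e-9
        assert F.probs.min() >= 0.0

    def test_permutation_equivariance(self, small_population, small_founders):
        _, _, geno = small_population
        F = FounderHMM().fit(small_founders).transform(geno)
        perm = np.array([3, 1, 7, 0, 5, 2, 6, 4])
        shuffled = FounderSet(
            tuple(np.array(small_founders.names)[perm]),
            small_founders.haplotypes[perm], small_founders.gmap,
        )
        F2 = FounderHMM().fit(shuffled).transform(geno)
        assert np.allclose(F.probs[:, :, perm], F2.probs, atol=1e-12)

    def test_accuracy_improves_with_density_and_low_error(self):
        from magicqtl.simulate import (emit_genotypes, simulate_founders,
                                       simulate_population_mosaics)
        scores = {}
        for n_markers, eps in [(15, 0.1), (60, 0.01)]:
            gmap = make_map({"1A": 100.0}, n=n_markers)
            founders = simulate_founders(gmap, 8, 0.5, seed=31)
            mosaics, ids = simulate_population_mosaics(founders, gmap, 40, seed=32)
            geno = emit_genotypes(mosaics, founders, eps, 0.0, seed=33,
                                  line_ids=ids)
            F = FounderHMM(error_rate=eps).fit(founders).transform(geno)
            dip = true_diplotypes(mosaics, gmap)
            hom = dip[:, :, 0] == dip[:, :, 1]
            truth = np.take_along_axis(
                F.probs, dip[:, :, 0][:, :, None], axis=2
            )[:, :, 0]
            scores[(n_markers, eps)] = truth[hom].mean()
        assert scores[(60, 0.01)] > scores[(15, 0.1)]

    def test_diplotype_marginal_consistent(self, small_population, small_founders):
        _, _, geno = small_population
        Fd = FounderHMM(inbred_mode=False).fit(small_founders).transform(geno)
        # symmetric pair posterior, and its marginal matches the stored probs
        assert np.allclose(Fd.diplotype, Fd.diplotype.transpose(0, 1, 3, 2))
        assert np.allclose(Fd.diplotype.sum(axis=3), Fd.probs, atol=1e-12)
        assert np.abs(Fd.probs.sum(axis=2) - 1.0).max() < 1e-9


class TestViterbi:
    @pytest.mark.parametrize("n_markers,min_accuracy", [(101, 0.94), (301, 0.98)])
    def test_recovers_true_mosaic_on_dense_noiseless_data(self, n_markers,
                                                          min_accuracy):
        # label accuracy is bounded by breakpoint ambiguity: around each true
        # breakpoint the neighbouring founders are locally indistinguishable
        # over a few markers (geometric window at divergence 0.5), so ~4
        # breakpoints/homolog cost ~5% of markers at 1 marker/cM and shrink
        # proportionally as density rises
        from magicqtl.simulate import (emit_genotypes, simulate_founders,
                                       simulate_population_mosaics)
        gmap = make_map({"1A": 100.0}, n=n_markers)
        founders = simulate_founders(gmap, 8, 0.5, seed=41)
        mosaics, ids = simulate_population_mosaics(founders, gmap, 20, seed=42)
        geno = emit_genotypes(mosaics, founders, 0.0, 0.0, seed=43, line_ids=ids)
        params = HMMParams(error_rate=1e-4)
        dip = true_diplotypes(mosaics, gmap)
        agree = total = allele_agree = 0
        H = founders.haplotypes
        for i in range(20):
            hom = dip[i, :, 0] == dip[i, :, 1]
            mos = viterbi_mosaic(geno.matrix[i], founders, gmap, params)
            path = mos.founders_at("1A", gmap.positions("1A"))[:, 0]
            idx = np.flatnonzero(hom)
            agree += (path[idx] == dip[i, idx, 0]).sum()
            allele_agree += (H[path[idx], idx] == H[dip[i, idx, 0], idx]).sum()
            total += hom.sum()
        assert agree / total > min_accuracy
        # allele-level agreement (what genotype data can actually resolve)
        # is essentially perfect even where labels are ambiguous
        assert allele_agree / total > 0.995

    def test_all_missing_gives_single_lowest_founder(self, tiny_map):
        H = np.zeros((3, tiny_map.n_markers), dtype=np.int8)
        H[1, ::2] = 1
        H[2, 1::2] = 1
        founders = FounderSet(("A", "B", "C"), H, tiny_map)
        G = np.full(tiny_map.n_markers, MISSING, dtype=np.int8)
        mos = viterbi_mosaic(G, founders, tiny_map)
        for chrom in tiny_map.chromosomes:
            t0, _ = mos.tracks[chrom]
            assert t0.founders.tolist() == [0]

    def test_viterbi_path_at_least_as_probable_as_truth(self):
        from magicqtl.simulate import (emit_genotypes, simulate_founders,
                                       simulate_population_mosaics)
        gmap = make_map({"1A": 60.0}, n=25)
        founders = simulate_founders(gmap, 8, 0.5, seed=51)
        mosaics, ids = simulate_population_mosaics(founders, gmap, 5, seed=52)
        geno = emit_genotypes(mosaics, founders, 0.01, 0.0, seed=53, line_ids=ids)
        params = HMMParams()
        dip = true_diplotypes(mosaics, gmap)

        def path_logprob(G, path, H, pos):
            from magicqtl.hmm import _haploid_emissions
            E = _haploid_emissions(G[None, :], H, params.error_rate)[0]
            lp = -np.log(H.shape[0]) + np.log(E[0, path[0]])
            for k in range(1, len(pos)):
                T = transition_matrix(pos[k] - pos[k - 1], params, H.shape[0])
                lp += np.log(T[path[k - 1], path[k]]) + np.log(E[k, path[k]])
            return lp

        pos = gmap.positions("1A")
        for i in range(5):
            mos = viterbi_mosaic(geno.matrix[i], founders, gmap, params)
            vpath = mos.founders_at("1A", pos)[:, 0]
            tpath = dip[i, :, 0]
            assert (path_logprob(geno.matrix[i], vpath, founders.haplotypes, pos)
                    >= path_logprob(geno.matrix[i], tpath, founders.haplotypes, pos)
                    - 1e-9)
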