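"""Generator behaviour: ancestry proportions, tract-length law, sweep
dynamics, phenotype architecture, determinism."""

import numpy as np
import pytest

from tractsel.genome_model import GenomeMap, ValidationError
from tractsel.synthetic_data import (
    AdmixtureModel,
    PhenotypeModel,
    SweepModel,
    simulate_independent_null,
    simulate_mosaics,
    simulate_phenotypes,
    simulate_sweep,
)
from tractsel.selcoef import forward_frequency

from conftest import make_matrix


class TestAdmixtureMosaics:
    def test_degenerate_proportions_single_tract(self):
        model = AdmixtureModel(
            scenario="independent", proportions=(1.0, 0.0, 0.0),
            n_individuals=3, seed=1,
            genome=GenomeMap.uniform({"1": 10_000_000}),
        )
        m = simulate_mosaics(model)
        for t in m.tracts():
            assert t.ancestry == "EUR"
            assert (t.start_bp, t.end_bp) == (0, 10_000_000)

    def test_nested_genome_fraction_matches_alpha(self):
        model = AdmixtureModel(n_individuals=53, seed=7)
        m = simulate_mosaics(model)
        # 106 haplotypes x 4 Morgans: Monte-Carlo error on the EUR fraction
        # is a few percent of the genome
        assert m.ancestry_fraction("EUR") == pytest.approx(0.13, abs=0.025)
        assert m.ancestry_fraction("WAF") == pytest.approx(0.68, abs=0.04)

    def test_same_seed_reproduces_identical_mosaics(self):
        a = simulate_mosaics(AdmixtureModel(n_individuals=4, seed=5))
        b = simulate_mosaics(AdmixtureModel(n_individuals=4, seed=5))
        assert a == b

    def test_mean_merged_tract_length_follows_exponential_law(self):
        # independent scenario, rate T2 per Morgan, i.i.d. labels: merged
        # (maximal-run) tracts have mean genetic length 1/(T2 * (1 - sum p^2))
        p = (0.13, 0.19, 0.68)
        t2 = 63
        model = AdmixtureModel(
            scenario="independent", proportions=p, t2=t2, n_individuals=40,
            seed=11, genome=GenomeMap.uniform({"1": 200_000_000}),
        )
        m = simulate_mosaics(model)
        lengths = np.array([t.length for t in m.tracts()]) / 1e8  # bp -> Morgan
        expected = 1.0 / (t2 * (1 - sum(q * q for q in p)))
        assert lengths.mean() == pytest.approx(expected, rel=0.05)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValidationError):
            AdmixtureModel(proportions=(0.5, 0.5, 0.5))
        with pytest.raises(ValidationError):
            AdmixtureModel(scenario="nested", t1=10, t2=20)


class TestIndependentNull:
    def test_label_frequencies_match_proportions(self):
        m = simulate_independent_null(n_individuals=53, n_fragments=10_000, seed=3)
        # fractions over 1.06e6 i.i.d. equal-length fragments
        se = np.sqrt(0.13 * 0.87 / (106 * 10_000))
        assert m.ancestry_fraction("EUR") == pytest.approx(0.13, abs=4 * se)

    def test_degenerate_proportions_merge_to_single_tract(self):
        m = simulate_independent_null(
            n_individuals=3, n_fragments=50, proportions=(0, 0, 1), seed=1
        )
        tracts = list(m.tracts())
        assert len(tracts) == 6  # one WAF tract per haplotype
        assert {t.ancestry for t in tracts} == {"WAF"}

    def test_two_fragment_tract_count_distribution(self):
        # n_frag=2 with proportions (.5, 0, .5): the 4 equally likely label
        # pairs give 2 tracts when labels differ (p=1/2), else 1
        counts = []
        for seed in range(300):
            m = simulate_independent_null(
                n_individuals=1, n_fragments=2, proportions=(0.5, 0.0, 0.5),
                seed=seed,
            )
            for key in m.haplotype_keys:
                _, codes = m.chromosome_arrays(*key, "1")
                counts.append(codes.size)
        counts = np.array(counts)
        assert set(counts) <= {1, 2}
        se = np.sqrt(0.25 / counts.size)  # binomial SE of the 1/2 rate
        assert np.mean(counts == 2) == pytest.approx(0.5, abs=4 * se)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            simulate_independent_null(n_individuals=2, proportions=(0.5, 0.1, 0.1))


class TestSweepSimulator:
    def test_neutral_allele_frequency_is_martingale(self, rng):
        # s=0: mean final frequency over replicates stays at p0
        founders = rng.integers(0, 2, size=(60, 1)).astype(np.uint8)
        finals = []
        for seed in range(250):
            model = SweepModel(
                n_diploid=30, n_snps=1, s=0.0, generations=15,
                initial_carriers=15, carrier_init="standing", seed=seed,
            )
            res = simulate_sweep(model, founder_haplotypes=founders)
            finals.append(res.trajectory[-1])
        p0 = founders.mean()
        se = np.std(finals) / np.sqrt(len(finals))
        assert np.mean(finals) == pytest.approx(p0, abs=4 * se + 1e-9)

    def test_selected_mean_trajectory_tracks_deterministic_recursion(self, rng):
        # large N (10^4 diploids), Hardy-Weinberg founders: the replicate
        # mean of the Wright-Fisher path follows the deterministic dominant
        # recursion within Monte-Carlo error
        n2 = 20_000
        carriers = 2_000
        trajs = []
        for seed in range(10):
            founders = np.zeros((n2, 1), dtype=np.uint8)
            rows = rng.choice(n2, size=carriers, replace=False)
            founders[rows, 0] = 1
            model = SweepModel(
                n_diploid=n2 // 2, n_snps=1, s=0.05, generations=63,
                initial_carriers=carriers, carrier_init="standing", seed=seed,
            )
            res = simulate_sweep(model, founder_haplotypes=founders)
            assert res.p0 == pytest.approx(0.1)
            trajs.append(res.trajectory)
        mean_traj = np.mean(trajs, axis=0)
        expected = forward_frequency(0.1, 0.05, 63, "dominant")
        np.testing.assert_allclose(mean_traj, expected, atol=0.02)

    def test_zero_recombination_copies_founder_haplotypes(self, rng):
        founders = rng.integers(0, 2, size=(40, 30)).astype(np.uint8)
        model = SweepModel(
            n_diploid=20, n_snps=30, s=0.0, generations=10,
            initial_carriers=10, carrier_init="standing",
            recomb_rate_per_bp=0.0, seed=4,
        )
        res = simulate_sweep(model, founder_haplotypes=founders)
        founder_set = {tuple(row) for row in founders}
        for row in res.matrix.haplotypes:
            assert tuple(row) in founder_set

    def test_donor_initialization_plants_identical_carriers(self, rng):
        founders = rng.integers(0, 2, size=(40, 21)).astype(np.uint8)
        model = SweepModel(
            n_diploid=20, n_snps=21, s=0.05, generations=0,
            initial_carriers=8, seed=4,
        )
        res = simulate_sweep(model, founder_haplotypes=founders)
        H = res.matrix.haplotypes
        carriers = H[:, res.focal_index] == 1
        assert carriers.sum() == 8
        assert np.all(H[carriers] == H[carriers][0])  # one donor background
        assert res.p0 == pytest.approx(8 / 40)

    def test_same_seed_reproduces_sweep(self):
        a = simulate_sweep(SweepModel(n_diploid=30, n_snps=50, generations=5,
                                      initial_carriers=10, sequence_length=5e4,
                                      seed=2))
        b = simulate_sweep(SweepModel(n_diploid=30, n_snps=50, generations=5,
                                      initial_carriers=10, sequence_length=5e4,
                                      seed=2))
        assert np.array_equal(a.matrix.haplotypes, b.matrix.haplotypes)
        assert np.array_equal(a.trajectory, b.trajectory)


class TestPhenotypes:
    def _matrix(self):
        # 6 samples; SNP0 dosages (0,1,2,0,1,2); SNP1 dosages (0,0,1,1,2,2)
        H = np.array(
            [
                [0, 0], [0, 0],
                [1, 0], [0, 0],
                [1, 0], [1, 1],
                [0, 0], [0, 1],
                [1, 1], [0, 1],
                [1, 1], [1, 1],
            ]
        ).reshape(12, 2)
        return make_matrix(H)

    def test_zero_effects_zero_noise_rise_equals_intercept(self):
        model = PhenotypeModel(
            carrier_rise=0.8, noncarrier_rise=0.8, locus2_effect=0.0,
            residual_sd=0.0, group_offsets={},
        )
        recs = simulate_phenotypes(self._matrix(), model, 0, 1, seed=1)
        for r in recs:
            assert max(r.post_values) - r.baseline == pytest.approx(0.8)

    def test_dominant_effect_exact_when_noise_free(self):
        model = PhenotypeModel(
            carrier_rise=2.0, noncarrier_rise=0.8, locus2_effect=0.0,
            residual_sd=0.0, group_offsets={},
        )
        m = self._matrix()
        recs = simulate_phenotypes(m, model, 0, 1, seed=1)
        dosage = m.dosage()
        for i, r in enumerate(recs):
            rise = max(r.post_values) - r.baseline
            expected = 2.0 if dosage[i, 0] >= 1 else 0.8
            assert rise == pytest.approx(expected)

    def test_locus2_additive_contribution(self):
        model = PhenotypeModel(
            carrier_rise=0.0, noncarrier_rise=0.0, locus2_effect=0.5,
            residual_sd=0.0, group_offsets={},
        )
        m = self._matrix()
        recs = simulate_phenotypes(m, model, 0, 1, seed=1)
        dosage = m.dosage()
        for i, r in enumerate(recs):
            assert max(r.post_values) - r.baseline == pytest.approx(0.5 * dosage[i, 1])
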