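"""Genome, historical population and trait-architecture tests."""
import numpy as np
import pytest
from scipy import stats

from heterosim.config import GenomeConfig, TraitConfig, trait_config_for_model
from heterosim.errors import (ConfigurationError, ConvergenceError,
                              InsufficientPolymorphismError)
from heterosim.genome import (QTLEffects, build_genetic_map, compute_variances,
                              dominance_deviation_variance,
                              sample_architecture, sample_effects,
                              scale_effects, simulate_historical)


class TestConfigValidation:
    def test_degenerate_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            GenomeConfig(historical_size=0).validate()
        with pytest.raises(ConfigurationError):
            GenomeConfig(n_candidate_loci=100, n_snps_target=400,
                         n_qtl_target=40).validate()
        with pytest.raises(ConfigurationError):
            GenomeConfig(mutation_rate=1.5).validate()
        with pytest.raises(ConfigurationError):
            TraitConfig(h2=0.5, sigma2_d_target=0.6).validate()


class TestHistoricalPopulation:
    def test_map_layout(self, small_genome_cfg, rng):
        gmap = build_genetic_map(small_genome_cfg, rng)
        assert gmap.n_loci == small_genome_cfg.n_candidate_loci
        assert np.all(gmap.position >= 0)
        assert np.all(gmap.position <= small_genome_cfg.chromosome_length)
        for c in range(gmap.n_chromosomes):
            pos = gmap.position[gmap.chromosome == c]
            assert np.all(np.diff(pos) >= 0)

    def test_enough_polymorphic_loci(self, small_world, small_genome_cfg):
        """Mutation-drift balance keeps at least half the candidate loci
        above the architecture MAF threshold."""
        p = small_world.historical.allele_frequencies()
        maf = np.minimum(p, 1 - p)
        assert (maf > small_genome_cfg.maf_threshold_arch).sum() >= \
            small_genome_cfg.n_candidate_loci // 2

    def test_heterozygosity_drift_decay(self):
        """With mutation off, heterozygosity decays as (1 - 1/2N)^t."""
        cfg = GenomeConfig(n_chromosomes=2, n_snps_target=2, n_qtl_target=2,
                           n_candidate_loci=400, mutation_rate=0.0,
                           historical_size=50, historical_generations=60)
        rng = np.random.default_rng(11)
        hets = []
        for _ in range(24):
            panel, _ = simulate_historical(cfg, rng)
            hets.append(panel.mean_heterozygosity())
        n, t = cfg.historical_size, cfg.historical_generations
        # initial heterozygosity: E[2p(1-p)] = 1/3 for p ~ U(0,1)
        expected = (1 / 3) * (1 - 1 / (2 * n)) ** t
        se = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert abs(np.mean(hets) - expected) < 3 * se + 0.01

    def test_mendelian_identity_without_recombination(self, rng):
        """With one tiny chromosome (no crossovers expected ~ Poisson(1e-9))
        and no mutation, every offspring haplotype equals a parental one."""
        from heterosim.population import random_mating_generation
        cfg = GenomeConfig(n_chromosomes=1, chromosome_length=1e-9,
                           n_snps_target=1, n_qtl_target=1,
                           n_candidate_loci=50, mutation_rate=0.0,
                           historical_size=2, historical_generations=0)
        panel, gmap = simulate_historical(cfg, rng)
        child = random_mating_generation(panel, 10, gmap, rng)
        parental = panel.haplotypes.reshape(-1, 50)
        for hap in child.haplotypes.reshape(-1, 50):
            assert any(np.array_equal(hap, p) for p in parental)


class TestArchitecture:
    def test_counts_and_disjointness(self, small_world, small_genome_cfg):
        gmap = small_world.gmap
        assert gmap.snp_indices.size == small_genome_cfg.n_snps_target
        assert gmap.qtl_indices.size == small_genome_cfg.n_qtl_target
        assert np.intersect1d(gmap.snp_indices, gmap.qtl_indices).size == 0
        per = small_genome_cfg.n_snps_target // small_genome_cfg.n_chromosomes
        for c in range(gmap.n_chromosomes):
            assert (gmap.chromosome[gmap.snp_indices] == c).sum() == per

    def test_all_selected_loci_pass_maf(self, small_world, small_genome_cfg):
        p = small_world.historical.allele_frequencies()
        maf = np.minimum(p, 1 - p)
        chosen = np.concatenate([small_world.gmap.snp_indices,
                                 small_world.gmap.qtl_indices])
        assert np.all(maf[chosen] > small_genome_cfg.maf_threshold_arch)

    def test_insufficient_polymorphism_error(self, small_genome_cfg, rng):
        gmap = build_genetic_map(small_genome_cfg, rng)
        from heterosim.population import HaplotypePanel, _alternating_sexes
        n = 10
        haps = np.zeros((n, 2, gmap.n_loci), dtype=np.uint8)  # all fixed
        panel = HaplotypePanel(
            ids=np.arange(n), sire=np.full(n, -1), dam=np.full(n, -1),
            sex=_alternating_sexes(n), breed=np.full(n, -1, dtype=np.int8),
            generation=0, haplotypes=haps)
        with pytest.raises(InsufficientPolymorphismError, match="shortfall"):
            sample_architecture(panel, gmap, small_genome_cfg, rng)


class TestEffectSampling:
    def test_gamma_magnitude_and_overdominance_rate(self, rng):
        """|a| ~ gamma(0.4, 1.66): mean 0.664; pre-scaling P(|h|>1) ~ 0.375."""
        eff = sample_effects(200_000, 1, rng)
        assert np.mean(np.abs(eff.a)) == pytest.approx(0.4 * 1.66, rel=0.02)
        expected = (1 - stats.norm.cdf(1, 0.5, 1)) + stats.norm.cdf(-1, 0.5, 1)
        assert np.mean(np.abs(eff.h) > 1) == pytest.approx(expected, abs=0.01)

    def test_d_is_h_times_abs_a(self, rng):
        eff = sample_effects(1000, 1, rng)
        assert np.allclose(eff.d, eff.h * np.abs(eff.a))

    def test_model3_clamps_overdominance(self, rng):
        eff = sample_effects(5000, 3, rng)
        assert np.max(np.abs(eff.d) - np.abs(eff.a)) <= 1e-12

    def test_signs_are_random(self, rng):
        eff = sample_effects(10_000, 1, rng)
        assert np.mean(eff.a > 0) == pytest.approx(0.5, abs=0.02)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ConfigurationError):
            sample_effects(0, 1, rng)
        with pytest.raises(ConfigurationError):
            sample_effects(10, 4, rng)


class TestVariances:
    def test_single_locus_cases(self):
        # additive only at p = 0.5: sigma2_a = 2pq a^2 = 0.5
        va, vd = compute_variances(QTLEffects(a=np.array([1.0]),
                                              d=np.array([0.0])), np.array([0.5]))
        assert (va, vd) == (0.5, 0.0)
        # dominance only at p = 0.5: alpha = 0, sigma2_d = u(1-u) d^2 = 0.25
        va, vd = compute_variances(QTLEffects(a=np.array([0.0]),
                                              d=np.array([1.0])), np.array([0.5]))
        assert va == 0.0 and vd == pytest.approx(0.25)
        assert dominance_deviation_variance(
            QTLEffects(a=np.array([0.0]), d=np.array([1.0])),
            np.array([0.5])) == pytest.approx(0.25)

    def test_fixed_loci_contribute_nothing(self, rng):
        eff = sample_effects(20, 1, rng)
        p = rng.choice([0.0, 1.0], 20)
        assert compute_variances(eff, p) == (0.0, 0.0)

    def test_matches_empirical_decomposition(self, rng):
        """Closed forms equal the empirical variances of the breeding-value
        and dominance components in a large HWE population."""
        n, m = 100_000, 30
        eff = sample_effects(m, 1, rng)
        p = rng.uniform(0.1, 0.9, m)
        X = rng.binomial(2, p, (n, m)).astype(float)
        q = 1 - p
        alpha = eff.a + (q - p) * eff.d
        bv = (X - 2 * p) @ alpha
        dom = (X == 1).astype(float) @ eff.d
        va, vd = compute_variances(eff, p)
        assert np.var(bv) == pytest.approx(va, rel=0.03)
        assert np.var(dom) == pytest.approx(vd, rel=0.03)


class TestScaling:
    @pytest.mark.parametrize("model_id", [1, 2, 3])
    def test_targets_reached(self, small_world, model_id, rng):
        trait = trait_config_for_model(model_id)
        p = small_world.base_freqs
        eff = scale_effects(sample_effects(p.size, model_id, rng), p, trait)
        va, vd = compute_variances(eff, p)
        assert va == pytest.approx(trait.sigma2_a_target, abs=1e-3)
        assert vd == pytest.approx(trait.sigma2_d_target, abs=1e-3)
        if model_id == 3:
            assert np.all(np.abs(eff.d) <= np.abs(eff.a) + 1e-12)

    def test_idempotent(self, small_world, rng):
        trait = trait_config_for_model(1)
        p = small_world.base_freqs
        eff = scale_effects(sample_effects(p.size, 1, rng), p, trait)
        again = scale_effects(eff, p, trait)
        assert np.allclose(again.a, eff.a, rtol=1e-3)
        assert np.allclose(again.d, eff.d, rtol=1e-3)

    def test_pure_additive_trait(self, rng):
        trait = TraitConfig(sigma2_d_target=0.0)
        raw = sample_effects(50, 1, rng)
        raw = QTLEffects(a=raw.a, d=np.zeros(50), model_id=1)
        eff = scale_effects(raw, np.full(50, 0.3), trait)
        va, vd = compute_variances(eff, np.full(50, 0.3))
        assert va == pytest.approx(0.3, abs=1e-3)
        assert vd == 0.0

    def test_no_segregating_qtl_raises(self, rng):
        eff = sample_effects(10, 1, rng)
        with pytest.raises(ConvergenceError):
            scale_effects(eff, np.ones(10), trait_config_for_model(1))
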