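"""The synthetic experiment generator: founder structure, Wright-Fisher
dynamics, Pool-seq sampling noise and bioassay mortality."""

import numpy as np
import pandas as pd
import pytest

from acehap.haplotype_classes import nucleotide_diversity
from acehap.inference import expected_class_trajectories
from acehap.io_formats import HaplotypeMatrix
from acehap.synthetic import (
    CLASSES,
    SimConfig,
    cold_config,
    hot_config,
    simulate_bioassay,
    simulate_experiment,
    simulate_founder,
    simulate_poolseq,
    simulate_wf_trajectories,
)
from acehap.io_formats import ConfigurationError


class TestSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            cold_config(founder_class_freqs=(0.5, 0.5, 0.1))
        with pytest.raises(ConfigurationError):
            cold_config(class_fitness=(1.0, -0.2, 1.0))
        with pytest.raises(ConfigurationError):
            cold_config(sampled_generations=(5, 10))
        with pytest.raises(ConfigurationError):
            cold_config(sampled_generations=(0, 10, 10))

    def test_regime_defaults_mirror_study_design(self):
        hot, cold = hot_config(), cold_config()
        assert hot.sampled_generations == (0, 15, 37, 59)
        assert cold.sampled_generations == (0, 11, 21, 31, 41, 51)
        assert hot.selection_contrast == pytest.approx(-0.031)
        assert cold.selection_contrast == pytest.approx(-0.055)


class TestFounder:
    def test_zero_diversity_class1_identical_off_special_sites(self):
        cfg = cold_config(seed=3, within_class_pi=(0.0, 0.0082),
                          n_failed_crosses=0, n_recombinants=0)
        founder, truth = simulate_founder(cfg)
        special = set(truth.resistance_positions) | {truth.g368a_position}
        keep = ~founder.sites["pos"].isin(special).to_numpy()
        rows = [i for i, h in enumerate(founder.haplotype_ids)
                if truth.class_labels[h] in ("1a", "1b")]
        sub = founder.alleles[np.ix_(rows, np.flatnonzero(keep))]
        assert (sub == sub[0]).all()

    def test_marker_sites_fixed_different_between_archetypes(
            self, default_founder):
        founder, truth = default_founder
        pos = founder.site_positions()
        m = np.isin(pos, truth.marker_positions)
        by_class = {c: [i for i, h in enumerate(founder.haplotype_ids)
                        if truth.class_labels[h] == c] for c in CLASSES}
        a = founder.alleles
        assert (a[np.ix_(by_class["1a"] + by_class["1b"],
                         np.flatnonzero(m))] == 1).all()
        assert (a[np.ix_(by_class["2"], np.flatnonzero(m))] == 0).all()

    def test_diversity_ratio_near_twenty(self):
        ratios = []
        for seed in range(6):
            cfg = cold_config(seed=seed)
            founder, truth = simulate_founder(cfg)
            groups = {"1": ("1a", "1b"), "2": ("2",)}
            pis = {}
            for name, labels in groups.items():
                ids = [h for h, lab in truth.class_labels.items()
                       if lab in labels]
                pis[name] = nucleotide_diversity(
                    founder.subset_haplotypes(ids)).pi
            ratios.append(pis["2"] / pis["1"])
        # targets 0.0082 / 0.0004 = 20.5; allow Poisson sampling scatter
        assert 14 < np.mean(ratios) < 28

    def test_capacity_error(self):
        with pytest.raises(ConfigurationError):
            simulate_founder(cold_config(n_marker_snps=40_000))


class TestWrightFisher:
    def test_frequencies_sum_to_one_every_generation(self):
        cfg = cold_config(seed=5)
        paths = simulate_wf_trajectories(cfg)
        np.testing.assert_allclose(paths.sum(axis=2), 1.0, atol=1e-12)

    def test_neutral_large_ne_keeps_frequencies_constant(self):
        cfg = cold_config(seed=5, class_fitness=(1.0, 1.0, 1.0),
                          ne_per_replicate=(10_000_000,) * 5)
        paths = simulate_wf_trajectories(cfg)
        drift = np.abs(paths - paths[:, :1, :]).max()
        assert drift < 5e-3

    def test_deterministic_limit_matches_expected_recursion(self):
        cfg = cold_config(seed=5)
        paths = simulate_wf_trajectories(cfg, deterministic=True)
        s = tuple(w - 1 for w in cfg.class_fitness)
        expected = expected_class_trajectories(
            cfg.founder_class_freqs, s, cfg.h, max(cfg.sampled_generations))
        for r in range(cfg.n_replicates):
            np.testing.assert_allclose(paths[r], expected, atol=1e-12)

    def test_lost_class_stays_lost(self):
        cfg = cold_config(seed=5, founder_class_freqs=(0.0, 0.5, 0.5))
        paths = simulate_wf_trajectories(cfg)
        assert (paths[:, :, 0] == 0).all()

    def test_stochastic_mean_matches_deterministic_drop(self):
        """Averaged over many replicate populations, the resistance-class
        frequency drop equals the deterministic expectation."""
        cfg = cold_config(ne_per_replicate=(250,) * 5)
        t = max(cfg.sampled_generations)
        s = tuple(w - 1 for w in cfg.class_fitness)
        det_drop = (cfg.founder_class_freqs[0]
                    - expected_class_trajectories(
                        cfg.founder_class_freqs, s, cfg.h, t)[t, 0])
        drops = []
        for seed in range(40):  # 40 x 5 = 200 replicate populations
            paths = simulate_wf_trajectories(cold_config(
                seed=seed, ne_per_replicate=(250,) * 5))
            drops.append(paths[:, 0, 0] - paths[:, t, 0])
        mean_drop = np.mean(drops)
        mc_sem = np.std(drops) / np.sqrt(np.size(drops))
        assert abs(mean_drop - det_drop) < 4 * mc_sem + 0.005

    def test_seed_reproducibility(self):
        a = simulate_experiment(cold_config(seed=9))
        b = simulate_experiment(cold_config(seed=9))
        assert a.counts == b.counts
        np.testing.assert_array_equal(a.class_paths, b.class_paths)


def _uniform_freq_setup(p, n_sites):
    """Founder where only class 1a carries the alt allele, so every site
    has true frequency equal to the 1a class frequency."""
    from acehap.synthetic import SimTruth

    sites = pd.DataFrame({"chrom": "sim", "pos": np.arange(1, n_sites + 1),
                          "ref": "A", "alt": "C"})
    alleles = np.array([[1] * n_sites, [0] * n_sites, [0] * n_sites],
                       dtype=np.int8)
    founder = HaplotypeMatrix(sites, ["a", "b", "c"], alleles, L=n_sites)
    truth = SimTruth(regime="cold",
                     class_labels={"a": "1a", "b": "1b", "c": "2"},
                     class_fitness=(1.0, 1.0, 1.0), h=0.5,
                     ne_per_replicate=(250,), sampled_generations=(0, 1),
                     founder_class_freqs=(p, 0.3, 0.7 - p),
                     marker_positions=[], resistance_positions=[],
                     g368a_position=0, selection_contrast=0.0, seed=0)
    return founder, truth


class TestPoolseq:
    def test_two_stage_sampling_variance(self):
        """Empirical variance of observed minus true frequency matches
        p(1-p)(1/coverage + 1/pool_haplotypes) closely."""
        p = 0.3
        n_sites = 10_000
        founder, truth = _uniform_freq_setup(p, n_sites)
        cfg = cold_config(sampled_generations=(0, 1), n_replicates=1,
                          ne_per_replicate=(250,), mean_coverage=80,
                          pool_size=1000)
        paths = np.full((1, 2, 3), [[p, 0.3, 0.4]])
        table = simulate_poolseq(paths, founder, truth, cfg,
                                 rng=np.random.default_rng(77))
        obs = table.alt_freq[0]
        expected_var = p * (1 - p) * (1 / 80 + 1 / 2000)
        assert np.var(obs - p) == pytest.approx(expected_var, rel=0.10)

    def test_true_frequency_zero_gives_zero_alt_counts(self):
        founder, truth = _uniform_freq_setup(0.0, 50)
        cfg = cold_config(sampled_generations=(0, 1), n_replicates=1,
                          ne_per_replicate=(250,))
        paths = np.full((1, 2, 3), [[0.0, 0.5, 0.5]])
        table = simulate_poolseq(paths, founder, truth, cfg,
                                 rng=np.random.default_rng(1))
        assert (table.alt_counts == 0).all()

    def test_high_coverage_limit_recovers_true_frequencies(self):
        p = 0.42
        founder, truth = _uniform_freq_setup(p, 200)
        cfg = cold_config(sampled_generations=(0, 1), n_replicates=1,
                          ne_per_replicate=(250,), mean_coverage=2e5,
                          pool_size=1_000_000)
        paths = np.full((1, 2, 3), [[p, 0.3, 0.28]])
        table = simulate_poolseq(paths, founder, truth, cfg,
                                 rng=np.random.default_rng(3))
        rmse = np.sqrt(np.mean((table.alt_freq - p) ** 2))
        assert rmse < 5e-3


class TestBioassay:
    def test_mortality_half_at_ld50(self):
        records = simulate_bioassay(10.0, 2.0, [10.0], n_per_vial=30,
                                    n_vials=400, seed=5)
        mortality = np.mean([r.mortality for r in records])
        assert mortality == pytest.approx(0.5, abs=0.02)

    def test_steep_slope_approaches_step_function(self):
        records = simulate_bioassay(10.0, 1e6, [5.0, 20.0], n_per_vial=30,
                                    n_vials=10, seed=5)
        by_dose = {}
        for r in records:
            by_dose.setdefault(r.dose, []).append(r.mortality)
        assert np.mean(by_dose[5.0]) == 0.0
        assert np.mean(by_dose[20.0]) == 1.0

    def test_dose_zero_is_control(self):
        records = simulate_bioassay(10.0, 2.0, [0.0], n_vials=5, seed=5)
        assert all(r.n_dead == 0 for r in records)

    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            simulate_bioassay(-1.0, 2.0, [1.0])
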