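"""Selection fitting, temporal Ne and CMH scans."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable

from acehap.inference import (
    SelectionFit,
    cmh_scan,
    estimate_ne,
    estimate_s,
    estimate_s_joint,
    expected_class_trajectories,
    expected_trajectory,
    resistance_cost,
)
from acehap.io_formats import AlleleCountTable, InsufficientDataError, \
    SampleInfo
from acehap.synthetic import simulate_neutral_sites


class TestExpectedTrajectory:
    def test_neutral_path_is_constant(self):
        np.testing.assert_allclose(expected_trajectory(0.3, 0.0, 0.5, 20),
                                   0.3)

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_boundaries_are_absorbing(self, p0):
        np.testing.assert_allclose(expected_trajectory(p0, 0.2, 0.5, 20),
                                   p0)

    def test_logit_slope_approximates_s_over_two_at_codominance(self):
        s, t = 0.01, 50
        path = expected_trajectory(0.5, s, 0.5, t)
        dlogit = np.log(path[-1] / (1 - path[-1])) - np.log(1.0)
        assert dlogit / t == pytest.approx(s / 2, rel=0.02)

    @pytest.mark.parametrize("s,h", [(0.1, 0.0), (0.1, 0.5), (0.1, 1.0),
                                     (-0.1, 0.5), (-0.3, 1.0)])
    def test_stays_in_unit_interval_and_monotone(self, s, h):
        path = expected_trajectory(0.4, s, h, 100)
        assert (path >= 0).all() and (path <= 1).all()
        diffs = np.diff(path)
        assert (diffs >= -1e-15).all() if s > 0 else (diffs <= 1e-15).all()

    def test_multiclass_recursion_reduces_to_biallelic(self):
        two = expected_class_trajectories([0.3, 0.7], [0.08, 0.0], 0.5, 40)
        one = expected_trajectory(0.3, 0.08, 0.5, 40)
        np.testing.assert_allclose(two[:, 0], one, atol=1e-14)


class TestEstimateS:
    def test_self_inverse_on_deterministic_data(self):
        gens = np.arange(0, 51, 10)
        path = expected_trajectory(0.5, 0.05, 0.5, 50)[gens]
        fit = estimate_s(gens, path)
        assert fit.s == pytest.approx(0.05, abs=1e-6)
        assert fit.p0 == pytest.approx(0.5, abs=1e-6)

    def test_constant_trajectory_gives_zero_s(self):
        fit = estimate_s([0, 10, 20, 30, 40], [0.4] * 5)
        assert fit.s == pytest.approx(0.0, abs=1e-8)

    def test_allele_relabelling_equivariance(self):
        """Relabelling the focal allele (p -> 1-p) inverts the relative
        fitness: exactly 1 + s' = 1/(1 + s), which is a sign flip up to
        O(s^2)."""
        rng = np.random.default_rng(4)
        gens = np.array([0, 11, 21, 31, 41, 51])
        path = expected_trajectory(0.6, -0.07, 0.5, 51)[gens]
        noisy = np.clip(path + rng.normal(0, 0.01, size=len(gens)), 0, 1)
        s_focal = estimate_s(gens, noisy).s
        s_flip = estimate_s(gens, 1 - noisy).s
        assert 1 + s_flip == pytest.approx(1 / (1 + s_focal), abs=1e-6)
        assert s_flip == pytest.approx(-s_focal, abs=abs(s_focal) ** 2 * 1.5)

    def test_fixed_trajectory_is_uninformative(self):
        with pytest.raises(InsufficientDataError):
            estimate_s([0, 10, 20], [0.0, 0.0, 0.0])

    def test_joint_fit_recovers_all_coefficients_exactly(self):
        gens = np.array([0, 11, 21, 31, 41, 51])
        truth_s = (-0.055, 0.0, 0.0935)
        paths = expected_class_trajectories((0.59, 0.25, 0.16), truth_s,
                                            0.5, 51)
        fit = estimate_s_joint(gens, paths[gens])
        assert fit.s["1a"] == pytest.approx(-0.055, abs=1e-6)
        assert fit.s["2"] == pytest.approx(0.0935, abs=1e-6)
        assert fit.contrast() == pytest.approx(-0.055, abs=1e-6)


class TestResistanceCost:
    def test_contrast_arithmetic(self):
        fits = [SelectionFit("R1", "1a", -0.02, 0.5, 250, 0.5, 0.0, (0, 51),
                             2),
                SelectionFit("R1", "1b", 0.01, 0.5, 250, 0.5, 0.0, (0, 51),
                             2)]
        contrasts, summary = resistance_cost(fits)
        assert contrasts.iloc[0]["contrast"] == pytest.approx(-0.03)
        assert summary["mean"] == pytest.approx(-0.03)

    def test_identical_fits_give_zero_contrast(self):
        fits = [SelectionFit("R1", lab, -0.02, 0.5, 250, 0.5, 0.0, (0, 51), 2)
                for lab in ("1a", "1b")]
        contrasts, _ = resistance_cost(fits)
        assert contrasts.iloc[0]["contrast"] == 0.0

    def test_incomplete_replicate_excluded(self):
        fits = [SelectionFit("R1", "1a", -0.02, 0.5, 250, 0.5, 0.0, (0, 51),
                             2),
                SelectionFit("R1", "1b", 0.01, 0.5, 250, 0.5, 0.0, (0, 51),
                             2),
                SelectionFit("R2", "1a", -0.05, 0.5, 250, 0.5, 0.0, (0, 51),
                             2)]
        contrasts, summary = resistance_cost(fits)
        assert contrasts["replicate"].tolist() == ["R1"]
        assert summary["n_replicates"] == 1


class TestEstimateNe:
    def test_no_change_gives_infinite_ne_flagged(self):
        x = np.full(100, 0.5)
        est = estimate_ne(x, x, t=10, pool_haplotypes_0=2000,
                          pool_haplotypes_t=2000, coverage_0=80,
                          coverage_t=80)
        assert np.isinf(est.ne) and est.flagged

    def test_monomorphic_input_is_an_error(self):
        zeros = np.zeros(100)
        with pytest.raises(InsufficientDataError):
            estimate_ne(zeros, zeros, t=10, pool_haplotypes_0=2000,
                        pool_haplotypes_t=2000, coverage_0=80,
                        coverage_t=80)

    def test_time_span_scaling_is_consistent(self):
        """Estimates at t and 2t of the same process agree (F accumulates
        linearly in t at these scales)."""
        from acehap.inference import estimate_ne_from_table

        ne_t, ne_2t = [], []
        for seed in range(20):
            tab1 = simulate_neutral_sites(800, 1, 250, 10, seed=seed)
            tab2 = simulate_neutral_sites(800, 1, 250, 20, seed=1000 + seed)
            ne_t.append(estimate_ne_from_table(tab1, "R1", 0, 10).ne)
            ne_2t.append(estimate_ne_from_table(tab2, "R1", 0, 20).ne)
        ratio = np.median(ne_2t) / np.median(ne_t)
        assert ratio == pytest.approx(1.0, abs=0.25)


def _two_point_table(counts_by_rep):
    """counts_by_rep: list of ((alt0, ref0), (altt, reft)) per replicate,
    single site."""
    samples, rows = [], []
    for k, ((a0, b0), (at, bt)) in enumerate(counts_by_rep):
        samples += [SampleInfo(f"R{k + 1}", 0, "x"),
                    SampleInfo(f"R{k + 1}", 51, "x")]
        rows += [[a0, 0, b0, 0, 0, 0], [at, 0, bt, 0, 0, 0]]
    counts = np.asarray(rows)[:, None, :]
    sites = pd.DataFrame({"chrom": ["3R"], "pos": [1],
                          "ref": ["C"], "alt": ["A"]})
    return AlleleCountTable(sites, samples, counts)


class TestCmh:
    def test_classic_matches_statsmodels_stratified_table(self):
        """Independent oracle: statsmodels' CMH chi-square on the same
        2x2xK tables (no continuity correction)."""
        cases = [
            [((60, 40), (40, 60))],
            [((60, 40), (40, 60))] * 5,
            [((10, 90), (30, 70)), ((20, 80), (25, 75)),
             ((50, 50), (55, 45))],
        ]
        for counts_by_rep in cases:
            table = _two_point_table(counts_by_rep)
            pairs = {f"R{k + 1}": (0, 51)
                     for k in range(len(counts_by_rep))}
            scan = cmh_scan(table, pairs, adjusted=False)
            tables = [np.array([[a0, b0], [at, bt]])
                      for (a0, b0), (at, bt) in counts_by_rep]
            oracle = StratifiedTable(tables).test_null_odds(correction=False)
            assert scan.iloc[0]["statistic"] == pytest.approx(
                oracle.statistic, abs=1e-10)
            assert scan.iloc[0]["pvalue"] == pytest.approx(oracle.pvalue,
                                                           abs=1e-10)

    def test_no_change_gives_zero_statistic_p_one(self):
        table = _two_point_table([((30, 70), (30, 70))] * 3)
        pairs = {f"R{k}": (0, 51) for k in ("1", "2", "3")}
        ne = {f"R{k}": 250.0 for k in ("1", "2", "3")}
        for adjusted in (False, True):
            scan = cmh_scan(table, pairs, ne=ne, adjusted=adjusted)
            assert scan.iloc[0]["statistic"] == pytest.approx(0.0, abs=1e-12)
            assert scan.iloc[0]["pvalue"] == 1.0

    def test_zero_coverage_site_reported_na_with_reason(self):
        table = _two_point_table([((0, 0), (30, 70))])
        scan = cmh_scan(table, {"R1": (0, 51)}, adjusted=False)
        assert np.isnan(scan.iloc[0]["statistic"])
        assert scan.iloc[0]["reason"] == "insufficient coverage"

    def test_adjusted_needs_ne(self):
        table = _two_point_table([((30, 70), (30, 70))])
        with pytest.raises(ValueError):
            cmh_scan(table, {"R1": (0, 51)}, adjusted=True)

    def test_adjusted_pvalues_uniform_under_neutral_null(self):
        table = simulate_neutral_sites(1000, 5, 250, 51, seed=3)
        pairs = {f"R{r + 1}": (0, 51) for r in range(5)}
        ne = {rep: 250.0 for rep in pairs}
        scan = cmh_scan(table, pairs, ne=ne, adjusted=True)
        from scipy.stats import kstest
        ks = kstest(scan["pvalue"].dropna(), "uniform").statistic
        assert ks < 0.05

    def test_benjamini_hochberg_column_optional(self):
        table = simulate_neutral_sites(50, 2, 250, 10, seed=0)
        pairs = {"R1": (0, 10), "R2": (0, 10)}
        scan = cmh_scan(table, pairs, adjusted=False)
        assert "q_bh" not in scan.columns
        scan_bh = cmh_scan(table, pairs, adjusted=False, bh_column=True)
        assert (scan_bh["q_bh"].dropna() >= scan_bh["pvalue"].dropna()
                - 1e-12).all()


class TestHaplotypeVersusSnpSignal:
    def test_shared_class1_markers_outrank_resistance_sites(
            self, default_experiment):
        """When the diverse susceptible class is fittest, SNPs shared by
        both class-1 subgroups show stronger frequency change than the
        resistance triple itself: the SNP-level scan points away from
        the true selection target."""
        exp = default_experiment
        cfg = exp.config
        pairs = {f"R{r + 1}": (0, cfg.sampled_generations[-1])
                 for r in range(cfg.n_replicates)}
        ne = {f"R{r + 1}": float(cfg.ne_per_replicate[r])
              for r in range(cfg.n_replicates)}
        scan = cmh_scan(exp.counts, pairs, ne=ne, adjusted=True,
                        pool_haplotypes=cfg.pool_haplotypes)
        marker_p = scan[scan["pos"].isin(exp.truth.marker_positions)]
        res_p = scan[scan["pos"].isin(exp.truth.resistance_positions)]
        assert (np.median(marker_p["neglog10_p"])
                > np.median(res_p["neglog10_p"]))
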