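"""End-to-end pipeline runs and calibration experiments on synthetic data.

These functions tie the stages together (simulate -> class calling ->
marker trajectories -> selection fitting) and measure how well the
estimators recover known truth: bias of the fitted s_1a - s_1b contrast,
type-I error of the CMH variants under pure drift, calibration of the
temporal Ne estimator, and coverage of the probit LD50 interval.  They
power both the test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from acehap.dose_response import fit_probit
from acehap.haplotype_classes import (
    ClassAssignment,
    MarkerSet,
    call_haplotype_classes,
    diversity_by_class,
    find_marker_snps,
)
from acehap.inference import (
    cmh_scan,
    estimate_ne_from_table,
    fit_class_selection,
    fit_class_selection_joint,
    resistance_cost,
    resistance_cost_joint,
)
from acehap.synthetic import (
    SimConfig,
    SimExperiment,
    cold_config,
    simulate_bioassay,
    simulate_experiment,
    simulate_neutral_sites,
)
from acehap.trajectories import ClassTrajectorySet, class_frequencies, filter_snps


def resistance_site_frame(sites: pd.DataFrame,
                          positions: list[int]) -> pd.DataFrame:
    """chrom/pos/resistance_nuc rows for the resistance triple; the
    resistance allele is the alternative allele at those sites."""
    sel = sites[sites["pos"].isin(positions)]
    return pd.DataFrame({"chrom": sel["chrom"], "pos": sel["pos"],
                         "resistance_nuc": sel["alt"]})


@dataclasses.dataclass
class PipelineResult:
    """Everything one synthetic experiment yields downstream."""

    experiment: SimExperiment
    assignment: ClassAssignment
    markers: MarkerSet
    diversity: pd.DataFrame
    trajectories: ClassTrajectorySet
    fits: list
    joint_fits: list
    contrasts: pd.DataFrame  # joint-fit contrasts (headline)
    contrast_summary: pd.Series
    marginal_contrasts: pd.DataFrame  # per-class marginal fits, subtracted
    marginal_summary: pd.Series
    ne_estimates: pd.DataFrame


def run_pipeline(config: SimConfig, min_coverage: int = 10,
                 estimate_ne: bool = False) -> PipelineResult:
    """Simulate one experiment and run the full downstream analysis.

    The headline resistance-cost contrast comes from the joint
    multi-class fit; the per-class marginal fits and their subtracted
    contrast are computed alongside for comparison.
    """
    exp = simulate_experiment(config)
    assignment = call_haplotype_classes(exp.founder,
                                        exp.truth.resistance_positions)
    markers = find_marker_snps(exp.founder, assignment)
    diversity = diversity_by_class(exp.founder, assignment)
    filtered, _ = filter_snps(exp.counts, min_mac=5,
                              min_coverage=min_coverage)
    res_sites = resistance_site_frame(exp.founder.sites,
                                      exp.truth.resistance_positions)
    traj = class_frequencies(filtered, markers, res_sites)
    ne_map = {f"R{r + 1}": float(config.ne_per_replicate[r])
              for r in range(config.n_replicates)}
    ne_rows = []
    if estimate_ne:
        g0, gt = config.sampled_generations[0], config.sampled_generations[-1]
        for rep in sorted(ne_map):
            est = estimate_ne_from_table(
                filtered, rep, g0, gt,
                pool_haplotypes=config.pool_haplotypes)
            ne_rows.append(dataclasses.asdict(est))
    fits = fit_class_selection(traj, ne=ne_map,
                               pool_haplotypes=config.pool_haplotypes)
    joint_fits = fit_class_selection_joint(
        traj, pool_haplotypes=config.pool_haplotypes)
    contrasts, summary = resistance_cost_joint(joint_fits)
    marg_contrasts, marg_summary = resistance_cost(fits)
    return PipelineResult(exp, assignment, markers, diversity, traj, fits,
                          joint_fits, contrasts, summary, marg_contrasts,
                          marg_summary, pd.DataFrame(ne_rows))


# ---------------------------------------------------------------------------
# recovery of the selection contrast


def recovery_experiment(n_seeds: int = 200, seed: int = 0,
                        **config_overrides) -> pd.DataFrame:
    """Full-pipeline recovery of the s_1a - s_1b contrast over many seeds.

    Defaults to the cold-regime scenario with a flat Ne of 250 per
    replicate.  Returns one row per seed with the estimated
    mean-across-replicates contrast and the truth.
    """
    overrides = dict(ne_per_replicate=(250,) * 5)
    overrides.update(config_overrides)
    rows = []
    for i in range(n_seeds):
        config = cold_config(seed=seed * 100_003 + i, **overrides)
        result = run_pipeline(config)
        rows.append({
            "seed": config.seed,
            "estimated_contrast": result.contrast_summary["mean"],
            "true_contrast": config.selection_contrast,
            "error": (result.contrast_summary["mean"]
                      - config.selection_contrast),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CMH calibration under the neutral null


def cmh_calibration(n_sites: int = 1000, n_replicates: int = 5,
                    ne: int = 250, t: int = 51, mean_coverage: float = 80.0,
                    pool_haplotypes: int = 2000, alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Empirical type-I error of the classic and drift-adjusted CMH tests
    on independent neutral SNPs, plus the KS distance of the adjusted
    p-values from uniformity."""
    table = simulate_neutral_sites(n_sites, n_replicates, ne, t,
                                   mean_coverage=mean_coverage,
                                   pool_haplotypes=pool_haplotypes,
                                   seed=seed)
    pairs = {f"R{r + 1}": (0, t) for r in range(n_replicates)}
    ne_map = {rep: float(ne) for rep in pairs}
    adj = cmh_scan(table, pairs, ne=ne_map, adjusted=True,
                   pool_haplotypes=pool_haplotypes)
    cls = cmh_scan(table, pairs, adjusted=False)
    p_adj = adj["pvalue"].dropna().to_numpy()
    p_cls = cls["pvalue"].dropna().to_numpy()
    from scipy.stats import kstest
    ks = kstest(p_adj, "uniform").statistic
    return {
        "alpha": alpha,
        "n_sites": n_sites,
        "adjusted_type1": float((p_adj < alpha).mean()),
        "classic_type1": float((p_cls < alpha).mean()),
        "adjusted_ks_uniform": float(ks),
    }


# ---------------------------------------------------------------------------
# Ne estimator calibration


def ne_calibration(n_seeds: int = 200, true_ne: int = 250,
                   n_snps: int = 1000, t: int = 15,
                   mean_coverage: float = 80.0, pool_haplotypes: int = 2000,
                   seed: int = 0) -> pd.DataFrame:
    """Distribution of the temporal Ne estimate over replicate neutral
    simulations with known true Ne."""
    rows = []
    for i in range(n_seeds):
        table = simulate_neutral_sites(n_snps, 1, true_ne, t,
                                       mean_coverage=mean_coverage,
                                       pool_haplotypes=pool_haplotypes,
                                       seed=seed * 100_003 + i)
        est = estimate_ne_from_table(table, "R1", 0, t,
                                     pool_haplotypes=pool_haplotypes)
        rows.append({"seed": i, "ne_hat": est.ne, "true_ne": true_ne,
                     "f_raw": est.f_raw, "f_corrected": est.f_corrected})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probit LD50 coverage


def probit_coverage_experiment(n_seeds: int = 200, ld50: float = 19.5,
                               slope: float = 2.0,
                               doses: tuple = (1, 2, 10, 20, 60, 90),
                               n_per_vial: int = 30, n_vials: int = 4,
                               seed: int = 0) -> pd.DataFrame:
    """Does the 95% LD50 interval cover the generating LD50?"""
    rows = []
    for i in range(n_seeds):
        records = simulate_bioassay(ld50, slope, doses,
                                    n_per_vial=n_per_vial, n_vials=n_vials,
                                    seed=seed * 100_003 + i)
        fit = fit_probit(records)
        lo, hi = fit.ld50_ci
        rows.append({"seed": i, "ld50_hat": fit.ld50,
                     "ci_low": lo, "ci_high": hi,
                     "covered": bool(lo <= ld50 <= hi),
                     "converged": fit.converged})
    return pd.DataFrame(rows)
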