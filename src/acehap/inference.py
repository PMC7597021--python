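"""Selection, effective population size and drift-aware CMH inference.

Selection coefficients are fitted per replicate by least squares between
an observed allele (or haplotype-class) frequency trajectory and the
deterministic diploid Wright-Fisher expectation under co-dominance
(h = 0.5 unless stated otherwise); the per-generation cost of the
resistance triple is the contrast s_1a - s_1b.  Temporal Ne comes from
the standardized variance F of allele-frequency change corrected for the
two-stage Pool-seq sampling noise.  SNP-wise tests use either the
classic Cochran-Mantel-Haenszel statistic over replicate 2x2 tables or a
drift-aware score statistic whose null variance includes drift and
Pool-seq sampling terms.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2

from acehap.io_formats import AlleleCountTable, InsufficientDataError
from acehap.trajectories import ClassTrajectorySet

logger = logging.getLogger("acehap")


# ---------------------------------------------------------------------------
# deterministic Wright-Fisher expectation


def expected_trajectory(p0: float, s: float, h: float, t: int) -> np.ndarray:
    """Deterministic diploid selection recursion, length t + 1.

    Each generation  p' = p (p w_AA + q w_Aa) / w_bar  with genotype
    fitness w_AA = 1 + s, w_Aa = 1 + h s, w_aa = 1 and q = 1 - p.
    p0 in {0, 1} is absorbing; s = 0 gives a constant path.
    """
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be in [0, 1]")
    if 1 + s <= 0 or 1 + h * s <= 0:
        raise ValueError("fitnesses 1+s and 1+hs must be positive")
    path = np.empty(t + 1)
    p = float(p0)
    path[0] = p
    for g in range(1, t + 1):
        q = 1.0 - p
        num = p * (p * (1 + s) + q * (1 + h * s))
        wbar = p * p * (1 + s) + 2 * p * q * (1 + h * s) + q * q
        p = num / wbar
        path[g] = p
    return path


def genotype_fitness(class_fitness: Sequence[float], h: float) -> np.ndarray:
    """Diploid genotype fitness for haplotype classes as alleles of one
    locus: 1 + s_i for homozygotes, 1 + h (s_i + s_j) for heterozygotes
    (co-dominance at h = 0.5)."""
    s = np.asarray(class_fitness, dtype=float) - 1.0
    w = 1.0 + h * (s[:, None] + s[None, :])
    np.fill_diagonal(w, 1.0 + s)
    return w


def selection_step(freqs: np.ndarray, class_fitness: Sequence[float],
                   h: float) -> np.ndarray:
    """One deterministic generation of viability selection on class
    frequencies: p_i' = p_i (sum_j p_j w_ij) / w_bar."""
    p = np.asarray(freqs, dtype=float)
    w = genotype_fitness(class_fitness, h)
    marginal = w @ p
    return p * marginal / (p @ marginal)


def expected_class_trajectories(p0: Sequence[float], s: Sequence[float],
                                h: float, t: int) -> np.ndarray:
    """Deterministic multi-class generalisation of
    :func:`expected_trajectory`; returns shape (t + 1, K).  For two
    classes with s = (s, 0) the first column equals the biallelic
    recursion."""
    p = np.asarray(p0, dtype=float)
    fitness = 1.0 + np.asarray(s, dtype=float)
    out = np.empty((t + 1, len(p)))
    out[0] = p
    for g in range(1, t + 1):
        p = selection_step(p, fitness, h)
        out[g] = p
    return out


# ---------------------------------------------------------------------------
# selection-coefficient fitting


@dataclasses.dataclass
class SelectionFit:
    """A fitted per-generation selection coefficient for one trajectory."""

    replicate: str
    label: str
    s: float
    h: float
    ne: float | None
    p0: float
    rss: float
    generations: tuple[int, ...]
    n_points: int


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def estimate_s(generations: Sequence[int], frequencies: Sequence[float],
               h: float = 0.5, ne: float | None = None,
               pool_haplotypes: int = 2000,
               s_bounds: tuple[float, float] = (-0.5, 0.5),
               replicate: str = "", label: str = "") -> SelectionFit:
    """Least-squares fit of (p0, s) to an observed frequency trajectory.

    The objective is the sum of squared deviations on the frequency scale
    between the observations and :func:`expected_trajectory`; s is
    searched within ``s_bounds`` and p0 is co-estimated.  Frequencies
    exactly at 0 or 1 are replaced by the pseudo-frequency
    ``1 / (2 * pool_haplotypes)`` (respectively its complement).  The
    starting value of s is the slope of logit frequency per generation
    divided by 2h; drift at Ne is not part of the objective (the fit is
    to the deterministic expectation), Ne is carried as metadata.
    """
    gens = np.asarray(generations, dtype=int)
    f = np.asarray(frequencies, dtype=float)
    if len(gens) != len(f):
        raise ValueError("generations and frequencies differ in length")
    finite = np.isfinite(f)
    gens, f = gens[finite], f[finite]
    if len(gens) < 2:
        raise InsufficientDataError("need >= 2 (generation, frequency) pairs")
    if np.any(np.diff(gens) <= 0):
        raise ValueError("generations must strictly increase")
    eps = 1.0 / (2 * pool_haplotypes)
    if np.all(f <= 0) or np.all(f >= 1):
        raise InsufficientDataError(
            "trajectory fixed at a boundary: no information about s")
    f = np.clip(f, eps, 1 - eps)

    t_max = int(gens[-1])
    slope = np.polyfit(gens, _logit(f), 1)[0]
    s0 = float(np.clip(slope / (2 * h) if h > 0 else slope,
                       s_bounds[0] + 1e-9, s_bounds[1] - 1e-9))
    p0_init = float(np.clip(f[0], eps, 1 - eps))

    def residuals(theta: np.ndarray) -> np.ndarray:
        p0, s = theta
        return expected_trajectory(p0, s, h, t_max)[gens] - f

    fit = least_squares(
        residuals, x0=[p0_init, s0],
        bounds=([eps, s_bounds[0]], [1 - eps, s_bounds[1]]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    p0_hat, s_hat = fit.x
    return SelectionFit(replicate=replicate, label=label, s=float(s_hat),
                        h=h, ne=ne, p0=float(p0_hat),
                        rss=float(np.sum(fit.fun ** 2)),
                        generations=tuple(int(g) for g in gens),
                        n_points=len(gens))


def fit_class_selection(trajectories: ClassTrajectorySet,
                        ne: Mapping[str, float] | None = None,
                        h: float = 0.5, pool_haplotypes: int = 2000,
                        classes: Sequence[str] = ("1a", "1b", "2"),
                        endpoints_only: bool = False) -> list[SelectionFit]:
    """Fit s for each haplotype class in each replicate.

    Uses all sampled generations by default; ``endpoints_only`` restricts
    the fit to the first and last time point.
    """
    fits = []
    for rep, sub in trajectories.table.groupby("replicate", sort=True):
        sub = sub.sort_values("generation")
        if endpoints_only:
            sub = sub.iloc[[0, -1]]
        for cls in classes:
            fits.append(estimate_s(
                sub["generation"].to_numpy(), sub[f"f_{cls}"].to_numpy(),
                h=h, ne=None if ne is None else ne.get(rep),
                pool_haplotypes=pool_haplotypes,
                replicate=str(rep), label=cls))
    return fits


@dataclasses.dataclass
class JointSelectionFit:
    """Selection coefficients of all haplotype classes fitted jointly.

    ``s`` maps class label to its selection coefficient relative to the
    reference class (which has s = 0); pairwise contrasts such as
    s_1a - s_1b are invariant to the choice of reference.
    """

    replicate: str
    s: dict[str, float]
    h: float
    p0: dict[str, float]
    rss: float
    generations: tuple[int, ...]

    def contrast(self, a: str = "1a", b: str = "1b") -> float:
        return self.s[a] - self.s[b]


def estimate_s_joint(generations: Sequence[int], frequencies: np.ndarray,
                     labels: Sequence[str] = ("1a", "1b", "2"),
                     reference: str = "1b", h: float = 0.5,
                     pool_haplotypes: int = 2000,
                     s_bounds: tuple[float, float] = (-0.5, 0.5),
                     replicate: str = "") -> JointSelectionFit:
    """Fit the co-dominant multi-class WF model to all class trajectories
    of one replicate at once.

    Unlike fitting each class marginally against a pooled "rest" (whose
    composition, and hence mean fitness, changes over the experiment —
    a known source of bias for pairwise contrasts when a third class is
    strongly selected), the joint fit estimates one selection
    coefficient per class, anchored at ``reference`` = 0, together with
    the founder composition, by least squares over the full
    (generation x class) frequency matrix.
    """
    gens = np.asarray(generations, dtype=int)
    f = np.asarray(frequencies, dtype=float)  # (n_gens, K)
    k = f.shape[1]
    if len(labels) != k or reference not in labels:
        raise ValueError("labels must match columns and contain the reference")
    if f.shape[0] != len(gens) or len(gens) < 2:
        raise InsufficientDataError("need >= 2 sampled generations")
    eps = 1.0 / (2 * pool_haplotypes)
    f = np.clip(f, eps, 1 - eps)
    ref_i = list(labels).index(reference)
    free = [i for i in range(k) if i != ref_i]
    t_max = int(gens[-1])

    # d log(p_i / p_ref) / dt ~ 2h (s_i - s_ref) at small s
    logratio = np.log(f[:, free] / f[:, [ref_i]])
    s_init = np.clip(np.polyfit(gens, logratio, 1)[0] / (2 * h),
                     s_bounds[0] + 1e-9, s_bounds[1] - 1e-9)
    p0_obs = np.clip(f[0], eps, None)
    z_init = np.log(p0_obs[free] / p0_obs[ref_i])

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s_free, z = theta[:k - 1], theta[k - 1:]
        s = np.zeros(k)
        s[free] = s_free
        expz = np.ones(k)
        expz[free] = np.exp(z)
        return s, expz / expz.sum()

    def residuals(theta: np.ndarray) -> np.ndarray:
        s, p0 = unpack(theta)
        path = expected_class_trajectories(p0, s, h, t_max)[gens]
        return (path - f).ravel()

    lb = np.concatenate([np.full(k - 1, s_bounds[0]), np.full(k - 1, -30.0)])
    ub = np.concatenate([np.full(k - 1, s_bounds[1]), np.full(k - 1, 30.0)])
    fit = least_squares(residuals, x0=np.concatenate([s_init, z_init]),
                        bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    s_hat, p0_hat = unpack(fit.x)
    return JointSelectionFit(
        replicate=replicate,
        s={lab: float(s_hat[i]) for i, lab in enumerate(labels)},
        h=h,
        p0={lab: float(p0_hat[i]) for i, lab in enumerate(labels)},
        rss=float(np.sum(fit.fun ** 2)),
        generations=tuple(int(g) for g in gens))


def fit_class_selection_joint(trajectories: ClassTrajectorySet,
                              h: float = 0.5, pool_haplotypes: int = 2000,
                              classes: Sequence[str] = ("1a", "1b", "2"),
                              reference: str = "1b"
                              ) -> list[JointSelectionFit]:
    """Joint multi-class fit for every replicate of a trajectory set."""
    fits = []
    for rep, sub in trajectories.table.groupby("replicate", sort=True):
        sub = sub.sort_values("generation")
        freqs = sub[[f"f_{c}" for c in classes]].to_numpy()
        fits.append(estimate_s_joint(
            sub["generation"].to_numpy(), freqs, labels=classes,
            reference=reference, h=h, pool_haplotypes=pool_haplotypes,
            replicate=str(rep)))
    return fits


def resistance_cost_joint(fits: Sequence[JointSelectionFit]
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-replicate s_1a - s_1b contrast from joint fits, with the
    across-replicate mean and SEM."""
    rows = [{"replicate": fit.replicate, "s_1a": fit.s["1a"],
             "s_1b": fit.s["1b"], "contrast": fit.contrast()}
            for fit in sorted(fits, key=lambda f: f.replicate)]
    contrasts = pd.DataFrame(rows, columns=["replicate", "s_1a", "s_1b",
                                            "contrast"])
    values = contrasts["contrast"].to_numpy()
    summary = pd.Series({
        "mean": values.mean() if len(values) else np.nan,
        "sem": (values.std(ddof=1) / np.sqrt(len(values))
                if len(values) > 1 else np.nan),
        "n_replicates": len(values),
    })
    return contrasts, summary


def resistance_cost(fits: Sequence[SelectionFit]
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-replicate contrast s_1a - s_1b and its across-replicate summary.

    Replicates missing either fit are excluded with a warning.  Returns
    the contrast table and a summary with the mean, the standard error of
    the mean and the replicate count.
    """
    by_rep: dict[str, dict[str, float]] = {}
    for fit in fits:
        if fit.label in ("1a", "1b"):
            by_rep.setdefault(fit.replicate, {})[fit.label] = fit.s
    rows = []
    for rep, d in sorted(by_rep.items()):
        if "1a" not in d or "1b" not in d:
            logger.warning("replicate %s lacks a 1a or 1b fit; excluded", rep)
            continue
        rows.append({"replicate": rep, "s_1a": d["1a"], "s_1b": d["1b"],
                     "contrast": d["1a"] - d["1b"]})
    contrasts = pd.DataFrame(rows, columns=["replicate", "s_1a", "s_1b",
                                            "contrast"])
    values = contrasts["contrast"].to_numpy()
    summary = pd.Series({
        "mean": values.mean() if len(values) else np.nan,
        "sem": (values.std(ddof=1) / np.sqrt(len(values))
                if len(values) > 1 else np.nan),
        "n_replicates": len(values),
    })
    return contrasts, summary


# ---------------------------------------------------------------------------
# temporal Ne


@dataclasses.dataclass
class NeEstimate:
    replicate: str
    ne: float  # effective number of diploids; may be +inf (flagged)
    n_snps: int
    t: int
    f_raw: float
    f_corrected: float
    method: str = "Fc-twostage"
    flagged: bool = False


def _sampling_term(pool_haplotypes: float,
                   coverage: np.ndarray | float) -> np.ndarray | float:
    """Variance share of one two-stage sample: 1/S + 1/R - 1/(S R)."""
    s, r = pool_haplotypes, coverage
    return 1.0 / s + 1.0 / r - 1.0 / (s * r)


def estimate_ne(x: np.ndarray, y: np.ndarray, t: int,
                pool_haplotypes_0: float, pool_haplotypes_t: float,
                coverage_0: np.ndarray | float,
                coverage_t: np.ndarray | float,
                replicate: str = "", min_snps: int = 50) -> NeEstimate:
    """Temporal Ne from allele frequencies x (generation 0) and y
    (generation t) at many SNPs.

    Per site F_c = (x - y)^2 / (z (1 - z)) with z = (x + y) / 2; the
    average F_c, corrected by the two-stage sampling terms of both time
    points, gives Ne = -t / (2 ln(1 - F_corr)).  Non-positive corrected F
    yields Ne = +inf with a flag.  Monomorphic sites carry no signal and
    are dropped; an entirely monomorphic input is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t < 1:
        raise ValueError("need t >= 1 generations between samples")
    z = (x + y) / 2.0
    denom = z * (1.0 - z)
    keep = denom > 0
    if not keep.any():
        raise InsufficientDataError("no polymorphic sites for Ne estimation")
    if keep.sum() < min_snps:
        logger.warning("only %d polymorphic SNPs for Ne (recommend >= %d)",
                       int(keep.sum()), min_snps)
    c0 = np.broadcast_to(np.asarray(
        _sampling_term(pool_haplotypes_0, coverage_0), dtype=float), x.shape)
    ct = np.broadcast_to(np.asarray(
        _sampling_term(pool_haplotypes_t, coverage_t), dtype=float), y.shape)
    fc = (x[keep] - y[keep]) ** 2 / denom[keep]
    f_raw = float(fc.mean())
    f_corr = float((fc - c0[keep] - ct[keep]).mean())
    if f_corr <= 0 or f_corr >= 1:
        return NeEstimate(replicate, np.inf, int(keep.sum()), int(t),
                          f_raw, f_corr, flagged=True)
    ne = -t / (2.0 * np.log(1.0 - f_corr))
    return NeEstimate(replicate, float(ne), int(keep.sum()), int(t),
                      f_raw, f_corr)


def estimate_ne_from_table(table: AlleleCountTable, replicate: str,
                           gen_0: int, gen_t: int,
                           pool_haplotypes: float = 2000,
                           min_snps: int = 50) -> NeEstimate:
    """Convenience wrapper extracting the two samples of a replicate."""
    i0 = table.sample_index(replicate, gen_0)
    it = table.sample_index(replicate, gen_t)
    freq = table.alt_freq
    cov = table.coverage
    ok = (cov[i0] > 0) & (cov[it] > 0)
    return estimate_ne(freq[i0, ok], freq[it, ok], gen_t - gen_0,
                       pool_haplotypes, pool_haplotypes,
                       cov[i0, ok], cov[it, ok],
                       replicate=replicate, min_snps=min_snps)


# ---------------------------------------------------------------------------
# CMH scans


def cmh_scan(table: AlleleCountTable,
             pairs: Mapping[str, tuple[int, int]],
             ne: Mapping[str, float] | None = None,
             adjusted: bool = True,
             pool_haplotypes: float = 2000,
             bh_column: bool = False) -> pd.DataFrame:
    """Per-SNP test of allele-frequency change shared across replicates.

    ``pairs`` maps each replicate to its (first, last) generation.  In
    classic mode the statistic is the 1-df Cochran-Mantel-Haenszel
    chi-square over the K replicate 2x2 allele-by-generation tables
    (no continuity correction).  In adjusted mode the score statistic

        (sum_k (x_k - y_k))^2 / sum_k Var_k,
        Var_k = z(1-z) [ 1 - (1 - 1/(2 Ne_k))^t_k
                         + sampling terms of both time points ]

    inflates the null variance by drift and two-stage Pool-seq noise, so
    p-values stay calibrated under pure drift.  Sites lacking coverage
    in any used sample are returned as NA with a reason.  An optional
    Benjamini-Hochberg column can be appended (off by default; the scan
    reports raw p-values).
    """
    if adjusted and ne is None:
        raise ValueError("adjusted mode needs per-replicate Ne estimates")
    reps = sorted(pairs)
    n_sites = table.n_sites
    alt = table.alt_counts
    cov = table.coverage

    a = np.empty((len(reps), n_sites))  # alt at first gen
    r0 = np.empty_like(a)
    c = np.empty_like(a)  # alt at last gen
    rt = np.empty_like(a)
    tspan = np.empty(len(reps))
    ne_arr = np.empty(len(reps))
    for k, rep in enumerate(reps):
        g0, gt = pairs[rep]
        i0, it = table.sample_index(rep, g0), table.sample_index(rep, gt)
        a[k], r0[k] = alt[i0], cov[i0]
        c[k], rt[k] = alt[it], cov[it]
        tspan[k] = gt - g0
        ne_arr[k] = np.nan if ne is None else ne[rep]

    valid = ((r0 > 0) & (rt > 0)).all(axis=0)
    stat = np.full(n_sites, np.nan)

    if adjusted:
        x = np.where(r0 > 0, a / np.maximum(r0, 1), np.nan)
        y = np.where(rt > 0, c / np.maximum(rt, 1), np.nan)
        z = (x + y) / 2.0
        drift = (1.0 - (1.0 - 1.0 / (2.0 * ne_arr)) ** tspan)[:, None]
        var = z * (1.0 - z) * (drift
                               + _sampling_term(pool_haplotypes, r0)
                               + _sampling_term(pool_haplotypes, rt))
        num = np.nansum(x - y, axis=0) ** 2
        den = np.nansum(var, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat[valid] = np.where(den[valid] > 0,
                                   num[valid] / np.maximum(den[valid], 1e-300),
                                   0.0)
    else:
        b, d = r0 - a, rt - c
        n = r0 + rt
        col1 = a + c
        col2 = b + d
        e = r0 * col1 / n
        v = r0 * rt * col1 * col2 / (n ** 2 * (n - 1.0))
        num = (a.sum(axis=0) - e.sum(axis=0)) ** 2
        den = v.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat[valid] = np.where(den[valid] > 0,
                                   num[valid] / np.maximum(den[valid], 1e-300),
                                   0.0)

    pvalue = np.where(np.isnan(stat), np.nan, chi2.sf(stat, df=1))
    out = pd.DataFrame({
        "chrom": table.sites["chrom"],
        "pos": table.sites["pos"],
        "statistic": stat,
        "pvalue": pvalue,
        "neglog10_p": -np.log10(np.clip(pvalue, 1e-300, None)),
        "mode": "adjusted" if adjusted else "classic",
        "reason": np.where(valid, "", "insufficient coverage"),
    })
    if bh_column:
        from statsmodels.stats.multitest import multipletests
        ok = ~out["pvalue"].isna()
        q = np.full(n_sites, np.nan)
        if ok.any():
            q[ok] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
        out["q_bh"] = q
    return out
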