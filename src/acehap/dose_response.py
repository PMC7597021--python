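"""Insecticide bioassay summaries and probit LD50 estimation.

Mortality after fixed-time exposure is modelled as
``P(death) = Phi(a + b log10 dose)``; the dose killing half the exposed
flies is ``LD50 = 10^(-a/b)``.  The model is fitted by binomial maximum
likelihood (a probit GLM), with a delta-method confidence interval for
LD50 on the log10-dose scale.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from acehap.io_formats import DoseResponseRecord, InsufficientDataError

logger = logging.getLogger("acehap")


@dataclasses.dataclass
class ProbitFit:
    intercept: float
    slope: float  # per log10(microgram)
    ld50: float  # micrograms
    se_intercept: float
    se_slope: float
    ld50_ci: tuple[float, float]
    loglik: float
    converged: bool
    heterogeneity_chi2: float
    heterogeneity_df: int

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return norm.cdf(self.intercept + self.slope * np.log10(dose))


def records_to_frame(records: Sequence[DoseResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def _abbott(dead: np.ndarray, exposed: np.ndarray,
            control_mortality: float) -> np.ndarray:
    """Abbott's natural-mortality correction of death counts."""
    p = dead / exposed
    p_adj = np.clip((p - control_mortality) / (1 - control_mortality), 0, 1)
    return np.round(p_adj * exposed)


def fit_probit(records: Sequence[DoseResponseRecord],
               abbott_correction: bool = False) -> ProbitFit:
    """Probit maximum-likelihood fit of a dose-mortality curve.

    Requires at least 3 distinct positive doses and one
    partial-mortality observation; dose-0 controls are excluded from the
    fit (log undefined) but, with ``abbott_correction``, their mean
    mortality rescales the treated mortalities first (off by default).
    Complete separation (all-or-nothing mortality around a threshold) is
    returned as a flagged fit with an unbounded confidence interval
    rather than an error.
    """
    df = records_to_frame(list(records))
    controls = df[df["dose"] == 0]
    df = df[df["dose"] > 0].copy()
    if df["dose"].nunique() < 3:
        raise InsufficientDataError("need >= 3 distinct positive doses")
    dead = df["n_dead"].to_numpy(dtype=float)
    exposed = df["n_exposed"].to_numpy(dtype=float)
    if abbott_correction and len(controls):
        c = controls["n_dead"].sum() / controls["n_exposed"].sum()
        if c > 0:
            dead = _abbott(dead, exposed, c)
    partial = (dead > 0) & (dead < exposed)
    if not partial.any():
        logger.warning("no partial-mortality observation: likely separation")

    logdose = np.log10(df["dose"].to_numpy())
    endog = np.column_stack([dead, exposed - dead])
    exog = sm.add_constant(logdose)
    model = sm.GLM(endog, exog, family=sm.families.Binomial(
        link=sm.families.links.Probit()))
    try:
        res = model.fit(maxiter=200)
        a, b = res.params
        cov = res.cov_params()
        # all-or-nothing mortality (complete separation) leaves the slope
        # unidentified no matter what IRLS reports
        converged = (bool(res.converged) and bool(partial.any())
                     and np.isfinite(cov).all())
    except Exception:  # perfect separation drives IRLS off the rails
        converged = False
    if not converged:
        return _separated_fit(logdose, dead, exposed)
    if b <= 0:
        logger.warning("non-positive probit slope %.3g: mortality does not "
                       "increase with dose", b)
    ld50 = float(10 ** (-a / b)) if b != 0 else np.inf
    # delta method on log10 LD50 = -a/b
    grad = np.array([-1.0 / b, a / b ** 2])
    var_log10 = float(grad @ cov @ grad)
    half = 1.96 * np.sqrt(max(var_log10, 0.0))
    ci = (float(10 ** (np.log10(ld50) - half)),
          float(10 ** (np.log10(ld50) + half)))
    fitted = norm.cdf(a + b * logdose)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (dead - exposed * fitted) ** 2 / np.clip(
            exposed * fitted * (1 - fitted), 1e-12, None)
    het = float(np.sum(resid))
    return ProbitFit(intercept=float(a), slope=float(b), ld50=ld50,
                     se_intercept=float(np.sqrt(cov[0, 0])),
                     se_slope=float(np.sqrt(cov[1, 1])),
                     ld50_ci=ci, loglik=float(res.llf), converged=True,
                     heterogeneity_chi2=het,
                     heterogeneity_df=max(len(df) - 2, 0))


def _separated_fit(logdose: np.ndarray, dead: np.ndarray,
                   exposed: np.ndarray) -> ProbitFit:
    """Fallback for complete separation: LD50 as the geometric midpoint
    between the highest all-survive and lowest all-die dose, flagged,
    with an unbounded CI."""
    p = dead / exposed
    lo = logdose[p < 0.5].max() if (p < 0.5).any() else logdose.min()
    hi = logdose[p >= 0.5].min() if (p >= 0.5).any() else logdose.max()
    ld50 = float(10 ** ((lo + hi) / 2))
    return ProbitFit(intercept=np.nan, slope=np.inf, ld50=ld50,
                     se_intercept=np.nan, se_slope=np.nan,
                     ld50_ci=(0.0, np.inf), loglik=np.nan, converged=False,
                     heterogeneity_chi2=np.nan, heterogeneity_df=0)


def single_dose_summary(records: Sequence[DoseResponseRecord]
                        ) -> pd.DataFrame:
    """Mean per-vial mortality and its SEM per (population, insecticide).

    Vials with zero exposed flies are dropped with a warning; groups
    with a single vial report the SEM as NA.
    """
    df = records_to_frame(list(records))
    empty = df["n_exposed"] == 0
    if empty.any():
        logger.warning("dropping %d vials with zero exposed flies",
                       int(empty.sum()))
        df = df[~empty]
    df["mortality"] = df["n_dead"] / df["n_exposed"]
    out = (df.groupby(["population", "insecticide"], sort=True)["mortality"]
           .agg(mean_mortality="mean",
                sem=lambda v: (v.std(ddof=1) / np.sqrt(len(v))
                               if len(v) > 1 else np.nan),
                n_vials="count")
           .reset_index())
    return out
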