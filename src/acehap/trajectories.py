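"""Marker-median haplotype-class frequency trajectories from Pool-seq.

The class-1 frequency of a sample is the median, over usable diagnostic
marker SNPs, of the class-1-allele read frequency; the 1a frequency is
the median of the three resistance-allele frequencies; 1b follows by
subtraction (clamped at zero) and class 2 as the complement.  Markers
that fail the coverage filter in any sample of a regime are dropped
regime-wide before the medians are taken.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from acehap.io_formats import AlleleCountTable, _NUC_INDEX
from acehap.haplotype_classes import MarkerSet

logger = logging.getLogger("acehap")


@dataclasses.dataclass
class FilterReport:
    """Sites removed by :func:`filter_snps`, with the reason."""

    excluded: pd.DataFrame  # chrom, pos, reason

    def reasons(self) -> pd.Series:
        return self.excluded["reason"].value_counts()


def filter_snps(table: AlleleCountTable, min_mac: int = 5,
                min_coverage: int = 10
                ) -> tuple[AlleleCountTable, FilterReport]:
    """Retain sites with a pooled minor-allele count of at least
    ``min_mac`` and coverage of at least ``min_coverage`` in **every**
    sample.  Returns the filtered table and an exclusion report."""
    alt_total = table.alt_counts.sum(axis=0)
    ref_total = table.ref_counts.sum(axis=0)
    mac = np.minimum(alt_total, ref_total)
    low_cov = (table.coverage < min_coverage).any(axis=0)
    low_mac = mac < min_mac

    reasons = []
    for j in np.flatnonzero(low_cov | low_mac):
        reasons.append({
            "chrom": table.sites.iloc[j]["chrom"],
            "pos": table.sites.iloc[j]["pos"],
            "reason": ("insufficient coverage" if low_cov[j]
                       else "minor allele count below threshold"),
        })
    keep = ~(low_cov | low_mac)
    if not keep.any():
        logger.warning("SNP filter removed every site")
    report = FilterReport(pd.DataFrame(
        reasons, columns=["chrom", "pos", "reason"]))
    return table.subset_sites(keep), report


@dataclasses.dataclass
class ClassTrajectorySet:
    """Tidy per-sample haplotype-class frequencies.

    ``table`` has one row per (replicate, generation) with normalized
    frequencies ``f_1a, f_1b, f_2`` (summing to 1), the raw
    pre-normalization values, the class-1 marker median ``f_1``, the
    number of usable markers, and a flag where the 1b clamp was active.
    """

    table: pd.DataFrame
    markers_used: pd.DataFrame
    n_markers_dropped: int

    def tidy(self) -> pd.DataFrame:
        """Long format: replicate, generation, class, frequency."""
        long = self.table.melt(
            id_vars=["replicate", "generation", "regime"],
            value_vars=["f_1a", "f_1b", "f_2"],
            var_name="class", value_name="frequency")
        long["class"] = long["class"].str.removeprefix("f_")
        return long


def _nuc_freqs(table: AlleleCountTable, site_idx: np.ndarray,
               nucs: np.ndarray) -> np.ndarray:
    """Frequency of the given nucleotide at the given sites, for every
    sample; shape (n_samples, len(site_idx))."""
    nuc_i = np.array([_NUC_INDEX[n] for n in nucs])
    counts = table.counts[:, site_idx, :][:, np.arange(len(site_idx)), nuc_i]
    cov = table.coverage[:, site_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cov > 0, counts / np.maximum(cov, 1), np.nan)


def class_frequencies(table: AlleleCountTable, markers: MarkerSet,
                      resistance_sites: pd.DataFrame,
                      renormalize: bool = True) -> ClassTrajectorySet:
    """Haplotype-class frequency trajectories from a (filtered) count table.

    ``resistance_sites`` needs columns ``chrom, pos, resistance_nuc``
    naming the resistance allele at each of the three sites; a resistance
    site absent from the table makes the 1a estimator undefined and
    raises ``KeyError``.  Markers absent from the table (filtered out)
    are dropped for all samples; with an even number of usable markers
    the median is the mean of the two central order statistics (the
    numpy convention).
    """
    key = table.site_key()
    marker_keys = (markers.sites["chrom"].astype(str) + ":"
                   + markers.sites["pos"].astype(str))
    present = marker_keys.isin(key)
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("dropped %d markers absent from the filtered table "
                    "(regime-wide)", n_dropped)
    usable = markers.sites.loc[present.to_numpy()]
    if len(usable) == 0:
        raise ValueError("no usable marker SNPs left after filtering")
    lookup = pd.Series(np.arange(len(key)), index=key)
    m_idx = lookup.loc[(usable["chrom"].astype(str) + ":"
                        + usable["pos"].astype(str))].to_numpy()
    m_freq = _nuc_freqs(table, m_idx, usable["class1_nuc"].to_numpy())

    res_keys = (resistance_sites["chrom"].astype(str) + ":"
                + resistance_sites["pos"].astype(str))
    missing_res = [k for k in res_keys if k not in lookup.index]
    if missing_res:
        raise KeyError(
            f"resistance sites absent from the filtered table: {missing_res}"
            " — the haplotype-class estimator is undefined without them")
    r_idx = lookup.loc[res_keys].to_numpy()
    r_freq = _nuc_freqs(table, r_idx,
                        resistance_sites["resistance_nuc"].to_numpy())

    f1 = np.nanmedian(m_freq, axis=1)
    f1a_raw = np.nanmedian(r_freq, axis=1)
    f2_raw = 1.0 - f1
    f1b_raw = f1 - f1a_raw
    clamped = f1b_raw < 0
    n_clamped = int(clamped.sum())
    if n_clamped:
        logger.info("1b clamp active in %d of %d samples", n_clamped,
                    len(f1))
    f1a = np.minimum(f1a_raw, f1)
    f1b = np.clip(f1b_raw, 0.0, None)
    triple = np.stack([f1a, f1b, f2_raw], axis=1)
    if renormalize:
        total = triple.sum(axis=1, keepdims=True)
        triple = triple / total

    rows = pd.DataFrame({
        "replicate": [s.replicate for s in table.samples],
        "generation": [s.generation for s in table.samples],
        "regime": [s.regime for s in table.samples],
        "f_1a": triple[:, 0], "f_1b": triple[:, 1], "f_2": triple[:, 2],
        "f_1a_raw": f1a_raw, "f_1b_raw": f1b_raw, "f_2_raw": f2_raw,
        "f_1": f1,
        "n_markers_used": len(usable),
        "clamped": clamped,
    })
    rows = rows.sort_values(["replicate", "generation"]).reset_index(drop=True)
    return ClassTrajectorySet(rows, usable.reset_index(drop=True), n_dropped)
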