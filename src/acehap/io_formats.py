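"""Readers and writers for the formats the pipeline touches.

Pool-seq allele counts travel in PoPoolation2 ``sync`` format (tab-separated
``chrom  pos  ref  A:T:C:G:N:del`` with one count column per sample),
founder haplotypes in VCF, and results in plain CSV/JSON with a
schema-versioned header.  All coordinates are 1-based and windows are
inclusive on both ends.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("acehap")

SCHEMA_VERSION = "acehap-schema-v1"

#: nucleotide order of a sync count column
SYNC_ORDER = ("A", "T", "C", "G", "N", "del")
_NUC_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3}
MISSING = -1


class SyncParseError(ValueError):
    """A sync line could not be parsed; the message names the line number."""


class ConfigurationError(ValueError):
    """Inconsistent user-supplied configuration (e.g. annotation mismatch)."""


class EmptyWindowError(ValueError):
    """A genomic window contained no usable records."""


class InsufficientDataError(ValueError):
    """Too few haplotypes/sites/time points for the requested analysis."""


@dataclasses.dataclass(frozen=True)
class GenomicSite:
    """A biallelic SNP at a 1-based genomic position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _NUC_INDEX:
                raise ValueError(f"allele must be one of A/C/G/T, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")


@dataclasses.dataclass(frozen=True)
class SampleInfo:
    """Annotation of one Pool-seq sample column."""

    replicate: str
    generation: int
    regime: str


@dataclasses.dataclass(frozen=True)
class DoseResponseRecord:
    """One insecticide bioassay vial: dose in micrograms, exposure and deaths."""

    population: str
    insecticide: str
    dose: float
    n_exposed: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValueError("need 0 <= n_dead <= n_exposed")

    @property
    def mortality(self) -> float:
        return self.n_dead / self.n_exposed


class AlleleCountTable:
    """Per-sample, per-site nucleotide read counts parsed from sync.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt``, sorted by
        (chrom, pos).
    samples
        One :class:`SampleInfo` per sync sample column.
    counts
        Integer array of shape ``(n_samples, n_sites, 6)`` in
        :data:`SYNC_ORDER`.  N and deletion counts are carried through but
        excluded from coverage.
    """

    def __init__(self, sites: pd.DataFrame, samples: Sequence[SampleInfo],
                 counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(samples), len(sites), 6):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(samples)}, {len(sites)}, 6)")
        if (counts < 0).any():
            raise ValueError("negative read counts")
        self.sites = sites.reset_index(drop=True)
        self.samples = [s if isinstance(s, SampleInfo) else SampleInfo(*s)
                        for s in samples]
        self.counts = counts
        self._check_generations()

    def _check_generations(self) -> None:
        seen: dict[str, int] = {}
        for s in self.samples:
            if s.replicate in seen and s.generation < seen[s.replicate]:
                raise ConfigurationError(
                    f"generations not non-decreasing within replicate "
                    f"{s.replicate!r}")
            seen[s.replicate] = s.generation

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def coverage(self) -> np.ndarray:
        """Sum of the four nucleotide counts, shape (n_samples, n_sites)."""
        return self.counts[:, :, :4].sum(axis=2)

    def _allele_counts(self, col: str) -> np.ndarray:
        idx = self.sites[col].map(_NUC_INDEX).to_numpy()
        return self.counts[:, np.arange(self.n_sites), idx]

    @property
    def alt_counts(self) -> np.ndarray:
        return self._allele_counts("alt")

    @property
    def ref_counts(self) -> np.ndarray:
        return self._allele_counts("ref")

    @property
    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency; NaN where coverage is zero."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.alt_counts / np.maximum(cov, 1), np.nan)

    # -- subsetting ---------------------------------------------------------

    def subset_sites(self, mask: np.ndarray) -> "AlleleCountTable":
        mask = np.asarray(mask)
        return AlleleCountTable(self.sites.loc[mask].reset_index(drop=True),
                                self.samples, self.counts[:, mask, :])

    def subset_samples(self, indices: Sequence[int]) -> "AlleleCountTable":
        indices = list(indices)
        return AlleleCountTable(self.sites, [self.samples[i] for i in indices],
                                self.counts[indices])

    def sample_index(self, replicate: str, generation: int) -> int:
        for i, s in enumerate(self.samples):
            if s.replicate == replicate and s.generation == generation:
                return i
        raise KeyError(f"no sample for replicate {replicate!r} "
                       f"generation {generation}")

    def site_key(self) -> pd.Index:
        return pd.Index(self.sites["chrom"].astype(str) + ":"
                        + self.sites["pos"].astype(str))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountTable):
            return NotImplemented
        return (self.sites.equals(other.sites)
                and self.samples == other.samples
                and np.array_equal(self.counts, other.counts))


def _choose_alt(ref: str, pooled: np.ndarray) -> str:
    """Global alt allele: highest pooled non-reference count, ties and the
    all-zero case resolved by alphabetical nucleotide order."""
    candidates = sorted(n for n in _NUC_INDEX if n != ref)
    best_count = -1
    chosen = candidates[0]
    for n in candidates:
        c = int(pooled[_NUC_INDEX[n]])
        if c > best_count:
            best_count, chosen = c, n
    return chosen


def read_sync(path: str | Path,
              sample_annotations: Sequence[SampleInfo | tuple]) -> AlleleCountTable:
    """Parse a PoPoolation2 sync file into an :class:`AlleleCountTable`.

    The alt allele of each site is defined globally (pooled over all
    samples) as the highest-count non-reference nucleotide, with ties broken
    alphabetically, so frequencies are comparable across generations.
    """
    annotations = [s if isinstance(s, SampleInfo) else SampleInfo(*s)
                   for s in sample_annotations]
    if len(annotations) == 0:
        raise ConfigurationError("sync file requires at least one sample column")
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    rows: list[list[list[int]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(f"line {lineno}: fewer than 4 columns")
            if len(fields) - 3 != len(annotations):
                raise ConfigurationError(
                    f"line {lineno}: {len(fields) - 3} sample columns but "
                    f"{len(annotations)} annotations supplied")
            chrom, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: bad position "
                                     f"{pos_s!r}") from exc
            if ref not in _NUC_INDEX:
                raise SyncParseError(f"line {lineno}: reference allele "
                                     f"{ref!r} is not A/C/G/T")
            site_counts = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"line {lineno}: count column {col!r} does not have "
                        f"6 fields")
                try:
                    site_counts.append([int(p) for p in parts])
                except ValueError as exc:
                    raise SyncParseError(f"line {lineno}: non-integer count "
                                         f"in {col!r}") from exc
            chroms.append(chrom)
            positions.append(pos)
            refs.append(ref)
            rows.append(site_counts)

    counts = (np.asarray(rows, dtype=np.int64).transpose(1, 0, 2)
              if rows else np.zeros((len(annotations), 0, 6), dtype=np.int64))
    pooled = counts.sum(axis=0)  # (n_sites, 6)
    alts = [_choose_alt(ref, pooled[i]) for i, ref in enumerate(refs)]
    sites = pd.DataFrame({"chrom": chroms, "pos": positions,
                          "ref": refs, "alt": alts})
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    counts = counts[:, order, :]
    return AlleleCountTable(sites, annotations, counts)


def write_sync(table: AlleleCountTable, path: str | Path) -> None:
    """Write an :class:`AlleleCountTable` back to sync format."""
    with open(path, "w") as fh:
        for j in range(table.n_sites):
            site = table.sites.iloc[j]
            cols = [":".join(str(c) for c in table.counts[i, j])
                    for i in range(table.n_samples)]
            fh.write("\t".join([str(site["chrom"]), str(site["pos"]),
                                site["ref"], *cols]) + "\n")


class HaplotypeMatrix:
    """Biallelic alleles of founder-derived haplotypes over a genomic window.

    ``alleles`` holds 0 (reference), 1 (alternative) or :data:`MISSING`
    (-1), one row per haplotype, sites sorted by position.  ``L`` is the
    number of nucleotides examined, used to normalise diversity.
    """

    def __init__(self, sites: pd.DataFrame, haplotype_ids: Sequence[str],
                 alleles: np.ndarray, L: int):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (len(haplotype_ids), len(sites)):
            raise ValueError("alleles shape does not match ids x sites")
        if not np.isin(alleles, [0, 1, MISSING]).all():
            raise ValueError("alleles must be 0, 1 or missing (-1)")
        if L <= 0:
            raise ValueError("window length L must be positive")
        if not sites["pos"].is_monotonic_increasing:
            order = np.argsort(sites["pos"].to_numpy(), kind="stable")
            sites = sites.iloc[order]
            alleles = alleles[:, order]
        self.sites = sites.reset_index(drop=True)
        self.haplotype_ids = list(haplotype_ids)
        self.alleles = alleles
        self.L = int(L)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_haplotypes(self, ids: Iterable[str]) -> "HaplotypeMatrix":
        wanted = list(ids)
        idx = [self.haplotype_ids.index(h) for h in wanted]
        return HaplotypeMatrix(self.sites, wanted, self.alleles[idx], self.L)

    def site_positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()


def read_haplotype_vcf(path: str | Path,
                       window: tuple[str, int, int],
                       L: int | None = None) -> HaplotypeMatrix:
    """Read founder haplotypes from a VCF of line x reference-strain F1s.

    Each VCF sample is one cross; the focal haplotype carries the
    non-reference allele of a heterozygous call, so genotypes map as
    0/0 -> 0, 0/1 or 1/1 -> 1, ./. -> missing.  Multi-allelic records are
    skipped with a warning.  ``window`` is (chrom, start, end), 1-based
    inclusive.
    """
    from cyvcf2 import VCF

    chrom, start, end = window
    if L is None:
        L = end - start + 1
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if rec.CHROM != chrom or not (start <= rec.POS <= end):
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()[:, :2]
        col = np.full(len(ids), MISSING, dtype=np.int8)
        valid = (gts >= 0).all(axis=1)
        col[valid] = (gts[valid] > 0).any(axis=1).astype(np.int8)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        columns.append(col)
    if n_multi:
        logger.warning("skipped %d multi-allelic/non-SNP records in window",
                       n_multi)
    if not positions:
        raise EmptyWindowError(
            f"no biallelic SNP records in {chrom}:{start}-{end}")
    sites = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "ref": refs, "alt": alts})
    alleles = np.stack(columns, axis=1)
    return HaplotypeMatrix(sites, ids, alleles, L)


def write_haplotype_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a HaplotypeMatrix as a minimal VCF 4.2 of F1-style genotypes.

    Allele 1 is emitted as the heterozygous genotype 0/1 (the cross design
    read back by :func:`read_haplotype_vcf`), allele 0 as 0/0, missing as
    ./. .
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = matrix.sites["chrom"].unique()
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.haplotype_ids) + "\n")
        code = {0: "0/0", 1: "0/1", MISSING: "./."}
        for j in range(matrix.n_sites):
            site = matrix.sites.iloc[j]
            gts = "\t".join(code[int(a)] for a in matrix.alleles[:, j])
            fh.write(f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t"
                     f"{site['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


# -- result serialization ---------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with a schema-versioned comment header
    and deterministic column order (as given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: object, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o: object):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump({"schema": SCHEMA_VERSION, "data": obj}, fh, indent=2,
                  default=_default)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        payload = json.load(fh)
    return payload["data"]
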