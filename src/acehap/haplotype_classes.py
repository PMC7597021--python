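"""Haplotype-class calling, marker-SNP discovery and nucleotide diversity.

Founder haplotypes at the *Ace* locus fall into two deeply diverged
groups: a recently swept, low-diversity class 1 and a diverse class 2.
Class 1 splits into 1a (carrying the three linked resistance mutations
I161V, G265A, F330Y) and 1b (identical background without them).  This
module reproduces the calling procedure: exclude failed crosses and
class-1/class-2 recombinants, split the remaining haplotypes by
agglomerative clustering on pairwise allele differences, assign 1a/1b by
the resistance triple, derive the diagnostic marker SNPs that separate
class 1 from class 2, and compute within-class nucleotide diversity

    pi = (mean over pairs of d_ij) / L

where d_ij counts differing nucleotides between sequences i and j and L
is the number of nucleotides examined (36,265 bp for the *Ace* gene).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from acehap.io_formats import HaplotypeMatrix, InsufficientDataError, MISSING

logger = logging.getLogger("acehap")

#: default Ace gene length used to normalise diversity (bp)
ACE_GENE_LENGTH = 36_265

RETAINED = ("1a", "1b", "2")


class AmbiguousStructureError(ValueError):
    """Clustering did not yield two clear top-level haplotype groups."""


class AnomalousHaplotypeError(ValueError):
    """A haplotype carries a strict subset of the resistance alleles."""


@dataclasses.dataclass
class ClassAssignment:
    """Haplotype id -> class label, plus the resistance sites used."""

    labels: dict[str, str]
    resistance_positions: list[int]

    def ids_for(self, *labels: str) -> list[str]:
        return [h for h, lab in self.labels.items() if lab in labels]

    @property
    def retained_ids(self) -> list[str]:
        return self.ids_for(*RETAINED)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"haplotype_id": list(self.labels),
                             "class": list(self.labels.values())})


@dataclasses.dataclass
class MarkerSet:
    """Diagnostic SNPs fixed-different between class 1 and class 2.

    ``class1_allele`` gives, per site, the 0/1 allele carried by every
    retained class-1 haplotype; ``class1_nuc`` is the corresponding
    nucleotide, usable directly against Pool-seq read counts.
    """

    sites: pd.DataFrame  # chrom, pos, ref, alt, class1_allele, class1_nuc

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()


@dataclasses.dataclass
class DiversityResult:
    label: str
    n: int
    pi: float
    L: int
    mean_pairwise_diff: float


# ---------------------------------------------------------------------------
# pairwise distances and clustering


def pairwise_difference_matrix(matrix: HaplotypeMatrix
                               ) -> tuple[np.ndarray, np.ndarray]:
    """(d, m): counts of differing sites and of comparable (both
    non-missing) sites for every haplotype pair."""
    a = matrix.alleles
    valid = a != MISSING
    both = valid[:, None, :] & valid[None, :, :]
    diff = (a[:, None, :] != a[None, :, :]) & both
    return diff.sum(axis=2), both.sum(axis=2)


def _difference_fraction(matrix: HaplotypeMatrix,
                         min_carriers: int = 2) -> np.ndarray:
    """Pairwise fraction of differing non-missing sites, computed on
    shared polymorphisms only (minor allele carried by at least
    ``min_carriers`` haplotypes).  Singleton/private variants carry no
    information about deep class structure and, in the diverse class,
    would otherwise swamp the diagnostic signal."""
    a = matrix.alleles
    ones = (a == 1).sum(axis=0)
    zeros = (a == 0).sum(axis=0)
    shared = np.minimum(ones, zeros) >= min_carriers
    if shared.any():
        matrix = HaplotypeMatrix(matrix.sites.loc[shared],
                                 matrix.haplotype_ids,
                                 a[:, shared], matrix.L)
    d, m = pairwise_difference_matrix(matrix)
    with np.errstate(invalid="ignore"):
        frac = np.where(m > 0, d / np.maximum(m, 1), 0.0)
    np.fill_diagonal(frac, 0.0)
    return frac


def cluster_two_groups(matrix: HaplotypeMatrix,
                       min_separation: float = 2.0) -> dict[str, int]:
    """Split haplotypes into two groups by average-linkage clustering on
    the fraction of differing non-missing shared-polymorphism sites.

    The dendrogram is cut into its two top-level groups; the split must
    be well separated (mean between-group distance at least
    ``min_separation`` times the larger mean within-group distance —
    recombinant chimeras legitimately sit at intermediate merge heights,
    so the cut itself cannot be gap-based), otherwise an
    :class:`AmbiguousStructureError` reports the diagnostics.
    """
    if matrix.n_haplotypes < 3:
        raise InsufficientDataError("need at least 3 haplotypes to cluster")
    frac = _difference_fraction(matrix)
    z = linkage(squareform(frac, checks=False), method="average")
    groups = fcluster(z, t=2, criterion="maxclust")
    n_groups = len(np.unique(groups))
    if n_groups != 2:
        raise AmbiguousStructureError(
            f"clustering yields {n_groups} top-level groups (expected 2)")
    in1 = groups == 1
    within = []
    for mask in (in1, ~in1):
        sub = frac[np.ix_(mask, mask)]
        iu = np.triu_indices(mask.sum(), k=1)
        within.append(float(sub[iu].mean()) if len(iu[0]) else 0.0)
    between = float(frac[np.ix_(in1, ~in1)].mean())
    if between < min_separation * max(max(within), 1e-12):
        raise AmbiguousStructureError(
            f"groups are not well separated: between-group mean distance "
            f"{between:.4f} vs within-group means {within[0]:.4f}/"
            f"{within[1]:.4f}")
    return dict(zip(matrix.haplotype_ids, (int(g) for g in groups)))


# ---------------------------------------------------------------------------
# exclusions


def _consensus(alleles: np.ndarray) -> np.ndarray:
    """Per-site majority allele over rows, ignoring missing entries."""
    ones = (alleles == 1).sum(axis=0)
    zeros = (alleles == 0).sum(axis=0)
    return (ones > zeros).astype(np.int8)


def exclude_failed_and_recombinant(matrix: HaplotypeMatrix,
                                   provisional: dict[str, int],
                                   min_block: int = 5) -> dict[str, str]:
    """Apply the two exclusion rules to provisionally clustered haplotypes.

    * ``excluded:homozygous`` — the source F1 cross produced only
      homozygous genotype calls, i.e. the haplotype carries no
      alternative allele at any non-missing site (a failed cross).
    * ``excluded:recombinant`` — along the chromosome the haplotype
      switches between class-1-type and class-2-type alleles at the
      provisional diagnostic sites, with at least ``min_block``
      consecutive diagnostic sites of each type.

    Returns haplotype id -> "1"/"2"/"excluded:homozygous"/
    "excluded:recombinant".
    """
    if matrix.n_haplotypes < 3:
        raise InsufficientDataError("need at least 3 haplotypes")
    ids = matrix.haplotype_ids
    out: dict[str, str] = {}
    for i, h in enumerate(ids):
        row = matrix.alleles[i]
        nonmissing = row != MISSING
        if nonmissing.any() and not (row[nonmissing] == 1).any():
            out[h] = "excluded:homozygous"

    # provisional diagnostic sites from cluster consensus sequences
    g1 = [i for i, h in enumerate(ids)
          if provisional.get(h) == 1 and h not in out]
    g2 = [i for i, h in enumerate(ids)
          if provisional.get(h) == 2 and h not in out]
    cons1 = _consensus(matrix.alleles[g1])
    cons2 = _consensus(matrix.alleles[g2])
    diagnostic = np.flatnonzero(cons1 != cons2)

    for i, h in enumerate(ids):
        if h in out:
            continue
        row = matrix.alleles[i, diagnostic]
        keep = row != MISSING
        types = np.where(row[keep] == cons1[diagnostic][keep], 1, 2)
        if _has_blocks_of_both(types, min_block):
            out[h] = "excluded:recombinant"
        else:
            out[h] = str(provisional[h])
    return out


def _has_blocks_of_both(types: np.ndarray, min_block: int) -> bool:
    """True if the sequence contains a run of >= min_block ones and a run
    of >= min_block twos."""
    found = {1: False, 2: False}
    run_val, run_len = 0, 0
    for t in types:
        if t == run_val:
            run_len += 1
        else:
            run_val, run_len = int(t), 1
        if run_len >= min_block:
            found[run_val] = True
    return found[1] and found[2]


# ---------------------------------------------------------------------------
# final assignment


def _resistance_indices(matrix: HaplotypeMatrix,
                        resistance_positions: Sequence[int]) -> np.ndarray:
    pos = matrix.site_positions()
    idx = []
    for p in resistance_positions:
        hits = np.flatnonzero(pos == p)
        if len(hits) == 0:
            raise KeyError(f"resistance site at position {p} not in matrix")
        idx.append(hits[0])
    return np.asarray(idx)


def assign_classes(matrix: HaplotypeMatrix,
                   resistance_positions: Sequence[int],
                   exclusions: dict[str, str],
                   allow_anomalous: bool = False) -> ClassAssignment:
    """Final class labels after exclusions.

    The cluster containing haplotypes that carry all resistance
    alternative alleles is class 1 (falling back to the lower-diversity
    cluster if no carrier exists); within class 1, carriers of the full
    resistance triple are 1a and non-carriers 1b.  A haplotype carrying
    a strict subset of the resistance alleles contradicts the observed
    haplotype structure and raises
    :class:`AnomalousHaplotypeError` unless ``allow_anomalous`` is set,
    in which case it is labelled ``anomalous``.
    """
    res_idx = _resistance_indices(matrix, resistance_positions)
    ids = matrix.haplotype_ids
    n_res = {h: int((matrix.alleles[i, res_idx] == 1).sum())
             for i, h in enumerate(ids)}

    group_of = {h: lab for h, lab in exclusions.items()
                if lab in ("1", "2")}
    carriers = {h for h, n in n_res.items()
                if n == len(res_idx) and h in group_of}
    if carriers:
        class1_group = {group_of[h] for h in carriers}
        if len(class1_group) > 1:
            raise AmbiguousStructureError(
                "resistance-triple carriers span both clusters")
        class1 = class1_group.pop()
    else:
        class1 = _lower_diversity_group(matrix, group_of)

    labels: dict[str, str] = {}
    for h in ids:
        lab = exclusions[h]
        if lab.startswith("excluded"):
            labels[h] = lab
        elif lab == class1:
            if n_res[h] == len(res_idx):
                labels[h] = "1a"
            elif n_res[h] == 0:
                labels[h] = "1b"
            else:
                if not allow_anomalous:
                    raise AnomalousHaplotypeError(
                        f"{h} carries {n_res[h]}/{len(res_idx)} resistance "
                        f"alleles")
                labels[h] = "anomalous"
        else:
            if n_res[h] not in (0, len(res_idx)) and not allow_anomalous:
                raise AnomalousHaplotypeError(
                    f"{h} carries {n_res[h]}/{len(res_idx)} resistance "
                    f"alleles")
            labels[h] = "2" if n_res[h] == 0 else "anomalous"
    return ClassAssignment(labels, [int(p) for p in resistance_positions])


def _lower_diversity_group(matrix: HaplotypeMatrix,
                           group_of: dict[str, str]) -> str:
    best, best_pi = None, np.inf
    for g in ("1", "2"):
        members = [h for h, lab in group_of.items() if lab == g]
        if len(members) < 2:
            continue
        sub = matrix.subset_haplotypes(members)
        res = nucleotide_diversity(sub, label=g)
        if res.pi < best_pi:
            best, best_pi = g, res.pi
    if best is None:
        raise AmbiguousStructureError("cannot orient clusters")
    return best


def call_haplotype_classes(matrix: HaplotypeMatrix,
                           resistance_positions: Sequence[int],
                           min_block: int = 5,
                           allow_anomalous: bool = False) -> ClassAssignment:
    """Full calling pipeline: cluster, exclude, assign.

    Failed crosses are removed before clustering (their all-reference
    rows otherwise masquerade as class-2 members), recombinants are
    detected on the provisional clusters, and the final 1a/1b/2 labels
    are derived from the resistance triple.
    """
    ids = matrix.haplotype_ids
    failed = []
    for i, h in enumerate(ids):
        row = matrix.alleles[i]
        nonmissing = row != MISSING
        if nonmissing.any() and not (row[nonmissing] == 1).any():
            failed.append(h)
    survivors = [h for h in ids if h not in failed]
    sub = matrix.subset_haplotypes(survivors)
    provisional = cluster_two_groups(sub)
    exclusions = exclude_failed_and_recombinant(sub, provisional,
                                                min_block=min_block)
    for h in failed:
        exclusions[h] = "excluded:homozygous"
    assignment = assign_classes(matrix, resistance_positions, exclusions,
                                allow_anomalous=allow_anomalous)
    counts = assignment.counts()
    logger.info("class calling: %s", counts)
    return assignment


# ---------------------------------------------------------------------------
# marker SNPs


def find_marker_snps(matrix: HaplotypeMatrix,
                     assignment: ClassAssignment) -> MarkerSet:
    """Sites at which every retained class-1 haplotype carries one allele
    and every retained class-2 haplotype the other.

    Missing entries are ignored, but any conflicting non-missing call
    disqualifies a site, as does a side with no non-missing call.  The
    resistance sites tag 1a within class 1 and are excluded.
    """
    ids1 = assignment.ids_for("1a", "1b")
    ids2 = assignment.ids_for("2")
    if not ids1 or not ids2:
        raise InsufficientDataError("need retained haplotypes in both classes")
    idx = {h: i for i, h in enumerate(matrix.haplotype_ids)}
    a1 = matrix.alleles[[idx[h] for h in ids1]]
    a2 = matrix.alleles[[idx[h] for h in ids2]]

    def fixed_allele(a: np.ndarray) -> np.ndarray:
        """Per site: 0 or 1 if unanimous among non-missing calls, else -9."""
        has0 = (a == 0).any(axis=0)
        has1 = (a == 1).any(axis=0)
        out = np.full(a.shape[1], -9, dtype=np.int8)
        out[has0 & ~has1] = 0
        out[has1 & ~has0] = 1
        return out

    f1, f2 = fixed_allele(a1), fixed_allele(a2)
    is_marker = (f1 >= 0) & (f2 >= 0) & (f1 != f2)
    res_pos = set(assignment.resistance_positions)
    pos = matrix.site_positions()
    is_marker &= ~np.isin(pos, list(res_pos))

    sites = matrix.sites.loc[is_marker, ["chrom", "pos", "ref", "alt"]].copy()
    sites["class1_allele"] = f1[is_marker]
    sites["class1_nuc"] = np.where(sites["class1_allele"] == 1,
                                   sites["alt"], sites["ref"])
    return MarkerSet(sites.reset_index(drop=True))


# ---------------------------------------------------------------------------
# nucleotide diversity


def nucleotide_diversity(matrix: HaplotypeMatrix, L: int | None = None,
                         label: str = "") -> DiversityResult:
    """Average pairwise difference count over all n(n-1)/2 sequence pairs,
    divided by the number of nucleotides examined L.

    Pairwise comparisons skip sites where either sequence is missing.
    """
    n = matrix.n_haplotypes
    if n < 2:
        raise InsufficientDataError("diversity needs at least 2 sequences")
    L = matrix.L if L is None else L
    if L <= 0:
        raise ValueError("L must be positive")
    d, _ = pairwise_difference_matrix(matrix)
    iu = np.triu_indices(n, k=1)
    mean_d = float(d[iu].mean())
    return DiversityResult(label=label, n=n, pi=mean_d / L, L=int(L),
                           mean_pairwise_diff=mean_d)


def diversity_by_class(matrix: HaplotypeMatrix,
                       assignment: ClassAssignment,
                       L: int | None = None,
                       groups: dict[str, tuple[str, ...]] | None = None
                       ) -> pd.DataFrame:
    """Diversity table per haplotype class (default: class 1 = 1a+1b
    pooled, and class 2, as reported for the founder haplotypes)."""
    if groups is None:
        groups = {"1": ("1a", "1b"), "2": ("2",)}
    rows = []
    for name, labels in groups.items():
        ids = assignment.ids_for(*labels)
        res = nucleotide_diversity(matrix.subset_haplotypes(ids), L=L,
                                   label=name)
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)
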