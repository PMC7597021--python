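"""Synthetic Evolve-and-Resequence experiments with known ground truth.

The generator emulates the structure of the real experiment end to end:

* a founder population segregating three haplotype classes at the *Ace*
  locus — class 1a (carrying the three linked resistance mutations I161V,
  G265A, F330Y), its susceptible sister class 1b (identical background,
  no resistance alleles) and a diverse susceptible class 2 whose
  within-class nucleotide diversity is roughly 20x that of class 1;
* experimentally derived founder haplotypes, including failed crosses
  (all-homozygous genotype calls) and class-1/class-2 recombinants that
  the class-calling step must exclude;
* diploid Wright-Fisher reproduction of five replicate populations per
  temperature regime, with co-dominant per-class fitness and drift at the
  replicate-specific effective population size;
* two-stage Pool-seq sampling (a pool of individuals, then binomial read
  sampling at finite coverage) written as PoPoolation2 sync;
* probit-distributed insecticide-bioassay mortality.

Every dataset carries a :class:`SimTruth` sufficient to regenerate it
bit-for-bit and to score any downstream estimate.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from acehap.io_formats import (
    AlleleCountTable,
    ConfigurationError,
    DoseResponseRecord,
    HaplotypeMatrix,
    SampleInfo,
)
from acehap.inference import selection_step

CLASSES = ("1a", "1b", "2")

#: Ace gene span on chromosome 3R (1-based inclusive); the +-200 kb
#: analysis window is 11,771,451-12,207,715.
CHROM = "3R"
GENE_START = 11_971_451
GENE_END = 12_007_715
GENE_LENGTH = GENE_END - GENE_START + 1  # 36,265 bp

_NUCS = np.array(["A", "C", "G", "T"])


@dataclasses.dataclass
class SimConfig:
    """Parameterization of one temperature regime of the experiment.

    Defaults reproduce the study conditions: five replicates kept at a
    census of 1000 flies, effective sizes near 175-270 diploids,
    Pool-seq of the whole population at ~80x coverage, 19/8/5 founder
    haplotypes in classes 1a/1b/2 (resistance-triple frequency 59%),
    166 diagnostic marker SNPs between class 1 and class 2, and
    within-class diversity pi = 0.0004 (class 1) vs 0.0082 (class 2).
    """

    regime: str = "cold"
    n_haplotypes_per_class: tuple[int, int, int] = (19, 8, 5)
    founder_class_freqs: tuple[float, float, float] = (19 / 32, 8 / 32, 5 / 32)
    #: relative fitness of the 1a, 1b, 2 haplotype classes
    class_fitness: tuple[float, float, float] = (1 - 0.055, 1.0, 1 + 1.7 * 0.055)
    h: float = 0.5
    census_n: int = 1000
    ne_per_replicate: tuple[int, ...] = (209, 255, 259, 198, 175)
    n_replicates: int = 5
    sampled_generations: tuple[int, ...] = (0, 11, 21, 31, 41, 51)
    n_marker_snps: int = 166
    #: target within-class diversity for class 1 (= 1a+1b) and class 2
    within_class_pi: tuple[float, float] = (0.0004, 0.0082)
    mean_coverage: float = 80.0
    pool_size: int = 1000  # individuals pooled for sequencing
    n_failed_crosses: int = 2
    n_recombinants: int = 2
    g368a_n_class2: int = 2  # class-2 carriers of G368A (all 1b carry it)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.founder_class_freqs) - 1.0) > 1e-12:
            raise ConfigurationError("founder_class_freqs must sum to 1")
        if any(w <= 0 for w in self.class_fitness):
            raise ConfigurationError("class fitness values must be positive")
        if self.sampled_generations[0] != 0 or any(
                b <= a for a, b in zip(self.sampled_generations,
                                       self.sampled_generations[1:])):
            raise ConfigurationError(
                "sampled_generations must start at 0 and strictly increase")
        if len(self.ne_per_replicate) != self.n_replicates:
            raise ConfigurationError("need one Ne per replicate")
        if not 0 <= self.h <= 1:
            raise ConfigurationError("dominance h must be in [0, 1]")

    @property
    def pool_haplotypes(self) -> int:
        return 2 * self.pool_size

    @property
    def selection_contrast(self) -> float:
        """True s_1a - s_1b (per-generation cost of the resistance triple)."""
        return (self.class_fitness[0] - 1.0) - (self.class_fitness[1] - 1.0)


def hot_config(seed: int = 0, **overrides) -> SimConfig:
    """Study conditions of the hot regime (generations 0, 15, 37, 59)."""
    params = dict(
        regime="hot",
        class_fitness=(1 - 0.031, 1.0, 1 + 1.7 * 0.031),
        ne_per_replicate=(252, 229, 268, 209, 245),
        sampled_generations=(0, 15, 37, 59),
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def cold_config(seed: int = 0, **overrides) -> SimConfig:
    """Study conditions of the cold regime (generations 0..51)."""
    return SimConfig(seed=seed, **overrides)


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    regime: str
    class_labels: dict[str, str]  # haplotype id -> 1a/1b/2/excluded:*
    class_fitness: tuple[float, float, float]
    h: float
    ne_per_replicate: tuple[int, ...]
    sampled_generations: tuple[int, ...]
    founder_class_freqs: tuple[float, float, float]
    marker_positions: list[int]
    resistance_positions: list[int]
    g368a_position: int
    selection_contrast: float
    seed: int


@dataclasses.dataclass
class SimExperiment:
    """A full simulated experiment: founder, trajectories, Pool-seq."""

    config: SimConfig
    truth: SimTruth
    founder: HaplotypeMatrix
    class_paths: np.ndarray  # (n_replicates, max_gen + 1, 3)
    counts: AlleleCountTable

    def sampled_class_frequencies(self) -> pd.DataFrame:
        """True class frequencies at the sampled generations (tidy)."""
        rows = []
        for r in range(self.config.n_replicates):
            for g in self.config.sampled_generations:
                for c, label in enumerate(CLASSES):
                    rows.append({"replicate": f"R{r + 1}", "generation": g,
                                 "class": label,
                                 "frequency": self.class_paths[r, g, c]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# founder haplotypes


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-component RNG streams from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_founder(config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[HaplotypeMatrix, SimTruth]:
    """Build founder haplotypes over the *Ace* gene with known class labels.

    Classes 1a and 1b share one archetype and differ only at the three
    linked resistance sites; class 2 differs from class 1 at
    ``n_marker_snps`` diagnostic sites.  Within-class variation is added
    as private mutations at a rate chosen so the expected nucleotide
    diversity matches ``within_class_pi`` (the contribution of the
    archetype differences — resistance triple and G368A — is subtracted
    first).  Failed crosses (all-reference rows) and class-1/class-2
    recombinant chimeras are appended and labelled in the truth.
    """
    if rng is None:
        rng = _streams(config.seed, 1)[0]
    n1a, n1b, n2 = config.n_haplotypes_per_class
    n_valid = n1a + n1b + n2

    # expected private-mutation load per haplotype so that realized pi
    # matches the target once archetype differences are accounted for
    n1 = n1a + n1b
    pairs1 = n1 * (n1 - 1) / 2
    g368a_n1b = n1b  # all 1b haplotypes carry G368A
    # archetype pairwise differences within class 1: the 3 resistance
    # sites plus G368A separate every 1a/1b pair
    d_arch_1 = 4 * n1a * n1b / pairs1 if pairs1 > 0 else 0.0
    # within class 2 only G368A segregates on the archetype
    pairs2 = n2 * (n2 - 1) / 2
    k = config.g368a_n_class2
    d_arch_2 = k * (n2 - k) / pairs2 if pairs2 > 0 else 0.0
    m1 = max(0.0, (config.within_class_pi[0] * GENE_LENGTH - d_arch_1) / 2)
    m2 = max(0.0, (config.within_class_pi[1] * GENE_LENGTH - d_arch_2) / 2)
    private_counts = np.concatenate([
        rng.poisson(m1, size=n1), rng.poisson(m2, size=n2)])
    n_private = int(private_counts.sum())

    n_sites = config.n_marker_snps + 3 + 1 + n_private
    if n_sites > GENE_LENGTH:
        raise ConfigurationError(
            f"{n_sites} sites exceed the {GENE_LENGTH} bp window capacity")
    positions = np.sort(rng.choice(GENE_LENGTH, size=n_sites, replace=False)
                        ) + GENE_START
    # fixed roles by random draw: resistance triple + G368A + markers
    role_idx = rng.permutation(n_sites)
    res_idx = np.sort(role_idx[:3])
    g368a_idx = role_idx[3]
    marker_idx = np.sort(role_idx[4:4 + config.n_marker_snps])
    private_idx = role_idx[4 + config.n_marker_snps:]

    ref = _NUCS[rng.integers(0, 4, size=n_sites)]
    alt_shift = rng.integers(1, 4, size=n_sites)
    alt = _NUCS[(np.searchsorted(_NUCS, ref) + alt_shift) % 4]

    n_extra = config.n_failed_crosses + config.n_recombinants
    alleles = np.zeros((n_valid + n_extra, n_sites), dtype=np.int8)
    labels_in_order = (["1a"] * n1a + ["1b"] * n1b + ["2"] * n2
                       + ["excluded:homozygous"] * config.n_failed_crosses
                       + ["excluded:recombinant"] * config.n_recombinants)
    # class-1 archetype carries the alternative allele at every marker
    alleles[:n1, marker_idx] = 1
    alleles[:n1a, res_idx] = 1
    carriers_368 = list(range(n1a, n1a + g368a_n1b))
    carriers_368 += list(rng.choice(np.arange(n1, n1 + n2), size=k,
                                    replace=False))
    alleles[carriers_368, g368a_idx] = 1

    # private mutations: each draws a unique reserved site
    pool = list(rng.permutation(private_idx))
    for hap, count in enumerate(private_counts):
        for _ in range(int(count)):
            alleles[hap, pool.pop()] = 1

    # recombinant chimeras: class-1 alleles up to a breakpoint near the
    # middle of the marker track, class-2 (reference) beyond
    row = n_valid + config.n_failed_crosses
    for _ in range(config.n_recombinants):
        lo, hi = int(0.4 * len(marker_idx)), int(0.6 * len(marker_idx))
        cut_pos = positions[marker_idx[rng.integers(lo, hi)]]
        left_markers = marker_idx[positions[marker_idx] <= cut_pos]
        alleles[row, left_markers] = 1
        row += 1

    order = rng.permutation(n_valid + n_extra)
    alleles = alleles[order]
    ids = [f"hap{i + 1:02d}" for i in range(n_valid + n_extra)]
    labels = {ids[i]: labels_in_order[order[i]] for i in range(len(ids))}

    sites = pd.DataFrame({"chrom": CHROM, "pos": positions,
                          "ref": ref, "alt": alt})
    matrix = HaplotypeMatrix(sites, ids, alleles, GENE_LENGTH)
    truth = SimTruth(
        regime=config.regime,
        class_labels=labels,
        class_fitness=config.class_fitness,
        h=config.h,
        ne_per_replicate=tuple(config.ne_per_replicate),
        sampled_generations=tuple(config.sampled_generations),
        founder_class_freqs=tuple(config.founder_class_freqs),
        marker_positions=[int(positions[i]) for i in marker_idx],
        resistance_positions=[int(positions[i]) for i in res_idx],
        g368a_position=int(positions[g368a_idx]),
        selection_contrast=config.selection_contrast,
        seed=config.seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Wright-Fisher evolution of haplotype classes


def simulate_wf_trajectories(config: SimConfig,
                             rngs: Sequence[np.random.Generator] | None = None,
                             deterministic: bool = False) -> np.ndarray:
    """Per-replicate haplotype-class frequency paths.

    Each generation applies deterministic selection and then multinomial
    drift of ``2 * Ne`` haplotypes (classes behave as alleles of a single
    locus; no recombination within the window).  With
    ``deterministic=True`` the drift step is skipped (the Ne -> infinity
    limit).  Returns shape ``(n_replicates, max_generation + 1, 3)``.
    """
    max_gen = max(config.sampled_generations)
    if rngs is None:
        rngs = _streams(config.seed, 1 + config.n_replicates)[1:]
    paths = np.empty((config.n_replicates, max_gen + 1, len(CLASSES)))
    for r in range(config.n_replicates):
        two_ne = 2 * config.ne_per_replicate[r]
        p = np.asarray(config.founder_class_freqs, dtype=float)
        paths[r, 0] = p
        for g in range(1, max_gen + 1):
            p = selection_step(p, config.class_fitness, config.h)
            if not deterministic:
                counts = rngs[r].multinomial(two_ne, p)
                p = counts / two_ne
            paths[r, g] = p
    return paths


# ---------------------------------------------------------------------------
# Pool-seq sampling


def class_site_frequencies(founder: HaplotypeMatrix,
                           labels: dict[str, str]) -> np.ndarray:
    """Alt-allele frequency of every site within each retained class,
    shape (3, n_sites).  Within-class composition is assumed to stay at
    its founder proportions throughout the experiment."""
    g = np.empty((len(CLASSES), founder.n_sites))
    for c, cls in enumerate(CLASSES):
        rows = [i for i, h in enumerate(founder.haplotype_ids)
                if labels[h] == cls]
        if not rows:
            raise ConfigurationError(f"no founder haplotypes in class {cls}")
        g[c] = (founder.alleles[rows] == 1).mean(axis=0)
    return g


def simulate_poolseq(paths: np.ndarray, founder: HaplotypeMatrix,
                     truth: SimTruth, config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> AlleleCountTable:
    """Two-stage Pool-seq sampling of the sampled generations.

    Per site and sample the true alt frequency follows from the class
    frequencies and the within-class founder composition; a pool of
    ``pool_size`` individuals (``2 * pool_size`` haplotypes) is drawn
    binomially, then reads binomially at Poisson(``mean_coverage``)
    depth.  Zero-coverage site/samples are allowed.
    """
    if rng is None:
        rng = _streams(config.seed, 2 + config.n_replicates)[-1]
    g = class_site_frequencies(founder, truth.class_labels)
    n_hap = config.pool_haplotypes
    samples: list[SampleInfo] = []
    counts = np.zeros((config.n_replicates * len(config.sampled_generations),
                       founder.n_sites, 6), dtype=np.int64)
    nuc_idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    ref_i = founder.sites["ref"].map(nuc_idx).to_numpy()
    alt_i = founder.sites["alt"].map(nuc_idx).to_numpy()
    i = 0
    for r in range(config.n_replicates):
        for gen in config.sampled_generations:
            p_true = paths[r, gen] @ g
            pool_freq = rng.binomial(n_hap, p_true) / n_hap
            cov = rng.poisson(config.mean_coverage, size=founder.n_sites)
            alt_reads = rng.binomial(cov, pool_freq)
            counts[i, np.arange(founder.n_sites), alt_i] = alt_reads
            counts[i, np.arange(founder.n_sites), ref_i] += cov - alt_reads
            samples.append(SampleInfo(f"R{r + 1}", int(gen), config.regime))
            i += 1
    return AlleleCountTable(founder.sites.copy(), samples, counts)


def simulate_experiment(config: SimConfig) -> SimExperiment:
    """Run the complete generator: founder, WF evolution, Pool-seq."""
    streams = _streams(config.seed, 2 + config.n_replicates)
    founder, truth = simulate_founder(config, streams[0])
    paths = simulate_wf_trajectories(config, streams[1:-1])
    counts = simulate_poolseq(paths, founder, truth, config, streams[-1])
    return SimExperiment(config, truth, founder, paths, counts)


# ---------------------------------------------------------------------------
# neutral SNP panels (for Ne and CMH calibration)


def simulate_neutral_sites(n_sites: int, n_replicates: int, ne: int, t: int,
                           mean_coverage: float = 80.0,
                           pool_haplotypes: int = 2000,
                           p0_range: tuple[float, float] = (0.1, 0.9),
                           seed: int = 0,
                           rng: np.random.Generator | None = None
                           ) -> AlleleCountTable:
    """Independent neutral SNPs drifting for ``t`` generations.

    Starting frequencies are shared across replicates (one founder) and
    drawn uniformly from ``p0_range``, emulating a filtered Pool-seq SNP
    panel.  Each replicate contributes samples at generation 0 and t with
    two-stage Pool-seq noise.  Sites are laid out on a synthetic contig.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    p0 = rng.uniform(*p0_range, size=n_sites)
    sites = pd.DataFrame({"chrom": "sim", "pos": np.arange(1, n_sites + 1),
                          "ref": "A", "alt": "C"})
    samples: list[SampleInfo] = []
    counts = np.zeros((2 * n_replicates, n_sites, 6), dtype=np.int64)
    two_ne = 2 * ne

    def pool_reads(p: np.ndarray, row: int) -> None:
        pool_freq = rng.binomial(pool_haplotypes, p) / pool_haplotypes
        cov = rng.poisson(mean_coverage, size=n_sites)
        alt_reads = rng.binomial(cov, pool_freq)
        counts[row, :, 2] = alt_reads          # C = alt
        counts[row, :, 0] = cov - alt_reads    # A = ref

    row = 0
    for r in range(n_replicates):
        pool_reads(p0, row)
        samples.append(SampleInfo(f"R{r + 1}", 0, "sim"))
        p = p0.copy()
        for _ in range(t):
            p = rng.binomial(two_ne, p) / two_ne
        pool_reads(p, row + 1)
        samples.append(SampleInfo(f"R{r + 1}", t, "sim"))
        row += 2
    return AlleleCountTable(sites, samples, counts)


# ---------------------------------------------------------------------------
# bioassays


def simulate_bioassay(ld50: float, slope: float, doses: Sequence[float],
                      n_per_vial: int = 30, n_vials: int = 4,
                      population: str = "anc", insecticide: str = "propoxur",
                      seed: int = 0,
                      rng: np.random.Generator | None = None
                      ) -> list[DoseResponseRecord]:
    """Probit-distributed mortality: P(death) = Phi(slope * (log10 dose -
    log10 LD50)); dose 0 is a control with mortality probability 0."""
    if ld50 <= 0 or slope <= 0:
        raise ConfigurationError("ld50 and slope must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for dose in doses:
        p = 0.0 if dose == 0 else float(
            norm.cdf(slope * (np.log10(dose) - np.log10(ld50))))
        for _ in range(n_vials):
            dead = int(rng.binomial(n_per_vial, p))
            records.append(DoseResponseRecord(population, insecticide,
                                              float(dose), n_per_vial, dead))
    return records
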