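"""Class calling, exclusion rules, marker discovery and diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acehap.haplotype_classes import (
    AnomalousHaplotypeError,
    call_haplotype_classes,
    cluster_two_groups,
    find_marker_snps,
    nucleotide_diversity,
)
from acehap.io_formats import HaplotypeMatrix, InsufficientDataError, MISSING
from acehap.synthetic import cold_config, simulate_founder


def _matrix(rows, L=100, positions=None, ids=None):
    rows = np.asarray(rows, dtype=np.int8)
    n_sites = rows.shape[1]
    positions = positions or list(range(1, n_sites + 1))
    sites = pd.DataFrame({"chrom": "3R", "pos": positions,
                          "ref": "A", "alt": "C"})
    ids = ids or [f"h{i}" for i in range(rows.shape[0])]
    return HaplotypeMatrix(sites, ids, rows, L)


class TestNucleotideDiversity:
    def test_identical_sequences_have_zero_pi(self):
        m = _matrix([[0, 1, 0]] * 3, L=100)
        assert nucleotide_diversity(m).pi == 0.0

    def test_single_pair_single_difference(self):
        m = _matrix([[0] * 100, [1] + [0] * 99], L=100)
        assert nucleotide_diversity(m).pi == pytest.approx(0.01)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(10, 50))
        rows[rng.random(rows.shape) < 0.05] = MISSING
        m = _matrix(rows, L=50)
        # independent oracle: explicit double loop over pairs
        n = rows.shape[0]
        total, n_pairs = 0, 0
        for i in range(n):
            for j in range(i + 1, n):
                both = (rows[i] != MISSING) & (rows[j] != MISSING)
                total += int(((rows[i] != rows[j]) & both).sum())
                n_pairs += 1
        expected = (total / n_pairs) / 50
        assert nucleotide_diversity(m).pi == pytest.approx(expected,
                                                           abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_invariant_under_row_permutation_and_allele_relabel(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(8, 30))
        base = nucleotide_diversity(_matrix(rows, L=30)).pi
        perm = rng.permutation(8)
        assert nucleotide_diversity(_matrix(rows[perm], L=30)).pi == base
        flip = rows.copy()
        cols = rng.choice(30, size=10, replace=False)
        flip[:, cols] = 1 - flip[:, cols]
        assert nucleotide_diversity(_matrix(flip, L=30)).pi == base

    def test_requires_two_sequences_and_positive_length(self):
        with pytest.raises(InsufficientDataError):
            nucleotide_diversity(_matrix([[0, 1]]))
        with pytest.raises(ValueError):
            nucleotide_diversity(_matrix([[0, 1], [1, 0]]), L=0)


def _toy_two_class(n1=6, n2=4, n_markers=12):
    """Class-1 haplotypes carry alt at all markers plus the resistance
    triple (first 3 of class 1 only); class-2 haplotypes are
    reference-like apart from one private singleton each (so they are
    distinguishable from failed crosses)."""
    n_sites = n_markers + 3 + n2
    rows = np.zeros((n1 + n2, n_sites), dtype=np.int8)
    rows[:n1, :n_markers] = 1
    rows[:3, n_markers:n_markers + 3] = 1  # first three are "1a"
    for j in range(n2):
        rows[n1 + j, n_markers + 3 + j] = 1  # private singleton
    res_pos = [n_markers + 1, n_markers + 2, n_markers + 3]
    return _matrix(rows, L=1000), res_pos


class TestClassCalling:
    def test_pure_haplotypes_retained_and_split_by_resistance(self):
        m, res_pos = _toy_two_class()
        a = call_haplotype_classes(m, res_pos)
        assert a.counts() == {"1a": 3, "1b": 3, "2": 4}

    def test_identical_haplotypes_share_a_class(self):
        m, res_pos = _toy_two_class()
        a = call_haplotype_classes(m, res_pos)
        # h3..h5 are identical 1b haplotypes
        assert len({a.labels["h3"], a.labels["h4"], a.labels["h5"]}) == 1

    def test_all_homozygous_haplotype_excluded(self):
        m, res_pos = _toy_two_class()
        rows = np.vstack([m.alleles, np.zeros((1, m.n_sites), dtype=np.int8)])
        # an all-reference row is indistinguishable from a failed cross
        m2 = _matrix(rows, L=1000, ids=[f"h{i}" for i in range(rows.shape[0])])
        a = call_haplotype_classes(m2, res_pos)
        assert a.labels["h10"] == "excluded:homozygous"

    def test_half_and_half_chimera_excluded_as_recombinant(self):
        m, res_pos = _toy_two_class(n_markers=12)
        chimera = np.zeros((1, m.n_sites), dtype=np.int8)
        chimera[0, :6] = 1  # class-1 alleles then class-2 alleles
        rows = np.vstack([m.alleles, chimera])
        m2 = _matrix(rows, L=1000, ids=[f"h{i}" for i in range(rows.shape[0])])
        a = call_haplotype_classes(m2, res_pos)
        assert a.labels["h10"] == "excluded:recombinant"

    def test_subset_of_resistance_alleles_is_anomalous(self):
        m, res_pos = _toy_two_class()
        m.alleles[0, 14] = 0  # h0 now carries only 2 of 3 resistance alleles
        with pytest.raises(AnomalousHaplotypeError):
            call_haplotype_classes(m, res_pos)
        a = call_haplotype_classes(m, res_pos, allow_anomalous=True)
        assert a.labels["h0"] == "anomalous"

    def test_too_few_haplotypes(self):
        m, _ = _toy_two_class()
        with pytest.raises(InsufficientDataError):
            cluster_two_groups(m.subset_haplotypes(["h0", "h1"]))

    def test_default_synthetic_founder_recovers_truth_exactly(
            self, default_founder):
        founder, truth = default_founder
        a = call_haplotype_classes(founder, truth.resistance_positions)
        assert a.labels == truth.class_labels
        # mirrors the study design: 4 of 36 haplotypes excluded (2 + 2)
        counts = a.counts()
        assert counts["excluded:homozygous"] == 2
        assert counts["excluded:recombinant"] == 2
        assert len(a.retained_ids) == 32


class TestMarkerSnps:
    def test_fixed_difference_is_a_marker_with_class1_allele(self):
        m, res_pos = _toy_two_class()
        a = call_haplotype_classes(m, res_pos)
        markers = find_marker_snps(m, a)
        assert len(markers) == 12
        assert (markers.sites["class1_allele"] == 1).all()
        assert not markers.sites["pos"].isin(res_pos).any()

    def test_single_conflicting_haplotype_disqualifies_site(self):
        m, res_pos = _toy_two_class()
        m.alleles[-1, 0] = 1  # one class-2 haplotype shares class-1 allele
        a = call_haplotype_classes(m, res_pos)
        markers = find_marker_snps(m, a)
        assert len(markers) == 11
        assert 1 not in markers.sites["pos"].tolist()

    def test_missing_calls_tolerated_if_consistent(self):
        m, res_pos = _toy_two_class()
        m.alleles[0, 0] = MISSING
        a = call_haplotype_classes(m, res_pos)
        markers = find_marker_snps(m, a)
        assert 1 in markers.sites["pos"].tolist()

    def test_symmetry_under_class_relabelling(self):
        """Swapping which cluster is 'class 1' preserves the marker site
        set and flips the tagged allele."""
        from acehap.haplotype_classes import ClassAssignment

        m, res_pos = _toy_two_class()
        a = call_haplotype_classes(m, res_pos)
        swapped_labels = {}
        for h, lab in a.labels.items():
            swapped_labels[h] = {"1a": "2", "1b": "2"}.get(lab, "1b")
        swapped = ClassAssignment(swapped_labels, a.resistance_positions)
        m1 = find_marker_snps(m, a)
        m2 = find_marker_snps(m, swapped)
        assert m1.sites["pos"].tolist() == m2.sites["pos"].tolist()
        assert (m1.sites["class1_allele"]
                == 1 - m2.sites["class1_allele"]).all()


class TestStructuralRecovery:
    @pytest.mark.parametrize("seed", range(3))
    def test_low_diversity_founders_recovered_perfectly(self, seed):
        """With within-class pi <= 0.001 and >= 20 markers, class calling
        is exact across seeds."""
        cfg = cold_config(seed=seed, within_class_pi=(0.0004, 0.001),
                          n_marker_snps=20)
        founder, truth = simulate_founder(cfg)
        a = call_haplotype_classes(founder, truth.resistance_positions)
        assert a.labels == truth.class_labels
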