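"""Survival labelling, md/min statistics and the retention rule table."""

import math

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

import hubscore as hs
from hubscore import Cluster, FilterThresholds, GeneType, PrecogLabel
from hubscore.classify import GeneMutationProfile
from hubscore.errors import ConsistencyError


def profile(gene="G", orf=0, non=0, cancer="MM"):
    return GeneMutationProfile(gene, cancer, orf, non)


class TestPrecogLabel:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (1.96, PrecogLabel.ONCOGENE),       # boundary inclusive
            (-1.96, PrecogLabel.TUMOUR_SUPPRESSOR),
            (2.5, PrecogLabel.ONCOGENE),
            (-2.4, PrecogLabel.TUMOUR_SUPPRESSOR),
            (1.9599, PrecogLabel.NONE),
            (0.0, PrecogLabel.NONE),
            (None, PrecogLabel.NONE),
        ],
    )
    def test_labels(self, z, expected):
        assert hs.precog_label(z) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            hs.precog_label(math.nan)


class TestMutationStats:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 2, 3, 4, 10], (3.0, 1.0)),
            ([2, 4], (3.0, 2.0)),  # mean-of-middle-two median
            ([7], (7.0, 7.0)),
        ],
    )
    def test_examples(self, counts, expected):
        profiles = [profile(f"G{i}", orf=c) for i, c in enumerate(counts)]
        assert hs.mutation_stats(profiles) == expected

    def test_zero_count_genes_excluded(self):
        profiles = [profile("A", orf=5), profile("B")]  # B unmutated
        assert hs.mutation_stats(profiles) == (5.0, 5.0)

    def test_no_mutated_gene_rejected(self):
        with pytest.raises(ValueError):
            hs.mutation_stats([profile("A")])


class TestIsRetained:
    TH = FilterThresholds(md=3.0, min_=1.0)

    def test_non_orf_no_effect_strict_threshold(self):
        # cutoff 3*md + min = 10, strict >
        assert not hs.is_retained(profile(non=10), PrecogLabel.NONE, None, self.TH)
        assert hs.is_retained(profile(non=11), PrecogLabel.NONE, None, self.TH)

    def test_orf_low_threshold(self):
        # cutoff md - min = 2, inclusive
        assert hs.is_retained(profile(orf=2), PrecogLabel.NONE, None, self.TH)
        assert not hs.is_retained(profile(orf=1), PrecogLabel.NONE, None, self.TH)

    def test_orf_ignores_precog_label(self):
        for label, z in [(PrecogLabel.NONE, None), (PrecogLabel.ONCOGENE, 2.2)]:
            assert hs.is_retained(profile(orf=2), label, z, self.TH)
            assert not hs.is_retained(profile(orf=1), label, z, self.TH)

    def test_non_orf_with_effect(self):
        # cutoff md + min = 4, inclusive
        assert hs.is_retained(profile(non=4), PrecogLabel.ONCOGENE, 2.0, self.TH)
        assert not hs.is_retained(profile(non=3), PrecogLabel.ONCOGENE, 2.0, self.TH)

    def test_both_rules(self):
        assert hs.is_retained(profile(orf=1, non=1), PrecogLabel.ONCOGENE, 2.0, self.TH)
        # no effect: strict > 3*md = 9
        assert not hs.is_retained(profile(orf=4, non=5), PrecogLabel.NONE, None, self.TH)
        assert hs.is_retained(profile(orf=5, non=5), PrecogLabel.NONE, None, self.TH)

    def test_unmutated_rescue_at_z_strong(self):
        assert hs.is_retained(profile(), PrecogLabel.ONCOGENE, 2.60, self.TH)
        assert not hs.is_retained(profile(), PrecogLabel.ONCOGENE, 2.00, self.TH)
        assert not hs.is_retained(profile(), PrecogLabel.NONE, None, self.TH)


class TestAssignCluster:
    def test_cases(self):
        assert hs.assign_cluster(profile(orf=1), PrecogLabel.NONE) is Cluster.MUT
        assert hs.assign_cluster(profile(), PrecogLabel.ONCOGENE) is Cluster.PRECOG
        assert (hs.assign_cluster(profile(orf=1), PrecogLabel.TUMOUR_SUPPRESSOR)
                is Cluster.MUT_PRECOG)

    def test_contract_violation(self):
        with pytest.raises(ConsistencyError):
            hs.assign_cluster(profile(), PrecogLabel.NONE)


class TestFilterGenes:
    def test_six_gene_toy_cohort(self):
        """Hand-evaluated rule table over all four location classes.

        Mutated counts {5, 1, 12, 2} give md=3.5, min=1.
        """
        profiles = {
            "A": profile("A", orf=5),                # ORF: 5 >= 2.5 -> MUT
            "B": profile("B", non=1),                # NON_ORF+eff: 1 >= 4.5? no
            "C": profile("C", non=12),               # NON_ORF: 12 > 11.5 -> MUT
            "D": profile("D", orf=1, non=1),         # BOTH+eff: 2 >= 2.5? no
            "E": profile("E"),                       # NONE: |2.7| >= 2.58 -> PRECOG
            "F": profile("F"),                       # NONE + z=1.0 -> pre-discarded
        }
        precog = [
            hs.PrecogRecord("B", "MM", 2.0),
            hs.PrecogRecord("D", "MM", -2.2),
            hs.PrecogRecord("E", "MM", 2.7),
            hs.PrecogRecord("F", "MM", 1.0),
        ]
        statuses = {s.gene: s for s in hs.filter_genes(profiles, precog)}
        assert "F" not in statuses  # discarded before evaluation
        assert statuses["A"].retained and statuses["A"].cluster is Cluster.MUT
        assert not statuses["B"].retained and statuses["B"].cluster is None
        assert statuses["C"].retained and statuses["C"].cluster is Cluster.MUT
        assert not statuses["D"].retained
        assert statuses["E"].retained and statuses["E"].cluster is Cluster.PRECOG
        assert statuses["E"].gene_type is GeneType.SEED
        assert statuses["A"].gene_type is GeneType.INTERACTOR

    def test_empty_precog_gives_only_interactors(self):
        profiles = {g: profile(g, orf=c) for g, c in [("A", 3), ("B", 8), ("C", 1)]}
        statuses = hs.filter_genes(profiles, [])
        assert all(s.cluster is Cluster.MUT for s in statuses if s.retained)
        assert all(s.gene_type is GeneType.INTERACTOR for s in statuses if s.retained)

    def test_all_unmutated_rescued_without_mutation_stats(self):
        """With no mutated gene at all, only the Meta-Z rescue branch runs."""
        profiles = {g: profile(g) for g in "AB"}
        precog = [hs.PrecogRecord("A", "", 2.9), hs.PrecogRecord("B", "", -3.0)]
        statuses = hs.filter_genes(profiles, precog)
        assert all(s.retained and s.cluster is Cluster.PRECOG for s in statuses)

    def test_partition_into_seeds_and_interactors(self):
        rng = np.random.default_rng(5)
        profiles = {
            f"G{i}": profile(f"G{i}", orf=int(rng.geometric(0.3)),
                             non=int(rng.geometric(0.5)) - 1)
            for i in range(40)
        }
        precog = [hs.PrecogRecord(f"G{i}", "", float(rng.normal(0, 2)))
                  for i in range(0, 40, 3)]
        retained = [s for s in hs.filter_genes(profiles, precog) if s.retained]
        seeds = {s.gene for s in retained if s.gene_type is GeneType.SEED}
        inters = {s.gene for s in retained if s.gene_type is GeneType.INTERACTOR}
        assert seeds | inters == {s.gene for s in retained}
        assert seeds & inters == set()
        for s in retained:  # cluster/type consistency
            assert (s.gene_type is GeneType.SEED) == (
                s.cluster in (Cluster.PRECOG, Cluster.MUT_PRECOG))

    @seed(2)
    @settings(max_examples=60, deadline=None)
    @given(
        f=st.integers(0, 40), extra=st.integers(1, 10),
        cls=st.sampled_from(["ORF", "NON_ORF", "BOTH"]),
        z=st.one_of(st.none(), st.floats(-4, 4)),
    )
    def test_monotone_in_mutation_count(self, f, extra, cls, z):
        """More mutations never flip a gene from retained to discarded."""
        th = FilterThresholds(md=6.0, min_=2.0)
        label = hs.precog_label(z)

        def prof(total):
            if cls == "ORF":
                return profile(orf=total)
            if cls == "NON_ORF":
                return profile(non=total)
            return profile(orf=1, non=total - 1)

        lo, hi = (f, f + extra) if cls != "BOTH" else (f + 2, f + 2 + extra)
        if hs.is_retained(prof(lo), label, z, th):
            assert hs.is_retained(prof(hi), label, z, th)
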