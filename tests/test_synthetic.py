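"""Generator contracts: degenerate draws, round trips, frequency recovery,
determinism."""

import numpy as np
import pandas as pd
import pytest

from hbbhaplo.ld import ld_pair, two_locus_counts
from hbbhaplo.rflp import profile_sequence
from hbbhaplo.synthetic import (
    HBA_ALLELE,
    HBS_ALLELE,
    CohortSpec,
    RegionSpec,
    cohort_from_labels,
    default_template,
    derive_seed,
    emit_sequences,
    simulate_cohort,
    simulate_region_panel,
)


class TestCohortSpecValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CohortSpec("x", 10, 0.1, {"Benin": 0.5, "Cameroon": 0.4})

    def test_unknown_label_named_in_error(self, table):
        spec = CohortSpec("x", 5, 0.0, {"Atlantis": 1.0})
        with pytest.raises(KeyError, match="Atlantis"):
            simulate_cohort(spec, table)

    def test_frequency_bounds(self):
        with pytest.raises(ValueError):
            CohortSpec("x", 5, 1.5, {"Benin": 1.0})
        with pytest.raises(ValueError):
            CohortSpec("x", 0, 0.1, {"Benin": 1.0})


class TestSimulateCohort:
    def test_zero_hbs_frequency_gives_all_hba(self, table):
        cohort = simulate_cohort(
            CohortSpec("x", 10, 0.0, {"Benin": 1.0}, seed=1), table
        )
        assert cohort.n_chromosomes == 20
        assert set(cohort.df["hbs_allele"]) == {HBA_ALLELE}

    def test_degenerate_mixture_realizes_single_pattern(self, table):
        cohort = simulate_cohort(
            CohortSpec("x", 5, 0.0, {"Benin": 1.0}, seed=1), table
        )
        benin = table.classical["Benin"]
        assert all(p.states == benin for p in cohort.profiles())

    def test_hbs_frequency_recovery_large_n(self, table):
        p = 0.06
        spec = CohortSpec("x", 2000, p, {"Benin": 1.0}, seed=11)
        cohort = simulate_cohort(spec, table)
        se = np.sqrt(p * (1 - p) / (2 * spec.n_individuals))
        assert abs(cohort.hbs_allele_frequency() - p) < 3 * se

    def test_mixture_and_maf_recovery_large_n(self, table):
        spec = CohortSpec(
            "x", 2000, 0.0, {"Benin": 0.6, "atypical I": 0.4},
            snp_mafs={"ABO_proxy": 0.3}, seed=13,
        )
        cohort = simulate_cohort(spec, table)
        n2 = 2 * spec.n_individuals
        prop = cohort.df["haplotype"].value_counts(normalize=True)
        for lab, p in spec.haplotype_mixture.items():
            assert abs(prop[lab] - p) < 3 * np.sqrt(p * (1 - p) / n2)
        maf = (cohort.df["ABO_proxy"] == 1).mean()
        assert abs(maf - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n2)

    def test_exact_allocation(self, table):
        spec = CohortSpec("x", 39, 0.0,
                          {"atypical I": 53 / 78, "Benin": 25 / 78}, seed=5)
        cohort = simulate_cohort(spec, table, allocation="exact")
        assert (cohort.df["haplotype"] == "atypical I").sum() == 53

    def test_determinism(self, table):
        spec = CohortSpec("x", 50, 0.1, {"Benin": 0.5, "atypical I": 0.5},
                          seed=21)
        a = simulate_cohort(spec, table)
        b = simulate_cohort(spec, table)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestRegionPanel:
    def test_single_founder_makes_identical_chromosomes(self):
        spec = RegionSpec(n_markers=6, core_index=2,
                          founder_haplotypes_per_block=1, n_individuals=20,
                          seed=3)
        panel = simulate_region_panel(spec)
        assert np.all(panel.data == panel.data[0])

    def test_between_block_r2_vanishes(self):
        spec = RegionSpec(n_markers=4, core_index=0, recomb_breakpoints=(2,),
                          n_individuals=5000, seed=17)
        f = [np.array([[0, 0], [1, 1]]), np.array([[0, 0], [1, 1]])]
        panel = simulate_region_panel(spec, founders=f)
        counts = two_locus_counts(panel, 0, 3)
        freqs = np.array(counts.haplotypes) / counts.total
        stats = ld_pair(freqs)
        assert stats.r_squared < 3 / panel.n_chromosomes * 3  # ~E[r2]=1/n

    def test_opposite_founders_give_complete_ld(self):
        spec = RegionSpec(n_markers=2, core_index=0, n_individuals=100, seed=1)
        panel = simulate_region_panel(
            spec, founders=[np.array([[0, 1], [1, 0]])]
        )
        counts = two_locus_counts(panel, 0, 1)
        stats = ld_pair(np.array(counts.haplotypes) / counts.total)
        assert stats.d_prime == 1.0

    def test_only_founder_patterns_occur_within_blocks(self):
        spec = RegionSpec(n_markers=9, core_index=4, recomb_breakpoints=(3, 6),
                          founder_haplotypes_per_block=3, n_individuals=200,
                          seed=23)
        panel = simulate_region_panel(spec)
        for a, b in spec.block_bounds:
            seen = {tuple(row) for row in panel.data[:, a:b]}
            assert len(seen) <= 3

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            RegionSpec(n_markers=1, core_index=0)
        with pytest.raises(ValueError):
            RegionSpec(n_markers=5, core_index=9)
        with pytest.raises(ValueError):
            RegionSpec(n_markers=5, core_index=0, recomb_breakpoints=(3, 3))

    def test_determinism(self):
        spec = RegionSpec(n_markers=8, core_index=3, recomb_breakpoints=(4,),
                          n_individuals=50, seed=9)
        a = simulate_region_panel(spec)
        b = simulate_region_panel(spec)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.positions, b.positions)


class TestEmitDigestRoundTrip:
    def test_all_cut_profile_has_every_site(self, table, template):
        cohort = cohort_from_labels(["atypical IV"] * 2, table)  # pattern +++-+
        for _, seq in emit_sequences(cohort, template):
            profile, codon6 = profile_sequence(seq, template.windows)
            assert profile.states == table.atypical["atypical IV"]
            assert codon6 == "+"

    def test_hbs_chromosome_loses_ddei_site(self, table, template):
        cohort = cohort_from_labels(
            ["Benin"] * 2, table, hbs_alleles=[HBS_ALLELE, HBA_ALLELE]
        )
        (_, s1), (_, s2) = emit_sequences(cohort, template)
        assert profile_sequence(s1, template.windows)[1] == "-"
        assert profile_sequence(s2, template.windows)[1] == "+"

    def test_random_profiles_round_trip(self, table, template, rng):
        labels = list(table.labels)
        picks = [labels[i] for i in rng.integers(0, len(labels), size=100)]
        hbs = [HBS_ALLELE if b else HBA_ALLELE
               for b in rng.integers(0, 2, size=100)]
        cohort = cohort_from_labels(picks, table, hbs_alleles=hbs)
        want_states = ["+" if a == HBA_ALLELE else "-" for a in hbs]
        for (rec, seq), pick, want in zip(
            emit_sequences(cohort, template), picks, want_states
        ):
            profile, codon6 = profile_sequence(seq, template.windows)
            assert profile.states == table.pattern(pick)
            assert codon6 == want

    def test_missing_template_window_names_locus(self, table, template):
        cohort = cohort_from_labels(["Benin"] * 2, table)
        crippled = type(template)(
            length=template.length,
            windows={k: v for k, v in template.windows.items()
                     if k != "HinfI_beta5"},
            variants=template.variants,
        )
        with pytest.raises(ValueError, match="HinfI_beta5"):
            emit_sequences(cohort, crippled)


def test_derive_seed_stable_and_stage_dependent():
    assert derive_seed(42, "panel") == derive_seed(42, "panel")
    assert derive_seed(42, "panel") != derive_seed(42, "cline")
    assert derive_seed(42, "panel") != derive_seed(43, "panel")
    assert 0 <= derive_seed(1, "x") < 2**31
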