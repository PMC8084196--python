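"""Frameshift / biallelic-knockout model, clone analysis, clone simulator."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprflp import (
    CloneRecord,
    EditingOutcomeModel,
    allele_disruption_prob,
    cell_ko_prob,
    clone_frameshift_rates,
    exact_frame_prob,
    simulate_clones,
    whole_percent,
)


class TestAlleleDisruptionProb:
    def test_closed_forms_at_default_parameters(self):
        m = EditingOutcomeModel()
        for n in (1, 2, 3):
            assert allele_disruption_prob(m, n) == pytest.approx(
                1 - (1 / 3) ** n
            )

    def test_whole_percent_reporting_conventions(self):
        m = EditingOutcomeModel()
        assert whole_percent(allele_disruption_prob(m, 1)) == 66
        assert whole_percent(allele_disruption_prob(m, 2), "nearest") == 89
        assert whole_percent(allele_disruption_prob(m, 3), "nearest") == 96

    def test_unedited_sites_contribute_nothing(self):
        assert allele_disruption_prob(EditingOutcomeModel(edit_prob=0.0), 2) == 0.0
        assert allele_disruption_prob(EditingOutcomeModel(), 0) == 0.0

    def test_per_site_edit_probabilities(self):
        m = EditingOutcomeModel(edit_prob=[1.0, 0.5], frameshift_fraction=2 / 3)
        # 1 - (1 - 2/3)(1 - 1/3) = 7/9
        assert allele_disruption_prob(m, 2) == pytest.approx(7 / 9)

    def test_monotone_in_sites_edit_prob_and_frameshift_fraction(self):
        for e, f in itertools.product([0.2, 0.6, 1.0], [0.1, 2 / 3, 1.0]):
            m = EditingOutcomeModel(edit_prob=e, frameshift_fraction=f)
            probs = [allele_disruption_prob(m, n) for n in range(5)]
            assert all(a <= b for a, b in zip(probs, probs[1:]))
        for f in (0.2, 0.5, 1.0):
            along_e = [
                allele_disruption_prob(
                    EditingOutcomeModel(edit_prob=e, frameshift_fraction=f), 2
                )
                for e in (0.2, 0.5, 1.0)
            ]
            assert along_e == sorted(along_e)
        for e in (0.2, 0.5, 1.0):
            along_f = [
                allele_disruption_prob(
                    EditingOutcomeModel(edit_prob=e, frameshift_fraction=f), 2
                )
                for f in (0.2, 0.5, 1.0)
            ]
            assert along_f == sorted(along_f)


class TestCellKoProb:
    def test_biallelic_values_at_defaults(self):
        m = EditingOutcomeModel()
        assert cell_ko_prob(m, 2) == pytest.approx((8 / 9) ** 2)
        assert whole_percent(cell_ko_prob(m, 2)) == 79
        assert cell_ko_prob(m, 3) == pytest.approx((26 / 27) ** 2)
        assert whole_percent(cell_ko_prob(m, 3)) == 92

    def test_haploid_equals_per_allele(self):
        m = EditingOutcomeModel(ploidy=1)
        for n in (1, 2, 3):
            assert cell_ko_prob(m, n) == allele_disruption_prob(m, n)


class TestExactFrameProb:
    def test_single_site_matches_any_site_model(self):
        m = EditingOutcomeModel()
        assert exact_frame_prob(m, 1) == pytest.approx(
            allele_disruption_prob(m, 1)
        )

    def test_two_sites_compensation_by_enumeration(self):
        # residues uniform over {0,1,2}: 3 of the 9 pairs sum to 0 mod 3
        m = EditingOutcomeModel()
        oracle = (
            sum(1 for a, b in itertools.product(range(3), repeat=2)
                if (a + b) % 3 != 0) / 9
        )
        assert exact_frame_prob(m, 2) == pytest.approx(oracle)
        assert oracle == pytest.approx(2 / 3)

    def test_in_frame_only_indels_never_shift(self):
        m = EditingOutcomeModel(indel_size_dist={3: 1.0})
        for n in (1, 2, 5):
            assert exact_frame_prob(m, n) == 0.0

    def test_brute_force_enumeration_oracle(self):
        # enumerate all (edited?, residue) combinations over 3 sites
        m = EditingOutcomeModel(
            edit_prob=0.8, indel_size_dist={1: 0.5, -1: 0.2, 3: 0.3}
        )
        residue_p = {0: 0.3, 1: 0.5, 2: 0.2}
        total_shift = 0.0
        for combo in itertools.product([None, 0, 1, 2], repeat=3):
            p = 1.0
            shift = 0
            for r in combo:
                if r is None:
                    p *= 0.2
                else:
                    p *= 0.8 * residue_p[r]
                    shift += r
            if shift % 3 != 0:
                total_shift += p
        assert exact_frame_prob(m, 3) == pytest.approx(total_shift)

    @settings(max_examples=50, derandomize=True)
    @given(
        e=st.floats(0, 1),
        f=st.floats(0, 1),
        n=st.integers(0, 6),
    )
    def test_never_exceeds_any_site_model(self, e, f, n):
        m = EditingOutcomeModel(edit_prob=e, frameshift_fraction=f)
        assert exact_frame_prob(m, n) <= allele_disruption_prob(m, n) + 1e-12


class TestCloneAnalysis:
    def _clones(self, both, only1, only2, none):
        records = []
        for i in range(both):
            records.append(CloneRecord(f"b{i}", (1, 2)))
        for i in range(only1):
            records.append(CloneRecord(f"o1{i}", (-1, 3)))
        for i in range(only2):
            records.append(CloneRecord(f"o2{i}", (0, 4)))
        for i in range(none):
            records.append(CloneRecord(f"n{i}", (0, -3)))
        return records

    def test_published_style_clone_counts(self):
        # 33 clones: site 1 frameshifted in 24, site 2 in 20, any in 29
        rates = clone_frameshift_rates(self._clones(15, 9, 5, 4))
        assert rates["per_site_percent"] == [72, 60]
        assert rates["combined_percent"] == 87
        assert rates["per_site"] == [pytest.approx(24 / 33),
                                     pytest.approx(20 / 33)]
        assert rates["combined"] == pytest.approx(29 / 33)

    def test_unedited_clones_rate_zero(self):
        clones = [CloneRecord(f"c{i}", (0, 0)) for i in range(5)]
        rates = clone_frameshift_rates(clones)
        assert rates["per_site"] == [0.0, 0.0]
        assert rates["combined"] == 0.0

    def test_combined_is_or_over_sites(self):
        clones = self._clones(2, 3, 4, 1)
        rates = clone_frameshift_rates(clones)
        by_hand = sum(
            1 for c in clones if any(s % 3 != 0 for s in c.indel_sizes)
        ) / len(clones)
        assert rates["combined"] == pytest.approx(by_hand)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="no clones"):
            clone_frameshift_rates([])


class TestSimulateClones:
    def test_combined_rate_matches_model_within_mc_error(self):
        m = EditingOutcomeModel()
        clones = simulate_clones(m, n_sites=2, n_clones=100_000, seed=42)
        rates = clone_frameshift_rates(clones)
        expected = 8 / 9
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(rates["combined"] - expected) < 3 * se

    def test_parameter_recovery_round_trip(self):
        # per-site rate estimates e * f; recover both at 1e5 clones
        e, f = 0.85, 0.5
        m = EditingOutcomeModel(edit_prob=e, frameshift_fraction=f)
        clones = simulate_clones(m, n_sites=2, n_clones=100_000, seed=7)
        edited_rate = np.mean([
            sum(s != 0 for s in c.indel_sizes) / 2 for c in clones
        ])
        rates = clone_frameshift_rates(clones)
        assert edited_rate == pytest.approx(e, abs=0.01)
        for r in rates["per_site"]:
            assert r == pytest.approx(e * f, abs=0.01)

    def test_zero_edit_prob_leaves_all_unedited(self):
        m = EditingOutcomeModel(edit_prob=0.0)
        clones = simulate_clones(m, 2, 100, seed=1)
        assert all(c.indel_sizes == (0, 0) for c in clones)

    def test_fixed_seed_bit_identical(self):
        m = EditingOutcomeModel()
        assert simulate_clones(m, 2, 500, seed=3) == simulate_clones(
            m, 2, 500, seed=3
        )


class TestModelValidation:
    def test_zero_size_indel_rejected(self):
        with pytest.raises(ValueError, match="size 0"):
            EditingOutcomeModel(indel_size_dist={0: 0.5, 1: 0.5})

    def test_unnormalized_distribution_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            EditingOutcomeModel(indel_size_dist={1: 0.5, 2: 0.4})

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            EditingOutcomeModel(edit_prob=1.5)
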