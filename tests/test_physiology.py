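"""Virtual-individual construction, obesity scaling, population sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tirzepbpk.errors import DomainError, ValidationError
from tirzepbpk.physiology import (
    ORGANS, SYSTEMIC_ORGANS, IndividualPhysiology, ObesityScaling,
    PopulationSpec, apply_obesity, bmi_percentile_95, build_individual,
    population_to_frame, reference_adult, sample_population,
)


class TestBuildIndividual:
    def test_reference_adult_matches_training_cohort(self):
        adult = reference_adult()
        assert adult.body_weight == pytest.approx(72.0)
        assert 24.0 < adult.bmi < 25.5  # BMI of the Asian training cohorts

    def test_sampled_adult_weight_plausible(self):
        adult = build_individual(30, "male", "normal", seed=1)
        assert 55 < adult.body_weight < 90

    @pytest.mark.parametrize("age,sex,wc", [
        (30, "male", "normal"), (10, "female", "normal"),
        (12, "female", "obese"), (17.5, "male", "obese"),
    ])
    def test_invariants_hold(self, age, sex, wc):
        ind = build_individual(age, sex, wc, seed=3)
        ind.validate()  # raises on violation
        assert set(ind.organ_volumes) == set(ORGANS)
        assert sum(ind.organ_blood_flows.values()) <= ind.cardiac_output * (1 + 1e-9)
        assert abs(sum(ind.organ_volumes.values()) - ind.body_weight) \
            <= 0.01 * ind.body_weight

    def test_obese_individual_exceeds_95th_percentile(self):
        ind = build_individual(12, "female", "obese", seed=7)
        assert ind.bmi > bmi_percentile_95(12, "female")

    def test_age_below_support_rejected(self):
        with pytest.raises(DomainError):
            build_individual(5, "male")

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValidationError):
            build_individual(12, "other")

    @pytest.mark.parametrize("sex", ["male", "female"])
    @pytest.mark.parametrize("wc", ["normal", "obese"])
    def test_growth_monotone_over_pediatric_ages(self, sex, wc):
        """Body weight and every organ volume grow with age (fixed seed)."""
        ages = np.arange(10.0, 18.01, 0.5)
        prev = None
        for age in ages:
            ind = build_individual(age, sex, wc, seed=3)
            if prev is not None:
                assert ind.body_weight >= prev.body_weight
                for organ in ORGANS:
                    assert ind.organ_volumes[organ] >= prev.organ_volumes[organ] * (1 - 1e-12)
            prev = ind

    def test_organs_strictly_larger_at_15_than_10(self):
        young = build_individual(10, "male", "normal", seed=3)
        old = build_individual(15, "male", "normal", seed=3)
        for organ in ORGANS:
            assert old.organ_volumes[organ] > young.organ_volumes[organ]


class TestApplyObesity:
    def test_kidney_and_liver_scale_by_factor(self):
        ind = build_individual(12, "male", "normal", seed=5)
        target = ind.body_weight * 1.3
        obese = apply_obesity(ind, ObesityScaling(), target)
        assert obese.organ_volumes["kidney"] == pytest.approx(
            ind.organ_volumes["kidney"] * 1.15)
        assert obese.organ_volumes["liver"] == pytest.approx(
            ind.organ_volumes["liver"] * 1.15)

    def test_gfr_scales_with_kidney_volume(self):
        ind = build_individual(14, "female", "normal", seed=5)
        obese = apply_obesity(ind, ObesityScaling(), ind.body_weight * 1.25)
        assert obese.gfr == pytest.approx(ind.gfr * 1.15)

    def test_mass_conservation(self):
        ind = build_individual(11, "male", "normal", seed=2)
        target = ind.body_weight * 1.4
        obese = apply_obesity(ind, ObesityScaling(), target)
        assert sum(obese.organ_volumes.values()) == pytest.approx(target, rel=1e-9)

    def test_identity_scaling_is_noop(self):
        ind = build_individual(13, "male", "normal", seed=9)
        identity = ObesityScaling(organ_volume_factors={o: 1.0 for o in ORGANS
                                                        if o != "adipose"})
        same = apply_obesity(ind, identity, ind.body_weight)
        for organ in ORGANS:
            assert same.organ_volumes[organ] == pytest.approx(
                ind.organ_volumes[organ], rel=1e-12)
        assert same.gfr == pytest.approx(ind.gfr)
        assert same.weight_class == "normal"

    def test_flows_rescale_with_volumes(self):
        ind = build_individual(12, "male", "normal", seed=5)
        obese = apply_obesity(ind, ObesityScaling(), ind.body_weight * 1.3)
        for organ in SYSTEMIC_ORGANS:
            expected = (ind.organ_blood_flows[organ]
                        * obese.organ_volumes[organ] / ind.organ_volumes[organ])
            assert obese.organ_blood_flows[organ] == pytest.approx(expected)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValidationError):
            ObesityScaling(organ_volume_factors={"kidney": 0.9})


class TestSamplePopulation:
    def test_counts_and_age_range(self):
        spec = PopulationSpec(50, 50, (10, 12), "normal", seed=42)
        pop = sample_population(spec)
        assert len(pop) == 100
        assert sum(1 for p in pop if p.sex == "female") == 50
        assert all(10 <= p.age_years <= 12 for p in pop)

    def test_seeded_determinism_bit_identical(self):
        spec = PopulationSpec(1, 0, (10, 10), "normal", seed=1)
        a = population_to_frame(sample_population(spec))
        b = population_to_frame(sample_population(spec))
        pd.testing.assert_frame_equal(a, b)

    def test_obese_population_above_percentile_curve(self):
        spec = PopulationSpec(10, 10, (15, 18), "obese", seed=9)
        for ind in sample_population(spec):
            assert ind.bmi > bmi_percentile_95(ind.age_years, ind.sex)

    def test_empty_population_rejected(self):
        with pytest.raises(ValidationError):
            PopulationSpec(0, 0, (10, 12))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(age=st.floats(10, 18), seed=st.integers(0, 2**31 - 1))
def test_bmi_consistency_property(age, seed):
    ind = build_individual(age, "female", "normal", seed=seed)
    assert ind.bmi == pytest.approx(
        ind.body_weight / (ind.height / 100.0) ** 2, abs=1e-9)
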