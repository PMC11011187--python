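"""Mass-balance fluxes, apparent digestibility, and the difference method."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedeval.digestibility import (
    DigestibilityError,
    NutrientFlux,
    apparent_digestibility,
    assert_mass_conservation,
    diet_digestibility,
    difference_method,
    ingredient_digestibility,
    nutrient_flux,
    nutrient_share,
)
from feedeval.simulate import simulate_trial
from feedeval.trial import NUTRIENTS, AnimalDayRecord, ProximateProfile
from tests.conftest import make_single_nutrient_dataset, random_truth_config


class TestNutrientFlux:
    def test_week_of_constant_feeding(self, dm_basis_diet_profile):
        # 7 d x 100 g offered, nothing refused, DM 90%, CP 12% of DM
        dataset = make_single_nutrient_dataset({"a1": 80.0})
        dataset.diet_profile = dm_basis_diet_profile
        dataset.records = [
            AnimalDayRecord("a1", day, 100.0, 0.0, 20.0, 0.5)
            for day in range(1, 8)]
        flux = nutrient_flux(dataset, "a1")
        assert flux.intake_g["cp"] == pytest.approx(75.6)   # 7*100*0.9*0.12
        assert flux.intake_g["dm"] == pytest.approx(630.0)

    def test_fully_refused_day_contributes_nothing(self, dm_basis_diet_profile):
        dataset = make_single_nutrient_dataset({"a1": 80.0})
        dataset.diet_profile = dm_basis_diet_profile
        base = [AnimalDayRecord("a1", 1, 100.0, 0.0, 0.0, 0.5)]
        with_refused = base + [AnimalDayRecord("a1", 2, 80.0, 80.0, 0.0, 0.5)]
        dataset.records = base
        reference = nutrient_flux(dataset, "a1").intake_g
        dataset.records = with_refused
        assert nutrient_flux(dataset, "a1").intake_g == reference

    def test_unknown_animal_raises_lookup_error(self):
        dataset = make_single_nutrient_dataset({"a1": 80.0})
        with pytest.raises(KeyError):
            nutrient_flux(dataset, "ghost")

    def test_matches_naive_daily_summation(self, rng):
        """Simulated fluxes equal an independent day-by-day loop."""
        config = random_truth_config(rng, seed=5, noise=True)
        dataset, _ = simulate_trial(config)
        for animal_id in dataset.animals():
            flux = nutrient_flux(dataset, animal_id)
            diet = dataset.diet_profile
            feces = dataset.fecal_profiles[animal_id]
            expected_i = {n: 0.0 for n in NUTRIENTS}
            expected_f = {n: 0.0 for n in NUTRIENTS}
            for r in dataset.records:
                if r.animal_id != animal_id:
                    continue
                eaten = r.offered_g - r.refused_g
                fdm = r.feces_fresh_g * r.feces_dm_fraction
                expected_i["dm"] += eaten * diet.dm_pct / 100
                expected_f["dm"] += fdm
                for n in ("cp", "ee", "cf", "nfe"):
                    expected_i[n] += eaten * diet.component(n) / 100
                    expected_f[n] += fdm * feces.component(n) / 100
            for n in NUTRIENTS:
                assert flux.intake_g[n] == pytest.approx(expected_i[n])
                assert flux.fecal_g[n] == pytest.approx(expected_f[n])


class TestApparentDigestibility:
    @pytest.mark.parametrize("intake,fecal,expected", [
        (75.6, 0.0, 100.0),     # no excretion
        (100.0, 25.0, 75.0),
        (80.0, 88.0, -10.0),    # negative apparent digestibility is legal
    ])
    def test_definition(self, intake, fecal, expected):
        flux = NutrientFlux("a", {"cp": intake}, {"cp": fecal})
        assert apparent_digestibility(flux, ("cp",))["cp"] == pytest.approx(
            expected)

    def test_zero_intake_names_the_nutrient(self):
        flux = NutrientFlux("a", {"cp": 0.0}, {"cp": 0.0})
        with pytest.raises(DigestibilityError, match="cp"):
            apparent_digestibility(flux, ("cp",))

    def test_mass_conservation_identity(self, rng):
        config = random_truth_config(rng, seed=8, noise=True)
        dataset, _ = simulate_trial(config)
        for animal_id in dataset.animals():
            flux = nutrient_flux(dataset, animal_id)
            assert_mass_conservation(flux, apparent_digestibility(flux))


class TestDietDigestibility:
    def test_identical_animals_have_zero_sd(self):
        dataset = make_single_nutrient_dataset({f"a{i}": 80.0 for i in range(5)})
        coeffs = diet_digestibility(dataset)
        assert coeffs.mean_pct["cp"] == pytest.approx(80.0)
        assert coeffs.sd_pct["cp"] == 0.0

    def test_mean_and_sample_sd(self):
        dataset = make_single_nutrient_dataset(
            {"a1": 70.0, "a2": 75.0, "a3": 80.0})
        coeffs = diet_digestibility(dataset)
        assert coeffs.mean_pct["cp"] == pytest.approx(75.0)
        assert coeffs.sd_pct["cp"] == pytest.approx(5.0)   # n-1 denominator
        assert coeffs.n_animals == 3

    def test_noise_free_trial_recovers_truth_exactly(self, rcm_config):
        dataset, truth = simulate_trial(rcm_config)
        coeffs = diet_digestibility(dataset)
        for nutrient, expected in truth["diet_digestibility"].items():
            assert coeffs.mean_pct[nutrient] == pytest.approx(
                expected, rel=1e-12)

    def test_pooled_aggregation_is_ratio_of_totals(self):
        dataset = make_single_nutrient_dataset({"a1": 70.0, "a2": 80.0})
        pooled = diet_digestibility(dataset, aggregate="pooled")
        # equal intakes of 100 g: pooled ratio equals the mean here
        assert pooled.mean_pct["cp"] == pytest.approx(75.0)
        assert pooled.sd_pct["cp"] == 0.0


class TestNutrientShare:
    def test_published_protein_share(self):
        ref = ProximateProfile("ref", 91, 12, 4, 5.8, 75.7, 2.5)
        ing = ProximateProfile("ing", 85, 15, 5.5, 38, 30.5, 11)
        shares = nutrient_share(ref, ing, 0.8)
        assert shares["cp"] == pytest.approx(9.6 / 12.6)

    def test_ingredient_lacking_nutrient_gives_share_one(self):
        ref = ProximateProfile("ref", 91, 12, 4, 5.8, 75.7, 2.5)
        ing = ProximateProfile("ing", 92, 72.4, 0.5, 0, 0, 4,
                               cf_absent=True, nfe_absent=True)
        shares = nutrient_share(ref, ing, 0.8)
        assert shares["cf"] == 1.0 and shares["nfe"] == 1.0

    def test_equal_concentrations_reduce_to_diet_fraction(self):
        profile = ProximateProfile("p", 90, 12, 4, 6, 70, 8)
        other = ProximateProfile("q", 90, 12, 4, 6, 70, 8)
        shares = nutrient_share(profile, other, 0.8)
        for nutrient in ("dm", "cp", "ee", "cf", "nfe"):
            assert shares[nutrient] == pytest.approx(0.8)


class TestDifferenceMethod:
    def test_blend_equal_to_parts(self):
        d = {"cp": 70.0}
        for s in (0.1, 0.5, 0.9):
            out = difference_method(d, d, {"cp": s})
            assert out["cp"] == pytest.approx(70.0)

    def test_zero_share_returns_diet_value(self):
        out = difference_method({"cp": 83.0}, {"cp": 20.0}, {"cp": 0.0})
        assert out["cp"] == 83.0

    def test_share_one_reports_absent(self, caplog):
        out = difference_method({"cf": 50.0}, {"cf": 40.0}, {"cf": 1.0})
        assert out["cf"] is None

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0),
           st.floats(0.0, 0.99), st.floats(0.01, 20.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_in_diet_digestibility(self, d_diet, d_ref,
                                                       share, delta):
        lo = difference_method({"cp": d_diet}, {"cp": d_ref}, {"cp": share})
        hi = difference_method({"cp": d_diet + delta}, {"cp": d_ref},
                               {"cp": share})
        assert hi["cp"] > lo["cp"]

    def test_recovers_planted_ingredient_digestibility(self):
        """Forward blend then inversion: 78% ref, 92% ingredient, s=9.6/12.6."""
        s = 9.6 / 12.6
        d_diet = s * 78.0 + (1 - s) * 92.0
        out = difference_method({"cp": d_diet}, {"cp": 78.0}, {"cp": s})
        assert out["cp"] == pytest.approx(92.0, abs=1e-12)

    def test_noise_free_exact_inversion(self, rng):
        """Generator truths recovered to >= 10 significant digits."""
        for seed in range(5):
            config = random_truth_config(rng, seed=100 + seed)
            dataset, truth = simulate_trial(config)
            ref_coeffs = diet_digestibility(
                make_reference_dataset(config))
            coeffs = ingredient_digestibility(
                dataset, ref_coeffs, config.reference_profile,
                config.ingredient_profile)
            for nutrient, expected in truth["ingredient_digestibility"].items():
                assert coeffs.mean_pct[nutrient] == pytest.approx(
                    expected, rel=1e-10)


def make_reference_dataset(config):
    """Simulate the matching pure-reference trial for a test config."""
    from dataclasses import replace

    ref_config = replace(config, inclusion_fraction=0.0,
                         ingredient_profile=None,
                         ingredient_digestibility={},
                         diet_id="T0", seed=config.seed + 10_000)
    dataset, _ = simulate_trial(ref_config)
    return dataset
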