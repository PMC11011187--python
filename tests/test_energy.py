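"""The digestible-component / TDN / DE / ME chain and ration blending."""

import numpy as np
import pytest

from feedeval import refdata, tables
from feedeval.digestibility import DigestibilityCoefficients
from feedeval.energy import (
    blend_diet_profile,
    digestible_fraction,
    energy_from_tdn,
    ingredient_energy_profile,
    tdn,
    to_dry_matter_basis,
)
from feedeval.trial import EnergyConstants, ProximateProfile


class TestDigestibleFraction:
    @pytest.mark.parametrize("component,dig,expected,tol", [
        (15.00, 67.65, 10.15, 0.005),   # rumen-content meal protein
        (62.64, 71.10, 44.54, 0.005),   # ear meal protein
    ])
    def test_published_protein_cells(self, component, dig, expected, tol):
        assert digestible_fraction(component, dig) == pytest.approx(
            expected, abs=tol)

    def test_full_digestibility_leaves_component_unchanged(self):
        assert digestible_fraction(38.0, 100.0) == 38.0


class TestTdn:
    def test_rumen_content_row(self):
        # printed digestible components in, printed TDN out
        value = tdn(10.15, 4.55, 34.78, 23.76)
        assert value == pytest.approx(78.93, abs=0.02)

    def test_ear_meal_row_with_absent_terms(self):
        assert tdn(44.54, 21.08, 0.0, 0.0) == pytest.approx(91.97, abs=0.02)

    def test_all_zero(self):
        assert tdn(0, 0, 0, 0) == 0.0

    def test_fat_weight_is_configurable(self):
        constants = EnergyConstants(ee_weight=3.0)
        assert tdn(0, 10, 0, 0, constants) == 30.0


class TestEnergyFromTdn:
    @pytest.mark.parametrize("tdn_pct,de,me", [
        (78.93, 3480.0, 2853.0),
        (93.65, 4129.0, 3386.0),
    ])
    def test_published_values(self, tdn_pct, de, me):
        got_de, got_me = energy_from_tdn(tdn_pct)
        assert got_de == pytest.approx(de, abs=2)
        assert got_me == pytest.approx(me, abs=2)

    def test_zero(self):
        assert energy_from_tdn(0.0) == (0.0, 0.0)


class TestIngredientEnergyProfile:
    def test_matches_term_by_term_oracle(self, rng):
        """Random inputs reproduce an independent brute-force recomputation."""
        for _ in range(20):
            comp = {n: rng.uniform(1, 40) for n in ("cp", "ee", "cf", "nfe")}
            digestibility = {n: rng.uniform(30, 99)
                             for n in ("dm", "cp", "ee", "cf", "nfe")}
            profile = ProximateProfile(
                "x", dm_pct=rng.uniform(80, 95), ash_pct=5.0,
                **{f"{n}_pct": v for n, v in comp.items()})
            coeffs = DigestibilityCoefficients(
                "x", mean_pct=digestibility,
                sd_pct={n: 0.0 for n in digestibility}, n_animals=9)
            ep = ingredient_energy_profile(profile, coeffs)
            expected_tdn = (comp["cp"] * digestibility["cp"]
                            + 2.25 * comp["ee"] * digestibility["ee"]
                            + comp["cf"] * digestibility["cf"]
                            + comp["nfe"] * digestibility["nfe"]) / 100.0
            assert ep.tdn_pct == pytest.approx(expected_tdn, rel=1e-12)
            assert ep.de_kcal_kg == pytest.approx(expected_tdn * 44.09)
            assert ep.me_kcal_kg == pytest.approx(expected_tdn * 44.09 * 0.82)
            assert ep.digestible_pct["dm"] == pytest.approx(
                profile.dm_pct * digestibility["dm"] / 100.0)

    def test_full_digestibility_returns_composition(self):
        profile = refdata.MEAL_COMPOSITIONS["RCM"]
        coeffs = DigestibilityCoefficients(
            "RCM", mean_pct={n: 100.0 for n in ("dm", "cp", "ee", "cf", "nfe")},
            sd_pct={}, n_animals=9)
        ep = ingredient_energy_profile(profile, coeffs)
        assert ep.digestible_pct["cp"] == profile.cp_pct
        assert ep.digestible_pct["cf"] == profile.cf_pct

    def test_absent_components_contribute_zero(self):
        ep = tables.energy_chain("BM")
        assert ep.digestible_pct["cf"] == 0.0
        assert "cf" in ep.absent and "nfe" in ep.absent

    def test_rumen_content_row_reproduces_fully(self):
        """The one published row that closes from composition x coefficients."""
        ep = tables.energy_chain("RCM")
        expected = refdata.EXPECTED_ENERGY["RCM"]
        for nutrient, key in (("dm", "ddm"), ("cp", "dcp"), ("ee", "dee"),
                              ("cf", "dcf"), ("nfe", "dnfe")):
            assert ep.digestible_pct[nutrient] == pytest.approx(
                expected[key], abs=0.02)
        assert ep.tdn_pct == pytest.approx(expected["tdn"], abs=0.02)
        assert ep.de_kcal_kg == pytest.approx(expected["de"], abs=2)
        assert ep.me_kcal_kg == pytest.approx(expected["me"], abs=2)

    def test_sd_propagation_is_linear_in_each_stage(self):
        ep = tables.energy_chain("RCM")
        sd = refdata.MEAL_DIGESTIBILITY_SD["RCM"]
        comp = refdata.MEAL_COMPOSITIONS["RCM"]
        assert ep.digestible_sd["cp"] == pytest.approx(
            comp.cp_pct * sd["cp"] / 100.0)
        assert ep.de_sd == pytest.approx(ep.tdn_sd * 44.09)
        assert ep.me_sd == pytest.approx(ep.de_sd * 0.82)


class TestBlending:
    def test_published_ration_cells(self):
        blended, me = blend_diet_profile(
            [refdata.BARLEY, refdata.MEAL_COMPOSITIONS["RCM"]], [0.8, 0.2],
            me_values=[refdata.BARLEY_ME, refdata.MEAL_ME["RCM"]])
        assert blended.cp_pct == pytest.approx(12.60)
        assert me == pytest.approx(2877.80)

    def test_degenerate_fractions_return_reference(self):
        # a (1, 0) blend is disallowed by the fraction domain; blending a
        # profile with itself is the equivalent identity
        blended, _ = blend_diet_profile(
            [refdata.BARLEY, refdata.BARLEY], [0.7, 0.3])
        for name in ("dm", "cp", "ee", "cf", "nfe", "ash"):
            assert blended.component(name) == pytest.approx(
                refdata.BARLEY.component(name))

    def test_blending_commutes_with_digestible_fraction(self, rng):
        """For shared coefficients, blend-then-digest == digest-then-blend."""
        a = refdata.BARLEY
        b = refdata.MEAL_COMPOSITIONS["RCM"]
        blended, _ = blend_diet_profile([a, b], [0.8, 0.2])
        for nutrient in ("cp", "ee", "cf", "nfe"):
            d = rng.uniform(30, 99)
            direct = digestible_fraction(blended.component(nutrient), d)
            parts = (0.8 * digestible_fraction(a.component(nutrient), d)
                     + 0.2 * digestible_fraction(b.component(nutrient), d))
            assert direct == pytest.approx(parts, rel=1e-12)

    def test_absent_only_when_all_parts_absent(self):
        blended, _ = blend_diet_profile(
            [refdata.BARLEY, refdata.MEAL_COMPOSITIONS["BM"]], [0.8, 0.2])
        assert not blended.cf_absent       # barley supplies crude fiber
        blended2, _ = blend_diet_profile(
            [refdata.MEAL_COMPOSITIONS["BM"], refdata.MEAL_COMPOSITIONS["CM"]],
            [0.5, 0.5])
        assert blended2.cf_absent and blended2.nfe_absent


def test_dry_matter_basis_conversion_scales_components():
    profile = refdata.MEAL_COMPOSITIONS["RCM"]
    dm = to_dry_matter_basis(profile)
    assert dm.basis == "dry_matter"
    assert dm.cp_pct == pytest.approx(profile.cp_pct * 100 / profile.dm_pct)
    assert to_dry_matter_basis(dm) is dm
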