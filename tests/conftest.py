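"""Shared fixtures: small handmade datasets and simulated trials."""

import numpy as np
import pytest

from feedeval.refdata import (
    BARLEY,
    MEAL_COMPOSITIONS,
    MEAL_DIGESTIBILITY,
    REFERENCE_TRUE_DIGESTIBILITY,
)
from feedeval.simulate import TrialSimConfig, simulate_trial, study_configs
from feedeval.trial import (
    AnimalDayRecord,
    DietSpec,
    ProximateProfile,
    TrialDataset,
)


@pytest.fixture
def dm_basis_diet_profile():
    """Diet with CP 12% of DM, DM 90% — the classic worked flux example."""
    return ProximateProfile("diet", dm_pct=90.0, cp_pct=12.0, ee_pct=4.0,
                            cf_pct=6.0, nfe_pct=70.0, ash_pct=8.0,
                            basis="dry_matter")


def make_single_nutrient_dataset(digestibilities):
    """One-day trial whose DM is pure protein: D_dm == D_cp == given value.

    ``digestibilities`` maps animal id -> desired apparent digestibility in
    percent; intake is fixed at 100 g DM so fecal DM is 100 - D.
    """
    profile = ProximateProfile("purecp", dm_pct=100.0, cp_pct=100.0,
                               ee_pct=0.0, cf_pct=0.0, nfe_pct=0.0,
                               ash_pct=0.0, basis="dry_matter")
    fecal = ProximateProfile("feces", dm_pct=100.0, cp_pct=100.0, ee_pct=0.0,
                             cf_pct=0.0, nfe_pct=0.0, ash_pct=0.0,
                             basis="dry_matter")
    records, weights, fecal_profiles = [], {}, {}
    for animal_id, d in digestibilities.items():
        records.append(AnimalDayRecord(animal_id, 1, offered_g=100.0,
                                       refused_g=0.0,
                                       feces_fresh_g=100.0 - d,
                                       feces_dm_fraction=1.0))
        weights[animal_id] = (800.0, 830.0)
        fecal_profiles[animal_id] = fecal
    diet = DietSpec("D", [("purecp", 1.0)], role="reference")
    return TrialDataset(diet=diet, diet_profile=profile,
                        fecal_profiles=fecal_profiles, records=records,
                        weights=weights)


@pytest.fixture
def rcm_config():
    """Noise-free rumen-content-meal treatment (all five nutrients)."""
    return TrialSimConfig(
        reference_profile=BARLEY,
        reference_digestibility=REFERENCE_TRUE_DIGESTIBILITY,
        ingredient_profile=MEAL_COMPOSITIONS["RCM"],
        ingredient_digestibility=MEAL_DIGESTIBILITY["RCM"],
        diet_id="T1", seed=11)


@pytest.fixture
def simulated_study():
    """All five study treatments, noise-free, with truth records."""
    out = {}
    for config in study_configs(seed=3):
        dataset, truth = simulate_trial(config)
        out[config.diet_id] = (dataset, truth, config)
    return out


def random_truth_config(rng, seed, noise=False):
    """A random but feasible truth configuration for inversion testing.

    Compositions are drawn so that every nutrient is present in both feeds
    and the reference's nutrient-intake share stays below ~0.99, keeping the
    difference-method inversion well conditioned.
    """
    def profile(name):
        parts = rng.uniform(5.0, 40.0, size=4)
        parts = parts / parts.sum() * rng.uniform(80.0, 95.0)
        return ProximateProfile(
            name, dm_pct=rng.uniform(85.0, 95.0),
            cp_pct=parts[0], ee_pct=parts[1], cf_pct=parts[2],
            nfe_pct=parts[3], ash_pct=rng.uniform(2.0, 5.0))

    # digestibilities low enough that fecal DM always covers the organics
    d_ref = {n: rng.uniform(40.0, 70.0) for n in ("cp", "ee", "cf", "nfe")}
    d_ref["dm"] = rng.uniform(30.0, 45.0)
    d_ing = {n: rng.uniform(40.0, 70.0) for n in ("cp", "ee", "cf", "nfe")}
    d_ing["dm"] = rng.uniform(30.0, 45.0)
    return TrialSimConfig(
        reference_profile=profile("ref"),
        reference_digestibility=d_ref,
        ingredient_profile=profile("ing"),
        ingredient_digestibility=d_ing,
        inclusion_fraction=rng.uniform(0.1, 0.5),
        refusal_fraction_mean=rng.uniform(0.0, 0.4),
        fecal_noise_cv=0.05 if noise else 0.0,
        diet_id="R", seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)
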