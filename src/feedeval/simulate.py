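"""Forward simulator of metabolic-cage digestibility trials.

The generator runs the trial's mass balance forwards from known "true"
digestibilities, so every downstream stage (flux bookkeeping, apparent
digestibility, the difference-method inversion, group statistics) can be
tested against ground truth without any external data.  Per animal and day:
offered feed and refusals are drawn, nutrient intakes follow from the
blended ration, each nutrient's fecal output is intake times the animal's
indigestibility (the blend of reference and ingredient truths through
nutrient-intake shares, plus a per-animal deviation), and fecal fresh mass
and pooled composition are back-computed.  Measurement noise — multiplicative
on fecal fresh mass, additive (percentage points) on fecal composition — is
applied last, leaving the stored truth record untouched.

With all noise and deviations at zero the analyzer inverts the generator
exactly; this generator/analyzer adjointness is the backbone of the test
suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import refdata
from .digestibility import nutrient_share
from .energy import blend_diet_profile
from .trial import (
    NUTRIENTS,
    AnimalDayRecord,
    DietSpec,
    FeedEvalError,
    ProximateProfile,
    TrialDataset,
)


logger = logging.getLogger(__name__)


class SimulationConfigError(FeedEvalError):
    """The configuration implies an impossible trial (e.g. negative feces)."""


@dataclass
class TrialSimConfig:
    """Ground truth and sampling plan for one simulated treatment.

    ``animal_sd_pp`` is the sd (percentage points) of a per-animal,
    per-nutrient deviation added to the diet-level true digestibility —
    biological animal-to-animal variation.  ``fecal_noise_cv`` is the
    day-level coefficient of variation of the measured fecal fresh mass;
    ``fecal_composition_noise_pp`` the sd of additive error on the pooled
    fecal composition.  ``seed`` is mandatory: every simulated trial is
    reproducible by construction.
    """

    reference_profile: ProximateProfile
    reference_digestibility: dict[str, float]
    seed: int
    ingredient_profile: ProximateProfile | None = None
    ingredient_digestibility: dict[str, float] = field(default_factory=dict)
    diet_id: str = "T"
    n_animals: int = refdata.N_ANIMALS
    n_days: int = refdata.N_DAYS
    inclusion_fraction: float = refdata.INCLUSION_FRACTION
    offered_g_mean: float = 40.0
    offered_g_cv: float = 0.10
    refusal_fraction_mean: float = 0.25
    refusal_fraction_cv: float = 0.30
    animal_sd_pp: float | dict[str, float] = 0.0
    fecal_noise_cv: float = 0.0
    fecal_composition_noise_pp: float = 0.0
    fecal_dm_fraction: float = 0.35
    body_weight_mean: float = refdata.BODY_WEIGHT_MEAN
    body_weight_sd: float = refdata.BODY_WEIGHT_SD
    daily_gain_mean: float = 6.0
    daily_gain_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationConfigError("seed is mandatory")
        if not 0.0 <= self.inclusion_fraction < 1.0:
            raise SimulationConfigError(
                f"inclusion_fraction {self.inclusion_fraction} outside [0, 1)")
        if self.inclusion_fraction > 0 and self.ingredient_profile is None:
            raise SimulationConfigError(
                "inclusion_fraction > 0 requires an ingredient profile")
        if not 0.0 <= self.refusal_fraction_mean < 1.0:
            raise SimulationConfigError("refusal fraction outside [0, 1)")
        for name in ("offered_g_cv", "refusal_fraction_cv", "fecal_noise_cv",
                     "fecal_composition_noise_pp"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if not 0.0 < self.fecal_dm_fraction <= 1.0:
            raise SimulationConfigError("fecal_dm_fraction outside (0, 1]")

    def deviation_sd(self, nutrient: str) -> float:
        if isinstance(self.animal_sd_pp, dict):
            return self.animal_sd_pp.get(nutrient, 0.0)
        return float(self.animal_sd_pp)

    def with_seed(self, seed: int) -> "TrialSimConfig":
        return replace(self, seed=seed)


def true_diet_digestibility(config: TrialSimConfig,
                            ) -> tuple[ProximateProfile, dict[str, float],
                                       dict[str, float | None]]:
    """Blend profile, true diet-level digestibility and nutrient shares.

    The diet's true digestibility of each nutrient is the share-weighted
    blend s*D_ref + (1-s)*D_ing; nutrients the ingredient does not supply
    (share 1) digest at the reference value alone.
    """
    if config.inclusion_fraction == 0.0 or config.ingredient_profile is None:
        diet_profile = config.reference_profile.with_values(
            ingredient_id=config.diet_id)
        shares: dict[str, float | None] = {
            n: 1.0 for n in NUTRIENTS
            if not config.reference_profile.is_absent(n)}
        return diet_profile, dict(config.reference_digestibility), shares

    ref_fraction = 1.0 - config.inclusion_fraction
    diet_profile, _ = blend_diet_profile(
        [config.reference_profile, config.ingredient_profile],
        [ref_fraction, config.inclusion_fraction], diet_id=config.diet_id)
    shares = nutrient_share(config.reference_profile,
                            config.ingredient_profile, ref_fraction)
    truth: dict[str, float] = {}
    for nutrient, share in shares.items():
        if share is None:
            continue
        d_ref = config.reference_digestibility[nutrient]
        if share >= 1.0:
            truth[nutrient] = d_ref
        else:
            d_ing = config.ingredient_digestibility[nutrient]
            truth[nutrient] = share * d_ref + (1.0 - share) * d_ing
    return diet_profile, truth, shares


def simulate_trial(config: TrialSimConfig,
                   ) -> tuple[TrialDataset, dict]:
    """Draw one treatment's dataset; returns (dataset, truth record).

    The truth record holds the seed, the shares, the diet-level and
    ingredient-level true digestibilities and each animal's realized
    (deviation-shifted) values — everything a recovery test needs.
    Configurations whose truths imply negative fecal mass for any nutrient
    are rejected with a :class:`SimulationConfigError`.
    """
    rng = np.random.default_rng(config.seed)
    diet_profile, diet_truth, shares = true_diet_digestibility(config)
    nutrients = [n for n in NUTRIENTS if not diet_profile.is_absent(n)]

    if config.inclusion_fraction > 0:
        diet = DietSpec(
            diet_id=config.diet_id,
            components=[
                (config.reference_profile.ingredient_id,
                 1.0 - config.inclusion_fraction),
                (config.ingredient_profile.ingredient_id,
                 config.inclusion_fraction),
            ],
            role="test",
            test_ingredient=config.ingredient_profile.ingredient_id,
            reference_diet=config.reference_profile.ingredient_id)
    else:
        diet = DietSpec(
            diet_id=config.diet_id,
            components=[(config.reference_profile.ingredient_id, 1.0)],
            role="reference")

    records: list[AnimalDayRecord] = []
    fecal_profiles: dict[str, ProximateProfile] = {}
    weights: dict[str, tuple[float, float]] = {}
    per_animal_truth: dict[str, dict[str, float]] = {}

    for index in range(config.n_animals):
        animal_id = f"{config.diet_id}-a{index + 1}"
        d_animal = {}
        for nutrient in nutrients:
            deviation = rng.normal(0.0, config.deviation_sd(nutrient)) \
                if config.deviation_sd(nutrient) > 0 else 0.0
            d_animal[nutrient] = diet_truth[nutrient] + deviation
            if d_animal[nutrient] > 100.0:
                raise SimulationConfigError(
                    f"{animal_id}: true {nutrient} digestibility "
                    f"{d_animal[nutrient]:.2f} > 100 implies negative fecal "
                    "mass; lower the truth or the per-animal deviation sd")
        per_animal_truth[animal_id] = d_animal

        fecal_totals = {n: 0.0 for n in nutrients}
        for day in range(1, config.n_days + 1):
            offered = rng.normal(config.offered_g_mean,
                                 config.offered_g_mean * config.offered_g_cv)
            offered = max(offered, 0.01 * config.offered_g_mean)
            refusal = rng.normal(
                config.refusal_fraction_mean,
                config.refusal_fraction_mean * config.refusal_fraction_cv) \
                if config.refusal_fraction_mean > 0 else 0.0
            refusal = float(np.clip(refusal, 0.0, 0.95))
            consumed = offered * (1.0 - refusal)

            day_fecal = {}
            for nutrient in nutrients:
                if nutrient == "dm":
                    intake = consumed * diet_profile.dm_pct / 100.0
                else:
                    intake = consumed * diet_profile.component(nutrient) / 100.0
                day_fecal[nutrient] = intake * (1.0 - d_animal[nutrient] / 100.0)
            for nutrient, mass in day_fecal.items():
                if mass < 0:
                    raise SimulationConfigError(
                        f"{animal_id} day {day}: negative fecal {nutrient} "
                        f"mass {mass:.4f} g; digestibility truth above 100")
            organic = sum(v for n, v in day_fecal.items() if n != "dm")
            if organic > day_fecal["dm"] + 1e-9 and day == 1:
                # tolerated: published coefficient sets need not satisfy an
                # exact component/DM mass balance (implied fecal ash < 0)
                logger.warning(
                    "%s: fecal organic components exceed fecal DM; truths "
                    "are not mass-balance consistent, proceeding",
                    animal_id)
            for nutrient in nutrients:
                fecal_totals[nutrient] += day_fecal[nutrient]

            fresh = day_fecal["dm"] / config.fecal_dm_fraction
            if config.fecal_noise_cv > 0:
                fresh *= max(1.0 + rng.normal(0.0, config.fecal_noise_cv), 0.05)
            records.append(AnimalDayRecord(
                animal_id=animal_id, day=day,
                offered_g=offered, refused_g=offered - consumed,
                feces_fresh_g=fresh,
                feces_dm_fraction=config.fecal_dm_fraction))

        # pooled 7-day fecal composition on a DM basis
        composition = {}
        for nutrient in nutrients:
            if nutrient == "dm":
                continue
            pct = fecal_totals[nutrient] / fecal_totals["dm"] * 100.0
            if config.fecal_composition_noise_pp > 0:
                pct += rng.normal(0.0, config.fecal_composition_noise_pp)
            composition[nutrient] = float(np.clip(pct, 0.0, 100.0))
        organic_pct = sum(composition.values())
        ash_pct = max(0.0, 100.0 - organic_pct)
        fecal_profiles[animal_id] = ProximateProfile(
            ingredient_id=f"feces:{animal_id}", dm_pct=100.0,
            cp_pct=composition.get("cp", 0.0),
            ee_pct=composition.get("ee", 0.0),
            cf_pct=composition.get("cf", 0.0),
            nfe_pct=composition.get("nfe", 0.0),
            ash_pct=min(ash_pct, 100.0),
            cf_absent="cf" not in composition,
            nfe_absent="nfe" not in composition,
            basis="dry_matter")

        initial = rng.normal(config.body_weight_mean, config.body_weight_sd)
        gain = rng.normal(config.daily_gain_mean, config.daily_gain_sd)
        weights[animal_id] = (float(initial),
                              float(initial + gain * config.n_days))

    dataset = TrialDataset(diet=diet, diet_profile=diet_profile,
                           fecal_profiles=fecal_profiles, records=records,
                           weights=weights)
    truth = {
        "seed": config.seed,
        "diet_id": config.diet_id,
        "shares": shares,
        "diet_digestibility": diet_truth,
        "reference_digestibility": dict(config.reference_digestibility),
        "ingredient_digestibility": dict(config.ingredient_digestibility),
        "per_animal_digestibility": per_animal_truth,
    }
    return dataset, truth


def study_configs(seed: int = 0, **overrides) -> list[TrialSimConfig]:
    """The five bundled study treatments as simulator configurations.

    T0 is the pure barley reference diet; T1-T4 blend 80% barley with 20%
    of one biowaste meal, using the bundled compositions as profiles and
    the bundled digestibility means as ingredient truths.  The reference
    diet's truths are the synthetic placeholders of :mod:`feedeval.refdata`.
    Seeds are derived per treatment so the five trials are independent.
    """
    configs = []
    for offset, (diet_id, meal) in enumerate(refdata.TREATMENT_MEALS.items()):
        kwargs = dict(
            reference_profile=refdata.BARLEY,
            reference_digestibility=refdata.REFERENCE_TRUE_DIGESTIBILITY,
            diet_id=diet_id,
            seed=seed * len(refdata.TREATMENT_MEALS) + offset,
        )
        if meal is None:
            kwargs["inclusion_fraction"] = 0.0
        else:
            kwargs["ingredient_profile"] = refdata.MEAL_COMPOSITIONS[meal]
            kwargs["ingredient_digestibility"] = refdata.MEAL_DIGESTIBILITY[meal]
        kwargs.update(overrides)
        configs.append(TrialSimConfig(**kwargs))
    return configs
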