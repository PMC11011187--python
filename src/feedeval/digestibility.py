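"""Apparent digestibility from intake/feces mass balance, and the difference
(indirect) method for ingredients that cannot be fed alone.

Apparent digestibility of a nutrient is the fraction of intake not recovered
in feces, D = (I - F) / I x 100 — "apparent" because endogenous fecal losses
are not corrected.  Feeds such as blood or tissue meals cannot make up a
whole ration, so they are fed blended into a reference diet of known
digestibility; assuming the reference diet's indigestibility is unchanged by
mixing, the ingredient's own coefficients follow by subtracting the
reference's contribution:

    D_ing = (D_diet - s * D_ref) / (1 - s)

where s is, nutrient by nutrient, the reference diet's fractional share of
the mixed diet's intake of that nutrient.  Weighting by nutrient-intake
shares rather than by diet proportions is essential: a 20% inclusion of a
70%-protein meal supplies far more than 20% of the protein.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .trial import (
    DRY_MATTER,
    NUTRIENTS,
    FeedEvalError,
    ProximateProfile,
    TrialDataset,
)

logger = logging.getLogger(__name__)


class DigestibilityError(FeedEvalError):
    """Digestibility is undefined for the named nutrient (zero intake)."""


@dataclass
class NutrientFlux:
    """Total intake (I) and fecal output (F) per nutrient over the collection.

    Masses are grams on a dry-matter-referenced basis: the ``dm`` entry is
    the DM mass itself; organic nutrients are their mass within that DM.
    """

    animal_id: str
    intake_g: dict[str, float]
    fecal_g: dict[str, float]

    def __post_init__(self) -> None:
        for name, value in list(self.intake_g.items()) + list(self.fecal_g.items()):
            if value < 0:
                raise FeedEvalError(
                    f"{self.animal_id}: negative {name} flux {value}")


@dataclass
class DigestibilityCoefficients:
    """Per-nutrient apparent digestibility, mean ± sd across animals.

    Values outside [0, 100] are legal — apparent digestibility can exceed
    bounds under measurement noise — but are recorded in ``flags``.
    ``per_animal`` keeps the animal-level coefficients for downstream
    group comparisons and per-animal energy chains.
    """

    subject_id: str
    mean_pct: dict[str, float]
    sd_pct: dict[str, float]
    n_animals: int
    per_animal: dict[str, dict[str, float]] = field(default_factory=dict)
    absent: set[str] = field(default_factory=set)
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in self.sd_pct.items():
            if sd < 0:
                raise FeedEvalError(f"negative sd for {name}")


def _nutrient_mass(fresh_g: float, profile: ProximateProfile,
                   nutrient: str) -> float:
    """Mass of one nutrient in ``fresh_g`` of material described by ``profile``.

    A dry-matter-basis profile applies its percentages to the DM mass; an
    as-analyzed profile applies them to the as-fed mass directly.
    """
    if nutrient == "dm":
        return fresh_g * profile.dm_pct / 100.0
    pct = profile.component(nutrient)
    if profile.basis == DRY_MATTER:
        return fresh_g * profile.dm_pct / 100.0 * pct / 100.0
    return fresh_g * pct / 100.0


def nutrient_flux(dataset: TrialDataset, animal_id: str) -> NutrientFlux:
    """Sum one animal's nutrient intake and fecal output over all days.

    Intake of each nutrient is net fresh consumption times the diet's
    nutrient content; fecal output is daily fecal DM (fresh mass x DM
    fraction) times the animal's pooled fecal composition.  Raises
    ``KeyError`` for an unknown animal and :class:`DigestibilityError` if
    total DM intake is zero.
    """
    records = dataset.records_for(animal_id)  # KeyError if unknown
    try:
        fecal_profile = dataset.fecal_profiles[animal_id]
    except KeyError:
        raise KeyError(
            f"no fecal composition for animal {animal_id!r}") from None

    intake = {n: 0.0 for n in NUTRIENTS}
    fecal = {n: 0.0 for n in NUTRIENTS}
    fecal_dm_total = 0.0
    for record in records:
        consumed = record.consumed_g
        for nutrient in NUTRIENTS:
            intake[nutrient] += _nutrient_mass(
                consumed, dataset.diet_profile, nutrient)
        fecal_dm_total += record.feces_fresh_g * record.feces_dm_fraction
    fecal["dm"] = fecal_dm_total
    for nutrient in NUTRIENTS:
        if nutrient == "dm":
            continue
        # pooled fecal composition is on a DM basis
        fecal[nutrient] = fecal_dm_total * fecal_profile.component(nutrient) / 100.0
    if intake["dm"] <= 0.0:
        raise DigestibilityError(
            f"animal {animal_id}: zero total dry-matter intake")
    return NutrientFlux(animal_id=animal_id, intake_g=intake, fecal_g=fecal)


def apparent_digestibility(flux: NutrientFlux,
                           nutrients: tuple[str, ...] = NUTRIENTS,
                           ) -> dict[str, float]:
    """D = (I - F) / I x 100 per nutrient; never clamped.

    Raises :class:`DigestibilityError`, naming the nutrient, when its intake
    is zero.  Out-of-range values (negative, or above 100) are returned
    as-is — callers flag them.
    """
    out = {}
    for nutrient in nutrients:
        intake = flux.intake_g[nutrient]
        if intake <= 0.0:
            raise DigestibilityError(
                f"animal {flux.animal_id}: digestibility of {nutrient} "
                "undefined (zero intake)")
        out[nutrient] = (intake - flux.fecal_g[nutrient]) / intake * 100.0
    return out


def diet_digestibility(dataset: TrialDataset,
                       aggregate: str = "per_animal",
                       ) -> DigestibilityCoefficients:
    """Treatment-level apparent digestibility of the diet as offered.

    ``aggregate="per_animal"`` (default) computes coefficients animal by
    animal, then reports their mean and sample sd (n-1) — the convention
    behind per-treatment sd columns.  ``aggregate="pooled"`` instead takes
    the ratio of summed intakes to summed fecal outputs across animals;
    its sd columns are then zero.
    """
    animals = dataset.animals()
    # a nutrient the diet does not supply has zero intake and no defined
    # digestibility; skip it rather than erroring
    nutrients = tuple(
        n for n in NUTRIENTS
        if not dataset.diet_profile.is_absent(n)
        and (n == "dm" or dataset.diet_profile.component(n) > 0.0))
    per_animal: dict[str, dict[str, float]] = {}
    fluxes = {a: nutrient_flux(dataset, a) for a in animals}
    for animal_id, flux in fluxes.items():
        per_animal[animal_id] = apparent_digestibility(flux, nutrients)

    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    flags: dict[str, str] = {}
    if aggregate == "pooled":
        for nutrient in nutrients:
            total_i = sum(f.intake_g[nutrient] for f in fluxes.values())
            total_f = sum(f.fecal_g[nutrient] for f in fluxes.values())
            mean[nutrient] = (total_i - total_f) / total_i * 100.0
            sd[nutrient] = 0.0
    elif aggregate == "per_animal":
        for nutrient in nutrients:
            values = np.array([per_animal[a][nutrient] for a in animals])
            mean[nutrient] = float(values.mean())
            sd[nutrient] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    for nutrient in nutrients:
        if not 0.0 <= mean[nutrient] <= 100.0:
            flags[nutrient] = "out_of_range"
    absent = {n for n in NUTRIENTS if n not in nutrients}
    return DigestibilityCoefficients(
        subject_id=dataset.diet.diet_id, mean_pct=mean, sd_pct=sd,
        n_animals=len(animals), per_animal=per_animal, absent=absent,
        flags=flags)


def nutrient_share(ref_profile: ProximateProfile,
                   ing_profile: ProximateProfile,
                   ref_fraction: float) -> dict[str, float | None]:
    """Reference diet's fractional share of each nutrient in the blend.

    s = f_ref * ref% / (f_ref * ref% + (1 - f_ref) * ing%), with both
    profiles on the same (as-fed) basis.  ``None`` marks a nutrient absent
    from both feeds (zero denominator); s == 1.0 marks a nutrient the test
    ingredient does not supply, for which the difference method is
    undefined.
    """
    if not 0.0 < ref_fraction < 1.0:
        raise ValueError(f"ref_fraction {ref_fraction} outside (0, 1)")
    shares: dict[str, float | None] = {}
    for nutrient in NUTRIENTS:
        ref_part = ref_fraction * ref_profile.component(nutrient)
        ing_part = (1.0 - ref_fraction) * ing_profile.component(nutrient)
        denominator = ref_part + ing_part
        if denominator == 0.0:
            shares[nutrient] = None
        else:
            shares[nutrient] = ref_part / denominator
    return shares


def difference_method(d_test_diet: dict[str, float],
                      d_ref: dict[str, float],
                      ref_nutrient_share: dict[str, float | None],
                      ) -> dict[str, float | None]:
    """Invert the blend to the test ingredient's own digestibility.

    D_ing = (D_diet - s * D_ref) / (1 - s) per nutrient.  Nutrients with
    s == 1 (the ingredient contributes none of that nutrient) or an absent
    share are reported as ``None`` with a logged warning — there is nothing
    to estimate.
    """
    out: dict[str, float | None] = {}
    for nutrient, share in ref_nutrient_share.items():
        if nutrient not in d_test_diet:
            continue
        if share is None:
            out[nutrient] = None
            continue
        if share >= 1.0:
            logger.warning(
                "nutrient %s: test ingredient contributes no intake "
                "(share=1); ingredient digestibility undefined", nutrient)
            out[nutrient] = None
            continue
        if not 0.0 <= share < 1.0:
            raise ValueError(f"share {share} for {nutrient} outside [0, 1)")
        out[nutrient] = (d_test_diet[nutrient] - share * d_ref[nutrient]) / (
            1.0 - share)
    return out


def ingredient_digestibility(test_dataset: TrialDataset,
                             reference_coeffs: DigestibilityCoefficients,
                             ref_profile: ProximateProfile,
                             ing_profile: ProximateProfile,
                             ref_fraction: float | None = None,
                             aggregate: str = "per_animal",
                             ) -> DigestibilityCoefficients:
    """Full indirect estimate for the test ingredient of one trial.

    The reference coefficients entering the subtraction are the reference
    treatment's mean values; per-animal variation of the *test* trial
    propagates through the linear inversion, so sd(D_ing) = sd(D_diet)/(1-s).
    """
    if ref_fraction is None:
        ref_fraction = 1.0 - test_dataset.diet.test_fraction
    shares = nutrient_share(ref_profile, ing_profile, ref_fraction)
    diet_coeffs = diet_digestibility(test_dataset, aggregate=aggregate)

    mean_estimate = difference_method(
        diet_coeffs.mean_pct, reference_coeffs.mean_pct, shares)
    absent = {n for n, v in mean_estimate.items() if v is None}
    estimable = {n: s for n, s in shares.items() if n not in absent}

    per_animal: dict[str, dict[str, float]] = {}
    for animal_id, d_diet in diet_coeffs.per_animal.items():
        estimate = difference_method(
            d_diet, reference_coeffs.mean_pct, estimable)
        per_animal[animal_id] = {
            n: v for n, v in estimate.items() if v is not None}
    mean = {n: v for n, v in mean_estimate.items() if v is not None}
    sd = {}
    flags = {}
    for nutrient in mean:
        share = shares[nutrient]
        assert share is not None
        sd[nutrient] = diet_coeffs.sd_pct.get(nutrient, 0.0) / (1.0 - share)
        if not 0.0 <= mean[nutrient] <= 100.0:
            flags[nutrient] = "out_of_range"
    return DigestibilityCoefficients(
        subject_id=ing_profile.ingredient_id, mean_pct=mean, sd_pct=sd,
        n_animals=diet_coeffs.n_animals, per_animal=per_animal,
        absent=absent, flags=flags)


def assert_mass_conservation(flux: NutrientFlux,
                             digestibility: dict[str, float],
                             rel_tol: float = 1e-9) -> None:
    """Check the algebraic identity I - F == D x I / 100 numerically."""
    for nutrient, d in digestibility.items():
        digested = flux.intake_g[nutrient] - flux.fecal_g[nutrient]
        implied = d * flux.intake_g[nutrient] / 100.0
        if not math.isclose(digested, implied, rel_tol=rel_tol,
                            abs_tol=1e-12):
            raise AssertionError(
                f"mass balance broken for {nutrient}: {digested} vs {implied}")
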