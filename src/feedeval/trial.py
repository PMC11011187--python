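"""Domain types for metabolic-cage feed-evaluation trials.

The objects here mirror what a digestibility trial actually records: the
proximate (Weende) composition of each feed, the recipe of each ration, and
per-animal daily bookkeeping of feed offered/refused and feces produced.
Validation is deliberately split in two: constructors raise on physically
impossible values (negative masses, fractions outside [0, 1]) while
:func:`validate_trial` reports every soft violation without raising, so a
whole dataset can be audited in one pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: Organic proximate components, in conventional reporting order.
COMPONENTS = ("cp", "ee", "cf", "nfe", "ash")

#: Nutrients whose digestibility is computed (ash is conventionally excluded).
NUTRIENTS = ("dm", "cp", "ee", "cf", "nfe")

#: Marker used in composition tables for components the feed does not contain.
ABSENT_MARKER = "†"  # dagger

AS_ANALYZED = "as_analyzed"
DRY_MATTER = "dry_matter"


class FeedEvalError(Exception):
    """Base class for all package errors."""


class ValidationError(FeedEvalError, ValueError):
    """A domain object violates one of its invariants."""


@dataclass
class ProximateProfile:
    """Proximate composition of one ingredient or mixed diet.

    ``dm_pct`` is percent dry matter of the as-fed mass.  The five organic
    components are percentages of the *analyzed* (air-dry) fraction when
    ``basis == "as_analyzed"`` or of the dry matter when
    ``basis == "dry_matter"``.  Feeds genuinely lacking crude fiber or
    nitrogen-free extract (pure animal tissues, blood) carry an explicit
    absent flag with the value pinned at zero, matching the dagger
    convention of composition tables.
    """

    ingredient_id: str
    dm_pct: float
    cp_pct: float
    ee_pct: float
    cf_pct: float
    nfe_pct: float
    ash_pct: float
    cf_absent: bool = False
    nfe_absent: bool = False
    basis: str = AS_ANALYZED

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, closure_tol: float = 2.0) -> None:
        """Raise :class:`ValidationError` on hard violations; warn on closure.

        The component sum is expected to be near 100 (closure of the Weende
        partition).  A sum outside ``closure_tol`` percentage points of 100 is
        logged as a warning and never raises: published tables occasionally
        contain non-closing rows and the analysis must be able to proceed.
        """
        if self.basis not in (AS_ANALYZED, DRY_MATTER):
            raise ValidationError(
                f"{self.ingredient_id}: unknown basis {self.basis!r}")
        if not self.dm_pct > 0:
            raise ValidationError(f"{self.ingredient_id}: dm_pct must be > 0")
        for name in ("dm",) + COMPONENTS:
            value = getattr(self, f"{name}_pct")
            if not 0.0 <= value <= 100.0:
                raise ValidationError(
                    f"{self.ingredient_id}: {name}_pct={value} outside [0, 100]")
        for name, flag in (("cf", self.cf_absent), ("nfe", self.nfe_absent)):
            if flag and getattr(self, f"{name}_pct") != 0.0:
                raise ValidationError(
                    f"{self.ingredient_id}: {name} flagged absent but nonzero")
        total = sum(getattr(self, f"{c}_pct") for c in COMPONENTS)
        if abs(total - 100.0) > closure_tol:
            logger.warning(
                "%s: proximate components sum to %.2f%% (closure tolerance "
                "±%.1f around 100); proceeding",
                self.ingredient_id, total, closure_tol)

    def component(self, name: str) -> float:
        """Percentage of one component (``cp``, ``ee``, ``cf``, ``nfe``, ``ash``)."""
        if name == "dm":
            return self.dm_pct
        if name not in COMPONENTS:
            raise KeyError(name)
        return getattr(self, f"{name}_pct")

    def is_absent(self, name: str) -> bool:
        return (name == "cf" and self.cf_absent) or (
            name == "nfe" and self.nfe_absent)

    def with_values(self, **changes) -> "ProximateProfile":
        return replace(self, **changes)


REFERENCE = "reference"
TEST = "test"


@dataclass
class DietSpec:
    """Recipe of one ration: ingredient ids and as-fed inclusion fractions.

    A *reference* diet is a feed that can be offered alone (its digestibility
    is measured directly); a *test* diet mixes the reference feed with exactly
    one test ingredient whose digestibility is later obtained by difference.
    """

    diet_id: str
    components: list[tuple[str, float]]
    role: str = TEST
    test_ingredient: str | None = None
    reference_diet: str | None = None

    def __post_init__(self) -> None:
        if self.role not in (REFERENCE, TEST):
            raise ValidationError(f"{self.diet_id}: unknown role {self.role!r}")
        for ingredient_id, fraction in self.components:
            if not 0.0 < fraction <= 1.0:
                raise ValidationError(
                    f"{self.diet_id}: inclusion fraction {fraction} for "
                    f"{ingredient_id} outside (0, 1]")
        # fractions must sum to 1; checked softly by validate_trial so a
        # misformulated diet can still be loaded and audited
        if self.role == TEST:
            if self.test_ingredient is None or self.reference_diet is None:
                raise ValidationError(
                    f"{self.diet_id}: a test diet must name exactly one test "
                    "ingredient and one reference diet")
            if self.test_ingredient not in {i for i, _ in self.components}:
                raise ValidationError(
                    f"{self.diet_id}: test ingredient "
                    f"{self.test_ingredient!r} not among components")

    def fraction_of(self, ingredient_id: str) -> float:
        for iid, fraction in self.components:
            if iid == ingredient_id:
                return fraction
        raise KeyError(ingredient_id)

    @property
    def test_fraction(self) -> float:
        if self.test_ingredient is None:
            return 0.0
        return self.fraction_of(self.test_ingredient)


@dataclass
class AnimalDayRecord:
    """One animal-day of intake and feces bookkeeping, all masses as-fed grams.

    Raw measurements are accepted as recorded; :func:`validate_trial`
    reports violations (negative masses, refusals exceeding the offer,
    DM fractions outside [0, 1]) without refusing to load them.
    """

    animal_id: str
    day: int
    offered_g: float
    refused_g: float
    feces_fresh_g: float
    feces_dm_fraction: float

    @property
    def consumed_g(self) -> float:
        """Net fresh consumption: offered minus the next-day residue."""
        return self.offered_g - self.refused_g


@dataclass
class EnergyConstants:
    """Unit constants of the TDN energy system.

    ``de_factor`` converts percent total digestible nutrients to digestible
    energy (kcal/kg per TDN percentage point); ``me_factor`` is the fraction
    of DE remaining as metabolizable energy after urinary and gaseous losses;
    ``ee_weight`` is fat's energy-density premium in the TDN sum.
    ``cp_nitrogen_factor`` (N-to-protein) is informational only — proximate
    tables arrive with CP already computed; 5.7 is a literature alternative
    for some feedstuffs.
    """

    de_factor: float = 44.09
    me_factor: float = 0.82
    ee_weight: float = 2.25
    cp_nitrogen_factor: float = 6.25

    def __post_init__(self) -> None:
        for name in ("de_factor", "me_factor", "ee_weight", "cp_nitrogen_factor"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass
class TrialDataset:
    """All records of one dietary treatment in a metabolic-cage trial.

    ``diet_profile`` is the composition of the mixed feed as offered;
    ``fecal_profiles`` hold each animal's pooled-collection fecal composition
    on a dry-matter basis; ``weights`` map animal id to (initial_g, final_g).
    """

    diet: DietSpec
    diet_profile: ProximateProfile
    fecal_profiles: dict[str, ProximateProfile]
    records: list[AnimalDayRecord]
    weights: dict[str, tuple[float, float]] = field(default_factory=dict)

    def animals(self) -> list[str]:
        seen: dict[str, None] = {}
        for record in self.records:
            seen.setdefault(record.animal_id, None)
        return list(seen)

    def records_for(self, animal_id: str) -> list[AnimalDayRecord]:
        out = [r for r in self.records if r.animal_id == animal_id]
        if not out:
            raise KeyError(f"no records for animal {animal_id!r}")
        return out

    @property
    def n_animals(self) -> int:
        return len(self.animals())


def validate_trial(dataset: TrialDataset) -> list[str]:
    """Audit a dataset against the trial invariants; never raises.

    Returns a list of human-readable violations, each locating the offending
    animal/day where applicable.  An empty list means the dataset is ready
    for analysis.  The canonical design is 9 animals x 7 collection days;
    smaller datasets are legal but flagged informationally by callers, not
    here.
    """
    violations: list[str] = []
    animals = dataset.animals()
    if not animals:
        violations.append("dataset has no animal records")

    total = sum(f for _, f in dataset.diet.components)
    if abs(total - 1.0) > 1e-9:
        violations.append(
            f"diet {dataset.diet.diet_id}: inclusion fractions do not sum to 1 "
            f"(sum={total:.6g})")

    for record in dataset.records:
        if record.refused_g > record.offered_g:
            violations.append(
                f"animal {record.animal_id} day {record.day}: refused_g "
                f"{record.refused_g} exceeds offered_g {record.offered_g}")
        if min(record.offered_g, record.refused_g, record.feces_fresh_g) < 0:
            violations.append(
                f"animal {record.animal_id} day {record.day}: negative mass")
        if not 0.0 <= record.feces_dm_fraction <= 1.0:
            violations.append(
                f"animal {record.animal_id} day {record.day}: "
                "feces_dm_fraction outside [0, 1]")

    for animal_id in animals:
        if animal_id not in dataset.weights:
            violations.append(f"animal {animal_id}: missing weight pair")
        if animal_id not in dataset.fecal_profiles:
            violations.append(f"animal {animal_id}: missing fecal composition")
    for animal_id, (initial, final) in dataset.weights.items():
        if initial <= 0 or final <= 0 or not (math.isfinite(initial) and math.isfinite(final)):
            violations.append(
                f"animal {animal_id}: non-positive or non-finite weight")
    return violations
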