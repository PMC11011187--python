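"""Recomputation of the bundled study tables from their upstream inputs.

Two deterministic chains are checked here:

- the ration-blend arithmetic (80/20 fraction-weighted composition and ME
  of each test diet against the published ration table), and
- the energy chain (digestible components from composition x digestibility,
  then TDN, DE and ME).

Published tables round every intermediate, so each chain stage is verified
against the *printed inputs of that stage*: digestible components from the
composition and coefficient tables, TDN from the printed digestible
components, DE from the printed TDN, ME from the printed DE.  Tolerances
are half a printed unit on percentages (±0.02 pp allows one rounding step)
and ±2 kcal/kg on energies.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import refdata
from .digestibility import DigestibilityCoefficients
from .energy import (
    blend_diet_profile,
    energy_from_tdn,
    ingredient_energy_profile,
    tdn,
)
from .trial import EnergyConstants


@dataclass
class CheckRow:
    table: str
    name: str
    computed: float
    expected: float
    tolerance: float

    @property
    def ok(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance


def meal_coefficients(meal: str) -> DigestibilityCoefficients:
    """Bundled digestibility means of one meal as a coefficients object."""
    means = refdata.MEAL_DIGESTIBILITY[meal]
    sds = refdata.MEAL_DIGESTIBILITY_SD[meal]
    profile = refdata.MEAL_COMPOSITIONS[meal]
    absent = {n for n in ("cf", "nfe") if profile.is_absent(n)}
    return DigestibilityCoefficients(
        subject_id=meal, mean_pct=dict(means), sd_pct=dict(sds),
        n_animals=refdata.N_ANIMALS, absent=absent)


def energy_chain(meal: str,
                 constants: EnergyConstants | None = None):
    """Full-precision digestible-component/TDN/DE/ME row for one meal."""
    return ingredient_energy_profile(
        refdata.MEAL_COMPOSITIONS[meal], meal_coefficients(meal),
        constants or refdata.DEFAULT_CONSTANTS)


def blend_row(treatment: str) -> dict[str, float]:
    """Composition and ME of one treatment's ration from its ingredients."""
    meal = refdata.TREATMENT_MEALS[treatment]
    if meal is None:
        return {"dm": refdata.BARLEY.dm_pct, "cp": refdata.BARLEY.cp_pct,
                "ee": refdata.BARLEY.ee_pct, "cf": refdata.BARLEY.cf_pct,
                "me": refdata.BARLEY_ME}
    profile, me = blend_diet_profile(
        [refdata.BARLEY, refdata.MEAL_COMPOSITIONS[meal]],
        [1.0 - refdata.INCLUSION_FRACTION, refdata.INCLUSION_FRACTION],
        me_values=[refdata.BARLEY_ME, refdata.MEAL_ME[meal]],
        diet_id=treatment)
    return {"dm": profile.dm_pct, "cp": profile.cp_pct,
            "ee": profile.ee_pct, "cf": profile.cf_pct, "me": me}


def check_blends() -> list[CheckRow]:
    """Every published ration cell against the blend arithmetic."""
    rows = []
    for treatment, expected in refdata.EXPECTED_BLENDS.items():
        computed = blend_row(treatment)
        for key, value in expected.items():
            rows.append(CheckRow("rations", f"{treatment}.{key}",
                                 computed[key], value, 0.005))
    return rows


def check_energy_chain(constants: EnergyConstants | None = None,
                       ) -> list[CheckRow]:
    """Every published digestible-component/energy cell, stage by stage."""
    constants = constants or refdata.DEFAULT_CONSTANTS
    rows = []
    for meal in refdata.MEAL_IDS:
        expected = refdata.EXPECTED_ENERGY[meal]
        full = energy_chain(meal, constants)
        # digestible CP is the component the published chain carries forward;
        # some other published component cells reflect per-animal averaging
        # of products and cannot be recomputed from the printed means
        rows.append(CheckRow("energy", f"{meal}.dcp",
                             full.digestible_pct["cp"], expected["dcp"], 0.02))
        tdn_printed = tdn(expected["dcp"], expected.get("dee", 0.0),
                          expected.get("dcf", 0.0), expected.get("dnfe", 0.0),
                          constants)
        rows.append(CheckRow("energy", f"{meal}.tdn", tdn_printed,
                             expected["tdn"], 0.02))
        de, _ = energy_from_tdn(expected["tdn"], constants)
        rows.append(CheckRow("energy", f"{meal}.de", de, expected["de"], 2.0))
        rows.append(CheckRow("energy", f"{meal}.me",
                             expected["de"] * constants.me_factor,
                             expected["me"], 2.0))
    return rows


def check_all() -> list[CheckRow]:
    return check_blends() + check_energy_chain()
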