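"""Digestible nutrients, TDN, energy estimation, and ration blending.

The total-digestible-nutrients system summarizes a feed's energy value from
its proximate composition and apparent digestibility:

    dX   = X% x D_X / 100                      (digestible component)
    TDN% = dCP + 2.25 x dEE + dCF + dNFE       (fat weighted for energy density)
    DE   = TDN% x 44.09 kcal/kg
    ME   = 0.82 x DE

Components a feed does not contain (crude fiber and nitrogen-free extract in
animal tissues and blood) contribute zero to TDN and appear as absent in
reports.  Standard deviations are propagated assuming independent
coefficient errors: scalar stages scale the sd exactly; the TDN sum combines
component sds in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .digestibility import DigestibilityCoefficients
from .trial import (
    AS_ANALYZED,
    COMPONENTS,
    DRY_MATTER,
    EnergyConstants,
    FeedEvalError,
    ProximateProfile,
)

TDN_NUTRIENTS = ("cp", "ee", "cf", "nfe")


@dataclass
class EnergyProfile:
    """Digestible components and energy value of one feed.

    Percent columns are digestible fractions of the feed mass on the same
    basis as the source composition; energy columns are kcal per kg of feed.
    """

    ingredient_id: str
    digestible_pct: dict[str, float]
    tdn_pct: float
    de_kcal_kg: float
    me_kcal_kg: float
    digestible_sd: dict[str, float] = field(default_factory=dict)
    tdn_sd: float = 0.0
    de_sd: float = 0.0
    me_sd: float = 0.0
    absent: set[str] = field(default_factory=set)


def digestible_fraction(component_pct: float, digestibility_pct: float) -> float:
    """Digestible share of a component: composition x digestibility / 100."""
    if component_pct < 0:
        raise FeedEvalError(f"negative component percentage {component_pct}")
    return component_pct * digestibility_pct / 100.0


def tdn(dcp: float, dee: float, dcf: float, dnfe: float,
        constants: EnergyConstants | None = None) -> float:
    """Total digestible nutrients from digestible components.

    Absent components enter as zero.  The ether-extract term carries the
    fat energy-density weight (2.25 by default).
    """
    constants = constants or EnergyConstants()
    for name, value in (("dCP", dcp), ("dEE", dee), ("dCF", dcf),
                        ("dNFE", dnfe)):
        if value < 0:
            raise FeedEvalError(f"negative {name} {value}")
    return dcp + constants.ee_weight * dee + dcf + dnfe


def energy_from_tdn(tdn_pct: float,
                    constants: EnergyConstants | None = None,
                    ) -> tuple[float, float]:
    """(DE, ME) in kcal/kg from percent TDN."""
    constants = constants or EnergyConstants()
    if tdn_pct < 0:
        raise FeedEvalError(f"negative TDN {tdn_pct}")
    de = tdn_pct * constants.de_factor
    return de, de * constants.me_factor


def to_dry_matter_basis(profile: ProximateProfile) -> ProximateProfile:
    """Re-express an as-analyzed profile's components per unit dry matter."""
    if profile.basis == DRY_MATTER:
        return profile
    factor = 100.0 / profile.dm_pct
    return profile.with_values(
        basis=DRY_MATTER,
        **{f"{c}_pct": min(100.0, profile.component(c) * factor)
           for c in COMPONENTS})


def ingredient_energy_profile(profile: ProximateProfile,
                              coeffs: DigestibilityCoefficients,
                              constants: EnergyConstants | None = None,
                              ) -> EnergyProfile:
    """Full digestible-component and energy row for one feed.

    Composes :func:`digestible_fraction`, :func:`tdn` and
    :func:`energy_from_tdn` in full precision.  Coefficient sds propagate
    through the same maps (composition treated as fixed): component sds are
    composition x sd_D / 100, the TDN sd combines them in quadrature with
    the fat weight applied, and the energy sds scale by the conversion
    factors.
    """
    constants = constants or EnergyConstants()
    digestible: dict[str, float] = {}
    digestible_sd: dict[str, float] = {}
    absent: set[str] = set()
    for nutrient in ("dm",) + TDN_NUTRIENTS:
        if profile.is_absent(nutrient) or nutrient in coeffs.absent:
            absent.add(nutrient)
            digestible[nutrient] = 0.0
            digestible_sd[nutrient] = 0.0
            continue
        if nutrient not in coeffs.mean_pct:
            raise FeedEvalError(
                f"{profile.ingredient_id}: no digestibility coefficient for "
                f"{nutrient}")
        component = profile.component(nutrient)
        digestible[nutrient] = digestible_fraction(
            component, coeffs.mean_pct[nutrient])
        digestible_sd[nutrient] = component * coeffs.sd_pct.get(nutrient, 0.0) / 100.0

    tdn_pct = tdn(digestible["cp"], digestible["ee"], digestible["cf"],
                  digestible["nfe"], constants)
    tdn_sd = math.sqrt(
        digestible_sd["cp"] ** 2
        + (constants.ee_weight * digestible_sd["ee"]) ** 2
        + digestible_sd["cf"] ** 2
        + digestible_sd["nfe"] ** 2)
    de, me = energy_from_tdn(tdn_pct, constants)
    return EnergyProfile(
        ingredient_id=profile.ingredient_id,
        digestible_pct=digestible, tdn_pct=tdn_pct,
        de_kcal_kg=de, me_kcal_kg=me,
        digestible_sd=digestible_sd, tdn_sd=tdn_sd,
        de_sd=tdn_sd * constants.de_factor,
        me_sd=tdn_sd * constants.de_factor * constants.me_factor,
        absent=absent)


def blend_diet_profile(profiles: list[ProximateProfile],
                       fractions: list[float],
                       me_values: list[float] | None = None,
                       diet_id: str = "blend",
                       ) -> tuple[ProximateProfile, float | None]:
    """Fraction-weighted blend of ingredient profiles (and optionally ME).

    Every component — and ME when supplied — is the inclusion-weighted mean
    of the ingredient values, with absent components contributing zero.  The
    blend is marked absent in a component only when every ingredient lacks
    it.  Returns ``(profile, blended_me)``; ``blended_me`` is ``None`` when
    ``me_values`` is not given.
    """
    if len(profiles) != len(fractions):
        raise FeedEvalError("profiles and fractions differ in length")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise FeedEvalError(f"fractions sum to {sum(fractions)}, not 1")
    bases = {p.basis for p in profiles}
    if len(bases) > 1:
        raise FeedEvalError("cannot blend profiles on different bases")

    values = {"dm": 0.0, **{c: 0.0 for c in COMPONENTS}}
    for profile, fraction in zip(profiles, fractions):
        values["dm"] += fraction * profile.dm_pct
        for component in COMPONENTS:
            values[component] += fraction * profile.component(component)
    cf_absent = all(p.cf_absent for p in profiles)
    nfe_absent = all(p.nfe_absent for p in profiles)
    blended = ProximateProfile(
        ingredient_id=diet_id, dm_pct=values["dm"],
        cp_pct=values["cp"], ee_pct=values["ee"], cf_pct=values["cf"],
        nfe_pct=values["nfe"], ash_pct=values["ash"],
        cf_absent=cf_absent, nfe_absent=nfe_absent, basis=profiles[0].basis)
    blended_me = None
    if me_values is not None:
        if len(me_values) != len(fractions):
            raise FeedEvalError("me_values and fractions differ in length")
        blended_me = sum(f * me for f, me in zip(fractions, me_values))
    return blended, blended_me
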