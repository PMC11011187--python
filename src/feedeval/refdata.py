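"""Bundled reference data from the motivating guinea-pig feeding study.

Four bovine slaughterhouse biowaste meals — rumen content (RCM), ear (EaM),
blood (BM) and cheek (CM) meal — were evaluated against a barley-meal
reference diet fed to nine guinea pigs per treatment for a seven-day
collection, each test ration blending 80% reference diet with 20% test
meal.  The published proximate compositions, apparent digestibility
coefficients, digestible-component/energy chain, ration formulas and weight
summaries are bundled here so the whole analysis chain can be exercised and
cross-checked without external files.

Component percentages are on the analyzed (air-dry) basis: all rows except
blood meal close to 100 without dry matter.  The blood-meal row sums to
76.9 and is knowingly non-closing; it loads with a warning, never an error.

The barley reference diet's published values are DM 91, CP 12, EE 4,
CF 5.8 (%) and ME 2884 kcal/kg.  Its ash and NFE were not published; the
values here (ash 2.5, NFE 75.7, closing the analyzed basis to 100) and the
reference-diet *true* digestibilities used by the simulator are synthetic
placeholders, not measured values.
"""

from __future__ import annotations

from .trial import EnergyConstants, ProximateProfile

MEAL_IDS = ("RCM", "EaM", "BM", "CM")

#: Proximate composition of the four biowaste meals (as analyzed).
MEAL_COMPOSITIONS: dict[str, ProximateProfile] = {
    "RCM": ProximateProfile("RCM", dm_pct=85.00, cp_pct=15.00, ee_pct=5.50,
                            cf_pct=38.00, nfe_pct=30.50, ash_pct=11.00),
    "EaM": ProximateProfile("EaM", dm_pct=88.91, cp_pct=62.64, ee_pct=22.4,
                            cf_pct=0.0, nfe_pct=0.0, ash_pct=14.86,
                            cf_absent=True, nfe_absent=True),
    "BM": ProximateProfile("BM", dm_pct=92.00, cp_pct=72.40, ee_pct=0.50,
                           cf_pct=0.0, nfe_pct=0.0, ash_pct=4.00,
                           cf_absent=True, nfe_absent=True),
    "CM": ProximateProfile("CM", dm_pct=91.76, cp_pct=84.19, ee_pct=6.91,
                           cf_pct=0.0, nfe_pct=0.0, ash_pct=8.90,
                           cf_absent=True, nfe_absent=True),
}

#: Composition sds of the meals, same layout (informational).
MEAL_COMPOSITION_SD: dict[str, dict[str, float]] = {
    "RCM": {"dm": 0.33, "cp": 0.30, "ee": 0.30, "cf": 1.37, "nfe": 1.84,
            "ash": 1.07},
    "EaM": {"dm": 1.32, "cp": 0.61, "ee": 0.52, "ash": 0.13},
    "BM": {"dm": 0.30, "cp": 1.19, "ee": 0.06, "ash": 0.16},
    "CM": {"dm": 0.02, "cp": 0.02, "ee": 0.03, "ash": 0.01},
}

#: Apparent digestibility coefficients of the meals, % (mean across 9 animals).
MEAL_DIGESTIBILITY: dict[str, dict[str, float]] = {
    "RCM": {"dm": 83.05, "cp": 67.65, "ee": 82.76, "cf": 91.52, "nfe": 77.91},
    "EaM": {"dm": 88.28, "cp": 71.10, "ee": 94.11},
    "BM": {"dm": 88.53, "cp": 97.63, "ee": 65.25},
    "CM": {"dm": 76.34, "cp": 96.03, "ee": 82.37},
}

#: Published per-treatment sds of the digestibility coefficients, pp.
MEAL_DIGESTIBILITY_SD: dict[str, dict[str, float]] = {
    "RCM": {"dm": 5.51, "cp": 4.69, "ee": 11.35, "cf": 4.73, "nfe": 9.21},
    "EaM": {"dm": 2.38, "cp": 7.95, "ee": 3.02},
    "BM": {"dm": 3.20, "cp": 0.74, "ee": 20.77},
    "CM": {"dm": 1.53, "cp": 0.39, "ee": 1.28},
}

#: Published digestible-component and energy chain, for cross-checking:
#: digestible DM/CP/EE/CF/NFE (%), TDN (%), DE and ME (kcal/kg).
EXPECTED_ENERGY: dict[str, dict[str, float]] = {
    "RCM": {"ddm": 70.60, "dcp": 10.15, "dee": 4.55, "dcf": 34.78,
            "dnfe": 23.76, "tdn": 78.93, "de": 3480.0, "me": 2853.0},
    "EaM": {"ddm": 78.49, "dcp": 44.54, "dee": 21.08,
            "tdn": 91.97, "de": 4055.0, "me": 3325.0},
    "BM": {"ddm": 81.45, "dcp": 70.68, "dee": 0.35,
           "tdn": 71.46, "de": 3151.0, "me": 2583.0},
    "CM": {"ddm": 70.05, "dcp": 80.84, "dee": 5.69,
           "tdn": 93.65, "de": 4129.0, "me": 3386.0},
}

#: Published ME of each meal, kcal/kg (enters ration-blend arithmetic).
MEAL_ME: dict[str, float] = {m: EXPECTED_ENERGY[m]["me"] for m in MEAL_IDS}

#: Barley reference diet as offered.  Ash and NFE are synthetic placeholders
#: (unpublished); see module docstring.
BARLEY = ProximateProfile("barley", dm_pct=91.0, cp_pct=12.0, ee_pct=4.0,
                          cf_pct=5.8, nfe_pct=75.7, ash_pct=2.5)
BARLEY_ME = 2884.0

#: Synthetic placeholder "true" digestibilities of the barley reference diet
#: for simulation (the study's measured barley coefficients are unpublished).
#: The DM value is pinned to the component values: with CP 75, EE 80, CF 40
#: and NFE 85 applied to the barley composition, fecal organic matter alone
#: is 18.6 g per 100 g as fed, so DM digestibility can be at most ~79%;
#: 77 leaves a small non-negative fecal-ash residual in every blend.
REFERENCE_TRUE_DIGESTIBILITY: dict[str, float] = {
    "dm": 77.0, "cp": 75.0, "ee": 80.0, "cf": 40.0, "nfe": 85.0,
}

#: Published chemical composition of the five evaluated rations
#: (100% barley and the four 80/20 blends).
EXPECTED_BLENDS: dict[str, dict[str, float]] = {
    "T0": {"dm": 91.0, "cp": 12.0, "ee": 4.0, "cf": 5.8, "me": 2884.0},
    "T1": {"dm": 89.80, "cp": 12.60, "ee": 4.30, "cf": 12.24, "me": 2877.80},
    "T2": {"dm": 90.58, "cp": 22.13, "ee": 7.68, "cf": 4.64, "me": 2972.20},
    "T3": {"dm": 91.20, "cp": 24.08, "ee": 3.30, "cf": 4.64, "me": 2823.80},
    "T4": {"dm": 91.15, "cp": 26.44, "ee": 4.58, "cf": 4.64, "me": 2984.40},
}

#: Test meal fed in each treatment (T0 is the pure reference diet).
TREATMENT_MEALS: dict[str, str | None] = {
    "T0": None, "T1": "RCM", "T2": "EaM", "T3": "BM", "T4": "CM",
}

INCLUSION_FRACTION = 0.2
N_ANIMALS = 9
N_DAYS = 7

#: Guinea-pig body weight at trial start, grams (cohort mean ± sd).
BODY_WEIGHT_MEAN = 822.0
BODY_WEIGHT_SD = 18.0

#: Published weight summaries per treatment over the 7-day collection:
#: initial/final weight and total/daily gain, mean and sd in grams.
GAIN_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "RCM": {"initial": (807.78, 68.75), "final": (836.33, 65.82),
            "total_gain": (28.56, 5.48), "daily_gain": (4.08, 0.78)},
    "EaM": {"initial": (834.44, 53.35), "final": (878.11, 53.17),
            "total_gain": (43.67, 8.14), "daily_gain": (6.24, 1.16)},
    "BM": {"initial": (840.33, 67.17), "final": (888.44, 63.6),
           "total_gain": (48.11, 8.93), "daily_gain": (6.87, 1.27)},
    "CM": {"initial": (806.11, 58.28), "final": (855.22, 55.51),
           "total_gain": (49.11, 7.22), "daily_gain": (7.02, 1.03)},
}

DEFAULT_CONSTANTS = EnergyConstants()
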