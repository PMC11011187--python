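"""Voluntary-intake and growth summaries for a trial treatment.

Intake of the *test ingredient* inside a mixed ration cannot be measured
directly — refusals of a homogeneous mash have the composition of the mash —
so the ingredient's intake is attributed by its inclusion fraction.  Intakes
are scaled two conventional ways: as a percentage of live weight and as
grams per kilogram of metabolic weight, W^0.75, the classical allometric
scale for intake and metabolic rate across body sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial import FeedEvalError, ProximateProfile, TrialDataset


def metabolic_weight(weight_g: float) -> float:
    """Metabolic body size in kg^0.75 from a body weight in grams."""
    if weight_g <= 0:
        raise FeedEvalError(f"non-positive body weight {weight_g}")
    return (weight_g / 1000.0) ** 0.75


@dataclass
class IntakeSummary:
    """Per-animal intake rows plus treatment mean ± sd.

    ``per_animal`` columns: mean_daily_dm_g (whole diet), attributed_dm_g
    (test-ingredient share), pct_live_weight, g_per_kg_metabolic.  The
    body-weight denominator is the mean of initial and final weight.
    """

    diet_id: str
    per_animal: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass
class GainSummary:
    """Per-animal weights and gains plus treatment mean ± sd.

    ``per_animal`` columns: initial_g, final_g, total_gain_g, daily_gain_g;
    daily gain is total gain over the collection-period length.
    """

    diet_id: str
    n_days: int
    per_animal: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]


def _summarize(frame: pd.DataFrame) -> tuple[dict[str, float], dict[str, float]]:
    mean = {c: float(frame[c].mean()) for c in frame.columns}
    sd = {c: float(frame[c].std(ddof=1)) if len(frame) > 1 else 0.0
          for c in frame.columns}
    return mean, sd


def intake_summary(dataset: TrialDataset,
                   inclusion_fraction: float | None = None,
                   ingredient_profile: ProximateProfile | None = None,
                   attribution: str = "as_fed",
                   ) -> IntakeSummary:
    """Daily DM intake and test-ingredient intake scaled to body size.

    ``attribution="as_fed"`` (default) applies the inclusion fraction to
    fresh consumption and converts with the ingredient's own DM content —
    appropriate because inclusion fractions are formulated as-fed;
    ``attribution="dm"`` applies the fraction to diet DM intake directly.
    The two coincide when the ingredient's DM equals the diet's DM.  With
    no test ingredient (a pure reference diet) the attributed columns equal
    the total-diet values with fraction 1.
    """
    if inclusion_fraction is None:
        inclusion_fraction = dataset.diet.test_fraction or 1.0
    if not 0.0 < inclusion_fraction <= 1.0:
        raise FeedEvalError(
            f"inclusion fraction {inclusion_fraction} outside (0, 1]")
    if attribution not in ("as_fed", "dm"):
        raise FeedEvalError(f"unknown attribution mode {attribution!r}")
    if attribution == "as_fed" and ingredient_profile is None:
        # without the ingredient's own DM, fall back to the diet DM
        ingredient_dm = dataset.diet_profile.dm_pct
    elif attribution == "as_fed":
        ingredient_dm = ingredient_profile.dm_pct
    rows = []
    for animal_id in dataset.animals():
        if animal_id not in dataset.weights:
            raise FeedEvalError(f"missing weights for animal {animal_id!r}")
        records = dataset.records_for(animal_id)
        fresh = np.array([r.consumed_g for r in records])
        daily_dm = float(fresh.mean()) * dataset.diet_profile.dm_pct / 100.0
        if attribution == "as_fed":
            attributed = (float(fresh.mean()) * inclusion_fraction
                          * ingredient_dm / 100.0)
        else:
            attributed = inclusion_fraction * daily_dm
        initial, final = dataset.weights[animal_id]
        mean_weight = (initial + final) / 2.0
        rows.append({
            "animal_id": animal_id,
            "mean_daily_dm_g": daily_dm,
            "attributed_dm_g": attributed,
            "pct_live_weight": attributed / mean_weight * 100.0,
            "g_per_kg_metabolic": attributed / metabolic_weight(mean_weight),
        })
    frame = pd.DataFrame(rows).set_index("animal_id")
    mean, sd = _summarize(frame)
    return IntakeSummary(diet_id=dataset.diet.diet_id, per_animal=frame,
                         mean=mean, sd=sd)


def gain_summary(dataset: TrialDataset, n_days: int = 7) -> GainSummary:
    """Initial/final weights and total/daily gains over the trial."""
    if n_days <= 0:
        raise FeedEvalError(f"n_days must be positive, got {n_days}")
    rows = []
    for animal_id in dataset.animals():
        if animal_id not in dataset.weights:
            raise FeedEvalError(f"missing weights for animal {animal_id!r}")
        initial, final = dataset.weights[animal_id]
        total = final - initial
        rows.append({
            "animal_id": animal_id,
            "initial_g": initial, "final_g": final,
            "total_gain_g": total, "daily_gain_g": total / n_days,
        })
    frame = pd.DataFrame(rows).set_index("animal_id")
    mean, sd = _summarize(frame)
    return GainSummary(diet_id=dataset.diet.diet_id, n_days=n_days,
                       per_animal=frame, mean=mean, sd=sd)
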