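"""End-to-end orchestration: digestibility → energy → intake → comparisons.

:func:`run_pipeline` drives the whole analysis over the five CSV schemas of
:mod:`feedeval.io`, writing tidy CSV outputs plus Markdown report tables in
the conventional feed-table layouts (mean ± sd with Duncan superscripts,
"-" for absent nutrients).  Every stage failure aborts with the stage name
in the message; the log records the exact energy constants used so the
44.09 / 0.82 / 2.25 provenance of each run is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .digestibility import (
    DigestibilityCoefficients,
    diet_digestibility,
    ingredient_digestibility,
)
from .energy import EnergyProfile, ingredient_energy_profile
from .intake import gain_summary, intake_summary
from .io import load_trials, read_composition_table
from .stats import GroupComparison, compare_treatments
from .trial import (
    NUTRIENTS,
    EnergyConstants,
    FeedEvalError,
    TrialDataset,
    validate_trial,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``aggregation`` selects per-animal (mean of ratios, sd across animals)
    or pooled (ratio of totals) digestibility; ``protected`` gates Duncan
    letters on a significant ANOVA F.
    """

    input_dir: Path
    output_dir: Path
    alpha: float = 0.05
    aggregation: str = "per_animal"
    protected: bool = False
    n_days: int = 7
    seed: int = 0
    constants: EnergyConstants = field(default_factory=EnergyConstants)

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not 0.0 < self.alpha < 1.0:
            raise FeedEvalError(f"alpha {self.alpha} outside (0, 1)")
        if not self.input_dir.exists():
            raise FeedEvalError(f"input directory {self.input_dir} not found")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        constants = EnergyConstants(**raw.pop("constants", {}))
        return cls(constants=constants, **raw)


@dataclass
class PipelineResult:
    reference_coeffs: DigestibilityCoefficients
    ingredient_coeffs: dict[str, DigestibilityCoefficients]
    energy_profiles: dict[str, EnergyProfile]
    intakes: dict[str, object]
    gains: dict[str, object]
    comparisons: list[GroupComparison]
    output_files: list[Path]


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FeedEvalError as error:
                raise FeedEvalError(f"stage {name}: {error}") from error
        return wrapper
    return decorate


def render_table(headers: list[str], rows: list[list[str]]) -> str:
    """Markdown table; empty results render the header only."""
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for row in rows:
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"


def format_cell(mean: float | None, sd: float | None = None,
                letters: str = "", digits: int = 2) -> str:
    """One report cell: "mean ± sd ^letters^", or "-" when absent."""
    if mean is None:
        return "-"
    cell = f"{mean:.{digits}f}"
    if sd is not None:
        cell += f" ± {sd:.{digits}f}"
    if letters:
        cell += f" ^{letters}^"
    return cell


@_stage("digestibility")
def _digestibility_stage(datasets, compositions, config):
    reference = [d for d in datasets.values() if d.diet.role == "reference"]
    if len(reference) != 1:
        raise FeedEvalError(
            f"expected exactly one reference-diet treatment, found "
            f"{len(reference)}")
    reference_ds = reference[0]
    ref_coeffs = diet_digestibility(reference_ds, aggregate=config.aggregation)
    ref_ingredient = reference_ds.diet.components[0][0]

    ingredient_coeffs: dict[str, DigestibilityCoefficients] = {}
    for dataset in datasets.values():
        if dataset.diet.role != "test":
            continue
        meal = dataset.diet.test_ingredient
        if meal not in compositions:
            raise FeedEvalError(f"no composition for test ingredient {meal!r}")
        if ref_ingredient not in compositions:
            raise FeedEvalError(
                f"no composition for reference feed {ref_ingredient!r}")
        ingredient_coeffs[meal] = ingredient_digestibility(
            dataset, ref_coeffs,
            compositions[ref_ingredient], compositions[meal],
            aggregate=config.aggregation)
    return reference_ds, ref_coeffs, ingredient_coeffs


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the report bundle.

    Outputs under ``config.output_dir``: ``digestibility.csv``,
    ``energy_profiles.csv``, ``intake.csv``, ``gains.csv``,
    ``comparisons.csv`` and Markdown tables ``digestibility.md``,
    ``energy.md``, ``gains.md``, ``intake.md``.
    """
    logger.info("energy constants: DE=TDN x %s, ME=DE x %s, EE weight %s",
                config.constants.de_factor, config.constants.me_factor,
                config.constants.ee_weight)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    datasets = load_trials(config.input_dir)
    if not datasets:
        raise FeedEvalError("stage load: no treatments found in input")
    for diet_id, dataset in datasets.items():
        problems = validate_trial(dataset)
        if problems:
            raise FeedEvalError(
                f"stage validate: treatment {diet_id}: " + "; ".join(problems))
    compositions = {p.ingredient_id: p for p in read_composition_table(
        config.input_dir / "compositions.csv")}

    reference_ds, ref_coeffs, ingredient_coeffs = _digestibility_stage(
        datasets, compositions, config)

    test_datasets = {d.diet.test_ingredient: d for d in datasets.values()
                     if d.diet.role == "test"}
    meals = list(ingredient_coeffs)

    energy_profiles = {
        meal: ingredient_energy_profile(
            compositions[meal], ingredient_coeffs[meal], config.constants)
        for meal in meals}
    intakes = {
        meal: intake_summary(
            test_datasets[meal],
            ingredient_profile=compositions[meal])
        for meal in meals}
    gains = {meal: gain_summary(test_datasets[meal], n_days=config.n_days)
             for meal in meals}

    comparisons = _comparisons(ingredient_coeffs, intakes, gains, config)
    files = _write_outputs(config, ref_coeffs, ingredient_coeffs,
                           energy_profiles, intakes, gains, comparisons)
    return PipelineResult(
        reference_coeffs=ref_coeffs, ingredient_coeffs=ingredient_coeffs,
        energy_profiles=energy_profiles, intakes=intakes, gains=gains,
        comparisons=comparisons, output_files=files)


@_stage("comparisons")
def _comparisons(ingredient_coeffs, intakes, gains, config):
    comparisons: list[GroupComparison] = []
    meals = list(ingredient_coeffs)
    if len(meals) < 2:
        return comparisons
    letters_kw = dict(alpha=config.alpha, protected=config.protected)
    for nutrient in NUTRIENTS:
        values, labels = [], []
        for meal in meals:
            coeffs = ingredient_coeffs[meal]
            if nutrient in coeffs.absent or not coeffs.per_animal:
                continue
            sample = [coeffs.per_animal[a][nutrient]
                      for a in coeffs.per_animal
                      if nutrient in coeffs.per_animal[a]]
            if len(sample) >= 2:
                values.append(sample)
                labels.append(meal)
        if len(values) >= 2:
            comparisons.append(compare_treatments(
                values, labels, variable=f"digestibility_{nutrient}",
                **letters_kw))
    for variable, summaries, column in (
            ("daily_gain_g", gains, "daily_gain_g"),
            ("total_gain_g", gains, "total_gain_g"),
            ("initial_g", gains, "initial_g"),
            ("final_g", gains, "final_g"),
            ("pct_live_weight", intakes, "pct_live_weight"),
            ("g_per_kg_metabolic", intakes, "g_per_kg_metabolic")):
        values = [summaries[m].per_animal[column].tolist() for m in meals]
        comparisons.append(compare_treatments(
            values, meals, variable=variable, **letters_kw))
    return comparisons


def _write_outputs(config, ref_coeffs, ingredient_coeffs, energy_profiles,
                   intakes, gains, comparisons) -> list[Path]:
    out = config.output_dir
    files = []
    letters = {c.variable: c.letters_by_label for c in comparisons}

    rows = []
    for subject, coeffs in [(ref_coeffs.subject_id, ref_coeffs)] + [
            (m, c) for m, c in ingredient_coeffs.items()]:
        for nutrient in NUTRIENTS:
            if nutrient in coeffs.absent:
                rows.append(dict(diet_id=subject, nutrient=nutrient,
                                 mean_pct="", sd_pct="", n=coeffs.n_animals,
                                 flag="absent"))
            elif nutrient in coeffs.mean_pct:
                rows.append(dict(
                    diet_id=subject, nutrient=nutrient,
                    mean_pct=coeffs.mean_pct[nutrient],
                    sd_pct=coeffs.sd_pct.get(nutrient, 0.0),
                    n=coeffs.n_animals,
                    flag=coeffs.flags.get(nutrient, "")))
    path = out / "digestibility.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    files.append(path)

    rows = []
    for meal, ep in energy_profiles.items():
        rows.append(dict(
            ingredient_id=meal,
            **{f"d{n}_pct": (None if n in ep.absent else ep.digestible_pct[n])
               for n in ("dm", "cp", "ee", "cf", "nfe")},
            tdn_pct=ep.tdn_pct, de_kcal_kg=ep.de_kcal_kg,
            me_kcal_kg=ep.me_kcal_kg))
    path = out / "energy_profiles.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    files.append(path)

    for name, summaries in (("intake", intakes), ("gains", gains)):
        frames = []
        for meal, summary in summaries.items():
            frame = summary.per_animal.copy()
            frame.insert(0, "ingredient_id", meal)
            frames.append(frame.reset_index())
        path = out / f"{name}.csv"
        pd.concat(frames).to_csv(path, index=False)
        files.append(path)

    rows = []
    for comparison in comparisons:
        for group in comparison.groups:
            rows.append(dict(
                variable=comparison.variable, group=group.label, n=group.n,
                mean=group.mean, sd=group.sd, letters=group.letters,
                f_statistic=comparison.anova.f_statistic,
                p_value=comparison.anova.p_value,
                mse=comparison.anova.mse, alpha=comparison.alpha))
    path = out / "comparisons.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    files.append(path)

    files.append(_markdown_digestibility(out, ingredient_coeffs, letters))
    files.append(_markdown_energy(out, energy_profiles, letters))
    files.append(_markdown_means(out, "gains.md", gains,
                                 [("initial_g", "Initial weight, g"),
                                  ("final_g", "Final weight, g"),
                                  ("total_gain_g", "Total gain, g"),
                                  ("daily_gain_g", "Daily gain, g")], letters))
    files.append(_markdown_means(out, "intake.md", intakes,
                                 [("attributed_dm_g", "Meal DM intake, g/d"),
                                  ("pct_live_weight", "% live weight"),
                                  ("g_per_kg_metabolic", "g/kg W^0.75^")],
                                 letters))
    return files


def _markdown_digestibility(out, ingredient_coeffs, letters) -> Path:
    headers = ["Meal", "DM(%)", "CP(%)", "EE(%)", "CF(%)", "NFE(%)"]
    rows = []
    for meal, coeffs in ingredient_coeffs.items():
        row = [meal]
        for nutrient in ("dm", "cp", "ee", "cf", "nfe"):
            if nutrient in coeffs.absent or nutrient not in coeffs.mean_pct:
                row.append("-")
            else:
                row.append(format_cell(
                    coeffs.mean_pct[nutrient], coeffs.sd_pct.get(nutrient),
                    letters.get(f"digestibility_{nutrient}", {}).get(meal, "")))
        rows.append(row)
    path = out / "digestibility.md"
    path.write_text("Apparent digestibility coefficients of the test meals\n\n"
                    + render_table(headers, rows))
    return path


def _markdown_energy(out, energy_profiles, letters) -> Path:
    headers = ["Meal", "dDM(%)", "dCP(%)", "dEE(%)", "dCF(%)", "dNFE(%)",
               "TDN (%)", "DE (kcal/kg)", "ME (kcal/kg)"]
    rows = []
    for meal, ep in energy_profiles.items():
        row = [meal]
        for nutrient in ("dm", "cp", "ee", "cf", "nfe"):
            if nutrient in ep.absent:
                row.append("-")
            else:
                row.append(format_cell(ep.digestible_pct[nutrient],
                                       ep.digestible_sd.get(nutrient)))
        row.append(format_cell(ep.tdn_pct, ep.tdn_sd))
        row.append(format_cell(ep.de_kcal_kg, ep.de_sd, digits=0))
        row.append(format_cell(ep.me_kcal_kg, ep.me_sd, digits=0))
        rows.append(row)
    path = out / "energy.md"
    path.write_text("Digestible components and energy contribution\n\n"
                    + render_table(headers, rows))
    return path


def _markdown_means(out, filename, summaries, columns, letters) -> Path:
    meals = list(summaries)
    headers = ["Parameter"] + meals
    rows = []
    for column, label in columns:
        row = [label]
        for meal in meals:
            summary = summaries[meal]
            row.append(format_cell(
                summary.mean[column], summary.sd[column],
                letters.get(column, {}).get(meal, "")))
        rows.append(row)
    path = out / filename
    path.write_text(render_table(headers, rows))
    return path


def write_simulated_trials(datasets: dict[str, TrialDataset],
                           truths: dict[str, dict],
                           compositions: list,
                           directory: str | Path) -> None:
    """Write simulated treatments to the five CSV schemas plus truth.json."""
    from . import io as fio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    profiles = list(compositions)
    profiles += [d.diet_profile for d in datasets.values()]
    fio.write_composition_table(profiles, directory / "compositions.csv")
    fio.write_diet_table([d.diet for d in datasets.values()],
                         directory / "diets.csv")
    fio.write_records_table({k: d.records for k, d in datasets.items()},
                            directory / "records.csv")
    fio.write_fecal_table({k: d.fecal_profiles for k, d in datasets.items()},
                          directory / "fecal_composition.csv")
    fio.write_weights_table({k: d.weights for k, d in datasets.items()},
                            directory / "weights.csv")
    with open(directory / "truth.json", "w") as handle:
        json.dump(truths, handle, indent=1, default=str)
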