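"""Readers and writers for the five trial CSV schemas.

Schemas (comma-separated, UTF-8, ``.`` decimal):

- ``compositions.csv``: ingredient_id,dm_pct,cp_pct,ee_pct,cf_pct,nfe_pct,ash_pct
- ``diets.csv``: diet_id,ingredient_id,fraction,role
- ``records.csv``: diet_id,animal_id,day,offered_g,refused_g,feces_fresh_g,feces_dm_fraction
- ``fecal_composition.csv``: diet_id,animal_id,cp_pct,ee_pct,cf_pct,nfe_pct,ash_pct
- ``weights.csv``: diet_id,animal_id,initial_g,final_g

In the CF and NFE columns of composition tables a dagger (``†``), ``NA`` or
an empty cell marks a component the feed does not contain; the value is read
as 0 with the corresponding absent flag set.  Reading is total: every
malformed cell yields a located diagnostic rather than a traceback.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .trial import (
    ABSENT_MARKER,
    AnimalDayRecord,
    DietSpec,
    FeedEvalError,
    ProximateProfile,
    TrialDataset,
)

logger = logging.getLogger(__name__)

ABSENT_TOKENS = {ABSENT_MARKER, "NA", ""}

COMPOSITION_COLUMNS = [
    "ingredient_id", "dm_pct", "cp_pct", "ee_pct", "cf_pct", "nfe_pct", "ash_pct",
]
DIET_COLUMNS = ["diet_id", "ingredient_id", "fraction", "role"]
RECORD_COLUMNS = [
    "diet_id", "animal_id", "day", "offered_g", "refused_g",
    "feces_fresh_g", "feces_dm_fraction",
]
FECAL_COLUMNS = [
    "diet_id", "animal_id", "cp_pct", "ee_pct", "cf_pct", "nfe_pct", "ash_pct",
]
WEIGHT_COLUMNS = ["diet_id", "animal_id", "initial_g", "final_g"]


class SchemaError(FeedEvalError):
    """A required column is missing from an input table."""


class ParseError(FeedEvalError):
    """A cell could not be parsed; the message locates row and column."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}")
    return frame


def _cell_float(raw: str, path, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric value {raw!r} at row {row}, "
            f"column {column!r}") from None


def read_composition_table(path: str | Path) -> list[ProximateProfile]:
    """Load ingredient/diet proximate profiles, honoring absent markers.

    Row order is preserved.  An empty table returns an empty list with a
    logged warning.
    """
    frame = _read_csv(path, COMPOSITION_COLUMNS)
    if frame.empty:
        logger.warning("%s: composition table is empty", path)
        return []
    profiles = []
    for i, row in frame.iterrows():
        values: dict[str, float] = {}
        flags = {"cf_absent": False, "nfe_absent": False}
        for column in COMPOSITION_COLUMNS[1:]:
            raw = str(row[column]).strip()
            nutrient = column[:-4]
            if nutrient in ("cf", "nfe") and raw in ABSENT_TOKENS:
                values[column] = 0.0
                flags[f"{nutrient}_absent"] = True
            else:
                values[column] = _cell_float(raw, path, i + 2, column)
        profiles.append(
            ProximateProfile(ingredient_id=str(row["ingredient_id"]),
                             **values, **flags))
    return profiles


def write_composition_table(profiles: list[ProximateProfile],
                            path: str | Path) -> None:
    """Write profiles back to CSV, restoring the dagger for absent cells."""
    rows = []
    for p in profiles:
        row = {"ingredient_id": p.ingredient_id}
        for column in COMPOSITION_COLUMNS[1:]:
            nutrient = column[:-4]
            if nutrient in ("cf", "nfe") and p.is_absent(nutrient):
                row[column] = ABSENT_MARKER
            else:
                row[column] = repr(getattr(p, column))
        rows.append(row)
    pd.DataFrame(rows, columns=COMPOSITION_COLUMNS).to_csv(path, index=False)


def read_diet_table(path: str | Path) -> list[DietSpec]:
    """Load ration recipes grouped by diet id.

    For test diets the test ingredient is the single component that is not
    itself a reference diet id, and the reference diet is the component that
    is one (the usual reference + one test ingredient layout).
    """
    frame = _read_csv(path, DIET_COLUMNS)
    diets: list[DietSpec] = []
    # ingredients making up reference-role diets identify the reference feed
    reference_ids = set(
        frame.loc[frame["role"].str.strip() == "reference", "ingredient_id"]
        .str.strip())
    for diet_id, group in frame.groupby("diet_id", sort=False):
        components = []
        for i, row in group.iterrows():
            components.append((
                str(row["ingredient_id"]).strip(),
                _cell_float(str(row["fraction"]).strip(), path, i + 2,
                            "fraction"),
            ))
        role = str(group["role"].iloc[0]).strip()
        test_ingredient = reference = None
        if role == "test":
            for ingredient_id, _ in components:
                if ingredient_id in reference_ids:
                    reference = ingredient_id
                else:
                    test_ingredient = ingredient_id
        diets.append(DietSpec(diet_id=str(diet_id), components=components,
                              role=role, test_ingredient=test_ingredient,
                              reference_diet=reference))
    return diets


def write_diet_table(diets: list[DietSpec], path: str | Path) -> None:
    rows = [
        {"diet_id": d.diet_id, "ingredient_id": iid,
         "fraction": repr(fraction), "role": d.role}
        for d in diets for iid, fraction in d.components
    ]
    pd.DataFrame(rows, columns=DIET_COLUMNS).to_csv(path, index=False)


def read_records_table(path: str | Path) -> dict[str, list[AnimalDayRecord]]:
    """Load daily intake/feces records keyed by diet id."""
    frame = _read_csv(path, RECORD_COLUMNS)
    out: dict[str, list[AnimalDayRecord]] = {}
    for i, row in frame.iterrows():
        try:
            day = int(float(str(row["day"]).strip()))
        except ValueError:
            raise ParseError(
                f"{path}: non-integer day {row['day']!r} at row {i + 2}"
            ) from None
        record = AnimalDayRecord(
            animal_id=str(row["animal_id"]).strip(),
            day=day,
            offered_g=_cell_float(str(row["offered_g"]).strip(), path, i + 2,
                                  "offered_g"),
            refused_g=_cell_float(str(row["refused_g"]).strip(), path, i + 2,
                                  "refused_g"),
            feces_fresh_g=_cell_float(str(row["feces_fresh_g"]).strip(), path,
                                      i + 2, "feces_fresh_g"),
            feces_dm_fraction=_cell_float(str(row["feces_dm_fraction"]).strip(),
                                          path, i + 2, "feces_dm_fraction"),
        )
        out.setdefault(str(row["diet_id"]).strip(), []).append(record)
    return out


def write_records_table(records: dict[str, list[AnimalDayRecord]],
                        path: str | Path) -> None:
    rows = []
    for diet_id, diet_records in records.items():
        for r in diet_records:
            rows.append({
                "diet_id": diet_id, "animal_id": r.animal_id, "day": r.day,
                "offered_g": repr(r.offered_g),
                "refused_g": repr(r.refused_g),
                "feces_fresh_g": repr(r.feces_fresh_g),
                "feces_dm_fraction": repr(r.feces_dm_fraction),
            })
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_fecal_table(path: str | Path) -> dict[str, dict[str, ProximateProfile]]:
    """Load per-animal pooled fecal compositions, dry-matter basis."""
    frame = _read_csv(path, FECAL_COLUMNS)
    out: dict[str, dict[str, ProximateProfile]] = {}
    for i, row in frame.iterrows():
        values = {}
        flags = {"cf_absent": False, "nfe_absent": False}
        for column in FECAL_COLUMNS[2:]:
            raw = str(row[column]).strip()
            nutrient = column[:-4]
            if nutrient in ("cf", "nfe") and raw in ABSENT_TOKENS:
                values[column] = 0.0
                flags[f"{nutrient}_absent"] = True
            else:
                values[column] = _cell_float(raw, path, i + 2, column)
        animal_id = str(row["animal_id"]).strip()
        profile = ProximateProfile(
            ingredient_id=f"feces:{animal_id}", dm_pct=100.0,
            basis="dry_matter", **values, **flags)
        out.setdefault(str(row["diet_id"]).strip(), {})[animal_id] = profile
    return out


def write_fecal_table(profiles: dict[str, dict[str, ProximateProfile]],
                      path: str | Path) -> None:
    rows = []
    for diet_id, by_animal in profiles.items():
        for animal_id, p in by_animal.items():
            row = {"diet_id": diet_id, "animal_id": animal_id}
            for column in FECAL_COLUMNS[2:]:
                nutrient = column[:-4]
                if nutrient in ("cf", "nfe") and p.is_absent(nutrient):
                    row[column] = ABSENT_MARKER
                else:
                    row[column] = repr(getattr(p, column))
            rows.append(row)
    pd.DataFrame(rows, columns=FECAL_COLUMNS).to_csv(path, index=False)


def read_weights_table(path: str | Path) -> dict[str, dict[str, tuple[float, float]]]:
    frame = _read_csv(path, WEIGHT_COLUMNS)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for i, row in frame.iterrows():
        out.setdefault(str(row["diet_id"]).strip(), {})[
            str(row["animal_id"]).strip()] = (
            _cell_float(str(row["initial_g"]).strip(), path, i + 2, "initial_g"),
            _cell_float(str(row["final_g"]).strip(), path, i + 2, "final_g"),
        )
    return out


def write_weights_table(weights: dict[str, dict[str, tuple[float, float]]],
                        path: str | Path) -> None:
    rows = [
        {"diet_id": diet_id, "animal_id": animal_id,
         "initial_g": repr(initial), "final_g": repr(final)}
        for diet_id, by_animal in weights.items()
        for animal_id, (initial, final) in by_animal.items()
    ]
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(path, index=False)


def load_trials(directory: str | Path,
                diet_profiles: dict[str, ProximateProfile] | None = None,
                ) -> dict[str, TrialDataset]:
    """Assemble one :class:`TrialDataset` per diet from a directory of CSVs.

    Expects the five schema files under ``directory``.  The as-offered
    profile of each diet is taken from ``compositions.csv`` rows whose
    ingredient_id equals the diet_id (the convention the ``simulate``
    subcommand writes), unless ``diet_profiles`` overrides it.
    """
    directory = Path(directory)
    compositions = {p.ingredient_id: p for p in
                    read_composition_table(directory / "compositions.csv")}
    if diet_profiles:
        compositions.update(diet_profiles)
    diets = read_diet_table(directory / "diets.csv")
    records = read_records_table(directory / "records.csv")
    fecal = read_fecal_table(directory / "fecal_composition.csv")
    weights = read_weights_table(directory / "weights.csv")

    datasets: dict[str, TrialDataset] = {}
    for diet in diets:
        if diet.diet_id not in records:
            continue
        if diet.diet_id not in compositions:
            raise SchemaError(
                f"no as-offered composition row for diet {diet.diet_id!r}")
        datasets[diet.diet_id] = TrialDataset(
            diet=diet,
            diet_profile=compositions[diet.diet_id],
            fecal_profiles=fecal.get(diet.diet_id, {}),
            records=records[diet.diet_id],
            weights=weights.get(diet.diet_id, {}),
        )
    return datasets
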