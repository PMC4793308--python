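"""Domain types and tabular I/O for individual-based monkey-plant feeding data.

The central object is the :class:`InteractionMatrix`: focal individuals as
rows, consumed plant species as columns, nonnegative integer weights per
cell (feeding-record counts, summed minutes, or presence/absence).  All
network metrics operate on this object.

Tabular files are plain UTF-8 CSV with a header row; ``-`` (or the
typographic en dash) in packaged reference tables denotes absence.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Habitat",
    "Sex",
    "AgeClass",
    "Item",
    "ObservationRecord",
    "Individual",
    "TransectRecord",
    "InteractionMatrix",
    "StatTestResult",
    "SchemaError",
    "ValidationError",
    "read_observations",
    "write_observations",
    "read_transects",
    "write_transects",
    "build_interaction_matrix",
    "load_fixture",
    "count_species_by_habitat",
]


class SchemaError(ValueError):
    """A required column is missing from a tabular file."""


class ValidationError(ValueError):
    """A row violates a field constraint (bad enum code, negative value...)."""


class Habitat(str, enum.Enum):
    continuous = "continuous"
    fragment = "fragment"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class AgeClass(str, enum.Enum):
    adult = "adult"
    juvenile = "juvenile"
    infant = "infant"


class Item(str, enum.Enum):
    """The seven plant items: bark, immature/mature fruit, flower,
    immature/mature leaf, petiole."""

    B = "B"
    IF = "IF"
    FL = "FL"
    MF = "MF"
    IL = "IL"
    ML = "ML"
    P = "P"


#: The six age/sex classes, in display order (adult female first).
SIX_CLASSES: tuple[tuple[Sex, AgeClass], ...] = (
    (Sex.F, AgeClass.adult),
    (Sex.M, AgeClass.adult),
    (Sex.F, AgeClass.juvenile),
    (Sex.M, AgeClass.juvenile),
    (Sex.F, AgeClass.infant),
    (Sex.M, AgeClass.infant),
)


def class_label(sex: Sex, age: AgeClass) -> str:
    return f"{age.value}_{sex.value}"


@dataclass(frozen=True)
class ObservationRecord:
    """One focal feeding bout."""

    record_id: str
    habitat: Habitat
    site_id: str
    individual_id: str
    sex: Sex
    age_class: AgeClass
    plant_species: str
    item: Item
    duration: float  # minutes

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration) or self.duration < 0:
            raise ValidationError(
                f"record {self.record_id!r}: duration must be finite and >= 0, "
                f"got {self.duration}"
            )


@dataclass(frozen=True)
class Individual:
    individual_id: str
    sex: Sex
    age_class: AgeClass
    habitat: Habitat
    group_id: str = ""

    @property
    def class_label(self) -> str:
        return class_label(self.sex, self.age_class)


@dataclass(frozen=True)
class TransectRecord:
    """One tree (dbh >= 10 cm) recorded on a 50 x 2 m vegetation transect."""

    site_id: str
    habitat: Habitat
    transect_id: str
    x: float
    y: float
    species: str
    dbh: float  # cm

    def __post_init__(self) -> None:
        if not np.isfinite(self.dbh) or self.dbh < 10:
            raise ValidationError(
                f"transect {self.transect_id!r}: dbh must be >= 10 cm, got {self.dbh}"
            )


@dataclass(frozen=True)
class StatTestResult:
    """A test statistic with degrees of freedom and p-value.

    ``df`` is a single number (t-tests, Mantel) or a (num, den) pair
    (F-tests); ``transform_applied`` records any variance-stabilizing
    transform applied before testing.
    """

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    transform_applied: str = "none"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Interaction matrix


class InteractionMatrix:
    """Individuals (rows) x plant species (columns) with integer weights.

    ``weights[i, j]`` counts feeding interactions (or minutes) of individual
    ``row_labels[i]`` on species ``col_labels[j]``.  ``binary()`` gives the
    qualitative presence/absence view used for nestedness.
    """

    def __init__(
        self,
        weights: np.ndarray,
        row_labels: Sequence[str],
        col_labels: Sequence[str],
    ) -> None:
        weights = np.asarray(weights)
        if weights.ndim != 2:
            raise ValueError("weights must be 2-D")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if weights.shape != (len(row_labels), len(col_labels)):
            raise ValueError("label lengths do not match weight shape")
        row_labels = [str(r).strip() for r in row_labels]
        col_labels = [str(c).strip() for c in col_labels]
        if len(set(row_labels)) != len(row_labels):
            raise ValueError("duplicate row labels")
        if len(set(col_labels)) != len(col_labels):
            raise ValueError("duplicate column labels")
        self.weights = weights
        self.row_labels = list(row_labels)
        self.col_labels = list(col_labels)

    # -- basic structure ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def is_binary(self) -> bool:
        return bool(np.isin(self.weights, (0, 1)).all())

    def binary(self) -> "InteractionMatrix":
        return InteractionMatrix(
            (self.weights > 0).astype(int), self.row_labels, self.col_labels
        )

    def row_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.weights, axis=1)

    def col_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.weights, axis=0)

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.row_labels, columns=self.col_labels
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="individual")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionMatrix":
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    @classmethod
    def from_csv(cls, path: str | Path) -> "InteractionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.weights, other.weights)
        )

    def __repr__(self) -> str:
        r, c = self.shape
        return f"<InteractionMatrix {r}x{c}, L={self.n_links}>"


# ---------------------------------------------------------------------------
# Tabular readers/writers

OBSERVATION_COLUMNS = [
    "record_id",
    "habitat",
    "site_id",
    "individual_id",
    "sex",
    "age_class",
    "plant_species",
    "item",
    "duration",
]

TRANSECT_COLUMNS = ["site_id", "habitat", "transect_id", "x", "y", "species", "dbh"]


def _require_columns(frame: pd.DataFrame, required: Iterable[str], kind: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{kind} file is missing column(s): {', '.join(missing)}")


def _parse_enum(cls, value, row: int, what: str):
    try:
        return cls(str(value).strip())
    except ValueError:
        raise ValidationError(
            f"row {row}: unknown {what} code {value!r} "
            f"(allowed: {', '.join(m.value for m in cls)})"
        ) from None


def read_observations(path: str | Path) -> list[ObservationRecord]:
    """Read focal feeding records from CSV, validating every row."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, OBSERVATION_COLUMNS, "observations")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            duration = float(getattr(row, "duration"))
        except ValueError:
            raise ValidationError(f"row {idx}: non-numeric duration") from None
        if not np.isfinite(duration) or duration < 0:
            raise ValidationError(f"row {idx}: duration must be finite and >= 0")
        records.append(
            ObservationRecord(
                record_id=str(getattr(row, "record_id")),
                habitat=_parse_enum(Habitat, getattr(row, "habitat"), idx, "habitat"),
                site_id=str(getattr(row, "site_id")),
                individual_id=str(getattr(row, "individual_id")),
                sex=_parse_enum(Sex, getattr(row, "sex"), idx, "sex"),
                age_class=_parse_enum(
                    AgeClass, getattr(row, "age_class"), idx, "age class"
                ),
                plant_species=str(getattr(row, "plant_species")).strip(),
                item=_parse_enum(Item, getattr(row, "item"), idx, "item"),
                duration=duration,
            )
        )
    return records


def write_observations(records: Iterable[ObservationRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "habitat": r.habitat.value,
            "site_id": r.site_id,
            "individual_id": r.individual_id,
            "sex": r.sex.value,
            "age_class": r.age_class.value,
            "plant_species": r.plant_species,
            "item": r.item.value,
            "duration": r.duration,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def read_transects(path: str | Path) -> list[TransectRecord]:
    frame = pd.read_csv(path)
    _require_columns(frame, TRANSECT_COLUMNS, "transects")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        dbh = float(getattr(row, "dbh"))
        if not np.isfinite(dbh) or dbh < 10:
            raise ValidationError(f"row {idx}: dbh must be >= 10 cm, got {dbh}")
        records.append(
            TransectRecord(
                site_id=str(getattr(row, "site_id")),
                habitat=_parse_enum(Habitat, getattr(row, "habitat"), idx, "habitat"),
                transect_id=str(getattr(row, "transect_id")),
                x=float(getattr(row, "x")),
                y=float(getattr(row, "y")),
                species=str(getattr(row, "species")).strip(),
                dbh=dbh,
            )
        )
    return records


def write_transects(records: Iterable[TransectRecord], path: str | Path) -> None:
    rows = [
        {
            "site_id": r.site_id,
            "habitat": r.habitat.value,
            "transect_id": r.transect_id,
            "x": r.x,
            "y": r.y,
            "species": r.species,
            "dbh": r.dbh,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRANSECT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrix construction


def build_interaction_matrix(
    records: Sequence[ObservationRecord],
    habitat: Habitat | str,
    weighting: str = "count",
    individuals: Sequence[Individual] | None = None,
) -> InteractionMatrix:
    """Build the individual x plant matrix for one habitat.

    weighting
        ``count`` — number of feeding records per cell; ``minutes`` —
        summed bout duration; ``binary`` — presence/absence.
    individuals
        Optional census.  Censused individuals of the habitat with no
        feeding record are retained as all-zero rows (with a warning) so
        that the reported number of monkeys matches the census.
    """
    habitat = Habitat(habitat)
    if weighting not in ("count", "minutes", "binary"):
        raise ValueError(f"unknown weighting {weighting!r}")
    sub = [r for r in records if r.habitat is habitat]
    if not sub and not individuals:
        raise ValueError(f"no feeding records for habitat {habitat.value!r}")

    row_ids = sorted({r.individual_id for r in sub})
    if individuals is not None:
        census_ids = [i.individual_id for i in individuals if i.habitat is habitat]
        silent = sorted(set(census_ids) - set(row_ids))
        if silent:
            logger.warning(
                "%d censused individual(s) with no feeding record in %s kept "
                "as all-zero rows: %s",
                len(silent),
                habitat.value,
                ", ".join(silent),
            )
        row_ids = sorted(set(census_ids) | set(row_ids))
    col_ids = sorted({r.plant_species for r in sub})
    if not row_ids or not col_ids:
        raise ValueError(f"no feeding records for habitat {habitat.value!r}")

    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: j for j, c in enumerate(col_ids)}
    dtype = float if weighting == "minutes" else int
    weights = np.zeros((len(row_ids), len(col_ids)), dtype=dtype)
    for rec in sub:
        i, j = ri[rec.individual_id], ci[rec.plant_species]
        if weighting == "minutes":
            weights[i, j] += rec.duration
        else:
            weights[i, j] += 1
    if weighting == "binary":
        weights = (weights > 0).astype(int)
    return InteractionMatrix(weights, row_ids, col_ids)


# ---------------------------------------------------------------------------
# Packaged reference tables

_FIXTURES = {
    "table2_ivi": "table2_ivi.csv",
    "table3_items": "table3_items.csv",
    "table4_attributes": "table4_attributes.csv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table.

    ``table2_ivi`` — top-10 importance value index per habitat;
    ``table3_items`` — consumed items and core/periphery occurrence
    percentages per plant species and habitat; ``table4_attributes`` —
    network attributes per habitat.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(_FIXTURES))}"
        )
    ref = resources.files("howlernet.data").joinpath(_FIXTURES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _item_list(cell: str) -> list[str]:
    cell = str(cell).strip()
    if cell in ("-", "–", "", "nan"):
        return []
    return [tok.strip() for tok in cell.split("|") if tok.strip()]


def species_items(table3: pd.DataFrame, habitat: Habitat | str) -> dict[str, list[str]]:
    """Map species -> consumed item codes in one habitat (empty list = absent)."""
    habitat = Habitat(habitat)
    col = "items_continuous" if habitat is Habitat.continuous else "items_fragments"
    return {
        str(row["species"]).strip(): _item_list(row[col])
        for _, row in table3.iterrows()
    }


def count_species_by_habitat(table3: pd.DataFrame) -> dict[str, int]:
    """Species bookkeeping from the per-species item table.

    A species counts toward a habitat iff it has at least one consumed item
    there.  Returns counts for each habitat, the total number of distinct
    species, the number shared between habitats, and the number of distinct
    item codes appearing anywhere in the table.
    """
    cont = {s for s, items in species_items(table3, Habitat.continuous).items() if items}
    frag = {s for s, items in species_items(table3, Habitat.fragment).items() if items}
    items: set[str] = set()
    for hab in Habitat:
        for lst in species_items(table3, hab).values():
            items.update(lst)
    return {
        "continuous": len(cont),
        "fragments": len(frag),
        "total": len(cont | frag),
        "shared": len(cont & frag),
        "n_items": len(items),
    }
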