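"""Nutrient reference table and the fixed milk (nfs) profile.

A food's nutrient content is looked up by its 8-digit USDA food code in an
FNDDS-style reference table holding per-100-g values for the 18 nutrients
tracked throughout the package.  The milk profile used by both diet-modeling
scenarios is the composite "milk, not further specified" (food code
11100000), carried as a fixed per-cup nutrient vector with a cup mass of
~225 g.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical nutrient order used by every table and vector in the package.
NUTRIENTS: tuple[str, ...] = (
    "energy",        # kcal
    "carbohydrate",  # g
    "fiber",         # g
    "total_sugars",  # g
    "added_sugars",  # tsp eq
    "protein",       # g
    "total_fat",     # g
    "mufa",          # g
    "pufa",          # g
    "sfa",           # g
    "calcium",       # mg
    "magnesium",     # mg
    "potassium",     # mg
    "sodium",        # mg
    "vitamin_a",     # ug RAE
    "folate",        # ug DFE
    "vitamin_b12",   # ug
    "vitamin_d",     # ug
)

#: Grams of sugar per teaspoon-equivalent of added sugars.
GRAMS_PER_TSP_ADDED_SUGAR = 4.2

#: Nutrient databases report dairy total sugars (lactose assay) slightly
#: above carbohydrate-by-difference; allow this much excess per 100 g.
SUGAR_CARB_TOLERANCE = 0.25

_FAT_PARTITION_TOL = 1e-6


class NutrientLookupError(KeyError):
    """Raised when a food code is absent from the reference table."""


class NutrientValidationError(ValueError):
    """Raised when a nutrient vector or food record violates an invariant."""


class NutrientVector:
    """An 18-component nutrient quantity, closed under addition and
    nonnegative scalar scaling."""

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(NUTRIENTS),):
            raise NutrientValidationError(
                f"expected {len(NUTRIENTS)} components, got shape {arr.shape}"
            )
        self.values = arr

    # -- constructors -------------------------------------------------
    @classmethod
    def zeros(cls) -> "NutrientVector":
        return cls(np.zeros(len(NUTRIENTS)))

    @classmethod
    def from_mapping(cls, mapping) -> "NutrientVector":
        missing = [k for k in NUTRIENTS if k not in mapping]
        if missing:
            raise NutrientValidationError(f"missing nutrients: {missing}")
        return cls([float(mapping[k]) for k in NUTRIENTS])

    # -- algebra ------------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(self.values + other.values)

    def __sub__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(self.values - other.values)

    def __mul__(self, scalar: float) -> "NutrientVector":
        if scalar < 0:
            raise NutrientValidationError("scaling factor must be nonnegative")
        return NutrientVector(self.values * float(scalar))

    __rmul__ = __mul__

    def __getitem__(self, name: str) -> float:
        return float(self.values[NUTRIENTS.index(name)])

    def __eq__(self, other) -> bool:
        return isinstance(other, NutrientVector) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        parts = ", ".join(f"{k}={v:g}" for k, v in zip(NUTRIENTS, self.values))
        return f"NutrientVector({parts})"

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(NUTRIENTS))

    def isclose(self, other: "NutrientVector", atol=1e-9) -> bool:
        return bool(np.allclose(self.values, other.values, atol=atol, rtol=0.0))

    # -- validation ---------------------------------------------------
    def validate(self, *, check_composition: bool = True) -> "NutrientVector":
        """Check invariants.

        Nonnegativity always; with ``check_composition`` (meant for
        per-100-g reference rows) also the fat partition, fiber/sugar vs
        carbohydrate bounds and the added-sugar gram bound.
        """
        if np.any(self.values < 0):
            bad = NUTRIENTS[int(np.argmax(self.values < 0))]
            raise NutrientValidationError(f"negative nutrient value: {bad}")
        if check_composition:
            if (
                self["mufa"] + self["pufa"] + self["sfa"]
                > self["total_fat"] + _FAT_PARTITION_TOL
            ):
                raise NutrientValidationError("mufa+pufa+sfa exceeds total fat")
            if self["fiber"] > self["carbohydrate"] + _FAT_PARTITION_TOL:
                raise NutrientValidationError("fiber exceeds carbohydrate")
            if self["total_sugars"] > self["carbohydrate"] + SUGAR_CARB_TOLERANCE:
                raise NutrientValidationError("total sugars exceed carbohydrate")
            if (
                self["added_sugars"] * GRAMS_PER_TSP_ADDED_SUGAR
                > self["total_sugars"] + _FAT_PARTITION_TOL
            ):
                raise NutrientValidationError("added sugars exceed total sugars")
        return self


@dataclass(frozen=True)
class FoodRecord:
    """One row of the nutrient reference: a food code and its per-100-g
    nutrient profile."""

    food_code: str
    wweia_code: str
    description: str
    nutrients_per_100g: NutrientVector

    def __post_init__(self):
        if len(self.food_code) != 8 or not self.food_code.isdigit():
            raise NutrientValidationError(
                f"food_code must be 8 digits, got {self.food_code!r}"
            )
        if len(self.wweia_code) != 4 or not self.wweia_code.isdigit():
            raise NutrientValidationError(
                f"wweia_code must be 4 digits, got {self.wweia_code!r}"
            )
        self.nutrients_per_100g.validate()


# ---------------------------------------------------------------------
# Milk, not further specified (food code 11100000)
# ---------------------------------------------------------------------

#: Per-cup (~225 g) nutrient content of milk-nfs, the composite across fat
#: levels used by both modeling scenarios.
MILK_NFS_PER_CUP = NutrientVector.from_mapping(
    {
        "energy": 122.0,
        "carbohydrate": 12.0,
        "fiber": 0.0,
        "total_sugars": 12.5,
        "added_sugars": 0.0,
        "protein": 8.1,
        "total_fat": 4.85,
        "mufa": 1.27,
        "pufa": 0.23,
        "sfa": 2.9,
        "calcium": 290.0,
        "magnesium": 27.0,
        "potassium": 358.0,
        "sodium": 103.5,
        "vitamin_a": 123.0,
        "folate": 11.5,
        "vitamin_b12": 1.14,
        "vitamin_d": 2.99,
    }
)

MILK_NFS_FOOD_CODE = "11100000"
DEFAULT_CUP_GRAMS = 225.0


@dataclass(frozen=True)
class MilkProfile:
    """Milk-nfs serving profile: per-cup nutrients and cup mass."""

    per_cup: NutrientVector = field(default_factory=lambda: MILK_NFS_PER_CUP)
    cup_grams: float = DEFAULT_CUP_GRAMS

    def __post_init__(self):
        if self.per_cup["fiber"] != 0.0:
            raise NutrientValidationError("milk-nfs must contain no fiber")
        if self.per_cup["added_sugars"] != 0.0:
            raise NutrientValidationError("milk-nfs must contain no added sugars")
        if self.energy_density <= 0:
            raise NutrientValidationError("milk energy density must be positive")

    @property
    def energy_density(self) -> float:
        """kcal per gram of milk."""
        return self.per_cup["energy"] / self.cup_grams

    def cups_for_energy(self, kcal: float) -> float:
        """Cup-equivalents of milk delivering exactly ``kcal``."""
        if kcal < 0:
            raise NutrientValidationError("energy must be nonnegative")
        return kcal / self.per_cup["energy"]

    def scale(self, cups: float) -> NutrientVector:
        return milk_nfs_profile(cups, per_cup=self.per_cup)


def milk_nfs_profile(cups: float, per_cup: NutrientVector | None = None) -> NutrientVector:
    """Nutrients in ``cups`` cup-equivalents of milk-nfs.

    Linear in ``cups``; negative amounts are rejected.
    """
    if cups < 0:
        raise NutrientValidationError(f"cups must be nonnegative, got {cups}")
    if per_cup is None:
        per_cup = MILK_NFS_PER_CUP
    return per_cup * cups


# ---------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------

REFERENCE_COLUMNS = ["food_code", "wweia_code", "description", *NUTRIENTS]


def default_reference_path() -> Path:
    return Path(
        importlib.resources.files("bevmod").joinpath("data/nutrient_reference.csv")
    )


def load_reference(path: str | Path | None = None, validate: bool = True) -> pd.DataFrame:
    """Load a nutrient reference CSV into a DataFrame indexed by food code.

    Codes are read as zero-padded strings (never integers).  Each row is
    checked against the per-100-g composition invariants unless ``validate``
    is disabled.
    """
    if path is None:
        path = default_reference_path()
    ref = pd.read_csv(path, dtype={"food_code": str, "wweia_code": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in ref.columns]
    if missing:
        raise NutrientValidationError(f"reference table missing columns: {missing}")
    ref = ref.set_index("food_code", drop=False)
    if ref.index.has_duplicates:
        dups = ref.index[ref.index.duplicated()].tolist()
        raise NutrientValidationError(f"duplicate food codes in reference: {dups}")
    if validate:
        for code, row in ref.iterrows():
            FoodRecord(
                food_code=str(code),
                wweia_code=str(row["wweia_code"]),
                description=str(row["description"]),
                nutrients_per_100g=NutrientVector(row[list(NUTRIENTS)].to_numpy(float)),
            )
    return ref


def lookup_nutrients(code: str, grams: float, reference: pd.DataFrame) -> NutrientVector:
    """Nutrients in ``grams`` of the food with 8-digit ``code``.

    Scales the per-100-g reference row linearly; unknown codes and negative
    gram amounts raise.
    """
    if grams < 0:
        raise NutrientValidationError(f"grams must be nonnegative, got {grams}")
    if code not in reference.index:
        raise NutrientLookupError(f"food code {code!r} not in reference table")
    per100 = reference.loc[code, list(NUTRIENTS)].to_numpy(dtype=float)
    return NutrientVector(per100 * (grams / 100.0))


def lookup_nutrients_frame(
    codes: pd.Series, grams: pd.Series, reference: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized :func:`lookup_nutrients` for a column of items."""
    if (grams < 0).any():
        raise NutrientValidationError("grams must be nonnegative")
    unknown = set(codes.unique()) - set(reference.index)
    if unknown:
        raise NutrientLookupError(f"food codes not in reference table: {sorted(unknown)}")
    per100 = reference.loc[codes, list(NUTRIENTS)].to_numpy(dtype=float)
    out = per100 * (grams.to_numpy(dtype=float)[:, None] / 100.0)
    return pd.DataFrame(out, columns=list(NUTRIENTS), index=codes.index)
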