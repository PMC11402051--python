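"""Synthetic day-1 24-h recall micro-data with known ground truth.

Emulates a stratified two-PSU-per-stratum dietary survey of children aged
1–5 y: each subject carries demographics and design fields (weight,
stratum, PSU); each recall line is one food item with an eating occasion,
codes, grams and per-portion nutrients.  Beverage gram intakes follow
age-linear means with zero-inflated gamma draws; non-beverage filler items
top expected daily energy up to an age-linear target.  All randomness flows
from one integer seed, so a fixed seed reproduces the dataset byte for
byte.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .nutrients import NUTRIENTS, lookup_nutrients_frame, load_reference

SUBJECT_COLUMNS = [
    "subject_id", "age", "gender", "ethnicity", "pir_category",
    "weight", "stratum", "psu",
]
ITEM_COLUMNS = [
    "subject_id", "occasion", "food_code", "wweia_code", "grams", *NUTRIENTS,
]

OCCASIONS = ("breakfast", "lunch", "dinner", "snack", "other")


class GeneratorConfigError(ValueError):
    pass


class CategorySpec(BaseModel):
    """Age-linear gram-intake model for one beverage category."""

    food_code: str
    intercept: float = Field(description="mean g/d at age 1")
    slope: float = Field(description="change in mean g/d per 1 y of age")
    prob: float = Field(gt=0, le=1, description="daily consumption probability")
    occasion_probs: Dict[str, float]

    @model_validator(mode="after")
    def _check(self):
        if abs(sum(self.occasion_probs.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("occasion probabilities must sum to 1")
        if set(self.occasion_probs) - set(OCCASIONS):
            raise GeneratorConfigError(f"unknown occasions in {self.occasion_probs}")
        return self

    def mean_at(self, age: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(age, float) - 1.0)


class FillerSpec(BaseModel):
    """A non-beverage item absorbing a share of the residual energy target."""

    food_code: str
    occasion: str
    share: float = Field(gt=0, le=1)


def _default_categories() -> Dict[str, CategorySpec]:
    milk_occ = {"breakfast": 0.35, "lunch": 0.20, "dinner": 0.30, "snack": 0.15}
    sweet_occ = {"breakfast": 0.05, "lunch": 0.35, "dinner": 0.35, "snack": 0.25}
    juice_occ = {"breakfast": 0.40, "lunch": 0.25, "dinner": 0.15, "snack": 0.20}
    return {
        "milk": CategorySpec(food_code="11100000", intercept=487.0, slope=-60.4,
                             prob=0.85, occasion_probs=milk_occ),
        "flavored_milk": CategorySpec(food_code="11511100", intercept=17.5, slope=14.8,
                                      prob=0.25, occasion_probs=milk_occ),
        "milk_substitutes": CategorySpec(food_code="11320000", intercept=18.3, slope=-3.01,
                                         prob=0.05, occasion_probs=milk_occ),
        "fruit_juice_100": CategorySpec(food_code="64100100", intercept=153.0, slope=-10.2,
                                        prob=0.55, occasion_probs=juice_occ),
        "soft_drinks": CategorySpec(food_code="92410310", intercept=16.5, slope=16.1,
                                    prob=0.35, occasion_probs=sweet_occ),
        "fruit_drinks": CategorySpec(food_code="92510610", intercept=72.5, slope=16.0,
                                     prob=0.45, occasion_probs=sweet_occ),
        "other_ssb": CategorySpec(food_code="95310560", intercept=14.0, slope=-0.3,
                                  prob=0.10, occasion_probs=sweet_occ),
        "coffee_tea": CategorySpec(food_code="92101000", intercept=16.0, slope=3.07,
                                   prob=0.08, occasion_probs=sweet_occ),
    }


def _default_fillers() -> List[FillerSpec]:
    return [
        FillerSpec(food_code="57123000", occasion="breakfast", share=0.25),
        FillerSpec(food_code="58106210", occasion="lunch", share=0.30),
        FillerSpec(food_code="27443000", occasion="dinner", share=0.35),
        FillerSpec(food_code="63107010", occasion="snack", share=0.10),
    ]


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic survey.

    Defaults: 1800 subjects per single-year age group (ages 1–5), 15 strata
    of 2 PSUs, demographic composition of a typical preschool NHANES age
    group, beverage intercepts equal to the observed age-1 means and slopes
    equal to the published per-year trend coefficients (milk −60.4 g/d/y,
    SSB +31.8 split across its subcategories, energy +108 kcal/d/y).
    """

    n_per_age: int = Field(default=1800, gt=0)
    ages: Tuple[int, ...] = (1, 2, 3, 4, 5)
    n_strata: int = Field(default=15, ge=1)
    psus_per_stratum: int = 2
    population_size: float = Field(default=4_000_000.0, gt=0)
    weight_sigma: float = Field(default=0.5, ge=0)
    gender_probs: Dict[str, float] = {"male": 0.5, "female": 0.5}
    ethnicity_probs: Dict[str, float] = {
        "mexican_american": 0.165,
        "other_hispanic": 0.073,
        "non_hispanic_white": 0.543,
        "non_hispanic_black": 0.137,
        "other": 0.082,
    }
    pir_probs: Dict[str, float] = {"<1.35": 0.399, "1.35-1.85": 0.108, ">1.85": 0.493}
    categories: Dict[str, CategorySpec] = Field(default_factory=_default_categories)
    fillers: List[FillerSpec] = Field(default_factory=_default_fillers)
    energy_intercept: float = 1289.0   # kcal/d at age 1
    energy_slope: float = 108.0        # kcal/d per 1 y of age
    gamma_shape: float = Field(default=4.0, gt=0)
    filler_gamma_shape: float = Field(default=8.0, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.psus_per_stratum < 2:
            raise GeneratorConfigError(
                "psus_per_stratum must be >= 2 (variance estimation would be undefined)"
            )
        for probs in (self.gender_probs, self.ethnicity_probs, self.pir_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise GeneratorConfigError("demographic probabilities must sum to 1")
        ages = np.asarray(self.ages, float)
        for name, cat in self.categories.items():
            if np.any(cat.mean_at(ages) < 0):
                raise GeneratorConfigError(
                    f"category {name!r} has a negative expected mean at some age"
                )
        if abs(sum(f.share for f in self.fillers) - 1.0) > 1e-9:
            raise GeneratorConfigError("filler energy shares must sum to 1")
        return self


# ---------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------

def _draw_categorical(rng, probs: Dict[str, float], n: int) -> np.ndarray:
    labels = list(probs)
    p = np.array([probs[k] for k in labels], float)
    return np.array(labels, dtype=object)[rng.choice(len(labels), size=n, p=p)]


def generate_design(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table: demographics plus survey-design fields.

    Subjects are spread round-robin over stratum×PSU cells; weights are
    lognormal, normalized to the configured population size.
    """
    n = config.n_per_age * len(config.ages)
    age = np.repeat(np.asarray(config.ages, int), config.n_per_age)
    cells = [
        (h, j)
        for h in range(1, config.n_strata + 1)
        for j in range(1, config.psus_per_stratum + 1)
    ]
    # round-robin over cells within each age group, so per-age analyses
    # still see every stratum with >= 2 PSUs
    stratum = np.empty(n, int)
    psu = np.empty(n, int)
    for a in config.ages:
        members = np.flatnonzero(age == a)
        order = rng.permutation(members)
        for pos, subj in enumerate(order):
            h, j = cells[pos % len(cells)]
            stratum[subj] = h
            psu[subj] = j
    weight = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    weight *= config.population_size / weight.sum()
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(1, n + 1)],
            "age": age,
            "gender": _draw_categorical(rng, config.gender_probs, n),
            "ethnicity": _draw_categorical(rng, config.ethnicity_probs, n),
            "pir_category": _draw_categorical(rng, config.pir_probs, n),
            "weight": weight,
            "stratum": stratum,
            "psu": psu,
        }
    )


def generate_recalls(
    subjects: pd.DataFrame,
    config: GeneratorConfig,
    reference: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Item table: zero-inflated gamma beverage draws plus energy filler.

    Per category the unconditional mean grams at age a is
    intercept + slope·(a−1); a Bernoulli(prob) indicator decides
    consumption and consumers draw Gamma(shape, mean/prob) grams.  Filler
    items then bring the expected daily energy to the configured age-linear
    target.  Every item's nutrients come from the reference lookup.
    """
    if reference is None:
        reference = load_reference()
    if rng is None:
        rng = np.random.default_rng()
    age = subjects["age"].to_numpy(float)
    n = len(subjects)
    energy_per_gram = reference["energy"] / 100.0

    frames = []
    bev_energy = np.zeros(n)
    for name, cat in config.categories.items():
        if cat.food_code not in reference.index:
            raise GeneratorConfigError(
                f"category {name!r}: food code {cat.food_code} not in reference"
            )
        mean = cat.mean_at(age)
        if np.any(mean < 0):
            raise GeneratorConfigError(f"negative expected mean for {name!r}")
        consumed = rng.random(n) < cat.prob
        grams = np.zeros(n)
        k = config.gamma_shape
        m = mean[consumed] / cat.prob
        grams[consumed] = rng.gamma(shape=k, scale=np.maximum(m, 1e-12) / k)
        bev_energy += mean * float(energy_per_gram[cat.food_code])
        idx = np.flatnonzero(consumed & (grams > 0))
        if len(idx) == 0:
            continue
        occ = _draw_categorical(rng, cat.occasion_probs, len(idx))
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subjects["subject_id"].to_numpy()[idx],
                    "occasion": occ,
                    "food_code": cat.food_code,
                    "grams": grams[idx],
                }
            )
        )

    filler_energy = config.energy_intercept + config.energy_slope * (age - 1.0) - bev_energy
    if np.any(filler_energy <= 0):
        raise GeneratorConfigError(
            "expected beverage energy exceeds the total-energy target at some age"
        )
    for spec in config.fillers:
        ed = float(energy_per_gram[spec.food_code])
        mean_grams = spec.share * filler_energy / ed
        k = config.filler_gamma_shape
        grams = rng.gamma(shape=k, scale=mean_grams / k)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subjects["subject_id"].to_numpy(),
                    "occasion": spec.occasion,
                    "food_code": spec.food_code,
                    "grams": grams,
                }
            )
        )

    items = pd.concat(frames, ignore_index=True)
    items = items.sort_values(["subject_id", "occasion", "food_code"], kind="stable")
    items = items.reset_index(drop=True)
    items["wweia_code"] = reference.loc[items["food_code"], "wweia_code"].to_numpy()
    nutr = lookup_nutrients_frame(items["food_code"], items["grams"], reference)
    items = pd.concat([items, nutr], axis=1)
    return items[ITEM_COLUMNS]


def generate_dataset(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded end-to-end generation: (subjects, items)."""
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    subjects = generate_design(config, rng)
    items = generate_recalls(subjects, config, reference=reference, rng=rng)
    return subjects, items


# ---------------------------------------------------------------------
# Micro-data IO (one CSV row per item, joined with subject fields)
# ---------------------------------------------------------------------

def write_microdata(subjects: pd.DataFrame, items: pd.DataFrame, path: str | Path) -> None:
    merged = items.merge(subjects, on="subject_id", how="left", validate="m:1")
    cols = SUBJECT_COLUMNS + [c for c in ITEM_COLUMNS if c != "subject_id"]
    merged[cols].to_csv(path, index=False)


def read_microdata(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(
        path,
        dtype={"food_code": str, "wweia_code": str},
        float_precision="round_trip",
    )
    subjects = (
        raw[SUBJECT_COLUMNS].drop_duplicates("subject_id").reset_index(drop=True)
    )
    items = raw[ITEM_COLUMNS].reset_index(drop=True)
    return subjects, items
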