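"""Within-person diet-modeling scenarios.

Scenario 1 (``add_milk``): one cup (~225 g) of milk-nfs is added to each
child's day, so the adjusted daily total is the baseline plus the per-cup
milk vector, for every nutrient and every subject.

Scenario 2 (``isocaloric_replace``): all nonmilk caloric beverages consumed
at lunch and dinner are removed and replaced with the exact milk-nfs amount
delivering the same energy (pooled over both meals), leaving every
subject's daily energy unchanged.  Children aged 1 y are excluded from both
scenarios by default, since they consume few nonmilk caloric beverages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Set

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .nutrients import NUTRIENTS, MilkProfile, NutrientVector
from .survey import (
    DesignEstimate,
    SurveyDesign,
    paired_design_test,
    population_ratio_mean,
)
from .taxonomy import ReplacementPolicy, classify_frame, load_rules, replaceable_mask


class ScenarioError(ValueError):
    pass


class ScenarioConfig(BaseModel):
    """Knobs of the two modeling scenarios."""

    scenario: Literal["add_milk", "isocaloric_replace"]
    cups_added: float = Field(default=1.0, ge=0)
    occasions: Set[str] = {"lunch", "dinner"}
    replaced_categories: Set[str] = {"cb", "milk_substitutes"}
    include_flavored_milk_in_replaced: bool = False
    exempt_juice: bool = False
    ages: Set[int] = {2, 3, 4, 5}

    def policy(self) -> ReplacementPolicy:
        if not self.occasions:
            raise ScenarioError("isocaloric replacement needs at least one occasion")
        return ReplacementPolicy(
            replaced_categories=frozenset(self.replaced_categories),
            occasions=frozenset(self.occasions),
            include_flavored_milk=self.include_flavored_milk_in_replaced,
            exempt_juice=self.exempt_juice,
        )


# ---------------------------------------------------------------------
# Daily totals
# ---------------------------------------------------------------------

def daily_totals(items: pd.DataFrame) -> NutrientVector:
    """Componentwise daily nutrient total for one subject-day."""
    if len(items) and items["subject_id"].nunique() > 1:
        raise ScenarioError("daily_totals expects items of a single subject")
    if len(items) == 0:
        return NutrientVector.zeros()
    return NutrientVector(items[list(NUTRIENTS)].sum(axis=0).to_numpy(float))


def daily_totals_frame(items: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-subject daily totals, with explicit zero rows for subjects who
    reported no items; indexed by subject_id in subject-table order."""
    totals = items.groupby("subject_id")[list(NUTRIENTS)].sum()
    return totals.reindex(subjects["subject_id"], fill_value=0.0)


# ---------------------------------------------------------------------
# Scenario result container
# ---------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Paired per-subject baseline/adjusted daily totals plus design info."""

    scenario: str
    subjects: pd.DataFrame
    baseline: pd.DataFrame
    adjusted: pd.DataFrame
    milk_cups_added: pd.Series
    milk_grams_added: pd.Series
    n_items_replaced: pd.Series
    alpha: float = 0.01
    _design: SurveyDesign = field(init=False, repr=False, default=None)

    def design(self) -> SurveyDesign:
        if self._design is None:
            self._design = SurveyDesign.from_frame(self.subjects)
        return self._design

    def paired_tests(self) -> pd.DataFrame:
        """Design-based paired test per nutrient, all ages pooled."""
        rows = []
        for nut in NUTRIENTS:
            est = paired_design_test(
                self.baseline[nut], self.adjusted[nut], self.design(), alpha=self.alpha
            )
            rows.append(
                {
                    "nutrient": nut,
                    "mean_difference": est.point,
                    "se": est.se,
                    "df": est.df,
                    "n": est.n,
                    "p_value": est.p_value,
                    "significant": (est.p_value is not None and est.p_value < self.alpha),
                    "degenerate": est.degenerate,
                }
            )
        return pd.DataFrame(rows)

    def summary_by_age(self) -> pd.DataFrame:
        """Tidy per-age table: baseline/adjusted weighted means with SEs and
        the per-age paired-test p-value (the shape of a published
        baseline/adjusted nutrient table)."""
        rows = []
        for age, idx in self.subjects.groupby("age").groups.items():
            sub = self.subjects.loc[idx]
            design = SurveyDesign.from_frame(sub)
            ids = sub["subject_id"]
            for nut in NUTRIENTS:
                b = population_ratio_mean(self.baseline[nut].loc[ids], design)
                a = population_ratio_mean(self.adjusted[nut].loc[ids], design)
                t = paired_design_test(
                    self.baseline[nut].loc[ids], self.adjusted[nut].loc[ids],
                    design, alpha=self.alpha,
                )
                rows.append(
                    {
                        "nutrient": nut,
                        "age": age,
                        "baseline_mean": b.point,
                        "baseline_se": b.se,
                        "adjusted_mean": a.point,
                        "adjusted_se": a.se,
                        "p_value": t.p_value,
                        "n": b.n,
                    }
                )
        return pd.DataFrame(rows)

    def mean_cups_added(self, over: str = "all") -> DesignEstimate:
        """Weighted mean cups of replacement/added milk, over all subjects
        or over replacers only."""
        cups = self.milk_cups_added.loc[self.subjects["subject_id"]]
        if over == "all":
            return population_ratio_mean(cups, self.design())
        if over == "replacers":
            mask = (cups > 0).to_numpy()
            if not mask.any():
                raise ScenarioError("no subjects received milk")
            return population_ratio_mean(cups[mask], self.design().subset(mask))
        raise ScenarioError(f"unknown averaging scope {over!r}")


def _filter_ages(subjects: pd.DataFrame, items: pd.DataFrame, ages: Set[int]):
    keep = subjects[subjects["age"].isin(ages)].reset_index(drop=True)
    items = items[items["subject_id"].isin(keep["subject_id"])].reset_index(drop=True)
    return keep, items


# ---------------------------------------------------------------------
# Scenario 1: add one cup of milk
# ---------------------------------------------------------------------

def add_milk(
    subjects: pd.DataFrame,
    items: pd.DataFrame,
    config: ScenarioConfig | None = None,
    milk: MilkProfile | None = None,
) -> ScenarioResult:
    """Adjusted daily total = baseline + cups_added × milk-nfs per-cup
    vector, identically for every subject in the configured ages."""
    if config is None:
        config = ScenarioConfig(scenario="add_milk")
    if milk is None:
        milk = MilkProfile()
    sub, its = _filter_ages(subjects, items, config.ages)
    baseline = daily_totals_frame(its, sub)
    delta = milk.per_cup.values * config.cups_added
    adjusted = baseline + delta
    ids = baseline.index
    cups = pd.Series(config.cups_added, index=ids, name="milk_cups_added")
    return ScenarioResult(
        scenario="add_milk",
        subjects=sub,
        baseline=baseline,
        adjusted=adjusted,
        milk_cups_added=cups,
        milk_grams_added=cups * milk.cup_grams,
        n_items_replaced=pd.Series(0, index=ids, name="n_items_replaced"),
    )


# ---------------------------------------------------------------------
# Scenario 2: isocaloric replacement at lunch and dinner
# ---------------------------------------------------------------------

def isocaloric_replace(
    subjects: pd.DataFrame,
    items: pd.DataFrame,
    config: ScenarioConfig | None = None,
    rules=None,
    milk: MilkProfile | None = None,
) -> ScenarioResult:
    """Replace each subject's lunch/dinner nonmilk caloric beverages with
    the milk-nfs amount carrying exactly their pooled energy.

    Subjects with no replaceable items are unchanged; everyone's daily
    energy is conserved by construction.
    """
    if config is None:
        config = ScenarioConfig(scenario="isocaloric_replace")
    if rules is None:
        rules = load_rules()
    if milk is None:
        milk = MilkProfile()
    if milk.energy_density <= 0:
        raise ScenarioError("milk energy density must be positive")
    if (items["energy"] < 0).any():
        raise ScenarioError("negative item energy in input")

    sub, its = _filter_ages(subjects, items, config.ages)
    baseline = daily_totals_frame(its, sub)

    labels = classify_frame(its, rules)
    mask = replaceable_mask(its, labels, config.policy())
    removed = (
        its.loc[mask].groupby("subject_id")[list(NUTRIENTS)].sum()
        .reindex(baseline.index, fill_value=0.0)
    )
    n_replaced = (
        its.loc[mask].groupby("subject_id").size()
        .reindex(baseline.index, fill_value=0).astype(int)
    )
    energy_removed = removed["energy"]
    cups = energy_removed / milk.per_cup["energy"]
    milk_added = np.outer(cups.to_numpy(), milk.per_cup.values)
    adjusted = baseline - removed + milk_added
    return ScenarioResult(
        scenario="isocaloric_replace",
        subjects=sub,
        baseline=baseline,
        adjusted=adjusted,
        milk_cups_added=cups.rename("milk_cups_added"),
        milk_grams_added=(cups * milk.cup_grams).rename("milk_grams_added"),
        n_items_replaced=n_replaced.rename("n_items_replaced"),
    )


def apply_replacement_to_items(
    items: pd.DataFrame,
    config: ScenarioConfig,
    rules=None,
    milk: MilkProfile | None = None,
) -> pd.DataFrame:
    """Item-level view of scenario 2: replaceable items removed, one milk
    item (per subject with any replacement) appended at the first replaced
    occasion.  Used to show idempotence of the substitution."""
    if rules is None:
        rules = load_rules()
    if milk is None:
        milk = MilkProfile()
    labels = classify_frame(items, rules)
    mask = replaceable_mask(items, labels, config.policy())
    kept = items.loc[~mask]
    repl = items.loc[mask]
    if repl.empty:
        return items.copy()
    new_rows = []
    for sid, grp in repl.groupby("subject_id"):
        energy = float(grp["energy"].sum())
        cups = milk.cups_for_energy(energy)
        row = {
            "subject_id": sid,
            "occasion": grp["occasion"].iloc[0],
            "food_code": "11100000",
            "wweia_code": "1004",
            "grams": cups * milk.cup_grams,
        }
        row.update(dict(zip(NUTRIENTS, (milk.per_cup * cups).values)))
        new_rows.append(row)
    out = pd.concat([kept, pd.DataFrame(new_rows)], ignore_index=True)
    return out.sort_values(["subject_id", "occasion", "food_code"]).reset_index(drop=True)
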