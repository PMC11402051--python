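"""End-to-end pipeline: generate/load → classify → estimate → model → report.

Produces the four analysis tables (beverage intake trends, nutrient intake
from caloric beverages including milk, and the two scenario
baseline/adjusted tables), a percent-change summary between the youngest
and oldest age, and a JSON run manifest.  Given a config and seed, output
tables are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .nutrients import NUTRIENTS, MilkProfile, load_reference
from .scenarios import ScenarioConfig, add_milk, isocaloric_replace
from .simulate import GeneratorConfig, generate_dataset, read_microdata
from .survey import (
    SurveyDesign,
    age_group_lsmeans,
    percent_change,
    trend_regression,
)
from .taxonomy import CATEGORY_LABELS, classify_frame, load_rules

log = logging.getLogger("bevmod")

#: Beverage rows of the intake-trend table, in publication order.
TREND_CATEGORIES = (
    "milk",
    "flavored_milk",
    "milk_substitutes",
    "cb_plus_m",
    "cb",
    "fruit_juice_100",
    "fruit_drinks",
    "soft_drinks",
    "ssb",
    "coffee_tea",
)


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    input_microdata: Optional[Path] = None
    generator: Optional[GeneratorConfig] = None
    reference_path: Optional[Path] = None
    taxonomy_path: Optional[Path] = None
    scenario: str = Field(default="both", pattern="^(add|replace|both)$")
    scenario_ages: set[int] = {2, 3, 4, 5}
    cups_added: float = 1.0
    alpha: float = 0.01

    @model_validator(mode="after")
    def _check(self):
        if (self.input_microdata is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_microdata and generator must be supplied"
            )
        return self

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"out_dir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _category_gram_totals(subjects, items, labels) -> pd.DataFrame:
    """Per-subject daily grams in each beverage category (zeros included)."""
    out = {}
    for cat in CATEGORY_LABELS:
        grams = items.loc[labels[cat], :].groupby("subject_id")["grams"].sum()
        out[cat] = grams.reindex(subjects["subject_id"], fill_value=0.0)
    return pd.DataFrame(out)


def beverage_trend_table(subjects, items, labels, design: SurveyDesign) -> pd.DataFrame:
    """Intake-trend table: per-age adjusted means ± SE and the age-trend
    regression coefficient, for energy and each beverage category."""
    cat_grams = _category_gram_totals(subjects, items, labels)
    frame = subjects.copy()
    frame["energy"] = (
        items.groupby("subject_id")["energy"].sum()
        .reindex(subjects["subject_id"], fill_value=0.0).to_numpy()
    )
    rows = []
    variables = [("energy", "energy_kcal")] + [(c, f"{c}_g") for c in TREND_CATEGORIES]
    for cat, varname in variables:
        if cat != "energy":
            frame[cat] = cat_grams[cat].to_numpy()
        ls = age_group_lsmeans(frame, cat if cat != "energy" else "energy", design)
        tr = trend_regression(frame, cat if cat != "energy" else "energy", design)
        row = {"variable": varname}
        for _, r in ls.iterrows():
            row[f"age{int(r['age'])}_mean"] = r["lsmean"]
            row[f"age{int(r['age'])}_se"] = r["se"]
        row.update(
            {"beta_age": tr.beta_age, "beta_se": tr.se, "p_trend": tr.p_value}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def cbm_nutrient_table(subjects, items, labels, design: SurveyDesign) -> pd.DataFrame:
    """Nutrient contribution of caloric beverages including milk, by the
    population ratio method: per-subject CB+M nutrient totals (zeros for
    nonconsumers), per-age adjusted means and the age trend."""
    cbm = items.loc[labels["cb_plus_m"], :]
    totals = (
        cbm.groupby("subject_id")[list(NUTRIENTS)].sum()
        .reindex(subjects["subject_id"], fill_value=0.0)
    )
    frame = subjects.copy()
    rows = []
    for nut in NUTRIENTS:
        frame[nut] = totals[nut].to_numpy()
        ls = age_group_lsmeans(frame, nut, design)
        tr = trend_regression(frame, nut, design)
        row = {"nutrient": nut}
        for _, r in ls.iterrows():
            row[f"age{int(r['age'])}_mean"] = r["lsmean"]
            row[f"age{int(r['age'])}_se"] = r["se"]
        row.update(
            {"beta_age": tr.beta_age, "beta_se": tr.se, "p_trend": tr.p_value}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change_summary(trend_table: pd.DataFrame, key: str, ages) -> pd.DataFrame:
    """Percent change between the youngest and oldest age-group mean."""
    first_col = f"age{min(ages)}_mean"
    last_col = f"age{max(ages)}_mean"
    rows = []
    for _, r in trend_table.iterrows():
        first, last = r[first_col], r[last_col]
        rows.append(
            {
                key: r[key],
                "first_mean": first,
                "last_mean": last,
                "percent_change": percent_change(first, last) if first != 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the report bundle as CSV/JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = load_reference(config.reference_path)
    rules = load_rules(config.taxonomy_path)

    if config.generator is not None:
        log.info("generating synthetic recalls (seed=%d)", config.seed)
        subjects, items = generate_dataset(config.generator, seed=config.seed,
                                           reference=reference)
    else:
        log.info("reading micro-data from %s", config.input_microdata)
        subjects, items = read_microdata(config.input_microdata)

    design = SurveyDesign.from_frame(subjects)
    log.info(
        "design: %d subjects, %d strata, %d df, weight sum %.0f",
        len(subjects), pd.unique(subjects["stratum"]).shape[0], design.df,
        design.weights.sum(),
    )
    labels = classify_frame(items, rules)

    paths: dict[str, Path] = {}

    trend = beverage_trend_table(subjects, items, labels, design)
    paths["beverage_trends"] = out / "beverage_trends.csv"
    trend.to_csv(paths["beverage_trends"], index=False)

    cbm = cbm_nutrient_table(subjects, items, labels, design)
    paths["cbm_nutrients"] = out / "cbm_nutrients.csv"
    cbm.to_csv(paths["cbm_nutrients"], index=False)

    ages = sorted(subjects["age"].unique())
    pct = pd.concat(
        [
            percent_change_summary(trend, "variable", ages).rename(
                columns={"variable": "quantity"}
            ),
            percent_change_summary(cbm, "nutrient", ages)
            .rename(columns={"nutrient": "quantity"})
            .assign(quantity=lambda d: "cbm_" + d["quantity"]),
        ],
        ignore_index=True,
    )
    paths["percent_change"] = out / "percent_change.csv"
    pct.to_csv(paths["percent_change"], index=False)

    milk = MilkProfile()
    if config.scenario in ("add", "both"):
        sc1 = add_milk(
            subjects, items,
            ScenarioConfig(scenario="add_milk", cups_added=config.cups_added,
                           ages=config.scenario_ages),
            milk=milk,
        )
        paths["scenario_add_milk"] = out / "scenario_add_milk.csv"
        sc1.summary_by_age().to_csv(paths["scenario_add_milk"], index=False)
    if config.scenario in ("replace", "both"):
        sc2 = isocaloric_replace(
            subjects, items,
            ScenarioConfig(scenario="isocaloric_replace", ages=config.scenario_ages),
            rules=rules, milk=milk,
        )
        paths["scenario_replace"] = out / "scenario_isocaloric_replace.csv"
        sc2.summary_by_age().to_csv(paths["scenario_replace"], index=False)
        cups_all = sc2.mean_cups_added("all")
        cups_repl = sc2.mean_cups_added("replacers")
        paths["replacement_milk"] = out / "replacement_milk_cups.csv"
        pd.DataFrame(
            [
                {"scope": "all_subjects", "mean_cups": cups_all.point, "se": cups_all.se},
                {"scope": "replacers_only", "mean_cups": cups_repl.point, "se": cups_repl.se},
            ]
        ).to_csv(paths["replacement_milk"], index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "bevmod_version": __version__,
        "n_subjects": int(len(subjects)),
        "n_items": int(len(items)),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
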