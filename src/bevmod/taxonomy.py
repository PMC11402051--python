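"""Beverage category assignment from WWEIA food-category codes.

Categories are defined by code prefixes of the 4-digit WWEIA category code
(1-digit prefix = main group, 2-digit = subgroup, 4-digit = single
category).  Composite categories nest:

    soft_drinks ⊆ ssb ⊆ cb ⊆ cb_plus_m,   fruit_drinks ⊆ ssb,
    milk ∪ flavored_milk ∪ milk_substitutes ⊆ cb_plus_m,   milk ∩ cb = ∅.

``cb`` (caloric beverages excluding milk) is every beverage-group item with
positive energy outside the water/diet/non-caloric subgroups; ``cb_plus_m``
additionally includes the milk family regardless of its energy.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

#: All category labels the classifier can emit.
CATEGORY_LABELS = (
    "milk",
    "flavored_milk",
    "milk_substitutes",
    "fruit_juice_100",
    "ssb",
    "soft_drinks",
    "fruit_drinks",
    "coffee_tea",
    "cb",
    "cb_plus_m",
)

MILK_FAMILY = frozenset({"milk", "flavored_milk", "milk_substitutes"})


class TaxonomyError(ValueError):
    """Raised for malformed codes or inconsistent rule tables."""


@dataclass(frozen=True)
class TaxonomyRule:
    label: str
    include_prefixes: tuple[str, ...]
    exclude_prefixes: tuple[str, ...] = ()
    requires_energy: bool = False

    def __post_init__(self):
        if not self.include_prefixes:
            raise TaxonomyError(f"rule {self.label!r} has no include prefixes")
        overlap = set(self.include_prefixes) & set(self.exclude_prefixes)
        if overlap:
            raise TaxonomyError(
                f"rule {self.label!r}: prefixes in both lists: {sorted(overlap)}"
            )
        for p in (*self.include_prefixes, *self.exclude_prefixes):
            if not p.isdigit() or len(p) not in (1, 2, 4):
                raise TaxonomyError(f"rule {self.label!r}: bad prefix {p!r}")

    def matches(self, wweia_code: str, energy: float) -> bool:
        if self.requires_energy and not energy > 0:
            return False
        if any(wweia_code.startswith(p) for p in self.exclude_prefixes):
            return False
        return any(wweia_code.startswith(p) for p in self.include_prefixes)


def default_rules_path() -> Path:
    return Path(importlib.resources.files("bevmod").joinpath("data/taxonomy.yaml"))


def load_rules(path: str | Path | None = None) -> tuple[TaxonomyRule, ...]:
    """Load taxonomy rules from YAML (packaged default when no path given)."""
    if path is None:
        path = default_rules_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = tuple(
        TaxonomyRule(
            label=entry["label"],
            include_prefixes=tuple(str(p) for p in entry["include_prefixes"]),
            exclude_prefixes=tuple(str(p) for p in entry.get("exclude_prefixes", [])),
            requires_energy=bool(entry.get("requires_energy", False)),
        )
        for entry in raw["rules"]
    )
    labels = [r.label for r in rules]
    if len(labels) != len(set(labels)):
        raise TaxonomyError("duplicate rule labels")
    return rules


def _check_code(wweia_code: str) -> str:
    code = str(wweia_code)
    if len(code) != 4 or not code.isdigit():
        raise TaxonomyError(f"wweia_code must be 4 digits, got {wweia_code!r}")
    return code


def classify(
    wweia_code: str, energy: float, rules: Iterable[TaxonomyRule] | None = None
) -> frozenset[str]:
    """Every beverage category label matching one item.

    Deterministic given (code, energy, rules); items matching nothing (plain
    water, diet drinks, solid foods) return the empty set.  ``cb_plus_m`` is
    derived from the nesting rule, never stored in the rule table.
    """
    code = _check_code(wweia_code)
    if rules is None:
        rules = load_rules()
    labels = {r.label for r in rules if r.matches(code, energy)}
    # milk family is excluded from cb even if a custom rule table overlaps
    if labels & MILK_FAMILY:
        labels.discard("cb")
    if "cb" in labels or labels & MILK_FAMILY:
        labels.add("cb_plus_m")
    return frozenset(labels)


def classify_frame(
    items: pd.DataFrame, rules: Iterable[TaxonomyRule] | None = None
) -> pd.DataFrame:
    """Vectorized classification: one boolean column per category label.

    ``items`` needs ``wweia_code`` and ``energy`` columns; the result is
    indexed like ``items``.
    """
    if rules is None:
        rules = load_rules()
    codes = items["wweia_code"].astype(str)
    bad = codes[(codes.str.len() != 4) | ~codes.str.isdigit()]
    if len(bad):
        raise TaxonomyError(f"malformed wweia codes: {sorted(bad.unique())[:5]}")
    energy = items["energy"].to_numpy(float)
    out = pd.DataFrame(False, index=items.index, columns=list(CATEGORY_LABELS))
    for rule in rules:
        hit = codes.str.startswith(tuple(rule.include_prefixes))
        if rule.exclude_prefixes:
            hit &= ~codes.str.startswith(tuple(rule.exclude_prefixes))
        if rule.requires_energy:
            hit &= energy > 0
        out[rule.label] |= hit
    milk_family = out[list(MILK_FAMILY)].any(axis=1)
    out["cb"] &= ~milk_family
    out["cb_plus_m"] = out["cb"] | milk_family
    return out


@dataclass(frozen=True)
class ReplacementPolicy:
    """Which items an isocaloric-substitution scenario removes.

    Defaults follow the lunch-and-dinner nonmilk-caloric-beverage model:
    anything in cb (which includes 100% juice, SSB and caloric coffee/tea)
    or a milk substitute, at lunch or dinner, with positive energy.  Plain
    and flavored milk are never replaced unless explicitly enabled.
    """

    replaced_categories: frozenset[str] = frozenset({"cb", "milk_substitutes"})
    occasions: frozenset[str] = frozenset({"lunch", "dinner"})
    include_flavored_milk: bool = False
    exempt_juice: bool = False


def is_replaceable(
    occasion: str,
    energy: float,
    labels: frozenset[str],
    policy: ReplacementPolicy | None = None,
) -> bool:
    """Whether one classified item is removed by the substitution scenario."""
    if policy is None:
        policy = ReplacementPolicy()
    if not energy > 0:
        return False
    if occasion not in policy.occasions:
        return False
    if "milk" in labels:
        return False
    if "flavored_milk" in labels and not policy.include_flavored_milk:
        return False
    if policy.exempt_juice and "fruit_juice_100" in labels:
        return False
    return bool(labels & policy.replaced_categories)


def replaceable_mask(
    items: pd.DataFrame,
    labels: pd.DataFrame,
    policy: ReplacementPolicy | None = None,
) -> pd.Series:
    """Vectorized :func:`is_replaceable` over an item table."""
    if policy is None:
        policy = ReplacementPolicy()
    mask = (items["energy"] > 0) & items["occasion"].isin(policy.occasions)
    mask &= ~labels["milk"]
    if not policy.include_flavored_milk:
        mask &= ~labels["flavored_milk"]
    if policy.exempt_juice:
        mask &= ~labels["fruit_juice_100"]
    mask &= labels[list(policy.replaced_categories)].any(axis=1)
    return mask
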