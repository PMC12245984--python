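"""Enumeration of candidate predictor combinations under collinearity rules.

The model space is every non-empty subset of the variable catalogue in which
no two variables share a mutual-exclusion group (e.g. BMI and BMI z score, or
age and log age, never appear together).  Enumeration is deterministic:
variable sets are emitted in lexicographic order of their sorted names, so
model identifiers are stable across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

CATEGORIES = ("clinical", "genetic", "metabolic", "immunological")


class CatalogError(ValueError):
    """Malformed catalogue or exclusion rule."""


@dataclass(frozen=True)
class CatalogVariable:
    name: str
    category: str
    exclusion_group: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise CatalogError(f"unknown category {self.category!r} for {self.name!r}")


@dataclass(frozen=True)
class VariableCatalog:
    variables: tuple[CatalogVariable, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise CatalogError("variable names must be unique")
        groups: dict[str, int] = {}
        for v in self.variables:
            if v.exclusion_group is not None:
                groups[v.exclusion_group] = groups.get(v.exclusion_group, 0) + 1
        for g, count in groups.items():
            if count < 2:
                raise CatalogError(f"exclusion group {g!r} has fewer than 2 members")

    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def category_of(self, name: str) -> str:
        for v in self.variables:
            if v.name == name:
                return v.category
        raise KeyError(name)


@dataclass(frozen=True)
class ModelSpec:
    """One predictor combination fitted with one modelling approach."""

    variables: tuple[str, ...]
    approach: str = "cox"  # "cox" | "rsf"
    stage: str | None = None

    def __post_init__(self):
        if not self.variables:
            raise ValueError("a model needs at least one variable")
        if self.approach not in ("cox", "rsf"):
            raise ValueError(f"unknown approach {self.approach!r}")

    @property
    def model_id(self) -> str:
        return "+".join(sorted(self.variables))


def default_catalog() -> VariableCatalog:
    """The study's variable catalogue with the main-text exclusion rules:
    BMI vs BMI z score, age vs log age, and IA-2A flag vs the
    autoantibody-combination factor are mutually exclusive pairs."""
    v = CatalogVariable
    return VariableCatalog(
        (
            v("age", "clinical", "age_form"),
            v("log_age", "clinical", "age_form"),
            v("gender", "clinical"),
            v("bmi", "clinical", "bmi_form"),
            v("bmi_z", "clinical", "bmi_form"),
            v("grs2", "genetic"),
            v("ia2a_flag", "immunological", "ab_form"),
            v("ab_combination", "immunological", "ab_form"),
            v("fasting_cpeptide", "metabolic"),
            v("auc_cpeptide", "metabolic"),
            v("auc_glucose", "metabolic"),
            v("cpeptide30", "metabolic"),
            v("hba1c", "metabolic"),
            v("index60", "metabolic"),
            v("beta2", "metabolic"),
        )
    )


def load_catalog(path) -> VariableCatalog:
    """Catalogue from YAML: a list of {name, category, exclusion_group}."""
    with open(str(path)) as fh:
        raw = yaml.safe_load(fh)
    return VariableCatalog(
        tuple(
            CatalogVariable(
                name=e["name"],
                category=e["category"],
                exclusion_group=e.get("exclusion_group"),
            )
            for e in raw
        )
    )


def _merged_groups(
    catalog: VariableCatalog, extra_rules: Iterable[Iterable[str]] | None
) -> list[frozenset[str]]:
    """Exclusion groups from the catalogue plus any extra rule sets."""
    names = set(catalog.names())
    groups: dict[str, set[str]] = {}
    for v in catalog.variables:
        if v.exclusion_group is not None:
            groups.setdefault(v.exclusion_group, set()).add(v.name)
    out = [frozenset(g) for g in groups.values()]
    for rule in extra_rules or []:
        rule = frozenset(rule)
        unknown = rule - names
        if unknown:
            raise CatalogError(f"exclusion rule names unknown variables {sorted(unknown)}")
        if len(rule) < 2:
            raise CatalogError("an exclusion rule needs at least 2 variables")
        out.append(rule)
    return out


def violates_rules(subset: Iterable[str], groups: Sequence[frozenset[str]]) -> bool:
    s = set(subset)
    return any(len(s & g) > 1 for g in groups)


def enumerate_models(
    catalog: VariableCatalog,
    extra_rules: Iterable[Iterable[str]] | None = None,
) -> list[tuple[str, ...]]:
    """All admissible non-empty variable subsets, lexicographically ordered.

    A subset is admissible when it contains at most one member of every
    mutual-exclusion group (catalogue groups plus ``extra_rules``).  Sets are
    ordered by size, then lexicographically by sorted variable names.
    """
    groups = _merged_groups(catalog, extra_rules)
    names = sorted(catalog.names())
    admissible = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            if not violates_rules(combo, groups):
                admissible.append(tuple(combo))
    return admissible


def describe_space(
    models: Sequence[Sequence[str]], catalog: VariableCatalog
) -> pd.DataFrame:
    """Deterministic tabulation of the enumerated space by category content."""
    rows = []
    for cat in CATEGORIES:
        members = {v.name for v in catalog.variables if v.category == cat}
        rows.append(
            {
                "category": cat,
                "n_models_containing": sum(1 for m in models if set(m) & members),
            }
        )
    rows.append({"category": "total", "n_models_containing": len(models)})
    return pd.DataFrame(rows)


def space_to_dataframe(
    models: Sequence[Sequence[str]], catalog: VariableCatalog | None = None
) -> pd.DataFrame:
    rows = []
    for m in models:
        row = {"model_id": "+".join(sorted(m)), "n_variables": len(m)}
        if catalog is not None:
            cats = sorted({catalog.category_of(v) for v in m})
            row["categories"] = "+".join(cats)
        rows.append(row)
    return pd.DataFrame(rows)
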