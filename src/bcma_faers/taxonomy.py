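"""MedDRA preferred-term grouping into composite adverse-event categories.

Reaction rows carry MedDRA preferred terms (PTs).  A :class:`TermDictionary`
maps each analysis category (CRS, ICANS, non-ICANS neurotoxicity, the
infection subcategories) to its PT set; term matching is exact and
case-insensitive after whitespace collapse — no substring matching, so
"infection" never swallows "COVID-19".  Category PT sets must be pairwise
disjoint, and a separate ``composites`` layer (e.g. an all-infection
composite) unions base categories without breaking disjointness.

The dictionary also carries the disease-progression PT set used to separate
non-relapse mortality from progression deaths.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .cohort import Cohort
from .errors import ConfigurationError

log = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_term(pt: str) -> str:
    return _WS.sub(" ", pt.strip()).casefold()


@dataclass
class TermDictionary:
    """Category -> preferred-term sets, composites, and progression terms."""

    categories: dict[str, set[str]]
    progression_terms: set[str] = field(default_factory=set)
    composites: dict[str, list[str]] = field(default_factory=dict)
    _term_to_category: dict[str, str] = field(init=False, repr=False)
    _progression: set[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lookup: dict[str, str] = {}
        for category, terms in self.categories.items():
            if not terms:
                raise ConfigurationError(f"category {category!r} has no terms")
            for t in terms:
                key = normalize_term(t)
                if key in lookup:
                    raise ConfigurationError(
                        f"term {t!r} appears in both {lookup[key]!r} and {category!r}; "
                        "category term sets must be disjoint"
                    )
                lookup[key] = category
        self._term_to_category = lookup
        self._progression = {normalize_term(t) for t in self.progression_terms}
        overlap = self._progression & set(lookup)
        if overlap:
            raise ConfigurationError(
                f"progression terms overlap event categories: {sorted(overlap)}"
            )
        for comp, members in self.composites.items():
            if comp in self.categories:
                raise ConfigurationError(f"composite {comp!r} shadows a base category")
            unknown = [m for m in members if m not in self.categories]
            if unknown:
                raise ConfigurationError(
                    f"composite {comp!r} references unknown categories {unknown}"
                )

    @property
    def category_names(self) -> list[str]:
        return list(self.categories)

    @property
    def all_names(self) -> list[str]:
        return list(self.categories) + list(self.composites)

    def lookup(self, pt: str) -> str | None:
        return self._term_to_category.get(normalize_term(pt))

    def is_progression(self, pt: str) -> bool:
        return normalize_term(pt) in self._progression

    def terms_for(self, name: str) -> set[str]:
        """Normalized PT set for a base category or composite."""
        if name in self.categories:
            return {normalize_term(t) for t in self.categories[name]}
        if name in self.composites:
            out: set[str] = set()
            for member in self.composites[name]:
                out |= {normalize_term(t) for t in self.categories[member]}
            return out
        raise KeyError(name)


def default_term_dictionary() -> TermDictionary:
    """Dictionary of the named toxicity entities, shipped as package data."""
    text = resources.files("bcma_faers.data").joinpath("terms.json").read_text()
    return _from_mapping(json.loads(text), "package data terms.json")


def load_term_dictionary(path: str | Path) -> TermDictionary:
    """Load a term dictionary from JSON or YAML."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _from_mapping(raw, str(path))


def _from_mapping(raw: object, source: str) -> TermDictionary:
    if not isinstance(raw, dict) or "categories" not in raw:
        raise ConfigurationError(f"{source}: expected a mapping with 'categories'")
    return TermDictionary(
        categories={str(k): {str(t) for t in v} for k, v in raw["categories"].items()},
        progression_terms={str(t) for t in raw.get("progression_terms", [])},
        composites={str(k): [str(m) for m in v]
                    for k, v in raw.get("composites", {}).items()},
    )


def categorize_event(pt: str, dictionary: TermDictionary) -> str | None:
    """The unique base category containing the preferred term, else ``None``."""
    return dictionary.lookup(pt)


@dataclass
class CategoryCounts:
    """Per-drug event and case counts per category (composites included)."""

    events: dict[str, dict[str, int]]
    cases: dict[str, dict[str, int]]
    total_events: dict[str, int]
    total_cases: dict[str, int]

    @property
    def drugs(self) -> list[str]:
        return list(self.total_events)


def _tabulate(cohort: Cohort, dictionary: TermDictionary) -> CategoryCounts:
    names = dictionary.all_names
    events = {d: {n: 0 for n in names} for d in cohort.drugs}
    cases = {d: {n: 0 for n in names} for d in cohort.drugs}
    total_events = {d: 0 for d in cohort.drugs}
    total_cases = {d: 0 for d in cohort.drugs}
    comp_of: dict[str, list[str]] = {}
    for comp, members in dictionary.composites.items():
        for m in members:
            comp_of.setdefault(m, []).append(comp)
    for case in cohort.cases:
        total_cases[case.drug] += 1
        total_events[case.drug] += len(case.reactions)
        hit: set[str] = set()
        for pt in case.reactions:
            cat = dictionary.lookup(pt)
            if cat is None:
                continue
            events[case.drug][cat] += 1
            hit.add(cat)
            for comp in comp_of.get(cat, ()):
                events[case.drug][comp] += 1
                hit.add(comp)
        for name in hit:
            cases[case.drug][name] += 1
    return CategoryCounts(events=events, cases=cases,
                          total_events=total_events, total_cases=total_cases)


def count_category_events(cohort: Cohort, dictionary: TermDictionary) -> CategoryCounts:
    """Event-level counts: reaction rows mapping to each category, per drug.

    Repeated identical terms within one case each count once per row; totals
    are all reaction rows per drug.  Case-level counts ride along in the
    returned :class:`CategoryCounts`.
    """
    return _tabulate(cohort, dictionary)


def count_category_cases(
    cohort: Cohort, dictionary: TermDictionary
) -> dict[str, dict[str, int]]:
    """Distinct cases with >= 1 reaction in each category, per drug."""
    return _tabulate(cohort, dictionary).cases
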