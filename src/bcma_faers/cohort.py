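"""Drug-name normalization and single-study-drug cohort construction.

FAERS drug rows carry verbatim names (brand, generic, development code,
free-text variants).  A :class:`DrugLexicon` maps each canonical study
product to its known variants; :func:`build_cohort` keeps exactly the cases
whose drug rows resolve to one distinct canonical study drug.  "More than one
drug" is read as more than one distinct *study* drug: concomitant non-study
medication never excludes a case, since essentially every myeloma report
lists supportive drugs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .io import RawRecordSet

log = logging.getLogger(__name__)

_WS = re.compile(r"\s+")
_TRAILING_PAREN = re.compile(r"\s*\([^()]*\)\s*$")

#: Days per year used for age conversion (Julian year).
DAYS_PER_YEAR = 365.25


def normalize_token(verbatim: str) -> str:
    """Uppercase, trim, collapse internal whitespace, strip one trailing
    parenthetical (e.g. dose or formulation annotations)."""
    s = _WS.sub(" ", verbatim.strip())
    s = _TRAILING_PAREN.sub("", s)
    return s.upper()


@dataclass
class DrugLexicon:
    """Mapping canonical product -> set of verbatim name variants."""

    entries: dict[str, set[str]]
    _lookup: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("drug lexicon is empty")
        lookup: dict[str, str] = {}
        for canonical, variants in self.entries.items():
            if not variants:
                raise ConfigurationError(f"lexicon entry {canonical!r} has no variants")
            for v in variants:
                key = normalize_token(v)
                if key in lookup and lookup[key] != canonical:
                    raise ConfigurationError(
                        f"variant {v!r} maps to both {lookup[key]!r} and {canonical!r}"
                    )
                lookup[key] = canonical
        self._lookup = lookup

    @property
    def drugs(self) -> list[str]:
        return list(self.entries)

    def match(self, verbatim: str) -> str | None:
        return self._lookup.get(normalize_token(verbatim))


def default_lexicon() -> DrugLexicon:
    """Lexicon for the three BCMA-directed products shipped as package data."""
    text = resources.files("bcma_faers.data").joinpath("lexicon.json").read_text()
    return DrugLexicon({k: set(v) for k, v in json.loads(text).items()})


def load_lexicon(path: str | Path) -> DrugLexicon:
    """Load a lexicon from a JSON or YAML file: canonical -> list of variants."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: lexicon must be a mapping")
    return DrugLexicon({str(k): {str(v) for v in vs} for k, vs in raw.items()})


def normalize_drug_name(verbatim: str, lexicon: DrugLexicon) -> str | None:
    """Canonical product for a verbatim drug name, or ``None`` if unmatched."""
    return lexicon.match(verbatim)


@dataclass
class CaseRecord:
    """One analyzable, deduplicated case."""

    caseid: str
    drug: str
    age_years: float | None
    sex: str | None
    reactions: list[str]
    outcome_codes: set[str]


@dataclass
class Cohort:
    cases: list[CaseRecord]
    drugs: list[str]

    def by_drug(self) -> dict[str, list[CaseRecord]]:
        out: dict[str, list[CaseRecord]] = {d: [] for d in self.drugs}
        for c in self.cases:
            out[c.drug].append(c)
        return out


def _age_in_years(age: float | None, age_cod: str | None) -> float | None:
    if age is None:
        return None
    unit = (age_cod or "YR").upper()
    if unit == "YR":
        return age
    if unit == "MON":
        return age / 12.0
    if unit == "DY":
        return age / DAYS_PER_YEAR
    log.warning("unknown age unit %r; age treated as missing", age_cod)
    return None


def build_cohort(
    records: RawRecordSet,
    lexicon: DrugLexicon,
    *,
    suspect_only: bool = False,
) -> Cohort:
    """Build the analysis cohort of single-study-drug cases.

    A case enters the cohort iff its drug rows map to exactly one distinct
    canonical study drug; zero or two-plus study drugs exclude it (counts
    logged).  ``suspect_only`` restricts the mapping to PS/SS drug rows.
    Ages are converted to years (months / 12, days / 365.25).
    """
    if not lexicon.entries:
        raise ConfigurationError("drug lexicon is empty")

    drugs_by_pid: dict[str, set[str]] = {}
    for row in records.drug:
        if suspect_only and row.role_cod not in {"PS", "SS"}:
            continue
        canonical = lexicon.match(row.drugname)
        if canonical is not None:
            drugs_by_pid.setdefault(row.primaryid, set()).add(canonical)

    reac_by_pid: dict[str, list[str]] = {}
    for row in records.reac:
        reac_by_pid.setdefault(row.primaryid, []).append(row.pt)
    outc_by_pid: dict[str, set[str]] = {}
    for row in records.outc:
        outc_by_pid.setdefault(row.primaryid, set()).add(row.outc_cod)

    cases: list[CaseRecord] = []
    n_no_study = n_multi = n_no_reac = 0
    seen_caseids: set[str] = set()
    for demo in records.demo:
        if demo.caseid in seen_caseids:
            log.warning("duplicate caseid %s in input; run deduplicate() first", demo.caseid)
            continue
        seen_caseids.add(demo.caseid)
        mapped = drugs_by_pid.get(demo.primaryid, set())
        if not mapped:
            n_no_study += 1
            continue
        if len(mapped) > 1:
            n_multi += 1
            continue
        reactions = reac_by_pid.get(demo.primaryid, [])
        if not reactions:
            n_no_reac += 1
        cases.append(
            CaseRecord(
                caseid=demo.caseid,
                drug=next(iter(mapped)),
                age_years=_age_in_years(demo.age, demo.age_cod),
                sex=demo.sex,
                reactions=reactions,
                outcome_codes=outc_by_pid.get(demo.primaryid, set()),
            )
        )
    log.info(
        "cohort waterfall: %d reports -> %d single-study-drug cases "
        "(%d without a study drug, %d with multiple study drugs, "
        "%d retained without reaction rows)",
        len(records.demo), len(cases), n_no_study, n_multi, n_no_reac,
    )
    return Cohort(cases=cases, drugs=lexicon.drugs)


def cohort_summary_counts(cohort: Cohort) -> dict[str, dict[str, int]]:
    """Per-drug ``{"n_cases": ..., "n_events": ...}``.

    ``n_events`` counts reaction rows (a preferred term repeated within one
    case counts once per row).
    """
    out = {d: {"n_cases": 0, "n_events": 0} for d in cohort.drugs}
    for case in cohort.cases:
        out[case.drug]["n_cases"] += 1
        out[case.drug]["n_events"] += len(case.reactions)
    return out
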