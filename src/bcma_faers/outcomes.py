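"""Seriousness-outcome classification and non-relapse mortality flagging.

FAERS OUTC codes mark report seriousness: DE death, LT life-threatening,
HO hospitalization, plus DS/CA/RI/OT grouped here as "other serious".  The
flags are non-exclusive — a fatal case is usually also hospitalized.

Non-relapse mortality (NRM) is defined at the report level: a case is NRM
iff it carries the DE outcome code and none of its reaction preferred terms
is a disease-progression term.  Death is determined by the outcome channel
only; a "Death" preferred term without DE does not count (logged when the
channels disagree).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cohort import CaseRecord, Cohort
from .io import OUTCOME_CODES
from .taxonomy import TermDictionary, normalize_term

log = logging.getLogger(__name__)

_OTHER_SERIOUS = {"DS", "CA", "RI", "OT"}


@dataclass(frozen=True)
class OutcomeProfile:
    death: bool
    life_threatening: bool
    hospitalization: bool
    other_serious: bool


def classify_outcomes(case: CaseRecord) -> OutcomeProfile:
    """Map a case's OUTC codes onto non-exclusive seriousness flags."""
    codes = set()
    for code in case.outcome_codes:
        if code in OUTCOME_CODES:
            codes.add(code)
        else:
            log.warning("case %s: unknown outcome code %r ignored", case.caseid, code)
    return OutcomeProfile(
        death="DE" in codes,
        life_threatening="LT" in codes,
        hospitalization="HO" in codes,
        other_serious=bool(codes & _OTHER_SERIOUS),
    )


def flag_nrm(case: CaseRecord, dictionary: TermDictionary) -> bool:
    """True iff the case is fatal and free of disease-progression terms."""
    if not classify_outcomes(case).death:
        if any(normalize_term(pt) == "death" for pt in case.reactions):
            log.info("case %s: 'Death' reaction term without DE outcome code", case.caseid)
        return False
    return not any(dictionary.is_progression(pt) for pt in case.reactions)


@dataclass
class MortalityCounts:
    """Per-drug case, all-cause-fatal and non-relapse-fatal counts."""

    n_cases: dict[str, int]
    n_death: dict[str, int]
    n_nrm: dict[str, int]

    @property
    def drugs(self) -> list[str]:
        return list(self.n_cases)


def count_mortality(cohort: Cohort, dictionary: TermDictionary) -> MortalityCounts:
    """Per-drug totals of cases, fatal cases and NRM cases.

    Invariant: ``n_nrm <= n_death <= n_cases`` for every drug.
    """
    n_cases = {d: 0 for d in cohort.drugs}
    n_death = dict(n_cases)
    n_nrm = dict(n_cases)
    for case in cohort.cases:
        n_cases[case.drug] += 1
        if classify_outcomes(case).death:
            n_death[case.drug] += 1
            if flag_nrm(case, dictionary):
                n_nrm[case.drug] += 1
    return MortalityCounts(n_cases=n_cases, n_death=n_death, n_nrm=n_nrm)
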