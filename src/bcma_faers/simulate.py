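"""Synthetic FAERS quarter generator with known ground truth.

Each configured drug contributes ``n_cases`` cases.  A case draws its
event count from a Poisson truncated at 1 (every FAERS report carries at
least one reaction), its reaction preferred terms i.i.d. from the drug's
multinomial ``reaction_probs``, and independent Bernoulli seriousness
outcomes (a case may be both fatal and hospitalized, matching the
non-exclusive outcome convention).  Fatal cases append a disease-progression
term with probability ``p_progression_given_death``, making non-relapse
mortality recoverable downstream.

Two nuisance processes exercise the ingest pipeline: ``duplicate_rate``
emits an additional earlier case version (perturbed age, reactions copied,
one outcome row dropped) that deduplication must discard, and
``polypharmacy_rate`` adds a second study-drug row that the cohort builder
must exclude.

:func:`expected_ror` gives the closed-form reporting odds ratio implied by a
configuration, the target for parameter-recovery experiments: with ``p`` the
index drug's category probability mass and ``q`` the event-weighted mixture
of the comparators' masses (weights ``n_cases x mean events per case``, the
truncated-Poisson mean ``lambda / (1 - exp(-lambda))``), the expected ROR is
``(p / (1-p)) / (q / (1-q))``.  The appended progression terms are not part
of the closed form; with death rates shared across drugs their small
dilution of the event denominators cancels in the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .cohort import DrugLexicon, build_cohort
from .errors import ConfigurationError
from .io import (DemoRecord, DrugRecord, OutcRecord, RawRecordSet, ReacRecord,
                 deduplicate)
from .stats import PanelRow, dispro_panel
from .taxonomy import (TermDictionary, count_category_events,
                       default_term_dictionary, normalize_term)

log = logging.getLogger(__name__)

#: Progression preferred term the generator appends to progression deaths.
PROGRESSION_TERM = "Disease progression"

_AGE_RANGE = (45.0, 80.0)
_P_FEMALE = 0.35


class DrugSimConfig(BaseModel):
    """Generative parameters for one drug's reports."""

    name: str
    variants: list[str] = Field(min_length=1)
    n_cases: int = Field(ge=0)
    reaction_probs: dict[str, float]
    events_per_case_mean: float = Field(gt=0.0, default=2.0)
    p_death: float = Field(ge=0.0, le=1.0, default=0.0)
    p_progression_given_death: float = Field(ge=0.0, le=1.0, default=0.0)
    p_life_threatening: float = Field(ge=0.0, le=1.0, default=0.0)
    p_hospitalization: float = Field(ge=0.0, le=1.0, default=0.0)

    @field_validator("reaction_probs")
    @classmethod
    def _probs_sum_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("reaction_probs must be non-empty")
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("reaction probabilities must lie in [0, 1]")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reaction_probs must sum to 1 (got {total})")
        return v

    @property
    def mean_events(self) -> float:
        """Mean of the zero-truncated Poisson event count."""
        lam = self.events_per_case_mean
        return lam / (1.0 - math.exp(-lam))


class SimConfig(BaseModel):
    """Full generator configuration for one synthetic quarter."""

    drugs: list[DrugSimConfig] = Field(min_length=1)
    duplicate_rate: float = Field(ge=0.0, le=1.0, default=0.0)
    polypharmacy_rate: float = Field(ge=0.0, le=1.0, default=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _distinct_names(self) -> "SimConfig":
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("drug names must be distinct")
        if self.polypharmacy_rate > 0 and len(self.drugs) < 2:
            raise ValueError("polypharmacy needs at least two study drugs")
        return self

    def lexicon(self) -> DrugLexicon:
        return DrugLexicon({d.name: set(d.variants) for d in self.drugs})


@dataclass
class CaseTruth:
    """Ground truth for one simulated case."""

    caseid: str
    drug: str
    reactions: list[str]
    death: bool
    progression: bool
    life_threatening: bool
    hospitalization: bool
    duplicated: bool
    polypharmacy: bool


@dataclass
class GroundTruth:
    cases: list[CaseTruth] = field(default_factory=list)

    def analyzable(self) -> list[CaseTruth]:
        """Cases the pipeline should retain (single study drug)."""
        return [c for c in self.cases if not c.polypharmacy]


def _truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    k = int(rng.poisson(lam))
    while k == 0:
        k = int(rng.poisson(lam))
    return k


def simulate_quarter(config: SimConfig) -> tuple[RawRecordSet, GroundTruth]:
    """Generate one FAERS-format quarter; deterministic for a fixed seed."""
    try:
        config = SimConfig.model_validate(config)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"invalid simulation config: {exc}") from exc

    rng = np.random.default_rng(config.seed)
    records = RawRecordSet()
    truth = GroundTruth()
    case_counter = 10_000_000

    for drug_cfg in config.drugs:
        terms = list(drug_cfg.reaction_probs)
        probs = np.array([drug_cfg.reaction_probs[t] for t in terms])
        probs = probs / probs.sum()
        other_drugs = [d for d in config.drugs if d.name != drug_cfg.name]
        for _ in range(drug_cfg.n_cases):
            case_counter += 1
            caseid = str(case_counter)
            duplicated = rng.random() < config.duplicate_rate
            poly = bool(other_drugs) and rng.random() < config.polypharmacy_rate
            version = 2 if duplicated else 1
            primaryid = f"{caseid}{version:02d}"

            n_events = _truncated_poisson(rng, drug_cfg.events_per_case_mean)
            reactions = [terms[i] for i in rng.choice(len(terms), size=n_events, p=probs)]
            death = rng.random() < drug_cfg.p_death
            progression = death and rng.random() < drug_cfg.p_progression_given_death
            if progression:
                reactions = reactions + [PROGRESSION_TERM]
            life_threat = rng.random() < drug_cfg.p_life_threatening
            hosp = rng.random() < drug_cfg.p_hospitalization

            age = float(rng.uniform(*_AGE_RANGE))
            sex = "F" if rng.random() < _P_FEMALE else "M"
            variant = drug_cfg.variants[rng.integers(len(drug_cfg.variants))]

            records.demo.append(DemoRecord(
                primaryid=primaryid, caseid=caseid, caseversion=version,
                age=round(age, 1), age_cod="YR", sex=sex))
            records.drug.append(DrugRecord(
                primaryid=primaryid, caseid=caseid, drug_seq=1,
                role_cod="PS", drugname=variant))
            if poly:
                other = other_drugs[rng.integers(len(other_drugs))]
                other_variant = other.variants[rng.integers(len(other.variants))]
                records.drug.append(DrugRecord(
                    primaryid=primaryid, caseid=caseid, drug_seq=2,
                    role_cod="SS", drugname=other_variant))
            for pt in reactions:
                records.reac.append(ReacRecord(primaryid=primaryid, caseid=caseid, pt=pt))
            outc_codes = [code for code, flag in
                          (("DE", death), ("LT", life_threat), ("HO", hosp)) if flag]
            for code in outc_codes:
                records.outc.append(OutcRecord(primaryid=primaryid, caseid=caseid,
                                               outc_cod=code))

            if duplicated:
                # Earlier version: reactions copied (so dedup failures would
                # not shift category proportions), age perturbed, last
                # outcome row missing.
                early_pid = f"{caseid}01"
                records.demo.append(DemoRecord(
                    primaryid=early_pid, caseid=caseid, caseversion=1,
                    age=round(age + 1.0, 1), age_cod="YR", sex=sex))
                records.drug.append(DrugRecord(
                    primaryid=early_pid, caseid=caseid, drug_seq=1,
                    role_cod="PS", drugname=variant))
                for pt in reactions:
                    records.reac.append(ReacRecord(primaryid=early_pid,
                                                   caseid=caseid, pt=pt))
                for code in outc_codes[:-1]:
                    records.outc.append(OutcRecord(primaryid=early_pid,
                                                   caseid=caseid, outc_cod=code))

            truth.cases.append(CaseTruth(
                caseid=caseid, drug=drug_cfg.name, reactions=reactions,
                death=death, progression=progression,
                life_threatening=life_threat, hospitalization=hosp,
                duplicated=duplicated, polypharmacy=poly))
    return records, truth


def expected_ror(
    config: SimConfig,
    drug: str,
    category: str,
    dictionary: TermDictionary,
) -> float | None:
    """Closed-form ROR implied by a configuration (see module docstring).

    Returns ``None`` when the category has zero probability mass among the
    comparator drugs (the odds ratio is undefined there).
    """
    terms = dictionary.terms_for(category)

    def mass(d: DrugSimConfig) -> float:
        return sum(p for t, p in d.reaction_probs.items()
                   if normalize_term(t) in terms)

    index = next((d for d in config.drugs if d.name == drug), None)
    if index is None:
        raise KeyError(drug)
    others = [d for d in config.drugs if d.name != drug]
    if not others:
        raise ConfigurationError("need at least two drugs for a comparator arm")
    p = mass(index)
    weights = [d.n_cases * d.mean_events for d in others]
    if sum(weights) == 0:
        return None
    q = sum(w * mass(d) for w, d in zip(weights, others)) / sum(weights)
    if q == 0.0:
        return None
    if p == 1.0 or q == 1.0:
        return None
    return (p / (1.0 - p)) / (q / (1.0 - q))


def benchmark_recovery_config(
    n_cases: int = 2000, seed: int = 0, null: bool = False
) -> tuple[SimConfig, TermDictionary]:
    """Standard three-drug recovery benchmark.

    Reaction frequencies give each analysis category a large event mass
    (0.15-0.37) so the closed-form comparison is informative at the benchmark
    size; events per case are Poisson(2.5) truncated at 1 (FAERS-like 2.4-2.7
    events per case), and death/progression/duplication/polypharmacy rates
    are shared across drugs.  With ``null=True`` all drugs share drug A's
    reaction frequencies, so every expected ROR is exactly 1.
    """
    probs_a = {"Cytokine release syndrome": 0.35, "Pneumonia": 0.12,
               "Sepsis": 0.08, "Tremor": 0.10, "Encephalopathy": 0.05,
               "Pyrexia": 0.20, "Fatigue": 0.10}
    probs_b = {"Cytokine release syndrome": 0.22, "Pneumonia": 0.18,
               "Sepsis": 0.12, "Tremor": 0.12, "Encephalopathy": 0.06,
               "Pyrexia": 0.20, "Fatigue": 0.10}
    probs_c = {"Cytokine release syndrome": 0.18, "Pneumonia": 0.22,
               "Sepsis": 0.15, "Tremor": 0.10, "Encephalopathy": 0.05,
               "Pyrexia": 0.20, "Fatigue": 0.10}
    if null:
        probs_b = probs_c = probs_a
    common = dict(events_per_case_mean=2.5, p_death=0.15,
                  p_progression_given_death=0.4, p_hospitalization=0.4,
                  p_life_threatening=0.08)
    config = SimConfig(
        drugs=[
            DrugSimConfig(name="drug-a", variants=["DRUG A", "BRAND-A"],
                          n_cases=n_cases, reaction_probs=probs_a, **common),
            DrugSimConfig(name="drug-b", variants=["DRUG B", "BRAND-B"],
                          n_cases=n_cases, reaction_probs=probs_b, **common),
            DrugSimConfig(name="drug-c", variants=["DRUG C", "BRAND-C"],
                          n_cases=n_cases, reaction_probs=probs_c, **common),
        ],
        duplicate_rate=0.05, polypharmacy_rate=0.03, seed=seed,
    )
    dictionary = TermDictionary(
        categories={
            "CRS": {"Cytokine release syndrome"},
            "infection": {"Pneumonia", "Sepsis"},
            "neurotoxicity": {"Tremor", "Encephalopathy"},
        },
        progression_terms={PROGRESSION_TERM},
    )
    return config, dictionary


@dataclass
class RecoveryCell:
    """Recovery diagnostics for one drug/category pair."""

    drug: str
    category: str
    expected: float
    n_estimates: int
    mean_log_bias: float
    coverage: float


@dataclass
class RecoverySummary:
    n_reps: int
    cells: list[RecoveryCell]

    @property
    def mean_abs_log_bias(self) -> float:
        return float(np.mean([abs(c.mean_log_bias) for c in self.cells]))

    @property
    def min_coverage(self) -> float:
        return min(c.coverage for c in self.cells)

    @property
    def overall_coverage(self) -> float:
        total = sum(c.n_estimates for c in self.cells)
        return sum(c.coverage * c.n_estimates for c in self.cells) / total


def run_pipeline_panel(
    records: RawRecordSet,
    lexicon: DrugLexicon,
    dictionary: TermDictionary,
    categories: list[str] | None = None,
    alpha: float = 0.05,
) -> list[PanelRow]:
    """Raw records -> dedup -> cohort -> category counts -> ROR panel."""
    cohort = build_cohort(deduplicate(records), lexicon)
    counts = count_category_events(cohort, dictionary)
    return dispro_panel(counts, categories=categories, alpha=alpha)


def recovery_experiment(
    config: SimConfig,
    n_reps: int,
    dictionary: TermDictionary | None = None,
    categories: list[str] | None = None,
    alpha: float = 0.05,
) -> RecoverySummary:
    """Simulate -> full pipeline -> ROR panel, ``n_reps`` times (seeds
    ``seed + i``), and summarize log-estimate bias and Wald CI coverage
    against :func:`expected_ror`."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    dictionary = dictionary or default_term_dictionary()
    if categories is None:
        categories = dictionary.category_names
    lexicon = config.lexicon()
    expected: dict[tuple[str, str], float] = {}
    for d in config.drugs:
        for cat in categories:
            e = expected_ror(config, d.name, cat, dictionary)
            if e is not None and e > 0:
                expected[(d.name, cat)] = e

    log_bias: dict[tuple[str, str], list[float]] = {k: [] for k in expected}
    covered: dict[tuple[str, str], list[bool]] = {k: [] for k in expected}
    for i in range(n_reps):
        rep_cfg = config.model_copy(update={"seed": config.seed + i})
        records, _ = simulate_quarter(rep_cfg)
        for row in run_pipeline_panel(records, lexicon, dictionary, categories, alpha):
            key = (row.drug, row.category)
            if key not in expected or row.estimate is None:
                continue
            est = row.estimate
            log_bias[key].append(math.log(est.point) - math.log(expected[key]))
            covered[key].append(est.ci_low <= expected[key] <= est.ci_high)

    cells = [
        RecoveryCell(
            drug=drug, category=cat, expected=expected[(drug, cat)],
            n_estimates=len(log_bias[(drug, cat)]),
            mean_log_bias=float(np.mean(log_bias[(drug, cat)])),
            coverage=float(np.mean(covered[(drug, cat)])),
        )
        for (drug, cat) in expected
        if log_bias[(drug, cat)]
    ]
    return RecoverySummary(n_reps=n_reps, cells=cells)
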