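"""Shared fixtures: hand-built record sets, default configs, tiny simulations."""

from __future__ import annotations

import pytest

from bcma_faers import (DemoRecord, DrugRecord, OutcRecord, RawRecordSet,
                        ReacRecord, default_lexicon, default_term_dictionary)
from bcma_faers.simulate import DrugSimConfig, SimConfig


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def terms():
    return default_term_dictionary()


def make_case(pid, caseid, drugnames, reactions, outcomes=(), version=1,
              age=60.0, age_cod="YR", sex="F"):
    """Rows of the four tables for one case, as a RawRecordSet fragment."""
    rs = RawRecordSet()
    rs.demo.append(DemoRecord(primaryid=pid, caseid=caseid, caseversion=version,
                              age=age, age_cod=age_cod, sex=sex))
    for i, name in enumerate(drugnames, start=1):
        rs.drug.append(DrugRecord(primaryid=pid, caseid=caseid, drug_seq=i,
                                  role_cod="PS" if i == 1 else "SS", drugname=name))
    for pt in reactions:
        rs.reac.append(ReacRecord(primaryid=pid, caseid=caseid, pt=pt))
    for code in outcomes:
        rs.outc.append(OutcRecord(primaryid=pid, caseid=caseid, outc_cod=code))
    return rs


def merge(*sets: RawRecordSet) -> RawRecordSet:
    out = RawRecordSet()
    for rs in sets:
        out.demo += rs.demo
        out.drug += rs.drug
        out.reac += rs.reac
        out.outc += rs.outc
    return out


@pytest.fixture
def toy_records() -> RawRecordSet:
    """Three cases: one ide-cel-only, one ide-cel + teclistamab, one with no
    study drug."""
    return merge(
        make_case("101", "1", ["ABECMA"],
                  ["Cytokine release syndrome", "Pyrexia"], ["DE", "HO"]),
        make_case("201", "2", ["ABECMA", "TECVAYLI"], ["Pneumonia"], ["HO"]),
        make_case("301", "3", ["LENALIDOMIDE"], ["Back pain"]),
    )


def small_sim_config(**overrides) -> SimConfig:
    base = dict(
        drugs=[
            DrugSimConfig(
                name="ide-cel", variants=["ABECMA", "IDECABTAGENE VICLEUCEL"],
                n_cases=60,
                reaction_probs={"Cytokine release syndrome": 0.3,
                                "Pyrexia": 0.5, "Tremor": 0.2},
                p_death=0.2, p_progression_given_death=0.5,
                p_hospitalization=0.4, p_life_threatening=0.1),
            DrugSimConfig(
                name="teclistamab", variants=["TECVAYLI"], n_cases=60,
                reaction_probs={"Cytokine release syndrome": 0.1,
                                "Pyrexia": 0.6, "Pneumonia": 0.3},
                p_death=0.2, p_progression_given_death=0.5,
                p_hospitalization=0.4),
        ],
        duplicate_rate=0.0, polypharmacy_rate=0.0, seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def sim_config() -> SimConfig:
    return small_sim_config()
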