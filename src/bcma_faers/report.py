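"""Cohort summary tables and forest-plot-ready output.

The study summary mirrors a standard pharmacovigilance "Table 1": per drug,
case and event totals, median age with IQR, percent female, seriousness
outcome counts with case-level percentages, and composite-category event
counts with event-level percentages.  Percentages always recompute from
their printed count and denominator; medians/IQRs use midpoint (type-7)
interpolation on the sorted non-missing ages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, cohort_summary_counts
from .outcomes import MortalityCounts, classify_outcomes, count_mortality
from .stats import PanelRow, percentage, round_half_away
from .taxonomy import CategoryCounts, TermDictionary, count_category_events

log = logging.getLogger(__name__)


@dataclass
class DrugSummary:
    drug: str
    n_cases: int
    n_events: int
    age_median: float | None
    age_q1: float | None
    age_q3: float | None
    n_female: int
    pct_female: float | None
    outcomes: dict[str, tuple[int, float]]    # flag -> (count, pct of cases)
    categories: dict[str, tuple[int, float]]  # category -> (events, pct of events)


@dataclass
class StudySummary:
    per_drug: dict[str, DrugSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.per_drug.values():
            row: dict[str, object] = {
                "drug": s.drug, "n_cases": s.n_cases, "n_events": s.n_events,
                "age_median": s.age_median, "age_q1": s.age_q1, "age_q3": s.age_q3,
                "n_female": s.n_female, "pct_female": s.pct_female,
            }
            for name, (count, pct) in s.outcomes.items():
                row[f"n_{name}"] = count
                row[f"pct_{name}"] = pct
            for name, (count, pct) in s.categories.items():
                row[f"events_{name}"] = count
                row[f"pct_{name}"] = pct
            rows.append(row)
        return pd.DataFrame(rows)


_OUTCOME_FLAGS = ("death", "life_threatening", "hospitalization", "other_serious")


def summarize(cohort: Cohort, dictionary: TermDictionary) -> StudySummary:
    """Per-drug cohort summary (counts, ages, outcome and category rates)."""
    counts = cohort_summary_counts(cohort)
    cat_counts = count_category_events(cohort, dictionary)
    by_drug = cohort.by_drug()
    summary = StudySummary()
    for drug in cohort.drugs:
        cases = by_drug[drug]
        n_cases = counts[drug]["n_cases"]
        n_events = counts[drug]["n_events"]
        ages = [c.age_years for c in cases if c.age_years is not None]
        n_missing_age = n_cases - len(ages)
        if n_missing_age:
            log.info("%s: %d case(s) without usable age excluded from median",
                     drug, n_missing_age)
        if ages:
            q1, med, q3 = np.percentile(ages, [25, 50, 75])  # linear = type 7
            age_stats = (float(med), float(q1), float(q3))
        else:
            age_stats = (None, None, None)
        n_female = sum(1 for c in cases if c.sex == "F")
        outcomes: dict[str, tuple[int, float]] = {}
        profiles = [classify_outcomes(c) for c in cases]
        for flag in _OUTCOME_FLAGS:
            n = sum(1 for p in profiles if getattr(p, flag))
            outcomes[flag] = (n, percentage(n, n_cases) if n_cases else 0.0)
        categories: dict[str, tuple[int, float]] = {}
        for name in dictionary.all_names:
            n = cat_counts.events[drug][name]
            categories[name] = (n, percentage(n, n_events) if n_events else 0.0)
        summary.per_drug[drug] = DrugSummary(
            drug=drug, n_cases=n_cases, n_events=n_events,
            age_median=age_stats[0], age_q1=age_stats[1], age_q3=age_stats[2],
            n_female=n_female,
            pct_female=percentage(n_female, n_cases) if n_cases else None,
            outcomes=outcomes, categories=categories,
        )
    return summary


def forest_table(
    panel_rows: list[PanelRow],
    mortality_rows: list[PanelRow] | None = None,
) -> pd.DataFrame:
    """Forest-plot-ready table: one row per contrast, numbers passed through
    from the estimates with no re-rounding."""
    records = []
    for row in list(panel_rows) + list(mortality_rows or []):
        t = row.table
        est = row.estimate
        records.append({
            "drug": row.drug,
            "contrast": row.category,
            "a": t.a if t else np.nan, "b": t.b if t else np.nan,
            "c": t.c if t else np.nan, "d": t.d if t else np.nan,
            "estimate": est.point if est else np.nan,
            "ci_low": est.ci_low if est else np.nan,
            "ci_high": est.ci_high if est else np.nan,
            "corrected": bool(est.corrected) if est else False,
        })
    return pd.DataFrame(records)


def plot_forest(table: pd.DataFrame, path: str, title: str = "") -> None:
    """Render a forest plot (log scale) of a forest_table frame to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = table.dropna(subset=["estimate"]).reset_index(drop=True)
    labels = [f"{r.drug}: {r.contrast}" for r in rows.itertuples()]
    y = np.arange(len(rows))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 1.5))
    ax.errorbar(
        rows["estimate"], y,
        xerr=[rows["estimate"] - rows["ci_low"], rows["ci_high"] - rows["estimate"]],
        fmt="s", color="black", ecolor="black", capsize=3,
    )
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.set_xlabel("odds ratio (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mortality_frame(counts: MortalityCounts) -> pd.DataFrame:
    """Mortality table: drug, n_cases, n_death, n_nrm, pct_death."""
    return pd.DataFrame([
        {
            "drug": d,
            "n_cases": counts.n_cases[d],
            "n_death": counts.n_death[d],
            "n_nrm": counts.n_nrm[d],
            "pct_death": percentage(counts.n_death[d], counts.n_cases[d])
            if counts.n_cases[d] else 0.0,
        }
        for d in counts.drugs
    ])


def category_frame(counts: CategoryCounts) -> pd.DataFrame:
    """Category counts as TSV-ready rows: drug, category, events, cases,
    total_events, pct (event denominator)."""
    rows = []
    for drug in counts.drugs:
        total = counts.total_events[drug]
        for name, n in counts.events[drug].items():
            rows.append({
                "drug": drug, "category": name, "events": n,
                "cases": counts.cases[drug][name], "total_events": total,
                "pct": percentage(n, total) if total else 0.0,
            })
    return pd.DataFrame(rows)
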