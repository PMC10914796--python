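"""Disproportionality statistics: 2x2 tables, ROR/OR with Wald CIs, rate ratios.

The reporting odds ratio (ROR) for a drug/event pair contrasts the odds of
that event among the index drug's reports against the same odds among the
comparator drugs' reports:

    ROR = (a / b) / (c / d) = (a * d) / (b * c)

with ``a`` = index-drug reports with the event, ``b`` = without, and ``c``,
``d`` the comparator analogues.  The 95% confidence interval is the Wald
(log-normal) interval:

    exp( ln ROR  +/-  z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) )

Zero cells get the Haldane–Anscombe correction (+0.5 to every cell), flagged
on the estimate.  Denominator convention: reaction RORs use event-level
counts (reaction rows), mortality ORs use case-level counts; the comparator
set is the union of the other in-scope study drugs, not the whole database
background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.stats import norm

from .errors import ConfigurationError
from .outcomes import MortalityCounts
from .taxonomy import CategoryCounts


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency counts: index drug with/without event (a/b), comparators
    with/without (c/d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each arm of the 2x2 table needs at least one report")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RatioEstimate:
    """Ratio point estimate with a Wald confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    alpha: float
    corrected: bool = False


def odds_ratio(table: TwoByTwo, alpha: float = 0.05) -> RatioEstimate | None:
    """(Reporting) odds ratio with a Wald ``1 - alpha`` interval.

    Zero cells trigger the Haldane–Anscombe +0.5 correction (``corrected``
    set).  Returns ``None`` when the event is unseen in both arms
    (``a + c == 0``): no estimate is defined there.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if table.a + table.c == 0:
        return None
    corrected = table.has_zero_cell
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (x + shift for x in (table.a, table.b, table.c, table.d))
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    log_point = math.log(point)
    return RatioEstimate(
        point=point,
        ci_low=math.exp(log_point - z * se),
        ci_high=math.exp(log_point + z * se),
        alpha=alpha,
        corrected=corrected,
    )


def rate_ratio(x1: int, n1: int, x2: int, n2: int) -> float | None:
    """Simple ratio of two proportions ``(x1/n1) / (x2/n2)``.

    Returns ``None`` (undefined) when the reference numerator ``x2`` is zero.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if x2 == 0:
        return None
    return (x1 / n1) / (x2 / n2)


def build_event_table(
    counts: CategoryCounts, drug: str, category: str
) -> TwoByTwo:
    """Event-level 2x2 table for one drug/category against the other drugs."""
    if drug not in counts.total_events:
        raise KeyError(drug)
    others = [d for d in counts.drugs if d != drug]
    if not others:
        raise ConfigurationError("need at least two drugs for a comparator arm")
    a = counts.events[drug][category]
    b = counts.total_events[drug] - a
    c = sum(counts.events[d][category] for d in others)
    d = sum(counts.total_events[d] for d in others) - c
    return TwoByTwo(a=a, b=b, c=c, d=d)


def build_fatality_table(
    counts: MortalityCounts, drug: str, fatal_field: Literal["death", "nrm"] = "death"
) -> TwoByTwo:
    """Case-level 2x2 table of fatal vs non-fatal reports for one drug."""
    if fatal_field not in ("death", "nrm"):
        raise ValueError(f"fatal_field must be 'death' or 'nrm', got {fatal_field!r}")
    fatal = counts.n_death if fatal_field == "death" else counts.n_nrm
    others = [d for d in counts.drugs if d != drug]
    if not others:
        raise ConfigurationError("need at least two drugs for a comparator arm")
    a = fatal[drug]
    b = counts.n_cases[drug] - a
    c = sum(fatal[d] for d in others)
    d = sum(counts.n_cases[d] for d in others) - c
    return TwoByTwo(a=a, b=b, c=c, d=d)


@dataclass(frozen=True)
class PanelRow:
    drug: str
    category: str
    table: TwoByTwo | None  # None when an arm has no reports at all
    estimate: RatioEstimate | None


def dispro_panel(
    counts: CategoryCounts,
    categories: list[str] | None = None,
    alpha: float = 0.05,
) -> list[PanelRow]:
    """One ROR per in-scope drug x category, each drug vs the union of the
    others.  ``None`` estimates (event unseen anywhere) propagate."""
    if categories is None:
        categories = list(next(iter(counts.events.values())))
    rows = []
    for drug in counts.drugs:
        for category in categories:
            try:
                table = build_event_table(counts, drug, category)
            except ValueError:  # a drug with no reports has no defined odds
                rows.append(PanelRow(drug, category, None, None))
                continue
            rows.append(PanelRow(drug, category, table, odds_ratio(table, alpha)))
    return rows


def mortality_panel(
    counts: MortalityCounts,
    fatal_field: Literal["death", "nrm"] = "death",
    alpha: float = 0.05,
) -> list[PanelRow]:
    """One mortality OR per drug vs the union of the other drugs."""
    rows = []
    for drug in counts.drugs:
        label = f"mortality ({fatal_field})"
        try:
            table = build_fatality_table(counts, drug, fatal_field)
        except ValueError:
            rows.append(PanelRow(drug, label, None, None))
            continue
        rows.append(PanelRow(drug, label, table, odds_ratio(table, alpha)))
    return rows


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero (reporting convention; Python's built-in
    rounds half to even)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def percentage(count: int, denominator: int, decimals: int = 1) -> float:
    """``round(100 * count / denominator)`` half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * count / denominator, decimals)
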