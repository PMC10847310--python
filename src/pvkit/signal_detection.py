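"""Disproportionality statistics for drug-event pairs.

Spontaneous reporting databases have no denominators, so association is
measured by disproportionality against the rest of the database.  Two
classical statistics are implemented on the standard 2x2 contingency table

    =============  ==========  ============
    .              target AE   other AEs
    =============  ==========  ============
    target drug    a           b
    other drugs    c           d
    =============  ==========  ============

* the proportional reporting ratio, PRR = (a/(a+b)) / (c/(c+d)), with the
  usual log-normal 95% confidence interval; and
* the Bayesian confidence propagation neural network information component,
  IC = log2((a + 0.5)/(E + 0.5)) with E = (a+b)(a+c)/N, using the
  closed-form credibility-interval approximation
  IC025 = IC - 3.3 (a+0.5)^-1/2 - 2.0 (a+0.5)^-3/2.

A pair is flagged as a signal when the case count exceeds 3, PRR >= 2 and
the PRR confidence interval's lower limit exceeds 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .faers_io import Vocabulary

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "UndefinedExposureError",
    "build_contingency",
    "prr",
    "ic",
    "is_signal",
    "screen_signals",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedExposureError(ValueError):
    """Raised when a margin of the 2x2 table is empty."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one drug-event pair against a background of other drugs."""

    a: float  # target drug, target event
    b: float  # target drug, other events
    c: float  # other drugs, target event
    d: float  # other drugs, other events

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n_total == 0:
            raise ValueError("contingency table is empty")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> float:
        return self.a + self.b

    @property
    def expected(self) -> float:
        """Expected count of cell *a* under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n_total

    def corrected(self) -> "ContingencyTable":
        """Haldane-Anscombe 0.5 continuity correction applied to all cells."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


def build_contingency(
    cases: pd.DataFrame, drug: str, event: str
) -> ContingencyTable:
    """Count the 2x2 table for one drug-event pair over assembled cases.

    A case counts once however many times the PT repeats on it; exposure
    means the case's suspect-drug set contains ``drug``; the background is
    every other case in the supplied collection.  PT comparison is exact
    string, case-insensitive.
    """
    if cases.empty:
        raise UndefinedExposureError("empty case collection")
    want = event.strip().casefold()
    exposed = np.fromiter(
        (drug in e for e in cases["exposure"]), dtype=bool, count=len(cases)
    )
    has_event = np.fromiter(
        (want in r for r in cases["reactions_folded"]), dtype=bool, count=len(cases)
    )
    a = int(np.sum(exposed & has_event))
    b = int(np.sum(exposed & ~has_event))
    c = int(np.sum(~exposed & has_event))
    d = int(np.sum(~exposed & ~has_event))
    return ContingencyTable(a, b, c, d)


def prr(table: ContingencyTable) -> tuple[float, float, float]:
    """Proportional reporting ratio with its 95% confidence interval.

    Requires both margins non-empty (a+b > 0 and c+d > 0).  When a = 0 or
    c = 0 the point estimate or its variance is degenerate; the 0.5
    continuity correction is applied to all four cells (flagged through
    :func:`prr_corrected` / ``SignalResult.corrected`` in the screen).
    """
    value, lo, hi, _ = prr_corrected(table)
    return value, lo, hi


def prr_corrected(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """As :func:`prr` but also reporting whether correction was applied."""
    if table.n_exposed == 0 or table.c + table.d == 0:
        raise UndefinedExposureError(
            "PRR undefined: a margin of the 2x2 table is empty"
        )
    corrected = table.a == 0 or table.c == 0
    t = table.corrected() if corrected else table
    # single final division keeps the point estimate exactly the correctly
    # rounded value of the underlying rational when counts are integers
    value = (t.a * (t.c + t.d)) / ((t.a + t.b) * t.c)
    se = math.sqrt(1.0 / t.a - 1.0 / (t.a + t.b) + 1.0 / t.c - 1.0 / (t.c + t.d))
    log_value = math.log(value)
    return (
        value,
        math.exp(log_value - Z_95 * se),
        math.exp(log_value + Z_95 * se),
        corrected,
    )


def ic(table: ContingencyTable) -> tuple[float, float]:
    """BCPNN information component and its 95% credibility lower bound.

    The shrinkage constant 0.5 in both numerator and denominator pulls the
    log2 observed/expected ratio toward zero for sparse cells; the IC025
    closed form approximates the posterior 2.5th percentile.
    """
    a = table.a
    e = table.expected
    value = math.log2((a + 0.5) / (e + 0.5))
    ic025 = value - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return value, ic025


def is_signal(n: float, prr_value: float, prr_ci_low: float, min_cases: int = 4) -> bool:
    """Signal rule: case count over 3, PRR >= 2, CI lower limit above 1.

    ``min_cases`` defaults to 4 (a count strictly greater than 3); some
    analyses prefer ``min_cases=3``.
    """
    return n >= min_cases and prr_value >= 2.0 and prr_ci_low > 1.0


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality result for one drug-event pair."""

    drug: str
    event: str
    n: int
    prr: float
    prr_ci_low: float
    prr_ci_high: float
    ic: float
    ic025: float
    is_signal: bool
    corrected: bool = False


SCREEN_COLUMNS = [
    "drug",
    "pt",
    "soc",
    "a",
    "b",
    "c",
    "d",
    "n",
    "prr",
    "prr_low",
    "prr_high",
    "ic",
    "ic025",
    "signal",
    "corrected",
]


def screen_signals(
    cases: pd.DataFrame,
    drugs: list[str] | None = None,
    events: list[str] | None = None,
    vocabulary: Vocabulary | None = None,
    soc: str | None = None,
    min_cases: int = 4,
    background: str = "all",
) -> pd.DataFrame:
    """Disproportionality screen over drug-event pairs with a >= 1.

    Parameters
    ----------
    cases
        Assembled, deduplicated case table.
    drugs
        Canonical ingredients to screen; defaults to every ingredient
        appearing in any case's exposure set.
    events
        PT strings to screen; defaults to every PT observed.
    vocabulary, soc
        When ``soc`` is given, restrict events to PTs mapping to that
        system organ class (requires ``vocabulary``).
    min_cases
        Case-count threshold of the signal rule (default 4, i.e. n > 3).
    background
        ``"all"``: background is every other case in the collection;
        ``"cohort"``: restrict the collection to cases exposed to at least
        one screened drug before tabulating.

    Returns a DataFrame sorted by drug then descending PRR.
    """
    if cases.empty:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    if background not in ("all", "cohort"):
        raise ValueError("background must be 'all' or 'cohort'")

    if drugs is None:
        drugs = sorted({d for e in cases["exposure"] for d in e})
    if background == "cohort":
        wanted = set(drugs)
        mask = [bool(e & wanted) for e in cases["exposure"]]
        cases = cases.loc[mask]
        if cases.empty:
            return pd.DataFrame(columns=SCREEN_COLUMNS)

    # inverted index: folded PT -> case positions
    pt_cases: dict[str, set[int]] = {}
    display_pt: dict[str, str] = {}
    for i, reactions in enumerate(cases["reactions"]):
        for pt in reactions:
            key = pt.casefold()
            pt_cases.setdefault(key, set()).add(i)
            display_pt.setdefault(key, pt)

    if events is not None:
        keys = [e.strip().casefold() for e in events]
        for e, k in zip(events, keys):
            display_pt.setdefault(k, e)
    else:
        keys = sorted(pt_cases)
    if soc is not None:
        if vocabulary is None:
            raise ValueError("SOC filtering requires a vocabulary")
        want = soc.strip().casefold()
        keys = [
            k
            for k in keys
            if (vocabulary.soc_of(display_pt[k]) or "").casefold() == want
        ]

    n_cases = len(cases)
    exposed_masks = {
        drug: np.fromiter(
            (drug in e for e in cases["exposure"]), dtype=bool, count=n_cases
        )
        for drug in drugs
    }

    rows = []
    for drug in drugs:
        exposed = exposed_masks[drug]
        n_exposed = int(exposed.sum())
        if n_exposed == 0 or n_exposed == n_cases:
            continue  # no exposed cases, or no background to compare against
        for key in keys:
            members = pt_cases.get(key)
            if not members:
                continue
            idx = np.fromiter(members, dtype=np.int64)
            a = int(exposed[idx].sum())
            if a < 1:
                continue
            c = len(members) - a
            b = n_exposed - a
            d = n_cases - n_exposed - c
            table = ContingencyTable(a, b, c, d)
            value, lo, hi, corrected = prr_corrected(table)
            ic_value, ic025 = ic(table)
            pt = display_pt[key]
            rows.append(
                {
                    "drug": drug,
                    "pt": pt,
                    "soc": vocabulary.soc_of(pt) if vocabulary else None,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "n": a,
                    "prr": value,
                    "prr_low": lo,
                    "prr_high": hi,
                    "ic": ic_value,
                    "ic025": ic025,
                    "signal": is_signal(a, value, lo, min_cases=min_cases),
                    "corrected": corrected,
                }
            )
    out = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    if len(out):
        out = out.sort_values(
            ["drug", "prr", "pt"], ascending=[True, False, True], kind="stable"
        ).reset_index(drop=True)
    return out
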