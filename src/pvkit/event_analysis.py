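"""Hemorrhagic-event classification, reporting rates, characteristic tables,
time-to-onset and the associated hypothesis tests.

Hemorrhagic adverse events are recognised lexically: any preferred term
containing the stem "haemorrhag" (or the American "hemorrhag"), plus a
configurable whitelist for terms such as "Haemorrhoids" that denote a
hemorrhagic condition without carrying the stem.  Intracranial-hemorrhage
and thrombocytopenia PTs are explicit configurable term lists.

Time to onset is the event date minus the earliest therapy start date for
the drug of interest, expressed in months of 30.4375 days (the Gregorian
mean); dates missing only the day component are imputed to mid-month.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .faers_io import Vocabulary
from .cleaning import CaseDrug

__all__ = [
    "EventTerms",
    "EventClassification",
    "classify_event",
    "ReportingRate",
    "reporting_rate",
    "format_percent",
    "summarize_characteristics",
    "overlap_analysis",
    "TimeToOnset",
    "time_to_onset",
    "tto_table",
    "TestResult",
    "chi_square",
    "rank_test",
    "median_tto_comparison",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.4375  # Gregorian mean month length

HEMORRHAGE_STEMS = ("haemorrhag", "hemorrhag")

DEFAULT_HEMORRHAGE_WHITELIST = frozenset({"Haemorrhoids"})

DEFAULT_INTRACRANIAL_PTS = frozenset(
    {
        "Cerebral haemorrhage",
        "Haemorrhage intracranial",
        "Haemorrhagic stroke",
        "Subarachnoid haemorrhage",
        "Intraventricular haemorrhage",
        "Central nervous system haemorrhage",
        "Cerebral microhaemorrhage",
        "Intracranial tumour haemorrhage",
        "Thalamus haemorrhage",
    }
)

DEFAULT_THROMBOCYTOPENIA_PTS = frozenset(
    {"Thrombocytopenia", "Platelet count decreased"}
)

AGE_BANDS = ["<18", "18–44", "45–64", "65–74", "≥75", "Unknown"]


@dataclass(frozen=True)
class EventTerms:
    """Configurable term lists driving event classification."""

    hemorrhage_whitelist: frozenset[str] = DEFAULT_HEMORRHAGE_WHITELIST
    intracranial: frozenset[str] = DEFAULT_INTRACRANIAL_PTS
    thrombocytopenia: frozenset[str] = DEFAULT_THROMBOCYTOPENIA_PTS

    def _folded(self, which: str) -> frozenset[str]:
        return frozenset(t.casefold() for t in getattr(self, which))


DEFAULT_TERMS = EventTerms()


@dataclass(frozen=True)
class EventClassification:
    pt: str
    is_hemorrhagic: bool
    is_intracranial: bool
    is_thrombocytopenia: bool
    soc: str | None = None


def classify_event(
    pt: str,
    vocabulary: Vocabulary | None = None,
    terms: EventTerms = DEFAULT_TERMS,
) -> EventClassification:
    """Classify one preferred term; intracranial implies hemorrhagic."""
    folded = pt.strip().casefold()
    intracranial = folded in terms._folded("intracranial")
    hemorrhagic = (
        intracranial
        or any(stem in folded for stem in HEMORRHAGE_STEMS)
        or folded in terms._folded("hemorrhage_whitelist")
    )
    return EventClassification(
        pt=pt.strip(),
        is_hemorrhagic=hemorrhagic,
        is_intracranial=intracranial,
        is_thrombocytopenia=folded in terms._folded("thrombocytopenia"),
        soc=vocabulary.soc_of(pt) if vocabulary else None,
    )


def _case_flags(
    cases: pd.DataFrame, terms: EventTerms
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-case hemorrhagic / intracranial / thrombocytopenia indicator arrays."""
    ich = terms._folded("intracranial")
    wl = terms._folded("hemorrhage_whitelist")
    tcp = terms._folded("thrombocytopenia")

    def hem(folded: frozenset[str]) -> bool:
        return any(
            any(stem in pt for stem in HEMORRHAGE_STEMS) or pt in wl or pt in ich
            for pt in folded
        )

    n = len(cases)
    reactions = cases["reactions_folded"]
    is_hem = np.fromiter((hem(r) for r in reactions), dtype=bool, count=n)
    is_ich = np.fromiter((bool(r & ich) for r in reactions), dtype=bool, count=n)
    is_tcp = np.fromiter((bool(r & tcp) for r in reactions), dtype=bool, count=n)
    return is_hem, is_ich, is_tcp


@dataclass(frozen=True)
class ReportingRate:
    """Exposed cases reporting the target event, as a proportion."""

    numerator: int
    denominator: int

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator


def reporting_rate(
    cases: pd.DataFrame,
    drug: str,
    target: str,
    vocabulary: Vocabulary | None = None,
    kind: str = "auto",
) -> ReportingRate:
    """Share of cases exposed to ``drug`` reporting at least one matching PT.

    ``target`` names either one preferred term or a system organ class
    (``kind`` in {"pt", "soc", "auto"}; "auto" treats the target as a SOC
    when the vocabulary knows it as one).  A case counts once however many
    matching PTs it lists.
    """
    exposed = cases.loc[[drug in e for e in cases["exposure"]]]
    if exposed.empty:
        raise ValueError(f"no cases exposed to {drug!r}")
    if kind not in ("pt", "soc", "auto"):
        raise ValueError("kind must be 'pt', 'soc' or 'auto'")
    as_soc = kind == "soc" or (
        kind == "auto"
        and vocabulary is not None
        and target.strip().casefold() in (s.casefold() for s in vocabulary.socs())
    )
    if as_soc:
        if vocabulary is None:
            raise ValueError("SOC reporting rate requires a vocabulary")
        members = frozenset(pt.casefold() for pt in vocabulary.pts_in(target))
        hits = sum(bool(r & members) for r in exposed["reactions_folded"])
    else:
        want = target.strip().casefold()
        hits = sum(want in r for r in exposed["reactions_folded"])
    return ReportingRate(int(hits), int(len(exposed)))


def format_percent(count: int, total: int) -> str:
    """Render a count as a percent at two significant figures.

    Values at or above 10% print as integers, below 10% with one decimal,
    and positive values below 0.1% as "<0.1%"; a zero count is "0%".
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    if count == 0:
        return "0%"
    pct = 100.0 * count / total
    if pct < 0.1:
        return "<0.1%"
    two_sig = float(f"{pct:.2g}")
    if two_sig >= 10:
        return f"{two_sig:.0f}%"
    return f"{pct:.1f}%"


def _age_band(age: float | None) -> str:
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return "Unknown"
    if age < 18:
        return "<18"
    if age < 45:
        return "18–44"
    if age < 65:
        return "45–64"
    if age < 75:
        return "65–74"
    return "≥75"


CHARACTERISTIC_COLUMNS = ["group", "level", "count", "percent"]


def summarize_characteristics(
    cases: pd.DataFrame,
    vocabulary: Vocabulary | None = None,
    terms: EventTerms = DEFAULT_TERMS,
) -> pd.DataFrame:
    """Characteristic table for a case subset (typically hemorrhagic cases).

    Groups: Regimen, Age band, Sex, outcome codes, SOC of the hemorrhagic
    PTs, and the hemorrhagic PTs themselves.  Regimen/Age/Sex partition the
    cases so their counts sum to N; a case with several outcomes, several
    hemorrhagic PTs or PTs across several SOCs counts once per level in
    those groups, mirroring FAERS multiplicity.  Percents always use the
    case total N as denominator.
    """
    n = len(cases)
    if n == 0:
        return pd.DataFrame(columns=CHARACTERISTIC_COLUMNS)
    if "regimen_kind" not in cases.columns:
        from .cleaning import add_regimens

        cases = add_regimens(cases)

    rows: list[tuple[str, str, int]] = []

    regimen_names = {
        "monotherapy": "Monotherapy",
        "combination": "Combination therapy",
        "none": "Not exposed",
    }
    counts = cases["regimen_kind"].value_counts()
    for kind in ("combination", "monotherapy", "none"):
        if counts.get(kind, 0):
            rows.append(("Regimen", regimen_names[kind], int(counts[kind])))

    bands = pd.Series([_age_band(a) for a in cases["age_years"]])
    band_counts = bands.value_counts()
    for band in AGE_BANDS:
        if band_counts.get(band, 0):
            rows.append(("Age", band, int(band_counts[band])))

    sexes = cases["sex"].map(lambda s: s if s in ("F", "M") else "Unknown")
    sex_counts = sexes.value_counts()
    for level in ("F", "M", "Unknown"):
        if sex_counts.get(level, 0):
            rows.append(("Sex", level, int(sex_counts[level])))

    outc_counter: dict[str, int] = {}
    for outcomes in cases["outcomes"]:
        levels = sorted(outcomes) if outcomes else ["Unknown"]
        for level in levels:
            outc_counter[level] = outc_counter.get(level, 0) + 1
    for level in sorted(outc_counter):
        rows.append(("OUTC_COD", level, outc_counter[level]))

    pt_counter: dict[str, int] = {}
    soc_counter: dict[str, int] = {}
    for reactions in cases["reactions"]:
        hem_pts = sorted(
            pt for pt in reactions if classify_event(pt, terms=terms).is_hemorrhagic
        )
        for pt in hem_pts:
            pt_counter[pt] = pt_counter.get(pt, 0) + 1
        socs = sorted(
            {
                (vocabulary.soc_of(pt) if vocabulary else None) or "Unknown"
                for pt in hem_pts
            }
        )
        for soc in socs:
            soc_counter[soc] = soc_counter.get(soc, 0) + 1
    for soc in sorted(soc_counter):
        rows.append(("soc_name", soc, soc_counter[soc]))
    for pt in sorted(pt_counter):
        rows.append(("pt_name", pt, pt_counter[pt]))

    return pd.DataFrame(
        [(g, level, c, format_percent(c, n)) for g, level, c in rows],
        columns=CHARACTERISTIC_COLUMNS,
    )


OVERLAP_COLUMNS = [
    "drug",
    "both",
    "hemorrhage_only",
    "thrombocytopenia_only",
    "neither",
    "pct_hemorrhage_with_thrombocytopenia",
]


def overlap_analysis(
    cases: pd.DataFrame,
    drugs: list[str] | None = None,
    terms: EventTerms = DEFAULT_TERMS,
) -> pd.DataFrame:
    """Per-drug overlap between hemorrhagic events and thrombocytopenia.

    For each drug's exposed cases, the four mutually exclusive counts
    (both, hemorrhage only, thrombocytopenia only, neither) partition the
    exposed total.  The reported percentage is both / (both + hemorrhage
    only): of the cases with a hemorrhagic event, how many also carried
    thrombocytopenia.
    """
    if drugs is None:
        drugs = sorted({d for e in cases["exposure"] for d in e})
    is_hem, _, is_tcp = _case_flags(cases, terms)
    rows = []
    for drug in drugs:
        exposed = np.fromiter(
            (drug in e for e in cases["exposure"]), dtype=bool, count=len(cases)
        )
        both = int(np.sum(exposed & is_hem & is_tcp))
        hem_only = int(np.sum(exposed & is_hem & ~is_tcp))
        tcp_only = int(np.sum(exposed & ~is_hem & is_tcp))
        neither = int(np.sum(exposed & ~is_hem & ~is_tcp))
        denom = both + hem_only
        rows.append(
            {
                "drug": drug,
                "both": both,
                "hemorrhage_only": hem_only,
                "thrombocytopenia_only": tcp_only,
                "neither": neither,
                "pct_hemorrhage_with_thrombocytopenia": (
                    100.0 * both / denom if denom else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows, columns=OVERLAP_COLUMNS)


@dataclass(frozen=True)
class TimeToOnset:
    caseid: int
    drug: str
    months: float

    def __post_init__(self) -> None:
        if self.months < 0:
            raise ValueError("time to onset must be non-negative")


def time_to_onset(
    case: pd.Series,
    drug: str,
    days_per_month: float = DAYS_PER_MONTH,
) -> TimeToOnset | None:
    """Event date minus earliest therapy start for ``drug``, in months.

    Dates missing the day are imputed to day 15 (midpoint, bounding the
    error at +/-15 days); dates missing the month are unusable.  Negative
    intervals (event before therapy start) return None.
    """
    event_dt = case["event_dt"]
    if event_dt is None:
        return None
    event = event_dt.to_date(impute_day=15)
    if event is None:
        return None
    starts = [
        d.start_dt.to_date(impute_day=15)
        for d in case["drugs"]
        if isinstance(d, CaseDrug) and d.canonical == drug and d.start_dt is not None
    ]
    starts = [s for s in starts if s is not None]
    if not starts:
        return None
    delta_days = (event - min(starts)).days
    if delta_days < 0:
        return None
    return TimeToOnset(int(case["caseid"]), drug, delta_days / days_per_month)


def tto_table(
    cases: pd.DataFrame,
    drugs: list[str] | None = None,
    event_terms: frozenset[str] | None = None,
    terms: EventTerms = DEFAULT_TERMS,
    days_per_month: float = DAYS_PER_MONTH,
) -> pd.DataFrame:
    """Long-format time-to-onset table, one row per (case, exposed drug).

    ``event_terms`` restricts to cases reporting one of the given PTs
    (casefolded); by default the intracranial-hemorrhage list is used.
    """
    if event_terms is None:
        event_terms = terms._folded("intracranial")
    else:
        event_terms = frozenset(t.casefold() for t in event_terms)
    hit = [bool(r & event_terms) for r in cases["reactions_folded"]]
    rows = []
    for _, case in cases.loc[hit].iterrows():
        for drug in sorted(case["exposure"]):
            if drugs is not None and drug not in drugs:
                continue
            tto = time_to_onset(case, drug, days_per_month=days_per_month)
            if tto is not None:
                rows.append(
                    {
                        "caseid": tto.caseid,
                        "drug": tto.drug,
                        "regimen_kind": case.get("regimen_kind"),
                        "months": tto.months,
                    }
                )
    return pd.DataFrame(rows, columns=["caseid", "drug", "regimen_kind", "months"])


@dataclass(frozen=True)
class TestResult:
    method: str  # "chi_square" | "wilcoxon" | "kruskal_wallis"
    statistic: float
    p_value: float
    df: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default.  Zero expected counts are an
    error: an exact test is then the appropriate tool.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2:
        raise ValueError("expected a 2-D count table")
    expected = stats.contingency.expected_freq(observed)
    if (expected <= 0).any():
        raise ValueError("zero expected count; use an exact test")
    statistic, p, df, _ = stats.chi2_contingency(observed, correction=yates)
    return TestResult("chi_square", float(statistic), float(p), int(df))


def _wilcoxon_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact rank-sum p by full enumeration (no ties assumed)."""
    combined = sorted(x + y)
    ranks = {}
    for i, v in enumerate(combined, 1):
        ranks.setdefault(v, []).append(i)
    # midranks in case of ties (enumeration remains valid under permutation)
    midrank = {v: sum(r) / len(r) for v, r in ranks.items()}
    obs = sum(midrank[v] for v in x)
    n, m = len(x), len(y)
    all_ranks = [midrank[v] for v in combined]
    sums = [sum(c) for c in itertools.combinations(all_ranks, n)]
    mean = sum(all_ranks) * n / (n + m)
    dev = abs(obs - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(sums)


def rank_test(groups: list[list[float]]) -> TestResult:
    """Rank-based comparison of two or more groups.

    Two groups: Wilcoxon rank-sum (exact by full enumeration when the
    combined sample size is at most 10, otherwise the normal approximation
    with tie correction).  More than two: Kruskal-Wallis with tie
    correction.  Identical values throughout give statistic 0 and p = 1.
    """
    groups = [list(map(float, g)) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    flat = [v for g in groups for v in g]
    if len(set(flat)) == 1:
        method = "wilcoxon" if len(groups) == 2 else "kruskal_wallis"
        return TestResult(method, 0.0, 1.0, None if len(groups) == 2 else len(groups) - 1)
    if len(groups) == 2:
        x, y = groups
        if len(flat) <= 10:
            p = _wilcoxon_exact_p(x, y)
            u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
            return TestResult("wilcoxon", u, min(p, 1.0))
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return TestResult("wilcoxon", float(res.statistic), float(res.pvalue))
    res = stats.kruskal(*groups)
    return TestResult(
        "kruskal_wallis", float(res.statistic), float(res.pvalue), len(groups) - 1
    )


def median_tto_comparison(
    strata: dict[str, list[float]],
) -> tuple[dict[str, float], TestResult]:
    """Median time to onset per stratum plus a rank test across strata.

    Empty strata are excluded with a warning; at least two non-empty strata
    with one observation each are required.
    """
    kept = {name: list(values) for name, values in strata.items() if len(values)}
    for name in strata:
        if name not in kept:
            warnings.warn(f"stratum {name!r} is empty; excluded", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("need at least two non-empty strata")
    medians = {name: float(np.median(values)) for name, values in kept.items()}
    return medians, rank_test(list(kept.values()))
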