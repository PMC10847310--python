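"""Report deduplication, suspect-role filtering, case assembly and regimen
classification for spontaneous adverse-event reports.

FAERS carries multiple versions of the same safety report (follow-ups share
a CASEID under new PRIMARYIDs).  The standard cleaning rule keeps, per
CASEID, the version with the most recent FDA receipt date, breaking ties by
the higher PRIMARYID.  Exposure to a drug of interest is defined by the
primary-suspect (PS) and secondary-suspect (SS) role codes only;
concomitant (C) and interacting (I) drugs are kept on the case for context
but never define exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .faers_io import DrugDictionary, PartialDate

__all__ = [
    "deduplicate",
    "filter_suspect",
    "assemble_cases",
    "CaseDrug",
    "Regimen",
    "classify_regimen",
    "add_regimens",
]

SUSPECT_ROLES = frozenset({"PS", "SS"})

#: columns of the assembled case table (one row per deduplicated report)
CASE_COLUMNS = [
    "primaryid",
    "caseid",
    "fda_dt",
    "event_dt",
    "age_years",
    "sex",
    "country",
    "outcomes",
    "reactions",
    "reactions_folded",
    "drugs",
    "exposure",
]


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One DEMO record per caseid: latest FDA_DT, then highest PRIMARYID.

    Partial dates compare componentwise with missing components smallest, so
    a year-only date loses to any same-year full date.  Input row order is
    preserved among the kept records; the operation is idempotent.
    """
    if demo.empty:
        return demo.copy()
    key = pd.DataFrame(
        {
            "caseid": demo["caseid"].to_numpy(),
            "_date": [d.sort_key() for d in demo["fda_dt"]],
            "primaryid": demo["primaryid"].to_numpy(),
        },
        index=demo.index,
    )
    keep = key.sort_values(["_date", "primaryid"], kind="stable").groupby("caseid").tail(1)
    return demo.loc[demo.index.isin(keep.index)].copy()


def filter_suspect(
    drug: pd.DataFrame, dictionary: DrugDictionary
) -> pd.DataFrame:
    """Annotate DRUG rows with canonical ingredient and exposure status.

    A row is an *exposure* when its drug matches the target dictionary and
    its role is PS or SS.  Matched drugs in other roles, and unmatched
    drugs in any role, are retained flagged context-only so co-medication
    summaries stay possible.
    """
    out = drug.copy()
    if out.empty:
        out["canonical"] = pd.Series(dtype=object)
        out["is_exposure"] = pd.Series(dtype=bool)
        return out
    # map over unique (drugname, prod_ai) pairs: synonym lists are short and
    # names repeat heavily, so this is far cheaper than a per-row regex pass
    pairs = out[["drugname", "prod_ai"]].drop_duplicates()
    canon = {
        (row.drugname, row.prod_ai): dictionary.match(row.drugname, row.prod_ai)
        for row in pairs.itertuples(index=False)
    }
    out["canonical"] = [
        canon[(dn, ai)] for dn, ai in zip(out["drugname"], out["prod_ai"])
    ]
    out["is_exposure"] = [
        c is not None and r in SUSPECT_ROLES
        for c, r in zip(out["canonical"], out["role_cod"])
    ]
    return out


class CaseDrug(NamedTuple):
    """One drug record attached to an assembled case."""

    name: str
    canonical: str | None
    role_cod: str
    start_dt: PartialDate | None


def _age_years(age: float | None, cod: str | None) -> float | None:
    from .faers_io import AGE_TO_YEARS

    if age is None or pd.isna(age):
        return None
    return age / AGE_TO_YEARS.get(cod or "YR", 1.0)


def assemble_cases(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    outc: pd.DataFrame,
    ther: pd.DataFrame,
    dictionary: DrugDictionary,
) -> pd.DataFrame:
    """Join the five FAERS tables into one row per surviving report.

    ``demo`` must already be deduplicated; ``drug`` rows are matched against
    the target dictionary (via :func:`filter_suspect` if not already done).
    Child rows whose primaryid has no surviving DEMO row are dropped and
    counted in ``DataFrame.attrs['orphans']``.  Therapy start dates join to
    their drug record through ``dsg_drug_seq``.

    The result carries, per case: demographics, the outcome-code set, the
    reaction PT set (plus a casefolded copy for matching), the full drug
    list as :class:`CaseDrug` tuples, and ``exposure`` — the frozenset of
    canonical target ingredients in suspect (PS/SS) roles.
    """
    if "canonical" not in drug.columns:
        drug = filter_suspect(drug, dictionary)
    alive = set(demo["primaryid"].tolist())
    orphans = {
        "drug": int((~drug["primaryid"].isin(alive)).sum()) if len(drug) else 0,
        "reac": int((~reac["primaryid"].isin(alive)).sum()) if len(reac) else 0,
        "outc": int((~outc["primaryid"].isin(alive)).sum()) if len(outc) else 0,
        "ther": int((~ther["primaryid"].isin(alive)).sum()) if len(ther) else 0,
    }
    drug = drug[drug["primaryid"].isin(alive)]
    reac = reac[reac["primaryid"].isin(alive)]
    outc = outc[outc["primaryid"].isin(alive)]
    ther = ther[ther["primaryid"].isin(alive)]

    # earliest start date per (primaryid, drug_seq); missing dates lose
    starts: dict[tuple[int, int], PartialDate] = {}
    for pid, seq, start in zip(ther["primaryid"], ther["dsg_drug_seq"], ther["start_dt"]):
        if start is None:
            continue
        key = (pid, seq)
        if key not in starts or start < starts[key]:
            starts[key] = start

    drugs_by_pid: dict[int, list[CaseDrug]] = {}
    exposure_by_pid: dict[int, set[str]] = {}
    for pid, seq, name, canonical, role, is_exp in zip(
        drug["primaryid"],
        drug["drug_seq"],
        drug["drugname"],
        drug["canonical"],
        drug["role_cod"],
        drug["is_exposure"],
    ):
        entry = CaseDrug(name, canonical, role, starts.get((pid, seq)))
        drugs_by_pid.setdefault(pid, []).append(entry)
        if is_exp:
            exposure_by_pid.setdefault(pid, set()).add(canonical)

    reac_by_pid = (
        reac.groupby("primaryid")["pt"].agg(frozenset).to_dict() if len(reac) else {}
    )
    outc_by_pid = (
        outc.groupby("primaryid")["outc_cod"].agg(frozenset).to_dict()
        if len(outc)
        else {}
    )

    empty: frozenset = frozenset()
    records = {
        "primaryid": demo["primaryid"].to_numpy(),
        "caseid": demo["caseid"].to_numpy(),
        "fda_dt": demo["fda_dt"].tolist(),
        "event_dt": demo["event_dt"].tolist() if "event_dt" in demo else [None] * len(demo),
        "age_years": [
            _age_years(a, c)
            for a, c in zip(demo.get("age", [None] * len(demo)), demo.get("age_cod", [None] * len(demo)))
        ],
        "sex": demo.get("sex", pd.Series(["unknown"] * len(demo))).tolist(),
        "country": demo.get("country", pd.Series([None] * len(demo))).tolist(),
    }
    pids = records["primaryid"]
    records["outcomes"] = [outc_by_pid.get(p, empty) for p in pids]
    reactions = [reac_by_pid.get(p, empty) for p in pids]
    records["reactions"] = reactions
    records["reactions_folded"] = [
        frozenset(pt.casefold() for pt in r) for r in reactions
    ]
    records["drugs"] = [tuple(drugs_by_pid.get(p, ())) for p in pids]
    records["exposure"] = [frozenset(exposure_by_pid.get(p, empty)) for p in pids]

    cases = pd.DataFrame(records, columns=CASE_COLUMNS)
    cases.attrs["orphans"] = orphans
    return cases


@dataclass(frozen=True)
class Regimen:
    """Exposure pattern of one case with respect to the target drug class."""

    kind: str  # "monotherapy" | "combination" | "none"
    inhibitors: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.inhibitors)
        expected = "none" if n == 0 else ("monotherapy" if n == 1 else "combination")
        if self.kind != expected:
            raise ValueError(f"kind {self.kind!r} inconsistent with {n} inhibitors")


def classify_regimen(exposure: frozenset[str] | set[str]) -> Regimen:
    """Monotherapy (one distinct canonical target ingredient among suspect
    drugs), combination (two or more), or none.

    Counting distinct canonical ingredients means trade/generic aliases of
    one drug never masquerade as a combination.
    """
    inhibitors = frozenset(exposure)
    if not inhibitors:
        return Regimen("none", inhibitors)
    if len(inhibitors) == 1:
        return Regimen("monotherapy", inhibitors)
    return Regimen("combination", inhibitors)


def add_regimens(cases: pd.DataFrame) -> pd.DataFrame:
    """Append a ``regimen_kind`` column derived from each case's exposure set."""
    out = cases.copy()
    out["regimen_kind"] = [classify_regimen(e).kind for e in out["exposure"]]
    return out
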