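"""Synthetic spontaneous-reporting-system generator with known ground truth.

Emulates the structure of FAERS quarterly extracts — case records with
duplicate CASEIDs, partial dates, multi-drug cases with role codes,
reaction lists drawn from a toy PT/SOC vocabulary, outcome codes and
therapy start dates — while keeping the generative truth (injected
drug-event reporting-rate ratios, duplicate counts, exposure marginals) in
a manifest, so every pipeline stage can be tested against a known answer
without downloading FAERS.

The injected effect for a (drug, PT) pair multiplies the per-case reporting
probability of that PT among cases exposed to the drug.  That multiplier is
exactly the reporting-rate ratio the PRR estimates under this design, which
makes recovery tolerances directly interpretable.

The default catalogs model a HER2-inhibitor pharmacovigilance cohort:
eight inhibitors (monoclonal antibodies, antibody-drug conjugates and
small molecules) with trade/generic synonyms, a toy vocabulary of common
oncology adverse events including the hemorrhagic and thrombocytopenia
terms the downstream analyses key on, and injected associations mirroring
the class's known safety profile (thrombocytopenia and intracranial
hemorrhage for the emtansine conjugate, interstitial lung disease for the
deruxtecan conjugate, memory impairment for tucatinib).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .faers_io import OUTCOME_CODES, PartialDate, SCHEMAS, write_table

__all__ = [
    "DrugSpec",
    "PtSpec",
    "Association",
    "SimConfig",
    "SimData",
    "generate",
    "write_faers_files",
    "DEFAULT_DRUGS",
    "DEFAULT_PTS",
    "DEFAULT_ASSOCIATIONS",
    "default_drug_dictionary",
    "default_vocabulary",
]


@dataclass(frozen=True)
class DrugSpec:
    """One target drug: canonical ingredient, synonyms, exposure marginal."""

    name: str
    synonyms: tuple[str, ...]
    exposure: float


@dataclass(frozen=True)
class PtSpec:
    """One preferred term with its SOC and baseline per-case probability."""

    pt: str
    soc: str
    baseline: float


@dataclass(frozen=True)
class Association:
    """Injected drug-event association: reporting-rate ratio rho > 0."""

    drug: str
    pt: str
    rho: float


DEFAULT_DRUGS: tuple[DrugSpec, ...] = (
    DrugSpec("trastuzumab", ("HERCEPTIN", "TRASTUZUMAB"), 0.25),
    DrugSpec("pertuzumab", ("PERJETA", "PERTUZUMAB"), 0.12),
    DrugSpec(
        "TDM-1",
        ("KADCYLA", "ADO-TRASTUZUMAB EMTANSINE", "TRASTUZUMAB EMTANSINE"),
        0.08,
    ),
    DrugSpec(
        "T-DXd",
        ("ENHERTU", "TRASTUZUMAB DERUXTECAN", "FAM-TRASTUZUMAB DERUXTECAN-NXKI"),
        0.05,
    ),
    DrugSpec("lapatinib", ("TYKERB", "LAPATINIB DITOSYLATE"), 0.08),
    DrugSpec("neratinib", ("NERLYNX", "NERATINIB MALEATE"), 0.04),
    DrugSpec("tucatinib", ("TUKYSA",), 0.04),
    DrugSpec("pyrotinib", ("PYROTINIB MALEATE",), 0.005),
)

DEFAULT_PTS: tuple[PtSpec, ...] = (
    PtSpec("Diarrhoea", "Gastrointestinal disorders", 0.12),
    PtSpec("Nausea", "Gastrointestinal disorders", 0.08),
    PtSpec("Vomiting", "Gastrointestinal disorders", 0.06),
    PtSpec("Fatigue", "General disorders and administration site conditions", 0.07),
    PtSpec("Pyrexia", "General disorders and administration site conditions", 0.03),
    PtSpec("Cardiac failure", "Cardiac disorders", 0.02),
    PtSpec("Ejection fraction decreased", "Investigations", 0.02),
    PtSpec("Gastrointestinal haemorrhage", "Gastrointestinal disorders", 0.008),
    PtSpec("Rectal haemorrhage", "Gastrointestinal disorders", 0.006),
    PtSpec("Haemorrhoids", "Gastrointestinal disorders", 0.004),
    PtSpec("Cerebral haemorrhage", "Nervous system disorders", 0.003),
    PtSpec("Haemorrhage intracranial", "Nervous system disorders", 0.002),
    PtSpec("Epistaxis", "Respiratory, thoracic and mediastinal disorders", 0.01),
    PtSpec("Thrombocytopenia", "Blood and lymphatic system disorders", 0.015),
    PtSpec("Platelet count decreased", "Investigations", 0.01),
    PtSpec("Headache", "Nervous system disorders", 0.05),
    PtSpec("Dizziness", "Nervous system disorders", 0.03),
    PtSpec("Memory impairment", "Nervous system disorders", 0.004),
    PtSpec("Neuropathy peripheral", "Nervous system disorders", 0.02),
    PtSpec("Pneumonia", "Infections and infestations", 0.02),
    PtSpec("Alopecia", "Skin and subcutaneous tissue disorders", 0.02),
    PtSpec(
        "Interstitial lung disease",
        "Respiratory, thoracic and mediastinal disorders",
        0.008,
    ),
)

DEFAULT_ASSOCIATIONS: tuple[Association, ...] = (
    Association("TDM-1", "Thrombocytopenia", 6.0),
    Association("TDM-1", "Cerebral haemorrhage", 4.0),
    Association("T-DXd", "Cerebral haemorrhage", 3.0),
    Association("T-DXd", "Interstitial lung disease", 8.0),
    Association("tucatinib", "Memory impairment", 5.0),
)

#: non-target co-medication added for realism (role C, or PS on unexposed cases)
BACKGROUND_DRUGS: tuple[str, ...] = ("PACLITAXEL", "DOCETAXEL", "CAPECITABINE")

#: log-normal time-to-onset parameters (mu, sigma) in log-days per drug;
#: antibody and conjugate toxicity tends to surface early, the small
#: molecule lapatinib late
DEFAULT_TTO_LOGNORMAL: dict[str, tuple[float, float]] = {
    "trastuzumab": (2.72, 1.0),   # median ~15 days (~0.5 months)
    "TDM-1": (3.13, 1.0),         # median ~23 days (~0.75 months)
    "lapatinib": (5.19, 1.0),     # median ~180 days (~6 months)
}
FALLBACK_TTO_LOGNORMAL = (4.09, 1.0)  # median ~60 days (~2 months)

DEFAULT_OUTCOME_DISTRIBUTION: dict[str, float] = {
    "DE": 0.08,
    "LT": 0.02,
    "HO": 0.30,
    "DS": 0.02,
    "CA": 0.005,
    "RI": 0.005,
    "OT": 0.35,
    # remaining mass: case has no outcome row
}

_COUNTRIES = ("US", "GB", "JP", "CN", "FR", "DE", "IT", "ES")
_COUNTRY_P = (0.40, 0.12, 0.10, 0.10, 0.08, 0.08, 0.06, 0.06)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic reporting system."""

    n_cases: int = 50_000
    drugs: tuple[DrugSpec, ...] = DEFAULT_DRUGS
    pts: tuple[PtSpec, ...] = DEFAULT_PTS
    associations: tuple[Association, ...] = DEFAULT_ASSOCIATIONS
    polypharmacy_rate: float = 0.15
    duplicate_rate: float = 0.10
    event_missing_rate: float = 0.20
    start_missing_rate: float = 0.30
    day_missing_rate: float = 0.10
    misname_rate: float = 0.05          # drugname unmatchable, prod_ai correct
    prod_ai_rate: float = 0.50          # prod_ai populated (post-2014 quarters)
    background_drug_rate: float = 0.20  # role-C co-medication per background drug
    age_missing_rate: float = 0.25
    outcome_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_DISTRIBUTION)
    )
    tto_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TTO_LOGNORMAL)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if self.n_cases > 0 and (not self.drugs or not self.pts):
            raise ValueError("drug and PT catalogs must be non-empty")
        rates = {
            "polypharmacy_rate": self.polypharmacy_rate,
            "duplicate_rate": self.duplicate_rate,
            "event_missing_rate": self.event_missing_rate,
            "start_missing_rate": self.start_missing_rate,
            "day_missing_rate": self.day_missing_rate,
            "misname_rate": self.misname_rate,
            "prod_ai_rate": self.prod_ai_rate,
            "background_drug_rate": self.background_drug_rate,
            "age_missing_rate": self.age_missing_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")
        for spec in self.drugs:
            if not 0.0 <= spec.exposure <= 1.0:
                raise ValueError(f"exposure for {spec.name} outside [0, 1]")
        for spec in self.pts:
            if not 0.0 <= spec.baseline <= 1.0:
                raise ValueError(f"baseline for {spec.pt} outside [0, 1]")
        names = {d.name for d in self.drugs}
        pts = {p.pt for p in self.pts}
        for assoc in self.associations:
            if assoc.rho <= 0:
                raise ValueError(f"rho must be positive for {assoc.drug}/{assoc.pt}")
            if assoc.drug not in names:
                raise ValueError(f"association names unknown drug {assoc.drug!r}")
            if assoc.pt not in pts:
                raise ValueError(f"association names unknown PT {assoc.pt!r}")
        total = sum(self.outcome_distribution.values())
        if total > 1.0 + 1e-9:
            raise ValueError("outcome probabilities sum above 1")
        unknown = set(self.outcome_distribution) - OUTCOME_CODES
        if unknown:
            raise ValueError(f"unknown outcome codes {sorted(unknown)}")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        if "drugs" in data:
            data["drugs"] = tuple(
                DrugSpec(d["name"], tuple(d["synonyms"]), float(d["exposure"]))
                for d in data["drugs"]
            )
        if "pts" in data:
            data["pts"] = tuple(
                PtSpec(p["pt"], p["soc"], float(p["baseline"])) for p in data["pts"]
            )
        if "associations" in data:
            data["associations"] = tuple(
                Association(a["drug"], a["pt"], float(a["rho"]))
                for a in data["associations"]
            )
        if "tto_lognormal" in data:
            data["tto_lognormal"] = {
                k: tuple(v) for k, v in data["tto_lognormal"].items()
            }
        return cls(**data)


@dataclass
class SimData:
    """Generated record collections plus the ground-truth manifest."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    manifest: dict


def recovery_config(rho: float, seed: int, n_cases: int = 50_000) -> SimConfig:
    """Benchmark scenario for effect-size recovery.

    A single injected association at reporting-rate ratio ``rho`` on a drug
    with exposure marginal 0.1 and an event with baseline probability 0.01,
    the rest of the cohort left at its defaults.
    """
    drugs = tuple(
        dataclasses.replace(d, exposure=0.1) if d.name == "TDM-1" else d
        for d in DEFAULT_DRUGS
    )
    return SimConfig(
        n_cases=n_cases,
        drugs=drugs,
        associations=(Association("TDM-1", "Platelet count decreased", rho),),
        seed=seed,
    )


def default_drug_dictionary():
    """Drug dictionary matching the default synthetic drug catalog."""
    from .faers_io import DrugDictionary

    return DrugDictionary({d.name: d.synonyms for d in DEFAULT_DRUGS})


def default_vocabulary():
    """PT -> SOC vocabulary matching the default synthetic PT catalog."""
    from .faers_io import Vocabulary

    return Vocabulary({p.pt: p.soc for p in DEFAULT_PTS})


_EPOCH = np.datetime64("2004-01-01")
_SPAN_DAYS = 6664  # through 2022-03-31


def _partial_dates(
    offsets: np.ndarray,
    missing: np.ndarray,
    day_missing: np.ndarray,
) -> list[PartialDate | None]:
    """Convert day offsets from the epoch into PartialDate objects."""
    stamps = pd.DatetimeIndex(_EPOCH + offsets.astype("timedelta64[D]"))
    years, months, days = stamps.year, stamps.month, stamps.day
    out: list[PartialDate | None] = []
    for i in range(len(offsets)):
        if missing[i]:
            out.append(None)
        elif day_missing[i]:
            out.append(PartialDate(int(years[i]), int(months[i])))
        else:
            out.append(PartialDate(int(years[i]), int(months[i]), int(days[i])))
    return out


def generate(config: SimConfig) -> SimData:
    """Generate the five FAERS-style collections plus a truth manifest.

    All randomness flows from one generator seeded by ``config.seed``, so a
    given configuration reproduces byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    schemas = {name: list(SCHEMAS[name].columns) for name in SCHEMAS}
    if n == 0:
        empty = {
            name: pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            for name, cols in schemas.items()
        }
        manifest = _manifest(config, duplicates=0, exposure_counts={})
        return SimData(
            empty["DEMO"], empty["DRUG"], empty["REAC"], empty["OUTC"], empty["THER"], manifest
        )

    drug_names = [d.name for d in config.drugs]
    exposure_p = np.array([d.exposure for d in config.drugs])
    n_drugs = len(drug_names)

    # --- exposures -------------------------------------------------------
    exposed = rng.random((n, n_drugs)) < exposure_p[None, :]
    poly = rng.random(n) < config.polypharmacy_rate
    deficit = poly & (exposed.sum(axis=1) < 2)
    for i in np.flatnonzero(deficit):
        absent = np.flatnonzero(~exposed[i])
        need = 2 - int(exposed[i].sum())
        picks = rng.choice(absent, size=need, replace=False)
        exposed[i, picks] = True

    # --- reactions -------------------------------------------------------
    baselines = np.array([p.baseline for p in config.pts])
    probs = np.tile(baselines, (n, 1))
    pt_index = {p.pt: k for k, p in enumerate(config.pts)}
    drug_index = {d: j for j, d in enumerate(drug_names)}
    for assoc in config.associations:
        j, k = drug_index[assoc.drug], pt_index[assoc.pt]
        probs[exposed[:, j], k] *= assoc.rho
    np.clip(probs, 0.0, 1.0, out=probs)
    reported = rng.random((n, len(config.pts))) < probs

    # --- identifiers and dates ------------------------------------------
    caseids = 10_000_000 + np.arange(n, dtype=np.int64)
    primaryids = caseids * 10 + 1
    start_offsets = rng.integers(0, _SPAN_DAYS - 400, size=n)

    first_drug = np.argmax(exposed, axis=1)  # first exposed column
    any_exposed = exposed.any(axis=1)
    mu_by_drug = np.array(
        [config.tto_lognormal.get(d, FALLBACK_TTO_LOGNORMAL)[0] for d in drug_names]
    )
    sigma_by_drug = np.array(
        [config.tto_lognormal.get(d, FALLBACK_TTO_LOGNORMAL)[1] for d in drug_names]
    )
    mus = np.where(any_exposed, mu_by_drug[first_drug], FALLBACK_TTO_LOGNORMAL[0])
    sigmas = np.where(any_exposed, sigma_by_drug[first_drug], FALLBACK_TTO_LOGNORMAL[1])
    intervals = rng.lognormal(mus, sigmas)
    event_offsets = start_offsets + np.ceil(intervals).astype(np.int64)
    fda_offsets = event_offsets + rng.integers(0, 90, size=n)

    event_missing = rng.random(n) < config.event_missing_rate
    event_day_missing = rng.random(n) < config.day_missing_rate
    fda_day_missing = np.zeros(n, dtype=bool)  # FDA receipt dates are complete

    # --- demographics ----------------------------------------------------
    ages = np.round(np.clip(rng.normal(58.0, 13.0, size=n), 18, 95))
    age_missing = rng.random(n) < config.age_missing_rate
    age_in_decades = rng.random(n) < 0.05
    sex_draw = rng.random(n)
    countries = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)

    never = np.zeros(n, dtype=bool)
    fda_dates = _partial_dates(fda_offsets, never, fda_day_missing)
    event_dates = _partial_dates(event_offsets, event_missing, event_day_missing)

    demo_rows = {
        "primaryid": primaryids,
        "caseid": caseids,
        "fda_dt": fda_dates,
        "event_dt": event_dates,
        "age": [
            None if m else (a / 10.0 if d else a)
            for a, m, d in zip(ages, age_missing, age_in_decades)
        ],
        "age_cod": [
            None if m else ("DEC" if d else "YR")
            for m, d in zip(age_missing, age_in_decades)
        ],
        "sex": np.where(sex_draw < 0.80, "F", np.where(sex_draw < 0.95, "M", "unknown")),
        "country": countries,
    }
    demo = pd.DataFrame(demo_rows, columns=schemas["DEMO"])

    # --- drug and therapy rows ------------------------------------------
    pairs = np.argwhere(exposed)  # sorted by case, then drug column
    i_arr, j_arr = pairs[:, 0], pairs[:, 1]
    n_pairs = len(pairs)
    synonym_pick = rng.random(n_pairs)
    misname = rng.random(n_pairs) < config.misname_rate
    has_prod_ai = rng.random(n_pairs) < config.prod_ai_rate
    stagger = rng.integers(0, 90, size=n_pairs)
    start_missing = rng.random(n_pairs) < config.start_missing_rate
    start_day_missing = rng.random(n_pairs) < config.day_missing_rate

    bg = rng.random((n, len(BACKGROUND_DRUGS))) < config.background_drug_rate
    forced_bg = rng.integers(0, len(BACKGROUND_DRUGS), size=n)  # PS for unexposed

    # per-case sequence numbers for the target rows (pairs are case-sorted)
    if n_pairs:
        _, first_idx, pair_counts = np.unique(
            i_arr, return_index=True, return_counts=True
        )
        seq = np.arange(n_pairs) - np.repeat(first_idx, pair_counts) + 1
    else:
        seq = np.zeros(0, dtype=np.int64)
    n_target = np.zeros(n, dtype=np.int64)
    np.add.at(n_target, i_arr, 1)

    syn_lists = [d.synonyms for d in config.drugs]
    names = [
        "UNKNOWN TABLET" if m else syn_lists[j][int(p * len(syn_lists[j]))]
        for j, p, m in zip(j_arr, synonym_pick, misname)
    ]
    upper = [d.name.upper() for d in config.drugs]
    prod_ais = [
        upper[j] if (m or ai) else None
        for j, m, ai in zip(j_arr, misname, has_prod_ai)
    ]
    target_offsets = start_offsets[i_arr] + np.where(seq == 1, 0, stagger)

    # background co-medication: role C on any case, PS on unexposed cases
    forced = ~any_exposed
    bg_rank = np.cumsum(bg, axis=1)
    bg_pairs = np.argwhere(bg)
    bi, bgcol = bg_pairs[:, 0], bg_pairs[:, 1]
    bg_seq = n_target[bi] + forced[bi].astype(np.int64) + bg_rank[bi, bgcol]
    bg_names = [BACKGROUND_DRUGS[g] for g in bgcol]
    forced_idx = np.flatnonzero(forced)
    forced_seq = n_target[forced_idx] + 1
    forced_names = [BACKGROUND_DRUGS[int(g)] for g in forced_bg[forced_idx]]

    drug_table = pd.DataFrame(
        {
            "primaryid": np.concatenate(
                [primaryids[i_arr], primaryids[forced_idx], primaryids[bi]]
            ),
            "drug_seq": np.concatenate([seq, forced_seq, bg_seq]),
            "role_cod": (
                np.where(seq == 1, "PS", "SS").tolist()
                + ["PS"] * len(forced_idx)
                + ["C"] * len(bi)
            ),
            "drugname": names + forced_names + bg_names,
            "prod_ai": prod_ais + [None] * (len(forced_idx) + len(bi)),
        },
        columns=schemas["DRUG"],
    )
    # stable per-case ordering: targets first, then forced PS, then role C
    drug_table = drug_table.sort_values(
        ["primaryid", "drug_seq"], kind="stable"
    ).reset_index(drop=True)

    start_dates = _partial_dates(target_offsets, start_missing, start_day_missing)
    ther_table = pd.DataFrame(
        {
            "primaryid": primaryids[i_arr],
            "dsg_drug_seq": seq,
            "start_dt": start_dates,
            "end_dt": [None] * n_pairs,
        },
        columns=schemas["THER"],
    )

    # --- reactions and outcomes -----------------------------------------
    reac_pairs = np.argwhere(reported)
    reac_table = pd.DataFrame(
        {
            "primaryid": primaryids[reac_pairs[:, 0]],
            "pt": [config.pts[k].pt for k in reac_pairs[:, 1]],
        },
        columns=schemas["REAC"],
    )

    outcome_codes = list(config.outcome_distribution)
    outcome_p = np.array([config.outcome_distribution[c] for c in outcome_codes])
    cum = np.cumsum(outcome_p)
    idx = np.searchsorted(cum, rng.random(n), side="right")
    has_outcome = idx < len(outcome_codes)
    outc_table = pd.DataFrame(
        {
            "primaryid": primaryids[has_outcome],
            "outc_cod": [outcome_codes[k] for k in idx[has_outcome]],
        },
        columns=schemas["OUTC"],
    )

    # --- duplicate report versions --------------------------------------
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_indices = np.flatnonzero(dup_mask)
    dup_later = rng.random(len(dup_indices)) < 0.5
    dup_delay = rng.integers(1, 120, size=len(dup_indices))
    if len(dup_indices):
        dup_pids = caseids[dup_indices] * 10 + 2
        dup_fda_offsets = fda_offsets[dup_indices] + np.where(dup_later, dup_delay, 0)
        dup_fda = _partial_dates(
            dup_fda_offsets,
            np.zeros(len(dup_indices), dtype=bool),
            np.zeros(len(dup_indices), dtype=bool),
        )
        dup_demo = demo.iloc[dup_indices].copy()
        dup_demo["primaryid"] = dup_pids
        dup_demo["fda_dt"] = dup_fda
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        remap = dict(zip(primaryids[dup_indices].tolist(), dup_pids.tolist()))

        def clone_children(table: pd.DataFrame) -> pd.DataFrame:
            mask = table["primaryid"].isin(remap)
            if not mask.any():
                return table
            extra = table.loc[mask].copy()
            extra["primaryid"] = extra["primaryid"].map(remap)
            return pd.concat([table, extra], ignore_index=True)

        drug_table = clone_children(drug_table)
        reac_table = clone_children(reac_table)
        outc_table = clone_children(outc_table)
        ther_table = clone_children(ther_table)

    exposure_counts = {
        name: int(exposed[:, j].sum()) for j, name in enumerate(drug_names)
    }
    manifest = _manifest(config, duplicates=int(dup_mask.sum()), exposure_counts=exposure_counts)
    return SimData(demo, drug_table, reac_table, outc_table, ther_table, manifest)


def _manifest(config: SimConfig, duplicates: int, exposure_counts: dict) -> dict:
    return {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_duplicates": duplicates,
        "exposure_counts": exposure_counts,
        "injected_associations": [
            {"drug": a.drug, "pt": a.pt, "rho": a.rho} for a in config.associations
        ],
    }


def write_faers_files(
    data: SimData, directory: str | Path, delimiter: str = "$"
) -> dict[str, Path]:
    """Write the five tables plus the manifest; round-trippable via parse_table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        "DEMO": data.demo,
        "DRUG": data.drug,
        "REAC": data.reac,
        "OUTC": data.outc,
        "THER": data.ther,
    }
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = directory / f"{name}.txt"
        try:
            write_table(table, path, name, delimiter=delimiter)
        except OSError as exc:  # pragma: no cover - I/O failure surface
            raise OSError(f"failed writing {path}: {exc}") from exc
        paths[name] = path
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(data.manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
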