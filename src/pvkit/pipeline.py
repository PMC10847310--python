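"""End-to-end pipeline: parse -> deduplicate -> assemble -> classify ->
signal screen and event analyses, with diffable tabular outputs.

Every analysis constant (signal thresholds, event term lists, month length,
background choice) lives in :class:`PipelineConfig`, loadable from YAML or
JSON.  All report tables are written sorted on stable keys so two runs on
identical inputs produce identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cleaning, event_analysis, faers_io, signal_detection
from .event_analysis import DAYS_PER_MONTH, EventTerms
from .synthetic_data import default_drug_dictionary, default_vocabulary

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "diff_reports", "DiffResult"]

logger = logging.getLogger("pvkit")

REPORT_FILES = (
    "signals.csv",
    "characteristics.csv",
    "overlap.csv",
    "tto.csv",
    "tests.json",
    "run_log.json",
)


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    drug_dictionary: str | Path | None = None  # TSV; default synthetic catalog
    vocabulary: str | Path | None = None       # TSV; default synthetic catalog
    targets: tuple[str, ...] = ()              # default: all dictionary ingredients
    min_cases: int = 4
    background: str = "all"
    soc_screen: str | None = "Nervous system disorders"
    days_per_month: float = DAYS_PER_MONTH
    delimiter: str = "$"
    terms: EventTerms = field(default_factory=EventTerms)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from YAML (or JSON, a YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        terms = raw.pop("terms", None)
        config = cls(**raw)
        if terms:
            config.terms = EventTerms(
                hemorrhage_whitelist=frozenset(
                    terms.get("hemorrhage_whitelist", event_analysis.DEFAULT_HEMORRHAGE_WHITELIST)
                ),
                intracranial=frozenset(
                    terms.get("intracranial", event_analysis.DEFAULT_INTRACRANIAL_PTS)
                ),
                thrombocytopenia=frozenset(
                    terms.get("thrombocytopenia", event_analysis.DEFAULT_THROMBOCYTOPENIA_PTS)
                ),
            )
        return config


@dataclass
class ReportBundle:
    """Paths and stage counts of one completed pipeline run."""

    output_dir: Path
    counts: dict[str, int]
    paths: dict[str, Path]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and counts so far."""

    def __init__(self, stage: str, counts: dict[str, int], cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.counts = counts


def _load_tables(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    input_dir = Path(config.input_dir)
    tables = {}
    for name in ("DEMO", "DRUG", "REAC", "OUTC", "THER"):
        candidates = [input_dir / f"{name}.txt", input_dir / f"{name.lower()}.txt"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"missing {name} table in {input_dir}")
        tables[name] = faers_io.parse_table(path, name, delimiter=config.delimiter).records
    return tables


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Outputs: ``signals.csv`` (disproportionality screen, optionally with a
    SOC-restricted section), ``characteristics.csv`` (characteristic table
    of hemorrhagic cases), ``overlap.csv`` (hemorrhage/thrombocytopenia
    overlap per drug), ``tto.csv`` (time-to-onset long table),
    ``tests.json`` (hypothesis tests) and ``run_log.json`` (record counts
    at every stage).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    counts: dict[str, int] = {}
    stage = "load"
    try:
        tables = _load_tables(config)
        counts["demo_parsed"] = len(tables["DEMO"])
        counts["drug_parsed"] = len(tables["DRUG"])
        counts["reac_parsed"] = len(tables["REAC"])

        stage = "dictionaries"
        dictionary = (
            faers_io.load_drug_dictionary(config.drug_dictionary)
            if config.drug_dictionary
            else default_drug_dictionary()
        )
        vocabulary = (
            faers_io.load_vocabulary(config.vocabulary)
            if config.vocabulary
            else default_vocabulary()
        )
        targets = list(config.targets) or dictionary.ingredients

        stage = "deduplicate"
        demo = cleaning.deduplicate(tables["DEMO"])
        counts["demo_deduplicated"] = len(demo)

        stage = "filter_suspect"
        drug = cleaning.filter_suspect(tables["DRUG"], dictionary)
        counts["drug_exposure_rows"] = int(drug["is_exposure"].sum())

        stage = "assemble"
        cases = cleaning.assemble_cases(
            demo, drug, tables["REAC"], tables["OUTC"], tables["THER"], dictionary
        )
        counts["cases_assembled"] = len(cases)

        stage = "classify_regimen"
        cases = cleaning.add_regimens(cases)
        regimen_counts = cases["regimen_kind"].value_counts()
        counts["cases_monotherapy"] = int(regimen_counts.get("monotherapy", 0))
        counts["cases_combination"] = int(regimen_counts.get("combination", 0))
        counts["cases_unexposed"] = int(regimen_counts.get("none", 0))

        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        stage = "screen_signals"
        signals = signal_detection.screen_signals(
            cases,
            drugs=targets,
            vocabulary=vocabulary,
            min_cases=config.min_cases,
            background=config.background,
        )
        if config.soc_screen:
            soc_signals = signal_detection.screen_signals(
                cases,
                drugs=targets,
                vocabulary=vocabulary,
                soc=config.soc_screen,
                min_cases=config.min_cases,
                background=config.background,
            )
            soc_signals = soc_signals.assign(screen=config.soc_screen)
            signals = pd.concat(
                [signals.assign(screen="all"), soc_signals], ignore_index=True
            )
        else:
            signals = signals.assign(screen="all")
        signals = signals.sort_values(
            ["screen", "drug", "soc", "pt"], kind="stable", na_position="last"
        ).reset_index(drop=True)
        paths["signals"] = out_dir / "signals.csv"
        signals.to_csv(paths["signals"], index=False, float_format="%.10g")
        counts["signal_pairs"] = len(signals)
        counts["signals_flagged"] = int(signals["signal"].sum()) if len(signals) else 0

        stage = "characteristics"
        is_hem, is_ich, is_tcp = event_analysis._case_flags(cases, config.terms)
        hem_cases = cases.loc[is_hem]
        counts["cases_hemorrhagic"] = len(hem_cases)
        characteristics = event_analysis.summarize_characteristics(
            hem_cases, vocabulary=vocabulary, terms=config.terms
        )
        paths["characteristics"] = out_dir / "characteristics.csv"
        characteristics.to_csv(paths["characteristics"], index=False)

        stage = "overlap"
        overlap = event_analysis.overlap_analysis(cases, drugs=targets, terms=config.terms)
        paths["overlap"] = out_dir / "overlap.csv"
        overlap.to_csv(paths["overlap"], index=False, float_format="%.10g")

        stage = "time_to_onset"
        tto = event_analysis.tto_table(
            cases, drugs=targets, terms=config.terms, days_per_month=config.days_per_month
        )
        tto = tto.sort_values(["drug", "caseid"], kind="stable").reset_index(drop=True)
        paths["tto"] = out_dir / "tto.csv"
        tto.to_csv(paths["tto"], index=False, float_format="%.10g")
        counts["tto_observations"] = len(tto)

        stage = "tests"
        tests = _hypothesis_tests(cases, tto, overlap, is_hem, is_tcp)
        paths["tests"] = out_dir / "tests.json"
        paths["tests"].write_text(json.dumps(tests, indent=2, sort_keys=True) + "\n")

        stage = "run_log"
        paths["run_log"] = out_dir / "run_log.json"
        paths["run_log"].write_text(json.dumps(counts, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        logger.error("pipeline failed at %s with counts %s", stage, counts)
        raise PipelineError(stage, counts, exc) from exc

    return ReportBundle(out_dir, counts, paths)


def _result_dict(result: event_analysis.TestResult) -> dict:
    return {
        "method": result.method,
        "statistic": result.statistic,
        "df": result.df,
        "p_value": result.p_value,
    }


def _hypothesis_tests(cases, tto, overlap, is_hem, is_tcp) -> dict:
    """The paper-style comparisons, on whatever the data supports."""
    tests: dict = {}

    # thrombocytopenia x hemorrhage association among hemorrhagic cases of
    # the drug with the largest overlap versus all other exposed cases
    flagged = overlap.dropna(subset=["pct_hemorrhage_with_thrombocytopenia"])
    if len(flagged) >= 2:
        top = flagged.sort_values(
            "pct_hemorrhage_with_thrombocytopenia", ascending=False
        ).iloc[0]
        others = flagged[flagged["drug"] != top["drug"]].sum(numeric_only=True)
        table = [
            [int(top["both"]), int(top["hemorrhage_only"])],
            [int(others["both"]), int(others["hemorrhage_only"])],
        ]
        if all(sum(r) > 0 for r in table) and all(
            table[0][j] + table[1][j] > 0 for j in (0, 1)
        ):
            result = event_analysis.chi_square(table)
            tests["thrombocytopenia_overlap_chi_square"] = {
                "drug": str(top["drug"]),
                **_result_dict(result),
            }

    # time to onset: monotherapy versus combination, and across drugs
    if len(tto):
        mono = tto.loc[tto["regimen_kind"] == "monotherapy", "months"].tolist()
        combo = tto.loc[tto["regimen_kind"] == "combination", "months"].tolist()
        if mono and combo:
            medians, result = event_analysis.median_tto_comparison(
                {"monotherapy": mono, "combination": combo}
            )
            tests["tto_mono_vs_combination"] = {
                "medians": medians,
                **_result_dict(result),
            }
        by_drug = {
            drug: grp["months"].tolist()
            for drug, grp in tto.groupby("drug")
            if len(grp) >= 3
        }
        if len(by_drug) >= 2:
            medians, result = event_analysis.median_tto_comparison(by_drug)
            tests["tto_across_drugs"] = {"medians": medians, **_result_dict(result)}
    return tests


@dataclass
class DiffResult:
    equal: bool
    differences: list[str]


def diff_reports(
    dir_a: str | Path, dir_b: str | Path, tolerance: float = 1e-9
) -> DiffResult:
    """Cell-level comparison of two report bundles.

    Numeric cells compare within ``tolerance``; a missing file, extra row
    or schema mismatch is a structural difference.
    """
    dir_a, dir_b = Path(dir_a), Path(dir_b)
    differences: list[str] = []
    for name in REPORT_FILES:
        a, b = dir_a / name, dir_b / name
        if a.exists() != b.exists():
            differences.append(f"{name}: present in one bundle only")
            continue
        if not a.exists():
            continue
        if name.endswith(".json"):
            if json.loads(a.read_text()) != json.loads(b.read_text()):
                differences.append(f"{name}: JSON content differs")
            continue
        fa, fb = pd.read_csv(a), pd.read_csv(b)
        if list(fa.columns) != list(fb.columns):
            differences.append(f"{name}: column sets differ")
            continue
        if len(fa) != len(fb):
            differences.append(f"{name}: row counts differ ({len(fa)} vs {len(fb)})")
            continue
        for col in fa.columns:
            xa, xb = fa[col], fb[col]
            if pd.api.types.is_numeric_dtype(xa) and pd.api.types.is_numeric_dtype(xb):
                both_nan = xa.isna() & xb.isna()
                close = np.isclose(
                    xa.fillna(0), xb.fillna(0), rtol=0, atol=tolerance
                ) | both_nan
                if not close.all():
                    rows = list(np.flatnonzero(~close))[:3]
                    differences.append(f"{name}: column {col!r} differs at rows {rows}")
            else:
                same = (xa.fillna("") == xb.fillna("")).all()
                if not same:
                    differences.append(f"{name}: column {col!r} differs")
    return DiffResult(not differences, differences)
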