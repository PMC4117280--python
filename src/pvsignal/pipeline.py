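"""End-to-end, year-stratified disproportionality analysis.

read (or simulate) → restrict to initial reports → resolve drug names →
build 2×2 tables per term group and period → PRR / χ² / Fisher / CIs →
Evans signal classification → tabular report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dedup import DedupMode, select_initial_reports
from .io import FileDialect, read_quarter
from .records import ReportDatabase
from .stats import (
    DisproportionalityResult,
    SignalCriteria,
    analyze_table,
    build_contingency,
    format_chi2,
    format_prr,
)
from .synthetic import SyntheticConfig, simulate_database
from .vocabulary import (
    DEFAULT_MAX_EDIT_DISTANCE,
    INGREDIENTS,
    DrugLexicon,
    TermGroup,
    build_default_lexicon,
    build_default_term_groups,
    load_lexicon,
    load_term_groups,
)

logger = logging.getLogger(__name__)


class AnalysisConfig(BaseModel):
    """Configuration of one pipeline run.

    Inputs come either from quarter directories on disk (``input_dirs``) or
    from the synthetic generator (``synthetic``); exactly one must be set.
    """

    model_config = ConfigDict(frozen=True)

    input_dirs: tuple[str, ...] | None = None
    synthetic: SyntheticConfig | None = None
    periods: tuple[str, ...] = ("2004", "2007")
    ingredients: tuple[str, ...] = INGREDIENTS
    term_groups_file: str | None = None
    lexicon_file: str | None = None
    dedup_mode: DedupMode = "paper"
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE
    min_cases: int = 3
    min_prr: float = 2.0
    min_chi2: float = 4.0
    ci_level: float = 0.95
    field_delimiter: str = "$"
    date_format: str = "%Y%m%d"

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if (self.input_dirs is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dirs and synthetic must be set")
        if not self.periods:
            raise ValueError("at least one period required")
        if not self.ingredients:
            raise ValueError("ingredient set must be non-empty")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def criteria(self) -> SignalCriteria:
        return SignalCriteria(self.min_cases, self.min_prr, self.min_chi2)

    def dialect(self) -> FileDialect:
        return FileDialect(field_delimiter=self.field_delimiter, date_format=self.date_format)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class ReportRow:
    """One term-group × period cell of the analysis report."""

    group_id: str
    period: str
    evaluable: bool
    result: DisproportionalityResult | None  # None when not evaluable


@dataclass
class AnalysisReport:
    rows: list[ReportRow]
    stage_counts: dict
    config_hash: str

    def row(self, group_id: str, period: str) -> ReportRow:
        return next(r for r in self.rows if r.group_id == group_id and r.period == period)

    def to_dataframe(self) -> pd.DataFrame:
        out = []
        for r in self.rows:
            if r.result is None:
                out.append(
                    {
                        "group": r.group_id, "period": r.period, "evaluable": False,
                        "a": 0, "b": 0, "prr": "-", "ci_low": "-", "ci_high": "-",
                        "ci_method": "-", "chi2_yates": "-", "fisher_p": "-", "signal": False,
                    }
                )
                continue
            res = r.result
            ci = res.ci or res.ci_exact
            out.append(
                {
                    "group": r.group_id,
                    "period": r.period,
                    "evaluable": True,
                    "a": res.table.a,
                    "b": res.table.b,
                    "prr": format_prr(res.prr),
                    "ci_low": f"{ci.low:.1f}" if ci else "-",
                    "ci_high": f"{ci.high:.1f}" if ci and math.isfinite(ci.high) else
                               ("inf" if ci else "-"),
                    "ci_method": ci.method if ci else "-",
                    "chi2_yates": format_chi2(res.chi2_yates),
                    "fisher_p": f"{res.fisher_p:.3g}",
                    "signal": res.signal,
                }
            )
        return pd.DataFrame(out)

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)

    def metadata(self) -> dict:
        return {"config_hash": self.config_hash, "stage_counts": self.stage_counts}


def _load_inputs(config: AnalysisConfig) -> ReportDatabase:
    if config.synthetic is not None:
        db, _ = simulate_database(config.synthetic)
        return db
    records = []
    dialect = config.dialect()
    for directory in config.input_dirs or ():
        db, summary = read_quarter(directory, dialect)
        logger.info(
            "read %s: %d parsed, %d skipped, %d orphan rows",
            directory, summary.records_parsed, summary.records_skipped,
            summary.orphan_drug_rows + summary.orphan_reaction_rows,
        )
        records.extend(db.records)
    return ReportDatabase(records)


def run_analysis(
    config: AnalysisConfig,
    lexicon: DrugLexicon | None = None,
    term_groups: Sequence[TermGroup] | None = None,
    database: ReportDatabase | None = None,
) -> AnalysisReport:
    """Run the full analysis and return one row per (term group, period).

    Pooled inputs are deduplicated to initial reports first, then split by
    receipt year into the configured periods, each analyzed independently
    with its own denominator.  Non-evaluable groups (no vocabulary terms)
    produce dash rows rather than errors.  Deterministic given the config
    (plus its seed for synthetic inputs); ``database`` overrides input
    loading for programmatic use.
    """
    if lexicon is None:
        lexicon = load_lexicon(config.lexicon_file) if config.lexicon_file else build_default_lexicon()
    if term_groups is None:
        term_groups = (
            load_term_groups(config.term_groups_file)
            if config.term_groups_file
            else build_default_term_groups()
        )
    criteria = config.criteria()

    raw = database if database is not None else _load_inputs(config)
    initial = select_initial_reports(raw, mode=config.dedup_mode)
    n_raw, n_initial = len(raw), len(initial)
    logger.info("dedup: %d raw reports -> %d initial (%d excluded)", n_raw, n_initial, n_raw - n_initial)

    stage_counts: dict = {
        "raw_reports": n_raw,
        "initial_reports": n_initial,
        "excluded_reports": n_raw - n_initial,
        "periods": {},
    }
    assert stage_counts["raw_reports"] == stage_counts["initial_reports"] + stage_counts["excluded_reports"]

    ingredients = frozenset(config.ingredients)
    rows: list[ReportRow] = []
    n_evaluable = sum(g.evaluable for g in term_groups)
    if n_evaluable == 0:
        logger.warning("no evaluable term group; emitting an all-dash report")
    for period in config.periods:
        period_db = initial.subset(lambda r, p=period: r.period_label == p)
        stage_counts["periods"][period] = {"n_reports": len(period_db), "cases": {}}
        for group in term_groups:
            if not group.evaluable:
                rows.append(ReportRow(group.group_id, period, False, None))
                stage_counts["periods"][period]["cases"][group.group_id] = None
                continue
            table = build_contingency(
                period_db, ingredients, group, lexicon, config.max_edit_distance
            )
            result = analyze_table(table, criteria, config.ci_level)
            stage_counts["periods"][period]["cases"][group.group_id] = table.case_total
            rows.append(ReportRow(group.group_id, period, True, result))
    return AnalysisReport(rows=rows, stage_counts=stage_counts, config_hash=config.config_hash())


def run_reference_analysis() -> AnalysisReport:
    """Run the pipeline on the bundled published-count fixture databases."""
    from .reference import REFERENCE_COUNTS, build_reference_database

    records = []
    for period in REFERENCE_COUNTS:
        records.extend(build_reference_database(period).records)
    config = AnalysisConfig(
        synthetic=SyntheticConfig(n_reports_per_period=0, random_seed=0),
        periods=tuple(REFERENCE_COUNTS),
    )
    return run_analysis(config, database=ReportDatabase(records))
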