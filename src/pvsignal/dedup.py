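"""Restriction to initial reports.

Spontaneous reporting systems allow any number of follow-up reports per
case, and the same reaction may be re-reported for the same person each
time.  Counting every report would therefore inflate reporting frequencies,
so the analysis keeps exactly one report per case: the initial one.
"""

from __future__ import annotations

import logging
from typing import Literal

from .records import ReportDatabase, ReportRecord

logger = logging.getLogger(__name__)

DedupMode = Literal["paper", "retain-earliest"]


def _sort_key(rec: ReportRecord) -> tuple:
    return (rec.receipt_date, rec.report_id)


def select_initial_reports(db: ReportDatabase, mode: DedupMode = "paper") -> ReportDatabase:
    """Keep at most one report per case.

    For every case the record flagged initial (sequence 0) is kept; among
    several initial-flagged records the earliest receipt date wins, ties
    broken by the lexicographically smallest report_id.  Cases with *no*
    initial record carry information only in follow-ups:

    * ``mode="paper"`` (default) drops such cases — follow-up content never
      enters the analysis;
    * ``mode="retain-earliest"`` keeps the case's earliest follow-up
      instead.

    Idempotent in both modes.
    """
    if mode not in ("paper", "retain-earliest"):
        raise ValueError(f"unknown dedup mode: {mode!r}")

    by_case: dict[str, list[ReportRecord]] = {}
    for rec in db:
        by_case.setdefault(rec.case_id, []).append(rec)

    kept: list[ReportRecord] = []
    dropped_cases = 0
    for case_id, recs in by_case.items():
        initials = [r for r in recs if r.is_initial]
        if initials:
            kept.append(min(initials, key=_sort_key))
        elif mode == "retain-earliest":
            logger.warning("case %r has no initial report; retaining earliest follow-up", case_id)
            kept.append(min(recs, key=_sort_key))
        else:
            dropped_cases += 1
            logger.warning("case %r has no initial report; dropped (paper mode)", case_id)
    if dropped_cases:
        logger.info("dedup dropped %d case(s) without an initial report", dropped_cases)
    return ReportDatabase(kept)
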